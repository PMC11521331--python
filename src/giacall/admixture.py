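"""Supervised admixture: EM estimation of a query's ancestry fractions.

Population allele frequencies F are fixed from the labeled reference panel
(the single query contributes nothing to F), leaving a one-sample maximum
likelihood problem for the fraction vector q on the simplex:

    l(q) = sum_j [ g_j ln(sum_k q_k f_kj) + (2 - g_j) ln(sum_k q_k (1 - f_kj)) ]

maximized by the standard EM update from the uniform start.  The Oceania
population is excluded by default (K = 7 when all eight populations are
present) because its inclusion biases every query toward a nonzero Oceania
fraction; the exclusion set is configurable.  The discrete call is the
unique population whose fraction strictly exceeds the majority threshold
(default 0.54), else NO_MAJORITY.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import NO_MAJORITY
from .config import WorkflowConfig
from .errors import ContractError
from .genotype_io import ReferencePanel

#: Frequencies are clipped to [EPS, 1 - EPS] to avoid -inf log-likelihoods.
EPS = 1e-6


@dataclass
class AdmixtureModel:
    """Fixed per-population alt-allele frequencies (K populations x J loci)."""

    populations: list[str]
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.ndim != 2 or self.freqs.shape[0] != len(self.populations):
            raise ContractError("freqs must be (n_populations, n_variants)")
        if np.any((self.freqs <= 0) | (self.freqs >= 1)):
            raise ContractError("frequencies must lie strictly in (0, 1)")


@dataclass
class AdmixtureResult:
    """Estimated fraction vector with its log-likelihood trace."""

    fractions: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        if abs(float(self.fractions.sum()) - 1.0) > 1e-9 or np.any(
                self.fractions < -1e-12):
            raise ContractError("fractions must lie on the simplex")


def fit_model(panel: ReferencePanel, cfg: WorkflowConfig) -> AdmixtureModel:
    """Estimate per-population allele frequencies from the reference panel.

    Populations in ``cfg.excluded_admixture_pops`` are omitted; every
    remaining population must have at least two samples.
    """
    labels = panel.label_array()
    pops = [p for p in sorted(set(labels.tolist()))
            if p not in cfg.excluded_admixture_pops]
    if not pops:
        raise ContractError("no populations left after exclusion")
    rows = []
    for pop in pops:
        mask = labels == pop
        if int(mask.sum()) < 2:
            raise ContractError(
                f"population {pop} has < 2 reference samples")
        f = panel.genotypes.dosages[mask].astype(np.float64).mean(axis=0) / 2.0
        rows.append(np.clip(f, EPS, 1.0 - EPS))
    return AdmixtureModel(populations=pops, freqs=np.stack(rows))


def _loglik(q: np.ndarray, f: np.ndarray, g: np.ndarray) -> float:
    a = q @ f
    b = q @ (1.0 - f)
    return float(g @ np.log(a) + (2.0 - g) @ np.log(b))


def em_fractions(g: np.ndarray, model: AdmixtureModel,
                 cfg: WorkflowConfig) -> AdmixtureResult:
    """Maximize the admixture likelihood for one query by EM.

    Starts at the uniform fraction vector; stops when the log-likelihood
    improves by less than ``cfg.admixture_tol`` or after
    ``cfg.admixture_max_iter`` updates.  The trace records the
    log-likelihood at every evaluated iterate, and is non-decreasing by
    the EM ascent property.
    """
    g = np.asarray(g, dtype=np.float64)
    if g.ndim != 1 or g.size < 1:
        raise ContractError("query dosage vector must be 1-D and non-empty")
    if not np.all(np.isin(g, (0.0, 1.0, 2.0))):
        raise ContractError("query dosages must be in {0, 1, 2} (no missing)")
    f = model.freqs
    k, j = f.shape
    if g.size != j:
        raise ContractError("query length must match model variants")
    if k == 1:
        return AdmixtureResult(fractions=np.array([1.0]),
                               loglik_trace=[_loglik(np.array([1.0]), f, g)],
                               converged=True, n_iter=0)
    q = np.full(k, 1.0 / k)
    trace = [_loglik(q, f, g)]
    converged = False
    n_iter = 0
    one_minus_f = 1.0 - f
    for n_iter in range(1, cfg.admixture_max_iter + 1):
        a = q @ f
        b = q @ one_minus_f
        q = q * (f @ (g / a) + one_minus_f @ ((2.0 - g) / b)) / (2.0 * j)
        q = np.clip(q, 0.0, None)
        q /= q.sum()
        trace.append(_loglik(q, f, g))
        if trace[-1] - trace[-2] < cfg.admixture_tol:
            converged = True
            break
    return AdmixtureResult(fractions=q, loglik_trace=trace,
                           converged=converged, n_iter=n_iter)


def discrete_admixture_call(r: AdmixtureResult, model: AdmixtureModel,
                            cfg: WorkflowConfig) -> str:
    """The unique population with fraction strictly > the majority
    threshold, else NO_MAJORITY."""
    over = np.flatnonzero(r.fractions > cfg.majority_threshold)
    if over.size == 1:
        return model.populations[int(over[0])]
    return NO_MAJORITY
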