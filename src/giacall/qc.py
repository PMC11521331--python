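"""Variant- and sample-level quality control.

Implements the workflow's QC stages from first principles:

* allele-frequency summaries and the MAF > 0.1% filter;
* the Hardy-Weinberg exact test with mid-p adjustment (conditional
  distribution of the heterozygote count given the minor-allele count);
* the KING-robust pairwise kinship estimator and greedy relatedness
  pruning at the second-degree cutoff phi > 0.09375;
* configurable sample exclusion (e.g. skewing subpopulations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .config import WorkflowConfig  # noqa: F401  (re-export: config lives here conceptually)
from .errors import ContractError, EmptyOutputError
from .genotype_io import MISSING, GenotypeMatrix, ReferencePanel

logger = logging.getLogger(__name__)

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class KinshipEstimate:
    """KING-robust kinship between one sample pair.

    ``phi`` is NaN when neither sample carries a heterozygote (the
    estimator's denominator vanishes). ``n_informative`` counts loci that
    contribute to either numerator or denominator.
    """

    sample_i: str
    sample_j: str
    phi: float
    n_informative: int


def allele_stats(m: GenotypeMatrix, variant_index: int
                 ) -> tuple[float, float, tuple[int, int, int]]:
    """Alt-allele frequency, MAF and genotype counts for one variant."""
    col = m.dosages[:, variant_index]
    if np.any(col == MISSING):
        raise ContractError("allele_stats requires complete genotypes")
    n0 = int(np.count_nonzero(col == 0))
    n1 = int(np.count_nonzero(col == 1))
    n2 = int(np.count_nonzero(col == 2))
    n = n0 + n1 + n2
    alt_freq = (n1 + 2 * n2) / (2 * n)
    return alt_freq, min(alt_freq, 1.0 - alt_freq), (n0, n1, n2)


def _hwe_log_pmf(n_het_obs: int, rare: int, n: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional pmf of the het count given minor-allele count.

    Returns (het_counts, normalized log-probabilities).  The support is
    every h with the parity of ``rare`` in [0, min(rare, 2n - rare)];
    P(h) ∝ 2^h * n! / (n_hom_major! * h! * n_hom_minor!).
    """
    h = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    n_hom_minor = (rare - h) // 2
    n_hom_major = n - h - n_hom_minor
    logp = (h * _LN2 + gammaln(n + 1) - gammaln(n_hom_major + 1)
            - gammaln(h + 1) - gammaln(n_hom_minor + 1))
    return h, logp - logsumexp(logp)


def hwe_midp(n_refhom: int, n_het: int, n_althom: int) -> float:
    """Mid-p Hardy-Weinberg exact test p-value.

    Sums the probability of every heterozygote-count table less probable
    than the observed one, plus half the probability of tables exactly as
    probable (the observed table included at half weight).  A monomorphic
    variant has a single possible table and returns 0.5.
    """
    if min(n_refhom, n_het, n_althom) < 0:
        raise ContractError("genotype counts must be non-negative")
    n = n_refhom + n_het + n_althom
    if n < 1:
        raise ContractError("at least one genotype required")
    rare = n_het + 2 * min(n_refhom, n_althom)
    h, logp = _hwe_log_pmf(n_het, rare, n)
    log_obs = float(logp[h == n_het][0])
    # classify tables relative to the observed probability in log space;
    # ties are genuine (symmetric tables), compared with a small tolerance
    tol = 1e-10
    below = logp < log_obs - tol
    equal = np.abs(logp - log_obs) <= tol
    p = np.exp(logp)
    return float(p[below].sum() + 0.5 * p[equal].sum())


def hwe_exact_p(n_refhom: int, n_het: int, n_althom: int) -> float:
    """Plain (non-mid-p) exact test: P(tables at most as probable)."""
    if min(n_refhom, n_het, n_althom) < 0:
        raise ContractError("genotype counts must be non-negative")
    n = n_refhom + n_het + n_althom
    rare = n_het + 2 * min(n_refhom, n_althom)
    h, logp = _hwe_log_pmf(n_het, rare, n)
    log_obs = float(logp[h == n_het][0])
    p = np.exp(logp)
    return float(min(1.0, p[logp <= log_obs + 1e-10].sum()))


def king_robust(g_i: np.ndarray, g_j: np.ndarray,
                sample_i: str = "i", sample_j: str = "j") -> KinshipEstimate:
    """KING-robust within-family kinship estimator.

    phi = (N_both_het - 2 * N_opposite_hom) / (N_het_i + N_het_j).
    Robust to population structure; 0.5 for duplicates, ~0.25 for
    first-degree relatives, ~0 for unrelated pairs.
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    if g_i.shape != g_j.shape:
        raise ContractError("dosage vectors must have equal length")
    het_i = g_i == 1
    het_j = g_j == 1
    both_het = int(np.count_nonzero(het_i & het_j))
    opp_hom = int(np.count_nonzero(((g_i == 0) & (g_j == 2))
                                   | ((g_i == 2) & (g_j == 0))))
    n_het_i = int(np.count_nonzero(het_i))
    n_het_j = int(np.count_nonzero(het_j))
    denom = n_het_i + n_het_j
    n_informative = int(np.count_nonzero(het_i | het_j)) + opp_hom
    phi = float("nan") if denom == 0 else (both_het - 2 * opp_hom) / denom
    return KinshipEstimate(sample_i, sample_j, phi, n_informative)


def kinship_matrix(m: GenotypeMatrix) -> np.ndarray:
    """All-pairs KING-robust phi (NaN where undefined), vectorized."""
    het = (m.dosages == 1).astype(np.float64)
    hom0 = (m.dosages == 0).astype(np.float64)
    hom2 = (m.dosages == 2).astype(np.float64)
    both_het = het @ het.T
    opp = hom0 @ hom2.T + hom2 @ hom0.T
    n_het = het.sum(axis=1)
    denom = n_het[:, None] + n_het[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(denom > 0, (both_het - 2 * opp) / denom, np.nan)
    return phi


def prune_related(panel: ReferencePanel, cfg: WorkflowConfig) -> ReferencePanel:
    """Drop samples until no retained pair has phi above the KING cutoff.

    Greedy: repeatedly remove the sample in the most above-threshold
    pairs, breaking ties by lexicographic sample id, so one representative
    of each related cluster survives.
    """
    m = panel.genotypes
    phi = kinship_matrix(m)
    np.fill_diagonal(phi, np.nan)
    over = np.nan_to_num(phi, nan=-1.0) > cfg.king_threshold
    active = np.ones(m.n_samples, dtype=bool)
    removed: list[str] = []
    while True:
        degree = (over & active[None, :] & active[:, None]).sum(axis=1)
        degree[~active] = 0
        if degree.max(initial=0) == 0:
            break
        top = int(degree.max())
        candidates = sorted(np.flatnonzero(degree == top),
                            key=lambda i: m.samples[i])
        victim = candidates[0]
        active[victim] = False
        removed.append(m.samples[victim])
    if removed:
        logger.info("prune_related: removed %d related samples: %s",
                    len(removed), removed)
    kept = [s for i, s in enumerate(m.samples) if active[i]]
    return ReferencePanel(
        genotypes=m.subset_samples(kept),
        labels={s: panel.labels[s] for s in kept},
    )


def variant_filter_mask(m: GenotypeMatrix, cfg: WorkflowConfig
                        ) -> tuple[np.ndarray, int, int]:
    """Boolean keep-mask for MAF and HWE filters plus removal counts."""
    d = m.dosages
    if np.any(d == MISSING):
        raise ContractError("variant filters require complete genotypes")
    n = m.n_samples
    n1 = np.count_nonzero(d == 1, axis=0)
    n2 = np.count_nonzero(d == 2, axis=0)
    alt_freq = (n1 + 2 * n2) / (2 * n)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    maf_pass = maf > cfg.maf_min
    hwe_pass = np.ones(m.n_variants, dtype=bool)
    for j in np.flatnonzero(maf_pass):
        n_het = int(n1[j])
        n_alt = int(n2[j])
        if hwe_midp(n - n_het - n_alt, n_het, n_alt) <= cfg.hwe_p_min:
            hwe_pass[j] = False
    keep = maf_pass & hwe_pass
    n_maf = int(np.count_nonzero(~maf_pass))
    n_hwe = int(np.count_nonzero(maf_pass & ~hwe_pass))
    return keep, n_maf, n_hwe


def apply_variant_filters(m: GenotypeMatrix, cfg: WorkflowConfig
                          ) -> GenotypeMatrix:
    """Retain variants with MAF > maf_min and HWE mid-p > hwe_p_min."""
    keep, n_maf, n_hwe = variant_filter_mask(m, cfg)
    logger.info("variant filters: %d removed by MAF, %d by HWE, %d kept",
                n_maf, n_hwe, int(keep.sum()))
    if not keep.any():
        raise EmptyOutputError("variant filtering")
    return m.subset_variants(np.flatnonzero(keep))


def exclude_samples(panel: ReferencePanel, ids: set[str]) -> ReferencePanel:
    """Remove the named samples from the panel (unknown ids warn only)."""
    ids = set(ids)
    unknown = ids - set(panel.genotypes.samples)
    if unknown:
        warnings.warn(f"exclude_samples: unknown ids ignored: {sorted(unknown)}",
                      stacklevel=2)
    if not ids - unknown:
        return panel
    kept = [s for s in panel.genotypes.samples if s not in ids]
    return ReferencePanel(
        genotypes=panel.genotypes.subset_samples(kept),
        labels={s: panel.labels[s] for s in kept},
    )
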