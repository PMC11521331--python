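"""Workflow configuration.

All thresholds default to the constants of the published consensus-GIA
workflow: MAF > 0.1%, Hardy-Weinberg exact-test mid-p > 1e-6, KING-robust
kinship cutoff 0.09375 (second-degree relations), LD pruning with a
100-variant window at r^2 0.2, 20 principal components, k-NN with k = 8,
top-1% correlation rule, and the > 0.54 admixture majority threshold with
Oceania excluded from supervised admixture (K = 7 when all 8 populations
are present).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

from .errors import ValidationError

#: Closed set of reference population labels.
POPULATIONS: tuple[str, ...] = (
    "AFR", "AMR", "CAS_SIB", "EAS", "EUR", "MEA", "OCN", "SAS",
)

#: Aliases accepted in label files (the slash form appears in publications).
_POP_ALIASES = {"CAS/SIB": "CAS_SIB", "CAS-SIB": "CAS_SIB"}


def normalize_population(value: str) -> str:
    """Map a population string to its canonical label or raise."""
    v = value.strip()
    v = _POP_ALIASES.get(v, v)
    if v not in POPULATIONS:
        raise ValidationError(f"unknown population label: {value!r}")
    return v


@dataclass
class WorkflowConfig:
    """Tunable thresholds of the GIA workflow (defaults = published values)."""

    maf_min: float = 0.001
    hwe_p_min: float = 1e-6
    king_threshold: float = 0.09375
    ld_window: int = 100
    ld_step: int = 1
    ld_r2_max: float = 0.2
    n_pcs: int = 20
    knn_k: int = 8
    corr_top_frac: float = 0.01
    majority_threshold: float = 0.54
    admixture_tol: float = 1e-6
    admixture_max_iter: int = 1000
    excluded_admixture_pops: frozenset[str] = frozenset({"OCN"})
    excluded_samples: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.maf_min < 0.5:
            raise ValidationError("maf_min must be in (0, 0.5)")
        if not 0 < self.hwe_p_min < 1:
            raise ValidationError("hwe_p_min must be in (0, 1)")
        if not 0 < self.corr_top_frac <= 1:
            raise ValidationError("corr_top_frac must be in (0, 1]")
        if not 0.5 < self.majority_threshold < 1:
            raise ValidationError("majority_threshold must be in (0.5, 1)")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if self.n_pcs < 2:
            raise ValidationError("n_pcs must be >= 2")
        if self.ld_window < 2 or self.ld_step < 1:
            raise ValidationError("ld_window must be >= 2 and ld_step >= 1")
        if not isinstance(self.excluded_admixture_pops, frozenset):
            object.__setattr__(
                self, "excluded_admixture_pops",
                frozenset(self.excluded_admixture_pops))
        if not isinstance(self.excluded_samples, frozenset):
            object.__setattr__(
                self, "excluded_samples", frozenset(self.excluded_samples))
        for pop in self.excluded_admixture_pops:
            normalize_population(pop)

    @classmethod
    def from_file(cls, path: str | Path) -> "WorkflowConfig":
        """Load a flat key/value YAML document mirroring the field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} is not a key/value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_admixture_pops"] = sorted(self.excluded_admixture_pops)
        d["excluded_samples"] = sorted(self.excluded_samples)
        return d

    def replace(self, **kwargs) -> "WorkflowConfig":
        return replace(self, **kwargs)
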