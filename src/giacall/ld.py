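"""Linkage-disequilibrium pruning on genotype correlations.

Slides a window of ``ld_window`` variants (advancing by ``ld_step``) along
each chromosome and removes one member of every retained pair whose squared
Pearson genotype correlation exceeds ``ld_r2_max`` — the member with the
lower minor-allele frequency, ties broken by later position.  After
pruning, no retained pair co-occurring in any window exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import WorkflowConfig
from .errors import ContractError
from .genotype_io import GenotypeMatrix


@dataclass(frozen=True)
class PruneResult:
    kept: list[int]
    removed: list[int]
    window: int
    r2_max: float


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Returns 0.0 when either vector is constant (uncorrelatable).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ContractError("vectors must have equal length")
    if x.size < 2:
        raise ContractError("vectors must have length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float((xc @ yc) ** 2 / (sx * sy))


def _unit_columns(d: np.ndarray) -> np.ndarray:
    """Center and L2-normalize columns; constant columns become zero."""
    z = d.astype(np.float64)
    z -= z.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(z, axis=0)
    nz = norms > 0
    z[:, nz] /= norms[nz]
    z[:, ~nz] = 0.0
    return z


def ld_prune(m: GenotypeMatrix, cfg: WorkflowConfig) -> PruneResult:
    """Sliding-window LD pruning; windows never span chromosomes.

    Implemented as an incremental sweep: when the window advances, only
    pairs involving newly entered variants can first violate the
    threshold, and removing a variant can never create a new violation,
    so checking each variant against retained predecessors within the
    window span is equivalent to the literal repeat-scan per window.
    """
    n = m.n_variants
    z = _unit_columns(m.dosages)
    # MAF per variant for victim selection
    alt = m.dosages.astype(np.float64).mean(axis=0) / 2.0
    maf = np.minimum(alt, 1.0 - alt)
    kept_mask = np.ones(n, dtype=bool)
    chroms = np.array([v.chrom for v in m.variants])
    w, step = cfg.ld_window, cfg.ld_step

    start = 0
    while start < n:
        stop = start + int(np.searchsorted(
            chroms[start:], chroms[start], side="right"))
        for s in range(start, stop, step):
            lo_new = start if s == start else s + w - step
            hi = min(s + w, stop)
            for j in range(max(lo_new, s + 1), hi):
                if not kept_mask[j]:
                    continue
                for i in range(s, j):
                    if not kept_mask[i]:
                        continue
                    r2 = float((z[:, i] @ z[:, j]) ** 2)
                    if r2 <= cfg.ld_r2_max:
                        continue
                    # victim: lower MAF; tie -> later position (higher index)
                    if maf[i] < maf[j]:
                        kept_mask[i] = False
                    else:
                        kept_mask[j] = False
                        break
            if s + w >= stop:
                break
        start = stop

    kept = [int(i) for i in np.flatnonzero(kept_mask)]
    removed = [int(i) for i in np.flatnonzero(~kept_mask)]
    return PruneResult(kept=kept, removed=removed,
                       window=w, r2_max=cfg.ld_r2_max)
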