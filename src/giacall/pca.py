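"""Genetic principal components of the standardized dosage matrix.

Dosages are standardized per variant as (d - 2p) / sqrt(2 p (1 - p)) with p
the sample alt-allele frequency — the usual scaling under which each column
has unit variance at Hardy-Weinberg proportions — and the top components
are taken from the thin SVD of the standardized matrix.  Scores are the
variance-scaled projections (left singular vectors times singular values),
so Euclidean distances between samples weight each axis by the variance it
explains.  Component signs are fixed so the largest-magnitude variant
loading on each axis is positive, making runs reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import WorkflowConfig
from .errors import ContractError
from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class PCScores:
    """Per-sample coordinates on the top principal components."""

    samples: list[str]
    scores: np.ndarray     # (n_samples, n_pcs)
    explained: np.ndarray  # (n_pcs,) eigenvalues, non-increasing

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.explained = np.asarray(self.explained, dtype=np.float64)
        if self.scores.shape[0] != len(self.samples):
            raise ContractError("score rows must match samples")
        if np.any(np.diff(self.explained) > 1e-9):
            raise ContractError("eigenvalues must be non-increasing")

    def row(self, sample: str) -> np.ndarray:
        return self.scores[self.samples.index(sample)]

    def subset(self, sample_ids: list[str]) -> "PCScores":
        idx = [self.samples.index(s) for s in sample_ids]
        return PCScores(samples=list(sample_ids),
                        scores=self.scores[idx],
                        explained=self.explained.copy())


def standardize(m: GenotypeMatrix) -> np.ndarray:
    """Frequency-standardize dosages: (d - 2p) / sqrt(2 p (1 - p))."""
    d = m.dosages
    if np.any(d == MISSING):
        raise ContractError("standardize requires complete genotypes")
    p = d.astype(np.float64).mean(axis=0) / 2.0
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ContractError(
            "monomorphic variant reached standardize (MAF filter violated)")
    return (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def compute_pcs(m: GenotypeMatrix, cfg: WorkflowConfig) -> PCScores:
    """Top ``cfg.n_pcs`` principal-component scores of all samples.

    Scores are U_k @ diag(S_k) from the thin SVD of the standardized
    matrix; ``explained`` holds S_k^2 / (n_samples - 1).
    """
    k = cfg.n_pcs
    if m.n_samples < k + 1:
        raise ContractError(
            f"need >= {k + 1} samples for {k} PCs, got {m.n_samples}")
    if m.n_variants < k:
        raise ContractError(
            f"need >= {k} variants for {k} PCs, got {m.n_variants}")
    x = standardize(m)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-|loading| variant coefficient positive
    for c in range(k):
        peak = np.argmax(np.abs(vt[c]))
        if vt[c, peak] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    return PCScores(samples=list(m.samples),
                    scores=u * s,
                    explained=s ** 2 / (m.n_samples - 1))
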