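"""PC-space classifiers: k-nearest-neighbor and top-1% PC correlation.

Both consume the same principal-component score convention produced by
:mod:`giacall.pca` and return a single discrete population call.  The
correlation classifier computes, for each reference sample, the Pearson
correlation between the query's PC score vector and that reference's score
vector (a correlation across the PC coordinates of one sample pair), takes
the top ``corr_top_frac`` of references, and votes; an exact tie between
populations in the top set yields the special Mixed-Ancestry call.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

from .config import WorkflowConfig
from .errors import ContractError
from .pca import PCScores

#: Special call produced only by the correlation classifier's tie rule.
MIXED_ANCESTRY = "MIXED_ANCESTRY"
#: Special call produced only by the admixture discrete-call rule.
NO_MAJORITY = "NO_MAJORITY"

_REL_TOL = 1e-12


def knn_classify(ref_scores: PCScores, labels: dict[str, str],
                 query_score: np.ndarray, cfg: WorkflowConfig) -> str:
    """Majority label among the k nearest reference samples.

    Distance ties at the k-th neighbor admit all tied samples before
    voting.  Label-frequency ties break by the smaller summed distance of
    the tied label's neighbors, then lexicographically.
    """
    n_ref = len(ref_scores.samples)
    if n_ref < cfg.knn_k:
        raise ContractError(
            f"need >= {cfg.knn_k} reference samples, got {n_ref}")
    q = np.asarray(query_score, dtype=np.float64)
    dist = np.linalg.norm(ref_scores.scores - q[None, :], axis=1)
    order = np.argsort(dist, kind="stable")
    kth = dist[order[cfg.knn_k - 1]]
    cut = kth * (1.0 + _REL_TOL) + _REL_TOL
    neighbors = [i for i in order if dist[i] <= cut]
    votes = Counter(labels[ref_scores.samples[i]] for i in neighbors)
    best = max(votes.values())
    tied = sorted(lab for lab, c in votes.items() if c == best)
    if len(tied) == 1:
        return tied[0]
    sums = {lab: sum(dist[i] for i in neighbors
                     if labels[ref_scores.samples[i]] == lab)
            for lab in tied}
    low = min(sums.values())
    finalists = sorted(lab for lab in tied
                       if sums[lab] <= low * (1.0 + _REL_TOL) + _REL_TOL)
    return finalists[0]


def _pairwise_pearson(ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Pearson correlation of q against each row of ref, across PC coords."""
    qc = q - q.mean()
    rc = ref - ref.mean(axis=1, keepdims=True)
    qn = float(np.linalg.norm(qc))
    rn = np.linalg.norm(rc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (rc @ qc) / (rn * qn)
    return np.nan_to_num(r, nan=0.0)


def correlation_classify(ref_scores: PCScores, labels: dict[str, str],
                         query_score: np.ndarray,
                         cfg: WorkflowConfig) -> str:
    """Vote among the top ``corr_top_frac`` most PC-correlated references.

    Takes ceil(corr_top_frac * N_ref) references by descending Pearson
    correlation of score vectors (ranking ties at the cutoff admit all
    tied samples); returns the most frequent label, or MIXED_ANCESTRY when
    two or more labels share the maximal count.
    """
    n_ref = len(ref_scores.samples)
    if n_ref < 2:
        raise ContractError("need >= 2 reference samples")
    if ref_scores.scores.shape[1] < 2:
        raise ContractError("need >= 2 PCs for a score-vector correlation")
    q = np.asarray(query_score, dtype=np.float64)
    r = _pairwise_pearson(ref_scores.scores, q)
    m = math.ceil(cfg.corr_top_frac * n_ref)
    order = np.argsort(-r, kind="stable")
    cutoff = r[order[m - 1]]
    top = [i for i in range(n_ref) if r[i] >= cutoff - _REL_TOL]
    votes = Counter(labels[ref_scores.samples[i]] for i in top)
    best = max(votes.values())
    winners = [lab for lab, c in votes.items() if c == best]
    if len(winners) > 1:
        return MIXED_ANCESTRY
    return winners[0]
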