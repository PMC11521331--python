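"""Validation statistics: confusion matrices and per-class metrics.

Per-class metrics are one-vs-rest sensitivity (recall), specificity,
balanced accuracy, precision and F1, macro-averaged (unweighted) across
truth classes.  Two accounting modes mirror the published validation:
``strict`` counts calls in categories with no truth counterpart (e.g. a
Mixed-Ancestry or Middle-Eastern call when no sample self-reports those)
as misclassifications; ``sire_covered_only`` drops those samples before
computing concordance, matching the "after removing groups not covered"
re-analysis.  Undefined ratios (zero denominators) are reported as NaN and
excluded from macro averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import MIXED_ANCESTRY
from .config import POPULATIONS
from .consensus import INCONCLUSIVE
from .errors import ContractError

_METRICS = ("sensitivity", "specificity", "balanced_accuracy",
            "precision", "f1")

_CANONICAL = tuple(POPULATIONS) + (MIXED_ANCESTRY, INCONCLUSIVE)


def _ordered(cats: set[str]) -> list[str]:
    known = [c for c in _CANONICAL if c in cats]
    extra = sorted(cats - set(_CANONICAL))
    return known + extra


@dataclass
class ClassMetrics:
    per_class: dict[str, dict[str, float]]
    macro: dict[str, tuple[float, float]]  # metric -> (mean, sd)
    concordance: float


def confusion_matrix(calls: list[str], truth: list[str]) -> pd.DataFrame:
    """Predicted (rows) x truth (columns) count matrix.

    Rows cover every predicted or truth category (so categories without
    truth representation appear as rows); columns cover truth categories.
    """
    if len(calls) != len(truth):
        raise ContractError("calls and truth must have equal length")
    rows = _ordered(set(calls) | set(truth))
    cols = _ordered(set(truth))
    cm = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for c, t in zip(calls, truth):
        cm.loc[c, t] += 1
    return cm


def compute_metrics(cm: pd.DataFrame, mode: str = "strict") -> ClassMetrics:
    """One-vs-rest metrics per truth class plus overall concordance."""
    if mode not in ("strict", "sire_covered_only"):
        raise ContractError(f"unknown mode {mode!r}")
    cm = cm.copy()
    if mode == "sire_covered_only":
        covered = [r for r in cm.index if r in cm.columns]
        cm = cm.loc[covered]
    total = int(cm.values.sum())
    per_class: dict[str, dict[str, float]] = {}
    diag = 0
    for cls in cm.columns:
        tp = int(cm.loc[cls, cls]) if cls in cm.index else 0
        fn = int(cm[cls].sum()) - tp
        fp = (int(cm.loc[cls].sum()) - tp) if cls in cm.index else 0
        tn = total - tp - fn - fp
        diag += tp
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        prec = tp / (tp + fp) if tp + fp else float("nan")
        f1 = (2 * prec * sens / (prec + sens)
              if prec + sens and not (np.isnan(prec) or np.isnan(sens))
              else float("nan"))
        bacc = (sens + spec) / 2
        per_class[cls] = dict(zip(_METRICS, (sens, spec, bacc, prec, f1)))
    macro = {}
    for met in _METRICS:
        vals = np.array([per_class[c][met] for c in cm.columns])
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            macro[met] = (float("nan"), float("nan"))
        else:
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            macro[met] = (float(vals.mean()), sd)
    concordance = diag / total if total else float("nan")
    return ClassMetrics(per_class=per_class, macro=macro,
                        concordance=concordance)


def metrics_table(metrics: ClassMetrics) -> pd.DataFrame:
    """Class-by-metric table with a trailing macro mean +/- SD row."""
    rows = {cls: vals for cls, vals in metrics.per_class.items()}
    df = pd.DataFrame(rows).T[list(_METRICS)]
    df.loc["macro_mean"] = [metrics.macro[m][0] for m in _METRICS]
    df.loc["macro_sd"] = [metrics.macro[m][1] for m in _METRICS]
    return df
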