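"""Presence/absence skill metrics: ROC AUC and the true skill statistic.

AUC is computed in the rank (Mann-Whitney) formulation: the probability
that a randomly chosen presence outscores a randomly chosen absence, with
ties counted one half.  This equals trapezoidal integration of the ROC
curve exactly.

TSS = sensitivity + specificity - 1 at a classification cutoff; a score at
or above the cutoff predicts presence.  :func:`optimize_tss` maximizes TSS
over all distinct-score midpoints (plus 0 and 1), which attains the exact
optimum because TSS is piecewise constant between observed scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "EvaluationResult",
    "roc_auc",
    "tss_at_cutoff",
    "optimize_tss",
    "gate_models",
]


@dataclass(frozen=True)
class EvaluationResult:
    """Skill of one model on one validation set."""

    auc: float
    tss: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_presence: int
    n_absence: int


def _check_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to evaluate")
    return scores, labels, n_pos, n_neg


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_presence > score_absence) + 0.5 P(tie)."""
    scores, labels, n_pos, n_neg = _check_labels(scores, labels)
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def tss_at_cutoff(scores, labels, cutoff: float) -> tuple[float, float, float]:
    """(sensitivity, specificity, TSS) with presence predicted at score >= cutoff."""
    scores, labels, n_pos, n_neg = _check_labels(scores, labels)
    pred = scores >= cutoff
    sens = float((pred & (labels == 1)).sum() / n_pos)
    spec = float((~pred & (labels == 0)).sum() / n_neg)
    return sens, spec, sens + spec - 1.0


def optimize_tss(scores, labels) -> EvaluationResult:
    """Maximize TSS over candidate cutoffs; ties resolved toward the lower cutoff.

    Candidates are the midpoints between consecutive distinct scores plus
    the endpoints 0 and 1, which covers every achievable confusion table.
    """
    scores, labels, n_pos, n_neg = _check_labels(scores, labels)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    candidates = np.unique(np.concatenate([[0.0], mids, [1.0], uniq]))
    best = None
    for c in candidates:  # ascending, so strict '>' keeps the lowest maximizer
        sens, spec, tss = tss_at_cutoff(scores, labels, c)
        if best is None or tss > best[0] + 1e-15:
            best = (tss, c, sens, spec)
    tss, cutoff, sens, spec = best
    return EvaluationResult(auc=roc_auc(scores, labels), tss=tss, cutoff=float(cutoff),
                            sensitivity=sens, specificity=spec,
                            n_presence=n_pos, n_absence=n_neg)


def gate_models(runs, tss_min: float = 0.9):
    """Select runs whose validation TSS is at or above the gate (boundary inclusive).

    A small epsilon keeps the boundary inclusive under floating-point
    arithmetic (sensitivity + specificity - 1 can evaluate to
    0.8999999999999999 when the exact value is 0.9).

    Returns (selected_runs, status) where status is "ok" or, when nothing
    qualifies, "warning: no model passed the TSS gate".
    """
    selected = [r for r in runs
                if getattr(r, "status", "ok") == "ok"
                and r.evaluation is not None
                and r.evaluation.tss >= tss_min - 1e-9]
    if not selected:
        return [], f"warning: no model passed the TSS gate at {tss_min}"
    return selected, "ok"


def evaluation_table(runs):
    """Tidy per-run evaluation table (one row per fitted model)."""
    import pandas as pd

    rows = []
    for r in runs:
        e = r.evaluation
        rows.append({
            "run_id": r.run_id, "algorithm": r.algorithm, "pa_set": r.pa_set,
            "repetition": r.repetition, "status": r.status,
            "AUC": e.auc if e else np.nan, "TSS": e.tss if e else np.nan,
            "cutoff": e.cutoff if e else np.nan,
            "sensitivity": e.sensitivity if e else np.nan,
            "specificity": e.specificity if e else np.nan,
        })
    return pd.DataFrame(rows)


def evaluation_long(runs):
    """Long (boxplot-ready) format: one row per run x metric."""
    wide = evaluation_table(runs)
    return wide.melt(id_vars=["run_id", "algorithm", "pa_set", "repetition", "status"],
                     value_vars=["AUC", "TSS"], var_name="metric", value_name="value")
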