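"""TSS-weighted ensemble: member weighting, HSI prediction, classification.

Single models that pass the skill gate (validation TSS >= 0.9 by default)
are combined by a weighted average.  Member i with TSS a_i receives weight

    W_i = a_i / sum_k a_k,

and the habitat suitability index at a pixel is the convex combination

    HSI = sum_i W_i * P_i(pixel),

where P_i is member i's predicted probability of presence.  HSI in [0, 1]
is read as the probability of species presence and classified into four
suitability levels: unsuitable (HSI < 0.3), low (0.3 <= HSI < 0.5),
moderate (0.5 <= HSI < 0.7) and high (HSI >= 0.7).

:class:`TSSWeightedEnsemble` packages the repeated-split fitting, gating
and weighting as a scikit-learn classifier (fit / predict_proba /
predict), so it composes with sklearn model selection; the plain functions
below are the building blocks the pipeline uses directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .evaluation import gate_models, optimize_tss
from .models import ALGORITHMS, ModelRun, PATable, _child_seed, fit_one, split_train_validation
from .raster import Landscape

__all__ = [
    "EnsembleModel",
    "SuitabilityMap",
    "TSSWeightedEnsemble",
    "compute_weights",
    "predict_hsi",
    "classify_hsi",
    "CLASS_LABELS",
    "DEFAULT_CLASS_THRESHOLDS",
]

CLASS_LABELS = ("unsuitable", "low", "moderate", "high")
DEFAULT_CLASS_THRESHOLDS = (0.3, 0.5, 0.7)


def compute_weights(member_tss) -> np.ndarray:
    """Normalized skill weights W_i = a_i / sum(a_i); requires all a_i > 0."""
    a = np.asarray(member_tss, dtype=float)
    if a.size == 0:
        raise ValueError("cannot weight an empty member list")
    if np.any(a <= 0):
        raise ValueError("member TSS values must be positive after gating")
    return a / a.sum()


@dataclass
class EnsembleModel:
    """Gated member runs plus their normalized TSS weights."""

    members: list[ModelRun]
    weights: np.ndarray
    gate: float
    status: str = "ok"
    evaluation: object | None = None  # ensemble-level skill on pooled validation rows

    @classmethod
    def from_runs(cls, runs: list[ModelRun], gate: float = 0.9) -> "EnsembleModel":
        selected, status = gate_models(runs, tss_min=gate)
        if not selected:
            return cls(members=[], weights=np.empty(0), gate=gate, status=status)
        w = compute_weights([r.evaluation.tss for r in selected])
        return cls(members=selected, weights=w, gate=gate, status=status)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def predict_rows(self, X) -> np.ndarray:
        """Weighted-average probability of presence for tabular rows."""
        if not self.members:
            raise RuntimeError(f"ensemble has no members ({self.status})")
        out = np.zeros(len(X))
        for w, run in zip(self.weights, self.members):
            out += w * run.predict(X)
        return np.clip(out, 0.0, 1.0)

    def member_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "run_id": [r.run_id for r in self.members],
            "algorithm": [r.algorithm for r in self.members],
            "TSS": [r.evaluation.tss for r in self.members],
            "weight": self.weights,
        })


@dataclass
class SuitabilityMap:
    """Continuous HSI surface (NaN off-mask) with its 4-level classification."""

    hsi: np.ndarray
    mask: np.ndarray
    landscape: Landscape
    species: str = ""
    thresholds: tuple[float, ...] = DEFAULT_CLASS_THRESHOLDS
    classes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.classes = classify_hsi(self.hsi, self.thresholds)

    def save(self, path) -> None:
        from .raster import write_band

        arr = np.where(self.mask, self.hsi, self.landscape.nodata)
        write_band(path, arr, self.landscape.transform,
                   nodata=self.landscape.nodata)


def predict_hsi(ensemble: EnsembleModel, landscape: Landscape,
                variables: list[str] | None = None,
                species: str = "",
                thresholds: tuple[float, ...] = DEFAULT_CLASS_THRESHOLDS,
                ) -> SuitabilityMap:
    """Weighted-average HSI over every mask cell of the landscape."""
    variables = variables or (ensemble.members[0].variables if ensemble.members
                              else None)
    if variables is None:
        raise RuntimeError("ensemble has no members to predict with")
    for run in ensemble.members:
        if run.variables != list(variables):
            raise ValueError(
                f"run {run.run_id} was trained on {run.variables}, "
                f"prediction requested for {list(variables)}")
    df = landscape.table(variables)
    vals = ensemble.predict_rows(df[variables])
    hsi = landscape.grid_from_mask_values(vals)
    return SuitabilityMap(hsi=hsi, mask=landscape.mask, landscape=landscape,
                          species=species, thresholds=thresholds)


def classify_hsi(hsi: np.ndarray,
                 thresholds: tuple[float, ...] = DEFAULT_CLASS_THRESHOLDS,
                 ) -> np.ndarray:
    """Classify HSI into four ordered levels with half-open intervals.

    Level k covers [t_k, t_{k+1}); HSI below the first threshold is
    unsuitable, at or above the last is highly suitable.  Returns an int
    array (-1 where HSI is NaN).
    """
    t = np.asarray(thresholds, dtype=float)
    if t.size != 3 or np.any(np.diff(t) <= 0) or t[0] <= 0 or t[-1] >= 1:
        raise ValueError("thresholds must be three strictly increasing values in (0, 1)")
    hsi = np.asarray(hsi, dtype=float)
    out = np.full(hsi.shape, -1, dtype=int)
    ok = np.isfinite(hsi)
    out[ok] = np.digitize(hsi[ok], t, right=False)
    return out


class TSSWeightedEnsemble(BaseEstimator, ClassifierMixin):
    """Skill-gated, TSS-weighted ensemble of presence/absence classifiers.

    ``fit(X, y)`` repeatedly splits the rows 75/25 (stratified), fits every
    requested algorithm on each training part, scores TSS on the held-out
    part, keeps runs with TSS >= ``tss_gate`` and weights them by
    W_i = TSS_i / sum TSS.  ``predict_proba`` returns the weighted-average
    probability (the HSI on tabular rows); ``predict`` thresholds it at the
    ensemble's own TSS-optimal cutoff.

    Parameters
    ----------
    algorithms : tuple of {"RF", "GBM", "GLM"}
    n_repetitions : int, default 10
        Number of re-drawn train/validation splits.
    train_fraction : float, default 0.75
    tss_gate : float, default 0.9
        Minimum validation TSS for ensemble membership (inclusive).
    hyperparams : dict mapping algorithm -> overrides, optional
    random_state : int, default 0

    Attributes
    ----------
    runs_ : list of ModelRun (all runs, including gated-out and failed)
    ensemble_ : EnsembleModel (gated members and weights)
    weights_ : ndarray of member weights, summing to 1
    evaluation_ : EvaluationResult of the ensemble on pooled validation rows
    classes_ : ndarray [0, 1]
    """

    def __init__(self, algorithms: tuple = ALGORITHMS, n_repetitions: int = 10,
                 train_fraction: float = 0.75, tss_gate: float = 0.9,
                 hyperparams: dict | None = None, random_state: int = 0):
        self.algorithms = algorithms
        self.n_repetitions = n_repetitions
        self.train_fraction = train_fraction
        self.tss_gate = tss_gate
        self.hyperparams = hyperparams
        self.random_state = random_state

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=[f"x{i}" for i in range(np.shape(X)[1])])
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if set(self.classes_) != {0, 1}:
            raise ValueError("y must contain exactly the labels 0 and 1")
        hp = self.hyperparams or {}
        runs: list[ModelRun] = []
        val_masks: dict[int, np.ndarray] = {}
        for rep in range(self.n_repetitions):
            table = PATable(X=X, y=y, pa_set=0)
            split_train_validation(table, fraction=self.train_fraction,
                                   seed=_child_seed(self.random_state, 1, 0, rep))
            val_masks[rep] = ~table.is_train
            for k, algo in enumerate(self.algorithms):
                run = fit_one(algo, table, hyperparams=hp.get(algo),
                              seed=_child_seed(self.random_state, 2, 0, rep, k),
                              repetition=rep)
                runs.append(run)
        self.runs_ = runs
        self.ensemble_ = EnsembleModel.from_runs(runs, gate=self.tss_gate)
        self.weights_ = self.ensemble_.weights
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        self.evaluation_ = self._score_ensemble(X, y, val_masks)
        self.ensemble_.evaluation = self.evaluation_
        return self

    def _score_ensemble(self, X, y, val_masks):
        """Out-of-fold ensemble skill on pooled validation rows.

        Each row's ensemble score is the TSS-weighted average over gated
        members whose validation set contained that row (so no member scores
        rows it trained on); rows never held out are excluded.
        """
        if not self.ensemble_.members:
            return None
        scores = np.zeros(len(X))
        wsum = np.zeros(len(X))
        for w, run in zip(self.ensemble_.weights, self.ensemble_.members):
            val = val_masks[run.repetition]
            scores[val] += w * run.predict(X[val])
            wsum[val] += w
        seen = wsum > 0
        if not seen.any() or len(np.unique(y[seen])) < 2:
            return None
        pooled = scores[seen] / wsum[seen]
        return optimize_tss(pooled, y[seen])

    def predict_proba(self, X):
        check_is_fitted(self, "ensemble_")
        if isinstance(X, pd.DataFrame):
            Xd = X
        else:
            Xd = pd.DataFrame(np.asarray(X, dtype=float),
                              columns=list(self.feature_names_in_))
        p1 = self.ensemble_.predict_rows(Xd)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        check_is_fitted(self, "ensemble_")
        cutoff = self.evaluation_.cutoff if self.evaluation_ is not None else 0.5
        return (self.predict_proba(X)[:, 1] >= cutoff).astype(int)
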