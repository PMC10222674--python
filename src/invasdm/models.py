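"""Base learners and the repeated presence/pseudo-absence fitting protocol.

True absences are unavailable for occurrence-only data, so the negative
class is built from pseudo-absences: background cells sampled uniformly
from the modellable mask excluding presence cells.  Several independent
pseudo-absence sets are drawn, each combined with the presences into a
design table, split 75/25 into training and validation (stratified by
label), and fitted with each retained algorithm over repeated splits.  The
full protocol therefore yields n_algorithms x n_repetitions x n_pa_sets
single-model runs, each evaluated on its held-out 25%.

Retained algorithms:

* ``RF``  — random forest, 500 trees.
* ``GBM`` — gradient boosted trees, 500 trees, learning rate 0.05, depth 3.
* ``GLM`` — binomial GLM with logit link over linear + quadratic terms
  (unpenalized logistic regression on degree-2 polynomial features).

Because pseudo-absences heavily outnumber presences, all learners are fitted
with balanced sample weights so both classes carry equal total influence.
Six further algorithms sometimes seen in ensemble SDM work (ANN, CTA, FDA,
GAM, MARS, SRE) are registered as names but deliberately not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.utils.class_weight import compute_sample_weight

from .evaluation import EvaluationResult, optimize_tss
from .prep import OccurrenceSet, extract_design
from .raster import Landscape

__all__ = [
    "PATable",
    "ModelRun",
    "ALGORITHMS",
    "UNIMPLEMENTED_ALGORITHMS",
    "make_estimator",
    "draw_pseudo_absences",
    "build_pa_table",
    "split_train_validation",
    "fit_one",
    "run_ensemble_protocol",
    "ProtocolConfig",
]

ALGORITHMS = ("RF", "GBM", "GLM")
#: registered but unimplemented single-model names
UNIMPLEMENTED_ALGORITHMS = ("ANN", "CTA", "FDA", "GAM", "MARS", "SRE")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "RF": {"n_estimators": 500, "min_samples_leaf": 1, "n_jobs": 1},
    "GBM": {"n_estimators": 500, "learning_rate": 0.05, "max_depth": 3},
    "GLM": {"degree": 2, "max_iter": 1000},
}


@dataclass
class PATable:
    """Presence + pseudo-absence design table for one replicate.

    ``y`` is 1 for presence, 0 for pseudo-absence; ``is_train`` holds the
    stratified 75/25 assignment once :func:`split_train_validation` has run.
    """

    X: pd.DataFrame
    y: np.ndarray
    pa_set: int
    is_train: np.ndarray | None = None
    pa_seed: int | None = None
    split_seed: int | None = None

    @property
    def n_rows(self) -> int:
        return len(self.X)


@dataclass
class ModelRun:
    """One fitted base learner with its held-out evaluation."""

    run_id: str
    algorithm: str
    pa_set: int
    repetition: int
    estimator: object | None
    evaluation: EvaluationResult | None
    variables: list[str]
    seed: int
    status: str = "ok"
    message: str = ""
    hyperparams: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        """Probability of presence for each row of X."""
        if self.status != "ok" or self.estimator is None:
            raise RuntimeError(f"run {self.run_id} is not usable ({self.status})")
        if isinstance(X, pd.DataFrame):
            X = X[self.variables]
        proba = self.estimator.predict_proba(X)[:, 1]
        return np.clip(proba, 0.0, 1.0)


def make_estimator(algorithm: str, seed: int, hyperparams: dict | None = None):
    """Construct an unfitted sklearn estimator for a registered algorithm."""
    hp = dict(DEFAULT_HYPERPARAMS.get(algorithm, {}))
    hp.update(hyperparams or {})
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, **hp)
    if algorithm == "GBM":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if algorithm == "GLM":
        degree = hp.pop("degree", 2)
        return Pipeline([
            ("scale", StandardScaler()),
            ("poly", PolynomialFeatures(degree=degree, include_bias=False)),
            ("logit", LogisticRegression(C=np.inf, solver="lbfgs", **hp)),
        ])
    if algorithm in UNIMPLEMENTED_ALGORITHMS:
        raise NotImplementedError(
            f"algorithm {algorithm!r} is registered but not implemented; "
            f"supported: {ALGORITHMS}")
    raise ValueError(f"unknown algorithm {algorithm!r}; supported: {ALGORITHMS}")


def draw_pseudo_absences(landscape: Landscape, occ: OccurrenceSet,
                         n_points: int = 5000, n_sets: int = 3,
                         seed: int = 0) -> list[pd.DataFrame]:
    """Draw independent uniform pseudo-absence sets from non-presence mask cells.

    Each set samples ``n_points`` distinct cells (without replacement within
    a set) uniformly from the mask excluding every presence cell; points are
    placed at cell centres.
    """
    rows, cols = landscape.mask_cells()
    nr, nc = landscape.shape
    flat = rows * nc + cols
    presence_flat = occ.rows * nc + occ.cols
    candidates = np.setdiff1d(flat, presence_flat)
    if n_points > candidates.size:
        raise ValueError(
            f"requested {n_points} pseudo-absences but only {candidates.size} "
            f"non-presence mask cells are available")
    ss = np.random.SeedSequence(seed)
    sets = []
    for child in ss.spawn(n_sets):
        rng = np.random.default_rng(child)
        chosen = rng.choice(candidates, size=n_points, replace=False)
        r, c = chosen // nc, chosen % nc
        x, y = landscape.transform.cell_center(r, c)
        sets.append(pd.DataFrame({"x": x, "y": y, "row": r, "col": c}))
    return sets


def build_pa_table(landscape: Landscape, occ: OccurrenceSet,
                   pa_points: pd.DataFrame, variables: list[str],
                   pa_set: int = 0, pa_seed: int | None = None) -> PATable:
    """Stack presence rows over one pseudo-absence set into a labelled table."""
    X_pres = extract_design(landscape, occ, variables)
    X_abs = pd.DataFrame(
        landscape.values_at_cells(pa_points["row"].to_numpy(),
                                  pa_points["col"].to_numpy(), variables),
        columns=variables)
    X = pd.concat([X_pres, X_abs], ignore_index=True)
    y = np.concatenate([np.ones(len(X_pres), dtype=int),
                        np.zeros(len(X_abs), dtype=int)])
    return PATable(X=X, y=y, pa_set=pa_set, pa_seed=pa_seed)


def split_train_validation(table: PATable, fraction: float = 0.75,
                           seed: int = 0) -> PATable:
    """Random train/validation split stratified by label.

    The per-class training count is round(fraction * n_class) with
    round-half-to-even; both classes must end up on both sides, otherwise an
    error advises a larger input.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    is_train = np.zeros(table.n_rows, dtype=bool)
    for label in (0, 1):
        idx = np.flatnonzero(table.y == label)
        n_train = int(np.rint(fraction * idx.size))
        if n_train == 0 or n_train == idx.size:
            raise ValueError(
                f"class {label} would be absent from one side of the split; "
                "supply more rows")
        chosen = rng.permutation(idx)[:n_train]
        is_train[chosen] = True
    table.is_train = is_train
    table.split_seed = seed
    return table


def fit_one(algorithm: str, table: PATable, hyperparams: dict | None = None,
            seed: int = 0, run_id: str | None = None,
            repetition: int = 0) -> ModelRun:
    """Fit one algorithm on the training rows and evaluate on the held-out rows.

    Failures (e.g. GLM non-convergence through separation) are reported as a
    run with status "failed", never as a crash; such runs are excluded
    downstream.
    """
    if table.is_train is None:
        raise ValueError("table has no train/validation assignment; "
                         "call split_train_validation first")
    run_id = run_id or f"{algorithm}_pa{table.pa_set}_rep{repetition}"
    variables = list(table.X.columns)
    Xtr = table.X[table.is_train]
    ytr = table.y[table.is_train]
    if len(np.unique(ytr)) < 2:
        raise ValueError("training rows must contain both classes")
    est = make_estimator(algorithm, seed=seed, hyperparams=hyperparams)
    # balanced weights: presences and pseudo-absences get equal total mass
    w = compute_sample_weight("balanced", ytr)
    try:
        if isinstance(est, Pipeline):
            est.fit(Xtr, ytr, logit__sample_weight=w)
        else:
            est.fit(Xtr, ytr, sample_weight=w)
        Xval = table.X[~table.is_train]
        yval = table.y[~table.is_train]
        scores = est.predict_proba(Xval)[:, 1]
        ev = optimize_tss(scores, yval)
    except Exception as exc:  # separation, singularities, ...
        return ModelRun(run_id=run_id, algorithm=algorithm, pa_set=table.pa_set,
                        repetition=repetition, estimator=None, evaluation=None,
                        variables=variables, seed=seed, status="failed",
                        message=f"{type(exc).__name__}: {exc}",
                        hyperparams=dict(hyperparams or {}))
    return ModelRun(run_id=run_id, algorithm=algorithm, pa_set=table.pa_set,
                    repetition=repetition, estimator=est, evaluation=ev,
                    variables=variables, seed=seed,
                    hyperparams=dict(hyperparams or {}))


@dataclass
class ProtocolConfig:
    """Configuration of the repeated-fit protocol (defaults: the full design
    of 3 algorithms x 10 repetitions x 3 pseudo-absence sets of 5000)."""

    algorithms: tuple[str, ...] = ALGORITHMS
    n_repetitions: int = 10
    n_pa_sets: int = 3
    n_pseudo_absences: int = 5000
    train_fraction: float = 0.75
    hyperparams: dict[str, dict] = field(default_factory=dict)


def _child_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master), *map(int, key)])
    return int(ss.generate_state(1)[0] % 2**31)


def run_ensemble_protocol(landscape: Landscape, occ: OccurrenceSet,
                          variables: list[str], config: ProtocolConfig,
                          seed: int = 0) -> list[ModelRun]:
    """Run the full factorial protocol and return one ModelRun per cell.

    Seeds fan out deterministically from the master seed to every
    (pseudo-absence set, repetition, algorithm) tuple; repetitions re-draw
    the 75/25 split within a fixed pseudo-absence set.
    """
    for a in config.algorithms:
        if a not in ALGORITHMS and a not in UNIMPLEMENTED_ALGORITHMS:
            raise ValueError(f"unknown algorithm {a!r}")
    pa_sets = draw_pseudo_absences(landscape, occ,
                                   n_points=config.n_pseudo_absences,
                                   n_sets=config.n_pa_sets,
                                   seed=_child_seed(seed, 0))
    runs: list[ModelRun] = []
    for s, pa in enumerate(pa_sets):
        base = build_pa_table(landscape, occ, pa, variables, pa_set=s)
        for rep in range(config.n_repetitions):
            table = PATable(X=base.X, y=base.y, pa_set=s)
            split_train_validation(table, fraction=config.train_fraction,
                                   seed=_child_seed(seed, 1, s, rep))
            for k, algo in enumerate(config.algorithms):
                run = fit_one(algo, table,
                              hyperparams=config.hyperparams.get(algo),
                              seed=_child_seed(seed, 2, s, rep, k),
                              repetition=rep,
                              run_id=f"{algo}_pa{s}_rep{rep}")
                runs.append(run)
    return runs
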