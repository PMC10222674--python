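"""Variable contributions, cumulative rates and best-suitable ranges.

Per-variable contributions use the permutation scheme common in ensemble
SDM tooling: a variable's raw importance is 1 minus the Pearson correlation
between the ensemble's predictions on the original rows and on rows with
that variable's column permuted, averaged over permutations and clipped to
[0, 1].  A variable no fitted member uses leaves predictions unchanged
(r = 1, importance 0); permuting a decisive variable destroys the
prediction ranking (r -> 0, importance -> 1).

Raw importances are normalized to percentages summing to 100, sorted
descending, and accumulated; the key variables are the smallest set whose
cumulative contribution reaches 90%.

Response curves are computed with the evaluation-strip method: the focal
variable is swept over its observed range while all other variables keep
their per-cell values, and the ensemble's HSI is averaged over a (seeded)
subsample of mask cells — a partial-dependence-style mean response.  The
"best suitable range" is the contiguous interval around the curve's maximum
where the mean response stays above a criterion level (half of the curve
maximum by default; an absolute HSI >= 0.5 criterion is also provided).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import EnsembleModel
from .raster import Landscape

__all__ = [
    "ImportanceTable",
    "ResponseCurve",
    "variable_contributions",
    "normalize_contributions",
    "key_variable_count",
    "response_curve",
    "best_suitable_range",
]

MAX_RESPONSE_CELLS = 10_000  # subsample cap for response-curve averaging


@dataclass
class ImportanceTable:
    """Per-variable contribution and cumulative rates, descending order."""

    table: pd.DataFrame  # columns: variable, contribution_pct, cumulative_pct

    def to_csv(self, path) -> None:
        out = self.table.rename(columns={
            "variable": "Variables",
            "contribution_pct": "Contribution Rate (%)",
            "cumulative_pct": "Cumulative Contribution Rate (%)",
        })
        out.to_csv(path, index=False)


@dataclass
class ResponseCurve:
    """Mean ensemble response to one variable over its observed range."""

    variable: str
    grid: np.ndarray
    mean_hsi: np.ndarray
    n_cells: int


def variable_contributions(ensemble: EnsembleModel, X: pd.DataFrame,
                           n_permutations: int = 3, seed: int = 0,
                           ) -> pd.Series:
    """Raw permutation importances, one per column of X, each in [0, 1]."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    base = ensemble.predict_rows(X)
    if np.ptp(base) == 0:
        warnings.warn("ensemble predictions are constant; importances set to 0",
                      stacklevel=2)
        return pd.Series(0.0, index=X.columns)
    rng = np.random.default_rng(seed)
    out = {}
    for var in X.columns:
        vals = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[var] = rng.permutation(Xp[var].to_numpy())
            perm = ensemble.predict_rows(Xp)
            if np.array_equal(perm, base):  # variable unused: exactly 0
                vals.append(0.0)
                continue
            if np.ptp(perm) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(base, perm)[0, 1])
            vals.append(np.clip(1.0 - r, 0.0, 1.0))
        out[var] = float(np.mean(vals))
    return pd.Series(out)


def normalize_contributions(raw: pd.Series) -> ImportanceTable:
    """Scale raw importances to percentages (sum 100), sort, accumulate."""
    raw = raw.astype(float)
    if (raw < 0).any():
        raise ValueError("raw importances must be nonnegative")
    total = raw.sum()
    if total <= 0:
        raise ValueError("all importances are zero; nothing to normalize")
    pct = (raw / total * 100.0).sort_values(ascending=False)
    df = pd.DataFrame({
        "variable": pct.index,
        "contribution_pct": pct.to_numpy(),
        "cumulative_pct": pct.cumsum().to_numpy(),
    }).reset_index(drop=True)
    return ImportanceTable(table=df)


def key_variable_count(table: ImportanceTable, cumulative_min: float = 90.0) -> int:
    """Smallest k whose top-k cumulative contribution reaches the threshold."""
    cum = table.table["cumulative_pct"].to_numpy()
    return int(np.searchsorted(cum, cumulative_min - 1e-9) + 1)


def response_curve(ensemble: EnsembleModel, landscape: Landscape,
                   variable: str, n_grid: int = 50, seed: int = 0,
                   variables: list[str] | None = None) -> ResponseCurve:
    """Evaluation-strip mean response of HSI to one variable."""
    variables = variables or ensemble.members[0].variables
    if variable not in variables:
        raise ValueError(f"{variable!r} is not among the predictors {variables}")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    df = landscape.table(variables)
    if len(df) > MAX_RESPONSE_CELLS:
        rng = np.random.default_rng(seed)
        df = df.iloc[rng.choice(len(df), MAX_RESPONSE_CELLS, replace=False)]
    lo = df[variable].min()
    hi = df[variable].max()
    if hi <= lo:
        raise ValueError(f"variable {variable!r} is constant over the mask")
    grid = np.linspace(lo, hi, n_grid)
    X = df[variables].copy()
    mean_hsi = np.empty(n_grid)
    for i, v in enumerate(grid):
        X[variable] = v
        mean_hsi[i] = ensemble.predict_rows(X).mean()
    return ResponseCurve(variable=variable, grid=grid, mean_hsi=mean_hsi,
                         n_cells=len(df))


def best_suitable_range(curve: ResponseCurve, criterion: str = "half_max",
                        ) -> tuple[float, float, dict]:
    """Contiguous high-response interval around the curve maximum.

    criterion "half_max": response >= 0.5 * max(curve); "absolute":
    response >= 0.5 in HSI units.  Returns (low, high, meta); meta records
    the criterion, the level used and a multimodality flag (set when
    qualifying grid points are not contiguous — the reported interval is
    then the widest contiguous block containing the global maximum).
    """
    y = np.asarray(curve.mean_hsi, dtype=float)
    if criterion == "half_max":
        level = 0.5 * y.max()
    elif criterion == "absolute":
        level = 0.5
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    ok = y >= level
    if not ok.any():
        return float("nan"), float("nan"), {
            "criterion": criterion, "level": level, "multimodal": False,
            "empty": True}
    imax = int(np.argmax(y))
    lo = imax
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = imax
    while hi < y.size - 1 and ok[hi + 1]:
        hi += 1
    multimodal = int(ok.sum()) != (hi - lo + 1)
    meta = {"criterion": criterion, "level": float(level),
            "multimodal": bool(multimodal), "empty": False}
    return float(curve.grid[lo]), float(curve.grid[hi]), meta


def importance_report(ensemble: EnsembleModel, landscape: Landscape,
                      variables: list[str], n_permutations: int = 3,
                      n_grid: int = 50, seed: int = 0,
                      criterion: str = "half_max") -> pd.DataFrame:
    """Full per-variable report: contribution, cumulative, best range."""
    df = landscape.table(variables)
    raw = variable_contributions(ensemble, df[variables],
                                 n_permutations=n_permutations, seed=seed)
    table = normalize_contributions(raw).table
    lows, highs = [], []
    for var in table["variable"]:
        curve = response_curve(ensemble, landscape, var, n_grid=n_grid,
                               seed=seed, variables=variables)
        lo, hi, _ = best_suitable_range(curve, criterion=criterion)
        lows.append(lo)
        highs.append(hi)
    table["best_range_low"] = lows
    table["best_range_high"] = highs
    return table
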