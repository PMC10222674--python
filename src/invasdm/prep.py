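"""Occurrence and predictor preparation.

Two standard pre-modelling steps:

* **Fishnet thinning** — occurrence records are reduced to at most one per
  grid cell at a chosen resolution (duplicates and sub-cell clusters
  collapse to the cell centre), which removes pseudo-replication from
  densely digitized source maps.
* **Collinearity screening** — pairwise Pearson correlations between
  candidate layers are computed over mask cells, and greedy elimination
  drops the lower-priority member of every pair with |r| at or above the
  threshold (default 0.7), a widely used cutoff for bioclimatic predictors.

The screen is exposed both as plain functions and as a scikit-learn
transformer (:class:`CollinearityFilter`) usable inside pipelines.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .raster import Landscape

__all__ = [
    "OccurrenceSet",
    "ScreenReport",
    "CollinearityFilter",
    "thin_occurrences",
    "screen_collinearity",
    "extract_design",
]


@dataclass
class OccurrenceSet:
    """Thinned presence records: one representative point per occupied cell."""

    species: str
    x: np.ndarray
    y: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    resolution: float
    n_input: int
    n_dropped_off_mask: int

    @property
    def n_records(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species": self.species, "x": self.x, "y": self.y})

    def save_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


@dataclass
class ScreenReport:
    """Outcome of the pairwise-correlation screen, reproducible for audit."""

    correlation: pd.DataFrame
    kept: list[str]
    dropped: list[dict] = field(default_factory=list)
    threshold: float = 0.7
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "threshold": self.threshold,
            "kept": self.kept,
            "dropped": self.dropped,
            "warnings": self.warnings,
            "correlation": self.correlation.round(6).to_dict(),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def thin_occurrences(points: pd.DataFrame, landscape: Landscape,
                     resolution: float | None = None,
                     species: str | None = None) -> OccurrenceSet:
    """Fishnet-thin presence points to one record per occupied grid cell.

    Points are assigned to cells by the half-open [edge, edge + res)
    convention; each occupied on-mask cell contributes its centre as the
    representative record.  Off-mask and off-grid points are dropped and
    counted.  Thinning is idempotent.

    Parameters
    ----------
    points : DataFrame with columns x, y (and optionally species).
    resolution : thinning cell size in map units; must equal the landscape
        cell size (the supported fishnet aligns with the analysis grid) or a
        positive integer multiple of it.
    """
    if len(points) == 0:
        raise ValueError("no occurrence points supplied")
    res = float(resolution if resolution is not None else landscape.transform.res)
    base = landscape.transform.res
    if res < base:
        raise ValueError(f"thinning resolution {res} is below cell size {base}")
    factor = res / base
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("thinning resolution must be an integer multiple of "
                         "the landscape cell size")
    factor = int(round(factor))

    x = np.asarray(points["x"], dtype=float)
    y = np.asarray(points["y"], dtype=float)
    row, col = landscape.transform.cell_of(x, y)
    nr, nc = landscape.shape
    inside = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
    on_mask = inside.copy()
    on_mask[inside] = landscape.mask[row[inside], col[inside]]
    n_dropped = int((~on_mask).sum())
    row, col = row[on_mask], col[on_mask]

    # fishnet cell at the requested resolution, then a representative
    # analysis cell (the first on-mask member encountered) per fishnet cell
    frow, fcol = row // factor, col // factor
    order = np.lexsort((col, row, fcol, frow))
    frow_s, fcol_s = frow[order], fcol[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = (frow_s[1:] != frow_s[:-1]) | (fcol_s[1:] != fcol_s[:-1])
    keep = order[first]
    krow, kcol = row[keep], col[keep]
    cx, cy = landscape.transform.cell_center(krow, kcol)

    sp = species or (str(points["species"].iloc[0]) if "species" in points else "species")
    return OccurrenceSet(species=sp, x=cx, y=cy, rows=krow, cols=kcol,
                         resolution=res, n_input=len(points),
                         n_dropped_off_mask=n_dropped)


def _pearson_matrix(landscape: Landscape, variables: list[str]) -> tuple[pd.DataFrame, list[str]]:
    rows, cols = landscape.mask_cells()
    mat = landscape.values_at_cells(rows, cols, variables)
    sd = mat.std(axis=0)
    constant = [v for v, s in zip(variables, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    return pd.DataFrame(corr, index=variables, columns=variables), constant


def screen_collinearity(landscape: Landscape, candidate_vars: list[str] | None = None,
                        threshold: float = 0.7,
                        priority: list[str] | None = None) -> ScreenReport:
    """Greedy |r|-based variable elimination over mask cells.

    While any kept pair has |Pearson r| >= ``threshold``, the lower-priority
    member is dropped (priority defaults to the input order; earlier is
    higher).  Constant layers, whose correlation is undefined, are dropped
    up front with a warning.  Every kept pair therefore satisfies
    |r| < threshold.
    """
    variables = list(candidate_vars or landscape.layer_names)
    if len(variables) < 2:
        raise ValueError("need at least two candidate variables")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    order = list(priority or variables)
    missing = [v for v in variables if v not in order]
    order = order + missing  # unlisted variables rank last, input order
    rank = {v: i for i, v in enumerate(order)}

    corr, constant = _pearson_matrix(landscape, variables)
    warns = []
    kept = [v for v in variables if v not in constant]
    dropped = [{"variable": v, "reason": "constant layer (undefined r)",
                "conflict_with": None} for v in constant]
    for v in constant:
        msg = f"dropping constant layer {v!r}: Pearson r undefined"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)

    while True:
        worst = None
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                r = abs(corr.loc[a, b])
                if r >= threshold and (worst is None or r > worst[0]):
                    worst = (r, a, b)
        if worst is None:
            break
        r, a, b = worst
        loser, winner = (a, b) if rank[a] > rank[b] else (b, a)
        kept.remove(loser)
        dropped.append({"variable": loser, "reason": f"|r|={r:.4f} >= {threshold}",
                        "conflict_with": winner})

    return ScreenReport(correlation=corr, kept=kept, dropped=dropped,
                        threshold=threshold, warnings=warns)


class CollinearityFilter(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer applying the greedy |r| < threshold screen.

    Fit computes pairwise Pearson correlations over the rows of X and
    eliminates columns exactly as :func:`screen_collinearity` does over mask
    cells; transform selects the kept columns.

    Parameters
    ----------
    threshold : float, default 0.7
        Pairs with |r| >= threshold conflict.
    priority : list of column names or indices, optional
        Higher priority (earlier) columns win conflicts; defaults to column
        order.

    Attributes
    ----------
    kept_ : list
        Names (DataFrame input) or indices of retained columns.
    correlation_ : DataFrame
        Full pairwise correlation matrix.
    dropped_ : list of dict
        Audit trail of eliminations.
    """

    def __init__(self, threshold: float = 0.7, priority: list | None = None):
        self.threshold = threshold
        self.priority = priority

    def fit(self, X, y=None):
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            mat = X.to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            names = list(range(mat.shape[1]))
        if mat.shape[1] < 2:
            raise ValueError("need at least two columns")
        order = list(self.priority or names)
        order += [v for v in names if v not in order]
        rank = {v: i for i, v in enumerate(order)}

        sd = mat.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(mat, rowvar=False)
        corr = pd.DataFrame(corr, index=names, columns=names)
        kept = [v for v, s in zip(names, sd) if s > 0]
        dropped = [{"variable": v, "reason": "constant column (undefined r)",
                    "conflict_with": None} for v, s in zip(names, sd) if s == 0]
        while True:
            worst = None
            for i, a in enumerate(kept):
                for b in kept[i + 1:]:
                    r = abs(corr.loc[a, b])
                    if r >= self.threshold and (worst is None or r > worst[0]):
                        worst = (r, a, b)
            if worst is None:
                break
            r, a, b = worst
            loser, winner = (a, b) if rank[a] > rank[b] else (b, a)
            kept.remove(loser)
            dropped.append({"variable": loser,
                            "reason": f"|r|={r:.4f} >= {self.threshold}",
                            "conflict_with": winner})
        self.kept_ = kept
        self.correlation_ = corr
        self.dropped_ = dropped
        self.n_features_in_ = mat.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "kept_")
        if isinstance(X, pd.DataFrame):
            return X[self.kept_]
        return np.asarray(X)[:, self.kept_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "kept_")
        return np.asarray([str(v) for v in self.kept_])


def extract_design(landscape: Landscape, occ: OccurrenceSet,
                   variables: list[str]) -> pd.DataFrame:
    """Per-point design matrix: layer values at each record's cell.

    Column order follows ``variables``.  A record on a no-data cell is an
    error (such points should not survive thinning).
    """
    unknown = [v for v in variables if v not in landscape.layers]
    if unknown:
        raise ValueError(f"unknown variables: {unknown}")
    mat = landscape.values_at_cells(occ.rows, occ.cols, variables)
    return pd.DataFrame(mat, columns=variables)
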