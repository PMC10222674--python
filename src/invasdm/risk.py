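"""Invasion risk index: overlay of invader and native suitability surfaces.

The invasion risk index at a cell is the difference of habitat suitability
indices,

    IRI = HSI_invader - HSI_native,

bounded in [-1, 1] because both inputs live in [0, 1].  Positive IRI marks
habitat more suitable for the invader than for the resident native
community, i.e. where displacement pressure concentrates; negative IRI
marks native-favoured habitat.  A binary high/low risk layer thresholds the
IRI (default threshold 0: high risk strictly above 0, matching the sign
interpretation).

For summaries, an ordinary-least-squares regression of IRI on invader HSI
is fitted per region with the standard 95% confidence band of the mean
response (statsmodels OLS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ensemble import SuitabilityMap
from .raster import Landscape

__all__ = [
    "RiskMap",
    "RiskRegression",
    "compute_iri",
    "binarize_risk",
    "fit_risk_regression",
]


@dataclass
class RiskMap:
    """Cellwise IRI surface (NaN off-mask) with provenance."""

    iri: np.ndarray
    mask: np.ndarray
    landscape: Landscape
    invader: str = "invader"
    native: str = "native"
    meta: dict | None = None

    def save(self, path) -> None:
        from .raster import write_band

        arr = np.where(self.mask, self.iri, self.landscape.nodata)
        write_band(path, arr, self.landscape.transform,
                   nodata=self.landscape.nodata)


@dataclass
class RiskRegression:
    """OLS fit of IRI on invader HSI over one region's cells."""

    region: str
    slope: float
    intercept: float
    slope_se: float
    n_cells: int
    r_squared: float
    status: str = "ok"
    band: pd.DataFrame | None = None  # columns: hsi, fit, ci_low, ci_high


def compute_iri(invader_map: SuitabilityMap, native_map: SuitabilityMap) -> RiskMap:
    """Cellwise IRI = invader HSI - native HSI on the shared mask."""
    if invader_map.hsi.shape != native_map.hsi.shape:
        raise ValueError("suitability maps are not co-registered "
                         f"({invader_map.hsi.shape} vs {native_map.hsi.shape})")
    if not np.array_equal(invader_map.mask, native_map.mask):
        raise ValueError("suitability maps have different masks")
    iri = invader_map.hsi - native_map.hsi
    meta = {"positive_means": f"more suitable for {invader_map.species or 'the invader'}",
            "range": [-1.0, 1.0]}
    return RiskMap(iri=iri, mask=invader_map.mask,
                   landscape=invader_map.landscape,
                   invader=invader_map.species, native=native_map.species,
                   meta=meta)


def binarize_risk(risk_map: RiskMap, threshold: float = 0.0) -> np.ndarray:
    """High-risk indicator: True where IRI > threshold (boundary exclusive)."""
    if not (-1.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [-1, 1]")
    out = np.zeros(risk_map.iri.shape, dtype=bool)
    ok = np.isfinite(risk_map.iri)
    out[ok] = risk_map.iri[ok] > threshold
    return out


def fit_risk_regression(risk_map: RiskMap, invader_map: SuitabilityMap,
                        regions: np.ndarray | None = None,
                        n_band_points: int = 100) -> list[RiskRegression]:
    """Per-region OLS of IRI on invader HSI with 95% mean-response band.

    ``regions`` is an optional categorical raster of region labels aligned
    with the mask; with none supplied the whole mask forms one region.
    Regions with constant invader HSI are reported as degenerate.
    """
    if risk_map.iri.shape != invader_map.hsi.shape:
        raise ValueError("risk map and invader map are not co-registered")
    mask = risk_map.mask & np.isfinite(risk_map.iri)
    if regions is None:
        regions = np.where(mask, "all", "")
    regions = np.asarray(regions)
    results: list[RiskRegression] = []
    for label in sorted({str(v) for v in np.unique(regions[mask])}):
        sel = mask & (regions.astype(str) == label)
        hsi = invader_map.hsi[sel]
        iri = risk_map.iri[sel]
        n = hsi.size
        if n < 3:
            raise ValueError(f"region {label!r} has fewer than 3 cells")
        if np.ptp(hsi) == 0:
            results.append(RiskRegression(region=label, slope=np.nan,
                                          intercept=np.nan, slope_se=np.nan,
                                          n_cells=n, r_squared=np.nan,
                                          status="degenerate: constant HSI"))
            continue
        Xd = sm.add_constant(hsi)
        fit = sm.OLS(iri, Xd).fit()
        grid = np.linspace(hsi.min(), hsi.max(), n_band_points)
        pred = fit.get_prediction(sm.add_constant(grid))
        ci = pred.conf_int(alpha=0.05)
        band = pd.DataFrame({"hsi": grid, "fit": pred.predicted_mean,
                             "ci_low": ci[:, 0], "ci_high": ci[:, 1]})
        results.append(RiskRegression(
            region=label, slope=float(fit.params[1]),
            intercept=float(fit.params[0]), slope_se=float(fit.bse[1]),
            n_cells=n, r_squared=float(fit.rsquared), band=band))
    return results


def regression_table(regressions: list[RiskRegression]) -> pd.DataFrame:
    return pd.DataFrame([{
        "region": r.region, "slope": r.slope, "intercept": r.intercept,
        "slope_se": r.slope_se, "n_cells": r.n_cells,
        "r_squared": r.r_squared, "status": r.status,
    } for r in regressions])
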