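"""Virtual landscapes and virtual species with known truth.

Species distribution models are hard to validate on real occurrence data
because the true niche is unknown.  The virtual-species approach sidesteps
this: environmental layers are simulated as spatially smooth correlated
random fields, a species' true suitability is a known product of parametric
per-variable response curves, and presences are sampled in proportion to
that truth.  Every downstream stage (thinning, screening, model fitting,
ensembling, importance, risk overlay) can then be checked by parameter
recovery against the retained truth maps.

The simulation assumes distribution-environment equilibrium: occupied
locations are a probability sample of suitable environmental space, with no
dispersal limitation or demographic lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import GridTransform, Landscape

__all__ = [
    "GaussianResponse",
    "LogisticResponse",
    "TrueNiche",
    "VirtualSample",
    "make_landscape",
    "make_species",
    "make_invasion_scenario",
    "demo_scenario",
]


# ---------------------------------------------------------------------------
# response curves and niches
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianResponse:
    """Bell-shaped response: exp(-(v - optimum)^2 / (2 * breadth^2))."""

    optimum: float
    breadth: float

    def __call__(self, v: np.ndarray) -> np.ndarray:
        return np.exp(-((np.asarray(v, dtype=float) - self.optimum) ** 2)
                      / (2.0 * self.breadth ** 2))


@dataclass(frozen=True)
class LogisticResponse:
    """Sigmoid response: 1 / (1 + exp(-(v - midpoint) / slope)).

    Positive slope favours high values of the variable, negative slope low
    values.
    """

    midpoint: float
    slope: float

    def __call__(self, v: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        z = (np.asarray(v, dtype=float) - self.midpoint) / self.slope
        return expit(z)


@dataclass
class TrueNiche:
    """Known multi-variable niche: product of per-variable responses.

    The product is rescaled so its maximum over the mask equals 1, which
    keeps truth in [0, 1] and makes "best suitable range" recovery
    well-posed.  `prevalence_target`, if set, is recorded for reference; the
    sampler works directly with the continuous truth.
    """

    responses: dict[str, GaussianResponse | LogisticResponse]
    prevalence_target: float | None = None

    def truth_map(self, landscape: Landscape) -> np.ndarray:
        """Per-cell true suitability in [0, 1]; NaN off the mask."""
        missing = [v for v in self.responses if v not in landscape.layers]
        if missing:
            raise ValueError(f"niche references unknown layers: {missing}")
        truth = np.ones(landscape.shape)
        for var, resp in self.responses.items():
            vals = landscape.layers[var]
            truth = truth * resp(vals)
        truth[~landscape.mask] = np.nan
        peak = np.nanmax(truth)
        if not np.isfinite(peak) or peak <= 0:
            raise ValueError("niche yields all-zero truth on the mask; "
                             "no presence can ever be sampled")
        truth = truth / peak
        return truth


@dataclass
class VirtualSample:
    """Presence points for one virtual species, with its truth map retained."""

    species: str
    x: np.ndarray
    y: np.ndarray
    truth: np.ndarray
    landscape: Landscape
    seed: int
    niche: TrueNiche | None = None

    @property
    def n_points(self) -> int:
        return self.x.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"species": self.species, "x": self.x, "y": self.y})


# ---------------------------------------------------------------------------
# landscape generation
# ---------------------------------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized Gaussian-filtered white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="wrap")
    return (f - f.mean()) / f.std()


def _coastal_mask(shape, rng: np.random.Generator, band_fraction: float = 0.6) -> np.ndarray:
    """Band of cells around a wavy 'coastline' running down the grid."""
    nr, nc = shape
    rows = np.arange(nr)
    # smooth meandering centreline across columns
    wiggle = ndimage.gaussian_filter1d(rng.standard_normal(nr), sigma=nr / 8,
                                       mode="wrap")
    wiggle = (wiggle - wiggle.mean()) / (wiggle.std() + 1e-12)
    centre = nc / 2 + wiggle * nc / 8
    half_width = band_fraction * nc / 2
    cols = np.arange(nc)
    mask = np.abs(cols[None, :] - centre[:, None]) <= half_width
    return mask


def make_landscape(shape: tuple[int, int] = (128, 128), n_layers: int = 12,
                   correlation: float = 0.3, mask_style: str = "coastal",
                   seed: int = 0, smoothness: float = 6.0,
                   cell_size: float = 1000.0,
                   layer_names: list[str] | None = None) -> Landscape:
    """Generate correlated smooth environmental layers over a masked grid.

    Each layer is sqrt(1-c) * own field + sqrt(c) * shared latent field, so
    the expected pairwise Pearson correlation between layers equals
    ``correlation``.  Fields are Gaussian-filtered white noise, standardized,
    then given distinct affine scales so layers look like different
    environmental variables ("env01" in one range, "env02" in another).

    Parameters
    ----------
    shape : grid (rows, cols), at least 32 x 32.
    n_layers : number of environmental variables, >= 2.
    correlation : shared-field weight in [0, 1).
    mask_style : "coastal" keeps a meandering band of cells (emulating a
        coastal study strip); "all" keeps every cell.
    seed : integer seed; same seed gives a bit-identical landscape.
    smoothness : Gaussian filter sigma in cells.
    cell_size : cell edge length in map units (default 1 km in metres).
    """
    nr, nc = shape
    if nr < 32 or nc < 32:
        raise ValueError(f"shape must be at least 32x32, got {shape}")
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    if not (0.0 <= correlation < 1.0):
        raise ValueError(f"correlation must be in [0, 1), got {correlation}")

    rng = np.random.default_rng(seed)
    shared = _smooth_field(rng, shape, smoothness)
    names = layer_names or [f"env{k + 1:02d}" for k in range(n_layers)]
    if len(names) != n_layers:
        raise ValueError("layer_names length must equal n_layers")

    w_shared = np.sqrt(correlation)
    w_own = np.sqrt(1.0 - correlation)
    layers: dict[str, np.ndarray] = {}
    for k, name in enumerate(names):
        own = _smooth_field(rng, shape, smoothness)
        z = w_own * own + w_shared * shared
        # distinct affine scale per variable: mean 10k+10, sd 2+k/2
        layers[name] = (10.0 * k + 10.0) + (2.0 + 0.5 * k) * z

    if mask_style == "coastal":
        mask = _coastal_mask(shape, rng)
    elif mask_style == "all":
        mask = np.ones(shape, dtype=bool)
    else:
        raise ValueError(f"unknown mask_style {mask_style!r}")

    transform = GridTransform(x0=0.0, y0=nr * cell_size, res=cell_size)
    return Landscape(layers=layers, mask=mask, transform=transform, seed=seed)


# ---------------------------------------------------------------------------
# species generation
# ---------------------------------------------------------------------------


def make_species(landscape: Landscape, niche: TrueNiche, n_presence: int = 500,
                 seed: int = 0, species: str = "virtual",
                 n_jitter_duplicates: int = 0) -> VirtualSample:
    """Sample presence points proportionally to the niche's true suitability.

    Presences are drawn without replacement from mask cells with probability
    proportional to truth, then placed at cell centres.  Optionally,
    ``n_jitter_duplicates`` extra points are added as sub-cell jitters of
    randomly chosen presences, so that grid thinning has duplicates to
    remove.
    """
    if n_presence < 30:
        raise ValueError("n_presence must be >= 30 for a usable sample")
    truth = niche.truth_map(landscape)
    rows, cols = landscape.mask_cells()
    p = truth[rows, cols]
    p = np.where(np.isfinite(p), p, 0.0)
    total = p.sum()
    if total <= 0:
        raise ValueError("truth map is all zero on the mask")
    if n_presence > p.size:
        raise ValueError("n_presence exceeds number of mask cells")
    rng = np.random.default_rng(seed)
    idx = rng.choice(p.size, size=n_presence, replace=False, p=p / total)
    x, y = landscape.transform.cell_center(rows[idx], cols[idx])

    if n_jitter_duplicates > 0:
        pick = rng.integers(0, n_presence, size=n_jitter_duplicates)
        res = landscape.transform.res
        jx = x[pick] + rng.uniform(-0.49, 0.49, size=n_jitter_duplicates) * res
        jy = y[pick] + rng.uniform(-0.49, 0.49, size=n_jitter_duplicates) * res
        x = np.concatenate([x, jx])
        y = np.concatenate([y, jy])

    return VirtualSample(species=species, x=x, y=y, truth=truth,
                         landscape=landscape, seed=seed, niche=niche)


def make_invasion_scenario(landscape: Landscape, native_niche: TrueNiche,
                           invader_niche: TrueNiche, seed: int = 0,
                           n_presence: int = 500,
                           native_species: str = "native",
                           invader_species: str = "invader",
                           ) -> tuple[VirtualSample, VirtualSample]:
    """Two virtual species on one landscape, truth maps retained.

    The true invasion risk index, truth_invader - truth_native, is exactly
    known, enabling recovery tests of the risk overlay.
    """
    shared_vars = set(native_niche.responses) & set(invader_niche.responses)
    if not shared_vars:
        raise ValueError("niches must overlap on at least one layer")
    ss = np.random.SeedSequence(seed)
    s_native, s_invader = (int(c.generate_state(1)[0] % 2**31)
                           for c in ss.spawn(2))
    native = make_species(landscape, native_niche, n_presence=n_presence,
                          seed=s_native, species=native_species)
    invader = make_species(landscape, invader_niche, n_presence=n_presence,
                           seed=s_invader, species=invader_species)
    return native, invader


# ---------------------------------------------------------------------------
# canonical demo scenario
# ---------------------------------------------------------------------------


def demo_niches() -> tuple[TrueNiche, TrueNiche]:
    """Strong-signal native and invader niches for the demo landscape.

    Both species respond to env01 and env03; the invader's thermal-analogue
    optimum on env01 is shifted up one layer standard deviation, so the two
    niches overlap but diverge along that gradient.  Breadths are about a
    sixth of each layer's spread, concentrated enough that presences are
    clearly separable from uniform background cells.
    """
    native = TrueNiche({
        "env01": GaussianResponse(optimum=10.0, breadth=0.35),
        "env03": GaussianResponse(optimum=31.0, breadth=0.61),
    })
    invader = TrueNiche({
        "env01": GaussianResponse(optimum=12.0, breadth=0.35),
        "env03": GaussianResponse(optimum=31.0, breadth=0.61),
    })
    return native, invader


def demo_scenario(shape: tuple[int, int] = (128, 128), seed: int = 0,
                  n_presence: int = 500, n_layers: int = 12,
                  with_collinear_layer: bool = True,
                  ) -> tuple[Landscape, VirtualSample, VirtualSample]:
    """Canonical synthetic study system: landscape + native + invader.

    A coastal-band landscape with ``n_layers`` moderately correlated
    environmental variables (plus, by default, one near-duplicate of env01
    so the collinearity screen has something to drop), and two overlapping
    strong-signal virtual species sampled at ``n_presence`` points each,
    with 100 sub-cell jitter duplicates apiece so fishnet thinning is
    exercised.
    """
    landscape = make_landscape(shape=shape, n_layers=n_layers,
                               correlation=0.3, mask_style="coastal",
                               seed=seed)
    if with_collinear_layer:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
        base = landscape.layers["env01"]
        dup = np.where(landscape.mask,
                       base + 0.1 * rng.standard_normal(landscape.shape),
                       landscape.nodata)
        landscape.layers["env_dup"] = dup
        landscape._order.append("env_dup")
    native_niche, invader_niche = demo_niches()
    ss = np.random.SeedSequence([seed, 7])
    s_nat, s_inv = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    native = make_species(landscape, native_niche, n_presence=n_presence,
                          seed=s_nat, species="native",
                          n_jitter_duplicates=100)
    invader = make_species(landscape, invader_niche, n_presence=n_presence,
                           seed=s_inv, species="invader",
                           n_jitter_duplicates=100)
    return landscape, native, invader
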