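"""Shared fixtures: small virtual landscapes and a fitted mini-ensemble.

Everything is generated programmatically and seeded, so the suite needs no
data files and is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

import invasdm as iv
from invasdm.models import ProtocolConfig


@pytest.fixture(scope="session")
def landscape64():
    """64x64 coastal landscape, 6 moderately correlated layers."""
    return iv.make_landscape(shape=(64, 64), n_layers=6, correlation=0.3,
                             mask_style="coastal", seed=11)


@pytest.fixture(scope="session")
def strong_species(landscape64):
    """Virtual species dominated by env01 (narrow optimum), weak env03 effect."""
    niche = iv.TrueNiche({
        "env01": iv.GaussianResponse(optimum=10.0, breadth=0.35),
        "env03": iv.GaussianResponse(optimum=31.0, breadth=2.5),
    })
    return iv.make_species(landscape64, niche, n_presence=300, seed=12,
                           species="strong")


@pytest.fixture(scope="session")
def fitted_small(landscape64, strong_species):
    """Small fitted ensemble (RF+GLM, 1 repetition, 1 PA set of 600)."""
    occ = iv.thin_occurrences(strong_species.to_frame(), landscape64)
    cfg = ProtocolConfig(algorithms=("RF", "GLM"), n_repetitions=1,
                         n_pa_sets=1, n_pseudo_absences=600,
                         hyperparams={"RF": {"n_estimators": 200}})
    runs = iv.run_ensemble_protocol(landscape64, occ,
                                    landscape64.layer_names, cfg, seed=13)
    ensemble = iv.EnsembleModel.from_runs(runs, gate=0.7)
    assert ensemble.n_members > 0, "fixture ensemble failed to gate any member"
    return {"landscape": landscape64, "species": strong_species, "occ": occ,
            "runs": runs, "ensemble": ensemble,
            "variables": landscape64.layer_names}


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
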