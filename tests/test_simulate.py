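"""Virtual landscape and virtual species generation."""

import numpy as np
import pytest

import invasdm as iv
from invasdm.simulate import demo_scenario


def _pairwise_r(landscape, a, b):
    rows, cols = landscape.mask_cells()
    va = landscape.layers[a][rows, cols]
    vb = landscape.layers[b][rows, cols]
    return float(np.corrcoef(va, vb)[0, 1])


class TestMakeLandscape:
    def test_same_seed_is_bit_identical(self):
        a = iv.make_landscape(shape=(32, 32), n_layers=3, seed=4)
        b = iv.make_landscape(shape=(32, 32), n_layers=3, seed=4)
        assert np.array_equal(a.mask, b.mask)
        for name in a.layer_names:
            assert np.array_equal(a.layers[name], b.layers[name])

    def test_zero_correlation_gives_near_independent_layers(self):
        # smoothed fields have few effective degrees of freedom, so allow a
        # generous Monte-Carlo band around 0
        land = iv.make_landscape(shape=(128, 128), n_layers=4,
                                 correlation=0.0, mask_style="all", seed=7)
        rs = [abs(_pairwise_r(land, a, b))
              for i, a in enumerate(land.layer_names)
              for b in land.layer_names[i + 1:]]
        assert np.median(rs) < 0.35

    def test_high_correlation_triggers_screen(self):
        land = iv.make_landscape(shape=(64, 64), n_layers=2,
                                 correlation=0.95, mask_style="all", seed=8)
        r = _pairwise_r(land, "env01", "env02")
        assert abs(r) > 0.7
        report = iv.screen_collinearity(land, threshold=0.7)
        assert len(report.kept) == 1

    @pytest.mark.parametrize("kwargs", [
        {"shape": (16, 64)},
        {"n_layers": 1},
        {"correlation": 1.0},
        {"correlation": -0.1},
        {"mask_style": "bogus"},
    ])
    def test_degenerate_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            iv.make_landscape(**{"shape": (32, 32), "n_layers": 2, **kwargs})

    def test_layers_share_mask_and_nodata_sentinel(self, landscape64):
        for name in landscape64.layer_names:
            arr = landscape64.layers[name]
            assert np.all(arr[~landscape64.mask] == landscape64.nodata)
            assert np.all(np.isfinite(arr[landscape64.mask]))


class TestMakeSpecies:
    def test_presence_count_and_on_mask(self, landscape64):
        niche = iv.TrueNiche({"env01": iv.GaussianResponse(10.0, 1.0)})
        vs = iv.make_species(landscape64, niche, n_presence=100, seed=3)
        assert vs.n_points == 100
        assert np.all(landscape64.on_mask(vs.x, vs.y))

    def test_truth_maximal_at_gaussian_optimum(self, landscape64):
        niche = iv.TrueNiche({"env01": iv.GaussianResponse(10.0, 1.0)})
        truth = niche.truth_map(landscape64)
        rows, cols = landscape64.mask_cells()
        vals = landscape64.layers["env01"][rows, cols]
        t = truth[rows, cols]
        # the cell nearest the optimum attains the map maximum
        assert t[np.argmin(np.abs(vals - 10.0))] == pytest.approx(t.max(), abs=1e-6)
        assert np.nanmax(truth) == pytest.approx(1.0)
        assert np.nanmin(truth) >= 0.0

    def test_presences_prefer_suitable_cells(self, landscape64, strong_species):
        truth = strong_species.truth
        rows, cols = landscape64.transform.cell_of(strong_species.x,
                                                   strong_species.y)
        mean_at_presence = truth[rows, cols].mean()
        mean_overall = np.nanmean(truth)
        assert mean_at_presence > mean_overall

    def test_presence_density_monotone_in_truth(self):
        # deciles of truth should attract monotonically more presences per cell
        land = iv.make_landscape(shape=(96, 96), n_layers=3, mask_style="all",
                                 seed=21)
        niche = iv.TrueNiche({"env01": iv.GaussianResponse(10.0, 2.0)})
        vs = iv.make_species(land, niche, n_presence=2000, seed=22)
        rows, cols = land.transform.cell_of(vs.x, vs.y)
        t_presence = vs.truth[rows, cols]
        t_all = vs.truth[land.mask]
        edges = np.quantile(t_all, np.linspace(0, 1, 11))
        edges[-1] += 1e-9
        per_cell = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            n_cells = ((t_all >= lo) & (t_all < hi)).sum()
            n_pres = ((t_presence >= lo) & (t_presence < hi)).sum()
            per_cell.append(n_pres / max(n_cells, 1))
        # allow small non-monotonic jitter in sparse deciles
        diffs = np.diff(per_cell)
        assert (diffs >= -1e-3).sum() >= 8
        assert per_cell[-1] > per_cell[0]

    def test_truth_invariant_to_layer_order(self, landscape64):
        niche = iv.TrueNiche({"env01": iv.GaussianResponse(10.0, 1.0),
                              "env03": iv.GaussianResponse(31.0, 2.0)})
        t1 = niche.truth_map(landscape64)
        reordered = iv.Landscape(
            layers={k: landscape64.layers[k]
                    for k in reversed(landscape64.layer_names)},
            mask=landscape64.mask, transform=landscape64.transform)
        t2 = niche.truth_map(reordered)
        assert np.array_equal(t1, t2, equal_nan=True)

    def test_all_zero_truth_is_error(self, landscape64):
        niche = iv.TrueNiche({"env01": iv.GaussianResponse(1e6, 1e-3)})
        with pytest.raises(ValueError, match="zero"):
            iv.make_species(landscape64, niche, n_presence=50, seed=1)

    def test_jitter_duplicates_extend_point_count(self, landscape64):
        niche = iv.TrueNiche({"env01": iv.GaussianResponse(10.0, 1.0)})
        vs = iv.make_species(landscape64, niche, n_presence=100, seed=3,
                             n_jitter_duplicates=40)
        assert vs.n_points == 140
        assert np.all(landscape64.on_mask(vs.x, vs.y))


class TestInvasionScenario:
    def test_identical_niches_give_zero_true_iri(self, landscape64):
        niche = iv.TrueNiche({"env01": iv.GaussianResponse(10.0, 1.0)})
        nat, inv = iv.make_invasion_scenario(landscape64, niche, niche, seed=5,
                                             n_presence=60)
        diff = inv.truth - nat.truth
        assert np.nanmax(np.abs(diff)) == pytest.approx(0.0, abs=1e-12)

    def test_shifted_optimum_flips_iri_sign_along_gradient(self, landscape64):
        nat = iv.TrueNiche({"env01": iv.GaussianResponse(9.0, 0.8)})
        inv = iv.TrueNiche({"env01": iv.GaussianResponse(11.0, 0.8)})
        a, b = iv.make_invasion_scenario(landscape64, nat, inv, seed=5,
                                         n_presence=60)
        iri = b.truth - a.truth
        rows, cols = landscape64.mask_cells()
        v = landscape64.layers["env01"][rows, cols]
        t = iri[rows, cols]
        assert t[v < 9.0].mean() < 0 < t[v > 11.0].mean()

    def test_disjoint_niches_reach_extreme_iri(self, landscape64):
        nat = iv.TrueNiche({"env01": iv.GaussianResponse(7.0, 0.3)})
        inv = iv.TrueNiche({"env01": iv.GaussianResponse(13.0, 0.3)})
        a, b = iv.make_invasion_scenario(landscape64, nat, inv, seed=6,
                                         n_presence=60)
        iri = b.truth - a.truth
        assert np.nanmax(np.abs(iri)) > 0.95

    def test_disjoint_variable_sets_rejected(self, landscape64):
        nat = iv.TrueNiche({"env01": iv.GaussianResponse(10.0, 1.0)})
        inv = iv.TrueNiche({"env02": iv.GaussianResponse(20.0, 1.0)})
        with pytest.raises(ValueError, match="overlap"):
            iv.make_invasion_scenario(landscape64, nat, inv, seed=1)


def test_demo_scenario_contains_collinear_layer_and_duplicates():
    land, native, invader = demo_scenario(shape=(64, 64), seed=3,
                                          n_presence=120, n_layers=6)
    assert "env_dup" in land.layer_names
    report = iv.screen_collinearity(land, threshold=0.7)
    assert "env_dup" not in report.kept
    # jittered duplicates present: thinning removes at least one point
    occ = iv.thin_occurrences(native.to_frame(), land)
    assert occ.n_records < native.n_points
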