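import numpy as np
import pytest

from hsmtransfer import synthio
from tests.conftest import SMALL_LANDSCAPE


def test_same_seed_reproduces_landscape_bitwise():
    cfg = synthio.LandscapeConfig(**SMALL_LANDSCAPE)
    l1 = synthio.make_landscape(cfg)
    l2 = synthio.make_landscape(cfg)
    np.testing.assert_array_equal(l1.bioclim.data, l2.bioclim.data)
    np.testing.assert_array_equal(l1.srad.data, l2.srad.data)
    np.testing.assert_array_equal(l1.landcover[2].data, l2.landcover[2].data)


def test_regions_are_disjoint_and_gap_is_nodata(small_landscape):
    in_a = small_landscape.region_mask("A")
    in_b = small_landscape.region_mask("B")
    assert not (in_a & in_b).any()
    assert (small_landscape.bioclim.mask == (in_a | in_b)).all()
    # the corridor between the regions carries no data
    gap = ~small_landscape.bioclim.mask
    assert gap.any()
    assert np.isnan(small_landscape.bioclim.data[:, gap]).all()


def test_overlapping_regions_are_rejected():
    with pytest.raises(synthio.ConfigurationError):
        synthio.LandscapeConfig(region_a=(0, 0, 100, 100),
                                region_b=(50, 0, 150, 100))


def test_bioclim_pool_carries_collinear_variable_families(small_landscape):
    table = small_landscape.bioclim.valid_table()
    r = np.corrcoef(table.T)
    np.fill_diagonal(r, 0.0)
    # at least one strongly collinear pair per latent family
    assert (np.abs(r) > 0.85).any()
    # ... but not everything is one big block
    assert (np.abs(r) < 0.5).any()


def test_region_b_background_is_less_heterogeneous(small_landscape):
    in_a = small_landscape.region_mask("A")
    in_b = small_landscape.region_mask("B")
    layer = small_landscape.bioclim.layer("bio01").data
    assert np.nanstd(layer[in_b]) < np.nanstd(layer[in_a])


def test_mirrored_regions_have_identical_environments():
    cfg = synthio.LandscapeConfig(**{**SMALL_LANDSCAPE,
                                     "heterogeneity": (1.0, 1.0),
                                     "mirror_regions": True})
    land = synthio.make_landscape(cfg)
    in_a = land.region_mask("A")
    in_b = land.region_mask("B")
    for k in range(3):
        np.testing.assert_allclose(land.bioclim.data[k][in_a],
                                   land.bioclim.data[k][in_b])


def test_environmental_shift_moves_region_b_means():
    base = synthio.make_landscape(synthio.LandscapeConfig(**SMALL_LANDSCAPE))
    shifted = synthio.make_landscape(
        synthio.LandscapeConfig(**{**SMALL_LANDSCAPE, "b_env_shift": 3.0}))
    in_b = base.region_mask("B")
    for k in (0, 5, 12):
        assert (np.nanmean(shifted.bioclim.data[k][in_b])
                > np.nanmean(base.bioclim.data[k][in_b]))


def test_monthly_stacks_have_seasonal_structure(small_landscape):
    s = small_landscape.srad.data
    mask = small_landscape.srad.mask
    monthly_means = np.array([np.nanmean(s[m][mask]) for m in range(12)])
    # solar radiation peaks in summer (month 7), lowest in winter
    assert monthly_means.argmax() in (5, 6, 7)
    assert monthly_means.argmin() in (0, 11, 1)


def test_presences_concentrate_in_suitable_cells(small_scenario):
    stack = small_scenario.landscape.bioclim
    suit = small_scenario.niche.true_suitability(stack, "A")
    occ = small_scenario.occ("A")
    at_presences = suit.values_at(occ.x, occ.y)
    in_a = small_scenario.region_mask("A")
    background_mean = np.nanmean(suit.data[in_a])
    assert np.mean(at_presences) > 2 * background_mean


def test_occurrences_stay_inside_their_region(small_scenario):
    for label in ("A", "B"):
        occ = small_scenario.occ(label)
        assert len(occ) > 0
        mask = small_scenario.region_mask(label)
        r, c = small_scenario.landscape.bioclim.cell_of(occ.x, occ.y)
        assert mask[r, c].all()


def test_cluster_b_realized_niche_is_narrower(small_scenario):
    stack = small_scenario.landscape.bioclim
    var = small_scenario.config.niche_vars[0]
    vals_a = stack.layer(var).values_at(*_xy(small_scenario.occ("A")))
    vals_b = stack.layer(var).values_at(*_xy(small_scenario.occ("B")))
    assert np.std(vals_b) < np.std(vals_a)


def _xy(occ):
    return occ.x, occ.y


def test_truth_overlap_is_partial_for_disjunct_scenario(small_scenario):
    d = synthio.truth_overlap(small_scenario)
    assert 0.0 < d < 1.0


def test_truth_overlap_is_one_for_mirrored_equal_niches():
    cfg = synthio.ScenarioConfig(
        landscape=synthio.LandscapeConfig(
            **{**SMALL_LANDSCAPE, "heterogeneity": (1.0, 1.0),
               "mirror_regions": True}),
        cluster_modifiers={"A": 1.0, "B": 1.0},
        n_occ_a=80, n_occ_b=80, seed=3)
    scenario = synthio.make_disjunct_scenario(cfg)
    assert synthio.truth_overlap(scenario) == pytest.approx(1.0, abs=1e-9)


def test_sampling_bias_pulls_points_toward_hotspot():
    cfg = synthio.ScenarioConfig(
        landscape=synthio.LandscapeConfig(**SMALL_LANDSCAPE),
        n_occ_a=300, n_occ_b=30, seed=3,
        bias_spec=synthio.BiasKernel([(5_000.0, 5_000.0)], sd=4_000.0,
                                     strength=50.0))
    biased = synthio.make_disjunct_scenario(cfg)
    plain = synthio.make_disjunct_scenario(
        synthio.ScenarioConfig(landscape=synthio.LandscapeConfig(
            **SMALL_LANDSCAPE), n_occ_a=300, n_occ_b=30, seed=3))
    def mean_dist(s):
        occ = s.occ("A")
        return np.mean(np.hypot(occ.x - 5_000.0, occ.y - 5_000.0))
    assert mean_dist(biased) < mean_dist(plain)
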