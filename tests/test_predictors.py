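import numpy as np
import pandas as pd
import pytest

from hsmtransfer import predictors
from hsmtransfer.raster import Grid, PredictorStack


def _monthly_stack(values, prefix):
    """12-layer stack whose single cell takes the given monthly values."""
    data = np.array(values, dtype=float).reshape(12, 1, 1)
    return PredictorStack([f"{prefix}_{m:02d}" for m in range(1, 13)],
                          data, (0.0, 0.0), 1.0, np.ones((1, 1), bool))


def test_derived_summaries_match_hand_computed_statistics():
    srad_vals = np.arange(1.0, 13.0)          # Jan..Dec = 1..12
    wind_vals = np.array([2.0] * 6 + [4.0] * 6)
    derived = predictors.derive_srad_wind_summaries(
        _monthly_stack(srad_vals, "srad"), _monthly_stack(wind_vals, "wind"))
    assert derived.n_layers == 10
    v = {name: derived.layer(name).data[0, 0] for name in derived.names}
    assert v["Srad_Ann_Mean"] == pytest.approx(np.mean(srad_vals))
    assert v["Srad_Ann_Sd"] == pytest.approx(np.std(srad_vals, ddof=1))
    # activity period = May..October = months 5..10 = values 5..10
    assert v["Srad_MayOct_Mean"] == pytest.approx(np.mean([5, 6, 7, 8, 9, 10]))
    assert v["Srad_MayOct_Sd"] == pytest.approx(
        np.std([5, 6, 7, 8, 9, 10], ddof=1))
    assert v["Srad_LSM"] == 1.0       # least sunny month
    assert v["Srad_MSM"] == 12.0      # sunniest month
    assert v["Wspeed_Ann_Mean"] == pytest.approx(3.0)
    assert v["Wspeed_MayOct_Mean"] == pytest.approx(np.mean([2, 2, 4, 4, 4, 4]))


def test_derived_summaries_require_twelve_months():
    eleven = PredictorStack([f"s_{m}" for m in range(11)],
                            np.zeros((11, 1, 1)), (0, 0), 1.0)
    twelve = _monthly_stack(np.zeros(12), "w")
    with pytest.raises(ValueError, match="12 monthly"):
        predictors.derive_srad_wind_summaries(eleven, twelve)


def test_habitat_percent_cover_counts_fine_cells_exactly():
    # 2x2 target cells, factor 2: each target covers 4 fine cells
    # (array row 0 is the SOUTHERN row)
    fine = Grid(np.array([
        [1, 1, 0, 2],
        [1, 0, 2, 2],
        [0, 0, 1, np.nan],
        [0, 0, 0, 1],
    ], dtype=float), (0.0, 0.0), 5.0)
    target = Grid(np.zeros((2, 2)), (0.0, 0.0), 10.0)
    grass = predictors.habitat_percent_cover(fine, {1}, target)
    np.testing.assert_allclose(grass.data,
                               [[75.0, 0.0],
                                [0.0, 100 * 2 / 3]])   # NaN fine cell excluded
    rocks = predictors.habitat_percent_cover(fine, {2}, target)
    np.testing.assert_allclose(rocks.data, [[0.0, 75.0], [0.0, 0.0]])


def test_habitat_percent_cover_rejects_non_nesting_grids():
    fine = Grid(np.zeros((3, 3)), (0.0, 0.0), 7.0)
    target = Grid(np.zeros((1, 1)), (0.0, 0.0), 10.0)
    with pytest.raises(ValueError):
        predictors.habitat_percent_cover(fine, {1}, target)


def test_candidate_pool_is_31_layers(small_landscape):
    stack = predictors.build_candidate_stack(small_landscape)
    assert stack.n_layers == 31
    assert sum(n.startswith("bio") for n in stack.names) == 19
    assert {"Grasslands", "Rocks_SparseVeg"} <= set(stack.names)
    derived = {"Srad_Ann_Mean", "Srad_Ann_Sd", "Wspeed_Ann_Mean",
               "Wspeed_Ann_Sd", "Srad_MayOct_Mean", "Srad_MayOct_Sd",
               "Wspeed_MayOct_Mean", "Wspeed_MayOct_Sd", "Srad_LSM",
               "Srad_MSM"}
    assert derived <= set(stack.names)


def test_vif_matches_regression_oracle():
    rng = np.random.default_rng(4)
    n = 400
    x1 = rng.normal(size=n)
    x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * rng.normal(size=n)
    x3 = rng.normal(size=n)
    df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
    vif = predictors.compute_vif(df)
    # oracle: R^2 from explicit OLS of each column on the others
    for col in df.columns:
        others = df.drop(columns=col).to_numpy()
        X = np.column_stack([np.ones(n), others])
        y = df[col].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r2 = 1 - np.sum((y - X @ beta) ** 2) / np.sum((y - y.mean()) ** 2)
        assert vif[col] == pytest.approx(1.0 / (1.0 - r2), rel=1e-9)
    assert vif["x1"] > 3.0 and vif["x3"] < 1.2


def test_vif_is_infinite_for_exact_linear_dependence():
    rng = np.random.default_rng(0)
    a = rng.normal(size=50)
    b = rng.normal(size=50)
    df = pd.DataFrame({"a": a, "b": b, "c": a + b})
    assert np.isinf(predictors.compute_vif(df)).all()


def test_pearson_filter_resolves_pairs_by_preference():
    rng = np.random.default_rng(1)
    n = 500
    a = rng.normal(size=n)
    b = a + 0.05 * rng.normal(size=n)          # |r(a,b)| ~ 0.999
    c = rng.normal(size=n)                     # independent
    df = pd.DataFrame({"A": a, "B": b, "C": c})
    spec = predictors.pearson_filter(df, ["A", "B", "C"])
    assert spec.name == "Ecol"
    assert spec.retained == ["A", "C"]         # B dropped (lower preference)
    assert any("dropped B" in line for line in spec.log)
    # flipping the ranking flips which member survives
    spec2 = predictors.pearson_filter(df, ["B", "A", "C"])
    assert spec2.retained == ["B", "C"]


def test_pearson_filter_drops_constant_variables_with_warning():
    df = pd.DataFrame({"A": np.arange(10.0), "K": np.ones(10)})
    with pytest.warns(UserWarning, match="constant"):
        spec = predictors.pearson_filter(df, ["A", "K"])
    assert spec.retained == ["A"]


def test_vif_two_stage_confirms_on_every_dataset():
    rng = np.random.default_rng(7)
    n = 300
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    x3 = rng.normal(size=n)
    study = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
    # dataset where x3 becomes collinear with x1
    bad = study.copy()
    bad["x3"] = bad["x1"] * 0.99 + 0.01 * rng.normal(size=n)
    spec = predictors.vif_filter_two_stage(study, [study, bad], threshold=10)
    assert "x3" not in spec.retained or "x1" not in spec.retained
    assert "x2" in spec.retained
    assert any("stage2" in line for line in spec.log)


def test_vif_two_stage_stage1_removes_worst_offender_first():
    rng = np.random.default_rng(3)
    n = 400
    base = rng.normal(size=n)
    df = pd.DataFrame({
        "p": base + 0.01 * rng.normal(size=n),
        "q": base + 0.01 * rng.normal(size=n),
        "r": rng.normal(size=n),
    })
    spec = predictors.vif_filter_two_stage(df, [], threshold=10)
    assert len(spec.retained) == 2 and "r" in spec.retained
    assert spec.log and spec.log[0].startswith("stage1 dropped")


def test_landcover_stability_counts_changed_localities_once(small_landscape):
    from hsmtransfer.synthio import OccurrenceSet
    lc0 = small_landscape.landcover[0]
    mask = ~np.isnan(lc0.data)
    r, c = np.nonzero(mask)
    x = lc0.origin[0] + (c[:200] + 0.5) * lc0.cell_size
    y = lc0.origin[1] + (r[:200] + 0.5) * lc0.cell_size
    occ = OccurrenceSet(x, y, np.full(200, "A", dtype=object))
    prop = predictors.landcover_stability(occ, small_landscape.landcover)
    assert 0.0 <= prop <= 1.0
    # more epochs can only increase the changed-at-least-once proportion
    prop2 = predictors.landcover_stability(occ, small_landscape.landcover[:2])
    assert prop2 <= prop
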