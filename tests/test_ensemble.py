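import numpy as np
import pandas as pd
import pytest

from hsmtransfer import ensemble as ens
from hsmtransfer.raster import Grid


def _member(weight, values):
    data = np.asarray(values, dtype=float).reshape(1, -1)
    return ens.EnsembleMember(weight, Grid(data, (0.0, 0.0), 1.0))


# --------------------------------------------------------------------------
# weighted mean / weighted SD (Eq.-1 style)
# --------------------------------------------------------------------------

def test_weighted_mean_map_matches_hand_computation():
    members = [_member(0.8, [0.2, 0.4]), _member(0.72, [0.6, 0.8])]
    wa = ens.weighted_mean_map(members).data.ravel()
    np.testing.assert_allclose(
        wa, [(0.8 * 0.2 + 0.72 * 0.6) / 1.52,
             (0.8 * 0.4 + 0.72 * 0.8) / 1.52])


def test_weighted_sd_reduces_to_sample_sd_for_equal_weights():
    values = np.array([0.1, 0.5, 0.7, 0.2])
    members = [_member(0.9, [v]) for v in values]
    sd = ens.weighted_sd_map(members).data.ravel()[0]
    assert sd == pytest.approx(np.std(values, ddof=1))


def test_weighted_sd_matches_hand_computed_unequal_weights():
    # two members, weights 3 and 1, values 0 and 1:
    # wa = 1/4; num = 3*(1/16) + 1*(9/16) = 12/16 = 0.75
    # denom = ((2-1)/2) * 4 = 2 -> sd = sqrt(0.375)
    members = [_member(3.0, [0.0]), _member(1.0, [1.0])]
    sd = ens.weighted_sd_map(members).data.ravel()[0]
    assert sd == pytest.approx(np.sqrt(0.375))


def test_weighted_sd_requires_at_least_two_members():
    with pytest.raises(ValueError):
        ens.weighted_sd_map([_member(0.9, [0.5])])


def test_member_selection_applies_the_boyce_cutoff(fitted_pair,
                                                   candidate_stack):
    from hsmtransfer.models import predict_suitability
    _, gam, gbm = fitted_pair
    pairs = [(gam, 0.95), (gbm, 0.69), (gam, np.nan), (gbm, 0.70)]
    members = ens.select_members(
        pairs, lambda m: predict_suitability(m, candidate_stack), cutoff=0.7)
    assert [m.weight for m in members] == [0.95, 0.70]
    with pytest.raises(ens.EmptyEnsembleError):
        ens.select_members([(gam, 0.5)], lambda m: None, cutoff=0.7)


# --------------------------------------------------------------------------
# variable importance
# --------------------------------------------------------------------------

def test_importance_ranks_the_informative_variable_first(fitted_pair):
    ds, gam, _ = fitted_pair
    sites = ds.values[gam.variables]
    imp = ens.variable_importance(gam, sites, n_shuffles=3, seed=0)
    assert (imp >= 0).all()
    assert imp.sum() > 0


def test_importance_is_zero_for_an_excluded_variable(fitted_pair):
    ds, gam, _ = fitted_pair
    dropped = [v for v, lvl in gam.gam_terms.items() if lvl == "out"]
    sites = ds.values[gam.variables]
    imp = ens.variable_importance(gam, sites, n_shuffles=2, seed=0)
    for v in dropped:
        assert imp[v] == 0.0


def test_weighted_importance_table_sums_to_100_percent():
    raw = [pd.Series({"a": 2.0, "b": 1.0, "c": 1.0}),
           pd.Series({"a": 1.0, "b": 3.0, "c": 0.0})]
    table = ens.weighted_importance_table([0.9, 0.7], raw).table
    assert table["Weighted_Avg_Imp"].sum() == pytest.approx(100.0)
    # member 1 normalizes to (50, 25, 25); member 2 to (25, 75, 0)
    exp_a = (0.9 * 50 + 0.7 * 25) / 1.6
    assert table.loc["a", "Weighted_Avg_Imp"] == pytest.approx(exp_a)
    assert (table["Weighted_StdDev_Imp"] >= 0).all()


def test_zero_importance_members_are_excluded_with_warning():
    raw = [pd.Series({"a": 0.0, "b": 0.0}), pd.Series({"a": 1.0, "b": 1.0})]
    with pytest.warns(UserWarning, match="zero total"):
        table = ens.weighted_importance_table([0.9, 0.8], raw).table
    np.testing.assert_allclose(table["Weighted_Avg_Imp"], [50.0, 50.0])


def test_curve_variables_are_low_cv_members_of_the_top_five():
    df = pd.DataFrame({
        "Weighted_Avg_Imp": [30.0, 25.0, 20.0, 10.0, 8.0, 4.0, 3.0],
        "Weighted_StdDev_Imp": [3.0, 20.0, 2.0, 1.0, 7.0, 0.1, 0.1],
    }, index=list("abcdefg"))
    df["CV"] = df["Weighted_StdDev_Imp"] / df["Weighted_Avg_Imp"]
    # normalize Avg to sum 100 to satisfy the table contract
    df["Weighted_Avg_Imp"] *= 100.0 / df["Weighted_Avg_Imp"].sum()
    chosen = ens.select_curve_variables(ens.ImportanceTable(df))
    # top-5 by Avg: a b c d e; CVs: a=.1, b=.8, c=.1, d=.1, e=.875
    assert set(chosen) == {"a", "c", "d"}


# --------------------------------------------------------------------------
# inflated response curves
# --------------------------------------------------------------------------

def test_inflated_curves_cover_profile_factorial_up_to_cap(fitted_pair):
    ds, gam, _ = fitted_pair
    sites = ds.values[gam.variables]
    curves = ens.inflated_response_curves(gam, gam.variables[0], sites,
                                          grid=25, max_combinations=50,
                                          seed=0)
    n_combos = curves["combination"].nunique()
    assert n_combos <= 50
    assert set(curves.columns) >= {"combination", "x", "suitability"}
    assert len(curves) == n_combos * 25
    assert curves["x"].min() == pytest.approx(sites[gam.variables[0]].min())


def test_inflated_curves_shift_additively_on_the_link_scale(fitted_pair):
    """For a GAM the linear predictor is additive, so curves along one
    variable under different fixed profiles differ only by a constant."""
    ds, gam, _ = fitted_pair
    sites = ds.values[gam.variables]
    focal = next(v for v, lvl in gam.gam_terms.items() if lvl != "out")
    curves = ens.inflated_response_curves(gam, focal, sites, grid=20,
                                          max_combinations=10, seed=1,
                                          scale="link")
    pivot = curves.pivot(index="x", columns="combination",
                         values="suitability")
    base = pivot.iloc[:, 0]
    for col in pivot.columns[1:]:
        offsets = pivot[col] - base
        # additivity is exact in theory; the tolerance absorbs float
        # cancellation between large truncated-power spline terms
        np.testing.assert_allclose(offsets, offsets.iloc[0], atol=1e-3)
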