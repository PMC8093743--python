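import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hsmtransfer import comparisons as cmp


# --------------------------------------------------------------------------
# rank-based inverse normal transform
# --------------------------------------------------------------------------

def test_rint_matches_blom_oracle_for_three_values():
    # n=3, Blom: Phi^-1((r - 3/8)/(3 + 1/4)) for r = 1, 2, 3
    out = cmp.rint(np.array([10.0, -5.0, 3.0]))
    expected = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
    np.testing.assert_allclose(out, expected)
    # the endpoints are the documented +/- 0.8694 Blom scores
    assert sorted(out)[0] == pytest.approx(-0.8694, abs=1e-4)
    assert sorted(out)[2] == pytest.approx(0.8694, abs=1e-4)


def test_rint_preserves_order_and_averages_ties():
    x = np.array([1.0, 2.0, 2.0, 5.0])
    out = cmp.rint(x)
    assert out[1] == out[2]
    assert out[0] < out[1] < out[3]


def test_rint_requires_three_distinct_values():
    with pytest.raises(ValueError):
        cmp.rint(np.array([1.0, 1.0, 2.0, 2.0]))


# --------------------------------------------------------------------------
# Hodges-Lehmann
# --------------------------------------------------------------------------

def test_hodges_lehmann_matches_brute_force_median():
    x = np.array([1.0, 3.0, 5.0])
    y = np.array([2.0, 4.0])
    diffs = sorted(a - b for a in x for b in y)   # [-3,-1,-1,1,1,3]
    assert cmp.hodges_lehmann(x, y) == pytest.approx(np.median(diffs))
    assert cmp.hodges_lehmann(x + 10.0, x) == pytest.approx(10.0)


# --------------------------------------------------------------------------
# normality gate
# --------------------------------------------------------------------------

def _factor_frame(n):
    rng = np.random.default_rng(0)
    return pd.DataFrame({"g": rng.choice(["u", "v"], size=n)})


def test_gate_routes_gaussian_residuals_to_parametric():
    rng = np.random.default_rng(1)
    n = 200
    factors = _factor_frame(n)
    y = rng.normal(size=n) + (factors["g"] == "u") * 2.0
    assert cmp.normality_gate(y.to_numpy(), factors) == "parametric"


def test_gate_routes_heavy_skew_to_nonparametric():
    rng = np.random.default_rng(2)
    n = 200
    factors = _factor_frame(n)
    y = rng.exponential(size=n) ** 2
    assert cmp.normality_gate(y, factors) == "nonparametric"


def test_gate_rejects_constant_metric():
    with pytest.raises(ValueError):
        cmp.normality_gate(np.ones(50), _factor_frame(50))


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

def _records(levels, mus, n=30, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for lvl, mu in zip(levels, mus):
        for v in rng.normal(mu, 1.0, size=n):
            rows.append({"f": lvl, "m": v})
    return pd.DataFrame(rows)


def test_two_level_comparison_is_mann_whitney_with_hl_shift():
    rec = _records(["a", "b"], [0.0, 2.0])
    (res,) = cmp.compare_groups(rec, "m", "f")
    assert res.test == "mann-whitney-u"
    a = rec.loc[rec["f"] == "a", "m"].to_numpy()
    b = rec.loc[rec["f"] == "b", "m"].to_numpy()
    oracle = stats.mannwhitneyu(a, b, alternative="two-sided")
    assert res.statistic == pytest.approx(float(oracle.statistic))
    assert res.p == pytest.approx(float(oracle.pvalue))
    assert res.estimated_difference == pytest.approx(
        cmp.hodges_lehmann(a, b))
    assert res.estimated_difference < 0    # a sits below b


def test_one_tailed_direction_is_respected():
    rec = _records(["a", "b"], [2.0, 0.0])
    (greater,) = cmp.compare_groups(rec, "m", "f", one_tailed="a")
    (lesser,) = cmp.compare_groups(rec, "m", "f", one_tailed="b")
    assert greater.p < 0.05 < lesser.p


def test_three_level_comparison_runs_kw_then_bh_adjusted_pairs():
    rec = _records(["a", "b", "c"], [0.0, 0.2, 3.0], seed=3)
    results = cmp.compare_groups(rec, "m", "f")
    assert results[0].test == "kruskal-wallis"
    pairs = results[1:]
    assert len(pairs) == 3                      # C(3, 2) follow-ups
    assert all(r.adjustment == "BH" for r in pairs)
    # BH oracle on the raw pairwise p-values
    raw = [r.p for r in pairs]
    order = np.argsort(raw)
    m = len(raw)
    stepped = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top
        prev = min(prev, raw[idx] * m / k)
        stepped[idx] = prev
    for r, adj in zip(pairs, stepped):
        assert r.p_adjusted == pytest.approx(adj)
    assert all(r.p_adjusted >= r.p for r in pairs)


def test_bh_adjustment_matches_textbook_example():
    # classic worked case: (0.01, 0.02, 0.04) -> (0.03, 0.03, 0.04)
    from statsmodels.stats.multitest import multipletests
    adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
    np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])


def test_groups_need_enough_observations():
    rec = pd.DataFrame({"f": ["a", "a", "a", "b", "b"],
                        "m": [1.0, 2.0, 3.0, 4.0, 5.0]})
    with pytest.raises(ValueError):
        cmp.compare_groups(rec, "m", "f")


# --------------------------------------------------------------------------
# novelty-performance correlation
# --------------------------------------------------------------------------

def test_novelty_correlation_recovers_a_negative_association():
    rng = np.random.default_rng(4)
    n = 120
    nov = rng.uniform(0, 100, n)
    rec = pd.DataFrame({
        "mode": np.where(np.arange(n) % 2 == 0, "SpBlockCV", "External"),
        "pct_nonanalog": nov,
        "auc": 0.9 - 0.004 * nov + rng.normal(0, 0.02, n),
        "B": 0.8 - 0.01 * nov + rng.normal(0, 0.1, n),
    })
    out = cmp.novelty_performance_correlation(rec, by_mode=True)
    pooled = out[(out["mode"] == "pooled") & (out["metric"] == "auc")].iloc[0]
    assert pooled["r"] < -0.8
    assert pooled["p"] < 1e-6
    assert pooled["df"] == n - 2
    # t statistic obeys t = r * sqrt(df / (1 - r^2))
    assert pooled["t"] == pytest.approx(
        pooled["r"] * np.sqrt(pooled["df"] / (1 - pooled["r"] ** 2)))
    assert set(out["mode"]) == {"pooled", "SpBlockCV", "External"}


def test_novelty_correlation_uses_rank_transformed_values():
    # a monotone but non-linear association still yields |r| near 1
    nov = np.linspace(1, 100, 50)
    rec = pd.DataFrame({
        "mode": ["External"] * 50,
        "pct_nonanalog": nov,
        "auc": 1.0 / nov,                      # monotone decreasing
        "B": np.exp(-nov / 10.0),
    })
    out = cmp.novelty_performance_correlation(rec)
    assert (out["r"] < -0.999).all()
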