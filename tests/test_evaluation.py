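import numpy as np
import pandas as pd
import pytest

from hsmtransfer import blocking, evaluation


# --------------------------------------------------------------------------
# AUC
# --------------------------------------------------------------------------

def _auc_brute_force(labels, scores):
    """Pair-counting oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 2, 60)
    labels[:2] = [0, 1]
    scores = np.round(rng.uniform(size=60), 1)    # coarse -> ties occur
    assert evaluation.auc(labels, scores) == pytest.approx(
        _auc_brute_force(labels, scores))


def test_auc_is_half_for_constant_scores():
    labels = np.array([0, 1, 0, 1])
    assert evaluation.auc(labels, np.ones(4)) == pytest.approx(0.5)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        evaluation.auc(np.ones(5), np.arange(5.0))


# --------------------------------------------------------------------------
# Continuous Boyce Index
# --------------------------------------------------------------------------

def test_boyce_is_high_when_presences_prefer_high_suitability():
    rng = np.random.default_rng(0)
    bg = rng.uniform(0, 1, 5000)
    pres = rng.choice(bg, size=800, p=bg / bg.sum())   # P proportional to s
    curve = evaluation.boyce_index(pres, bg)
    assert curve.defined
    assert curve.B > 0.9


def test_boyce_is_low_when_presences_avoid_high_suitability():
    rng = np.random.default_rng(0)
    bg = rng.uniform(0, 1, 5000)
    w = 1.0 - bg
    pres = rng.choice(bg, size=800, p=w / w.sum())
    curve = evaluation.boyce_index(pres, bg)
    assert curve.B < -0.9


def test_boyce_is_near_zero_for_random_presences():
    rng = np.random.default_rng(1)
    bg = rng.uniform(0, 1, 5000)
    pres = rng.choice(bg, size=1500)
    curve = evaluation.boyce_index(pres, bg)
    assert abs(curve.B) < 0.2


def test_boyce_window_width_is_a_tenth_of_the_range():
    bg = np.linspace(0.2, 0.7, 1000)
    curve = evaluation.boyce_index(np.array([0.5]), bg)
    assert curve.width == pytest.approx(0.05)
    assert len(curve.centers) <= 101


def test_boyce_f_ratio_matches_hand_computation():
    # background: 100 cells uniform on [0,1]; presences all at 0.95
    bg = np.linspace(0.0, 1.0, 101)
    pres = np.full(10, 0.95)
    curve = evaluation.boyce_index(pres, bg, width_fraction=0.1, n_windows=5)
    # the top window [0.9, 1.0] holds all presences; bg share ~ 11/101
    top = curve.f_ratio[-1]
    assert top == pytest.approx((10 / 10) / (11 / 101))


def test_boyce_undefined_for_constant_background():
    curve = evaluation.boyce_index(np.array([0.5]), np.full(100, 0.5))
    assert not curve.defined and np.isnan(curve.B)


# --------------------------------------------------------------------------
# novelty masks
# --------------------------------------------------------------------------

def _cal_square():
    # calibration fills two opposite corners of the unit square
    rng = np.random.default_rng(4)
    a = rng.uniform(0.0, 0.35, size=(60, 2))
    b = rng.uniform(0.65, 1.0, size=(60, 2))
    return pd.DataFrame(np.vstack([a, b]), columns=["u", "v"])


def test_novelty_mask_classifies_three_site_types():
    cal = _cal_square()
    proj = pd.DataFrame({
        "u": [0.10, 0.90, 0.10, 2.00],
        "v": [0.10, 0.90, 0.90, 0.10],
    })
    classes, pct = evaluation.novelty_mask(cal, proj, bins_per_var=5)
    assert classes[0] == "analog"                 # inside an occupied corner
    assert classes[1] == "analog"
    assert classes[2] == "multivariate-novel"     # in range, unseen combo
    assert classes[3] == "strict-novel"           # u beyond calibration max
    assert pct == pytest.approx(50.0)


def test_novelty_mask_is_all_analog_for_identical_data():
    cal = _cal_square()
    classes, pct = evaluation.novelty_mask(cal, cal)
    assert (classes == "analog").all()
    assert pct == 0.0


def test_novelty_mask_strict_takes_precedence_over_multivariate():
    cal = pd.DataFrame({"u": [0.0, 1.0], "v": [0.0, 1.0]})
    proj = pd.DataFrame({"u": [5.0], "v": [5.0]})
    classes, _ = evaluation.novelty_mask(cal, proj)
    assert classes[0] == "strict-novel"


# --------------------------------------------------------------------------
# validation modes on real fitted models
# --------------------------------------------------------------------------

def test_internal_validation_scores_only_the_test_fold(
        fitted_pair, candidate_stack):
    ds, gam, _ = fitted_pair
    coords = ds.values[["x", "y"]].to_numpy()
    scheme = blocking.checkerboard_folds(coords, 10_000.0,
                                         candidate_stack.origin)
    rec = evaluation.evaluate_internal(gam, scheme, ds, candidate_stack,
                                       test_fold=1)
    assert rec.mode == "SpBlockCV"
    assert 0.0 <= rec.auc <= 1.0
    assert 0.0 <= rec.pct_nonanalog <= 100.0
    n_class = sum(rec.novelty_counts.values())
    assert n_class == int((scheme.fold == 1).sum())


def test_external_validation_reports_high_novelty_across_clusters(
        fitted_pair, small_datasets, candidate_stack):
    ds, gam, _ = fitted_pair
    target = next(d for d in small_datasets
                  if d.group == "B" and d.size == "Full")
    bg = pd.DataFrame(candidate_stack.values_at(target.pa_x, target.pa_y),
                      columns=candidate_stack.names)
    rec = evaluation.evaluate_external(gam, target, bg)
    assert rec.mode == "External"
    internal_classes, internal_pct = evaluation.novelty_mask(
        gam.train_values[gam.variables],
        ds.values[gam.variables])
    # the disjunct cluster is environmentally more novel than the home data
    assert rec.pct_nonanalog >= internal_pct
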