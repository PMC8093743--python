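"""Transferability scoring: AUC, Continuous Boyce Index, novelty masks.

Internal transferability ("SpBlockCV") scores a model on its held-out
checkerboard test fold; external transferability projects a model fitted on
one population cluster onto a presence-pseudoabsence dataset of the other.
Environmental novelty of the projection sites relative to the calibration
sites is quantified with univariate range checks (strict novelty) and joint
bin-occupancy checks (multivariate novelty).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from .blocking import (BlockingScheme, checkerboard_folds,
                       first_zero_crossing, residual_correlogram,
                       select_block_size)
from .models import FittedHSM, fit_gam, fit_gbm
from .raster import PredictorStack
from .sampling import PresPseudoAbsDataset, assemble_datasets
from .synthio import Scenario

__all__ = [
    "BoyceCurve", "EvaluationRecord", "auc", "boyce_index", "novelty_mask",
    "evaluate_internal", "evaluate_external", "run_experiment",
]


@dataclass
class BoyceCurve:
    centers: np.ndarray          # window midpoints on the suitability axis
    f_ratio: np.ndarray          # predicted-to-expected ratio per window
    width: float
    B: float                     # Spearman(F_i, centers)
    defined: bool = True


@dataclass
class EvaluationRecord:
    tags: dict                   # factorial coordinates
    mode: str                    # "SpBlockCV" | "External"
    auc: float
    B: float
    pct_nonanalog: float
    novelty_counts: dict         # analog / multivariate / strict counts

    def as_row(self) -> dict:
        row = dict(self.tags)
        row.update(mode=self.mode, auc=self.auc, B=self.B,
                   pct_nonanalog=self.pct_nonanalog,
                   n_analog=self.novelty_counts["analog"],
                   n_multivariate=self.novelty_counts["multivariate"],
                   n_strict=self.novelty_counts["strict"])
        return row


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney normalization)."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("both classes required for AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def boyce_index(presence_suitability: np.ndarray,
                background_suitability: np.ndarray,
                width_fraction: float = 0.1,
                n_windows: int = 101) -> BoyceCurve:
    """Continuous Boyce Index.

    A window of width ``width_fraction`` times the background suitability
    range slides along that range at ``n_windows`` evenly spaced midpoints;
    each window's predicted-to-expected ratio F_i is the proportion of test
    presences inside divided by the proportion of background cells inside
    (windows with no background cells are skipped). B is the Spearman
    correlation between F_i and the window midpoints.
    """
    pres = np.asarray(presence_suitability, dtype=float)
    bg = np.asarray(background_suitability, dtype=float)
    if pres.size < 1 or bg.size < 10:
        raise ValueError("need >=1 presence and >=10 background values")
    lo, hi = bg.min(), bg.max()
    rng = hi - lo
    if rng <= 0:
        return BoyceCurve(np.array([]), np.array([]), 0.0, np.nan, False)
    width = width_fraction * rng
    centers = np.linspace(lo + width / 2, hi - width / 2, n_windows)
    f = np.full(n_windows, np.nan)
    for i, c in enumerate(centers):
        inside_bg = np.count_nonzero((bg >= c - width / 2)
                                     & (bg <= c + width / 2))
        if inside_bg == 0:
            continue
        inside_p = np.count_nonzero((pres >= c - width / 2)
                                    & (pres <= c + width / 2))
        f[i] = (inside_p / pres.size) / (inside_bg / bg.size)
    ok = ~np.isnan(f)
    if ok.sum() < 3 or np.nanstd(f[ok]) == 0:
        return BoyceCurve(centers[ok], f[ok], width, np.nan, False)
    B = spearmanr(f[ok], centers[ok]).statistic
    return BoyceCurve(centers[ok], f[ok], width, float(B), True)


def novelty_mask(calibration: pd.DataFrame, projection: pd.DataFrame,
                 bins_per_var: int = 5) -> tuple[np.ndarray, float]:
    """Classify projection sites as analog / multivariate-novel / strict-novel.

    Strict novelty: any variable outside the calibration min-max.
    Multivariate novelty: all variables in range, but the joint combination
    of per-variable bins (binned on calibration ranges) never occurs among
    calibration sites. Returns (classes array, percent nonanalog).
    """
    if len(calibration) == 0:
        raise ValueError("empty calibration set")
    cols = list(calibration.columns)
    proj = projection[cols]
    cal = calibration[cols].to_numpy(float)
    prj = proj.to_numpy(float)
    lo, hi = cal.min(axis=0), cal.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)

    def binned(m):
        b = np.floor((m - lo) / span * bins_per_var).astype(int)
        return np.clip(b, 0, bins_per_var - 1)

    cal_bins = {tuple(row) for row in binned(cal)}
    strict = np.any((prj < lo) | (prj > hi), axis=1)
    prj_bins = binned(prj)
    multi = np.array([tuple(row) not in cal_bins for row in prj_bins])
    multi &= ~strict
    classes = np.where(strict, "strict-novel",
                       np.where(multi, "multivariate-novel", "analog"))
    pct = 100.0 * (strict.sum() + multi.sum()) / len(prj)
    return classes, float(pct)


def _novelty_counts(classes: np.ndarray) -> dict:
    return {
        "analog": int(np.sum(classes == "analog")),
        "multivariate": int(np.sum(classes == "multivariate-novel")),
        "strict": int(np.sum(classes == "strict-novel")),
    }


# --------------------------------------------------------------------------
# validation modes
# --------------------------------------------------------------------------

def evaluate_internal(model: FittedHSM, scheme: BlockingScheme,
                      dataset: PresPseudoAbsDataset, stack: PredictorStack,
                      test_fold: int = 1,
                      boyce_kw: Optional[dict] = None) -> EvaluationRecord:
    """Spatial-block cross-validation scores on the test fold.

    Boyce background = valid raster cells lying inside test-fold blocks;
    novelty compares test-fold sites with training-fold calibration values.
    """
    vals = dataset.values
    is_test = scheme.fold == test_fold
    if not is_test.any() or is_test.all():
        raise ValueError("empty train or test fold")
    test = vals[is_test]
    train = vals[~is_test]
    scores = model.predict(test)
    a = auc(test["label"].to_numpy(), scores)

    # background: valid cells whose block parity matches the test fold
    bx, by = stack.valid_xy()
    bi = np.floor((bx - scheme.origin[0]) / scheme.block_size).astype(int)
    bj = np.floor((by - scheme.origin[1]) / scheme.block_size).astype(int)
    in_test_blocks = ((bi + bj) % 2) == test_fold
    bg_table = pd.DataFrame(stack.valid_table()[in_test_blocks],
                            columns=stack.names)
    bg_scores = model.predict(bg_table)
    pres_scores = scores[test["label"].to_numpy() == 1]
    curve = boyce_index(pres_scores, bg_scores, **(boyce_kw or {}))

    classes, pct = novelty_mask(train[model.variables],
                                test[model.variables])
    return EvaluationRecord(dict(model.tags), "SpBlockCV", a,
                            curve.B, pct, _novelty_counts(classes))


def evaluate_external(model: FittedHSM, target: PresPseudoAbsDataset,
                      target_background: pd.DataFrame,
                      boyce_kw: Optional[dict] = None) -> EvaluationRecord:
    """Project a cluster's model onto the other cluster's dataset.

    Boyce background = the target cluster's buffer cells; novelty compares
    the target sites with the model's own training values.
    """
    vals = target.values
    scores = model.predict(vals)
    a = auc(vals["label"].to_numpy(), scores)
    bg_scores = model.predict(target_background)
    pres_scores = scores[vals["label"].to_numpy() == 1]
    curve = boyce_index(pres_scores, bg_scores, **(boyce_kw or {}))
    classes, pct = novelty_mask(model.train_values[model.variables],
                                vals[model.variables])
    return EvaluationRecord(dict(model.tags), "External", a,
                            curve.B, pct, _novelty_counts(classes))


# --------------------------------------------------------------------------
# factorial driver
# --------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Factorial levels and per-stage tunables for one full experiment."""

    predictor_sets: dict = None          # name -> list of variables
    algorithms: tuple = ("GAM", "GBM")
    fold_assignments: tuple = (0, 1)     # test-fold parity per assignment
    # sampling
    thin_dist: float = 1500.0
    thin_replicates: int = 3
    pa_inner: float = 1500.0
    pa_outer: float = 120_000.0
    pa_n: int = 1000
    pa_sets: int = 10
    # blocking
    correlogram_pace: float = 10_000.0
    correlogram_max_bins: int = 6
    moran_tol: float = 0.05
    block_size_override: Optional[float] = None
    block_size_cap: Optional[float] = None   # default: half min region span
    # models
    gbm_learning_rate: float = 0.001
    gbm_max_trees: int = 10_000
    gbm_tree_grid_step: int = 100
    gbm_cv_folds: int = 5
    # evaluation
    boyce_width_fraction: float = 0.1
    boyce_n_windows: int = 101
    novelty_bins: int = 5
    seed: int = 0


@dataclass
class ExperimentResult:
    records: pd.DataFrame                 # one row per model x mode
    models: list[FittedHSM]
    datasets: list[PresPseudoAbsDataset]
    block_sizes: dict                     # (group, size) -> meters
    failures: list[dict] = field(default_factory=list)


def _full_data_block_size(datasets, cfg, stack, cap, rng_seed) -> dict:
    """Block size per presence dataset from full-data residual correlograms.

    One GAM and one GBM are fitted on the first pseudoabsence replicate of
    each presence dataset; response residuals (0/1 - predicted) feed
    Moran's I correlograms which are averaged across the two algorithms
    before applying the stable-zero rule. When no bin run satisfies the
    rule, the first sign change of I estimates the autocorrelation range
    (the correlogram x-intercept), with 3x pace as a last resort; the block
    size is capped so a checkerboard remains possible inside each region.
    """
    out = {}
    any_set = next(iter(cfg.predictor_sets.values()))
    for ds in datasets:
        if ds.replicate != 1:
            continue
        vals = ds.values
        coords = vals[["x", "y"]].to_numpy()
        correlos = []
        gam = fit_gam(vals, any_set)
        gbm = fit_gbm(vals, any_set,
                      learning_rate=cfg.gbm_learning_rate,
                      max_trees=min(cfg.gbm_max_trees, 200),
                      tree_grid_step=cfg.gbm_tree_grid_step,
                      cv_folds=2, seed=rng_seed)
        max_dist = cfg.correlogram_pace * cfg.correlogram_max_bins
        for m in (gam, gbm):
            if not m.ok:
                continue
            resid = vals["label"].to_numpy() - m.predict(vals)
            correlos.append(residual_correlogram(
                resid, coords, cfg.correlogram_pace, max_dist,
                seed=rng_seed))
        bs = cfg.correlogram_pace * 3
        if correlos:
            mean_I = np.nanmean([c.morans_i for c in correlos], axis=0)
            merged = correlos[0]
            merged.morans_i = mean_I
            merged.defined = ~np.isnan(mean_I)
            try:
                bs = select_block_size(merged, cfg.moran_tol,
                                       cfg.block_size_override)
            except ValueError:
                xing = first_zero_crossing(merged)
                if xing is not None:
                    bs = xing
        if cap is not None:
            bs = min(bs, cap)
        out[(ds.group, ds.size)] = bs
    return out


def run_experiment(scenario: Scenario, candidate_stack: PredictorStack,
                   cfg: ExperimentConfig) -> ExperimentResult:
    """Fit and evaluate the full model factorial on one scenario.

    Produces #presence-datasets x #PA-replicates x #predictor-sets x
    #algorithms x #fold-assignments models (480 under the default levels),
    each scored internally (SpBlockCV) and, for single-cluster groups,
    externally on a randomly chosen dataset of the other cluster.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_ds, s_blk, s_fit, s_ext = (s.generate_state(1)[0] % (2**31)
                                 for s in ss.spawn(4))
    datasets = assemble_datasets(
        scenario.occ("A"), scenario.occ("B"), candidate_stack,
        thin_dist=cfg.thin_dist, thin_replicates=cfg.thin_replicates,
        pa_inner=cfg.pa_inner, pa_outer=cfg.pa_outer,
        pa_n=cfg.pa_n, pa_sets=cfg.pa_sets, seed=s_ds)
    cap = cfg.block_size_cap
    if cap is None:
        spans = []
        for rect in (scenario.landscape.region_a,
                     scenario.landscape.region_b):
            spans.append(min(rect[2] - rect[0], rect[3] - rect[1]))
        cap = min(spans) / 2.0
    block_sizes = _full_data_block_size(datasets, cfg, candidate_stack,
                                        cap, s_blk)

    # external-validation backgrounds: each cluster's buffer cells
    ext_background = {}
    for label in ("A", "B"):
        ds0 = next(d for d in datasets
                   if d.group == label and d.size == "Full")
        bg = pd.DataFrame(
            np.vstack([candidate_stack.values_at(ds0.pa_x, ds0.pa_y)]),
            columns=candidate_stack.names)
        ext_background[label] = bg

    boyce_kw = dict(width_fraction=cfg.boyce_width_fraction,
                    n_windows=cfg.boyce_n_windows)
    rng_ext = np.random.default_rng(s_ext)
    rows, model_list, failures = [], [], []
    fit_seed = s_fit
    for ds in datasets:
        bs = block_sizes[(ds.group, ds.size)]
        coords = ds.values[["x", "y"]].to_numpy()
        try:
            scheme = checkerboard_folds(coords, bs,
                                        candidate_stack.origin)
        except ValueError as exc:
            failures.append(dict(dataset=ds.tag, stage="blocking",
                                 error=str(exc)))
            continue
        for set_name, variables in cfg.predictor_sets.items():
            for algo in cfg.algorithms:
                for assign_idx, test_fold in enumerate(cfg.fold_assignments,
                                                       start=1):
                    fit_seed += 1
                    tags = dict(group=ds.group, size=ds.size,
                                replicate=ds.replicate,
                                predictor_set=set_name, algorithm=algo,
                                assignment=assign_idx)
                    train = ds.values[scheme.fold != test_fold]
                    if algo == "GAM":
                        model = fit_gam(train, variables)
                    else:
                        model = fit_gbm(
                            train, variables,
                            learning_rate=cfg.gbm_learning_rate,
                            max_trees=cfg.gbm_max_trees,
                            tree_grid_step=cfg.gbm_tree_grid_step,
                            cv_folds=cfg.gbm_cv_folds, seed=fit_seed)
                    model.tags = tags
                    model_list.append(model)
                    if not model.ok:
                        failures.append(dict(dataset=ds.tag, stage="fit",
                                             error=model.status, **tags))
                        continue
                    try:
                        rec = evaluate_internal(model, scheme, ds,
                                                candidate_stack, test_fold,
                                                boyce_kw)
                        rows.append(rec.as_row())
                    except ValueError as exc:
                        failures.append(dict(dataset=ds.tag,
                                             stage="internal",
                                             error=str(exc), **tags))
                    if ds.group in ("A", "B"):
                        other = "B" if ds.group == "A" else "A"
                        pool = [d for d in datasets if d.group == other
                                and d.size == ds.size]
                        target = pool[rng_ext.integers(len(pool))]
                        try:
                            rec = evaluate_external(model, target,
                                                    ext_background[other],
                                                    boyce_kw)
                            row = rec.as_row()
                            row["external_target"] = target.tag
                            rows.append(row)
                        except ValueError as exc:
                            failures.append(dict(dataset=ds.tag,
                                                 stage="external",
                                                 error=str(exc), **tags))
    records = pd.DataFrame(rows)
    return ExperimentResult(records, model_list, datasets, block_sizes,
                            failures)
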