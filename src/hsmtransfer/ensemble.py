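"""Boyce-weighted ensembles, variable importance, inflated response curves.

Models attaining a Continuous Boyce Index B >= 0.7 in spatial-block CV form
the ensemble for their calibration-group x size x predictor-set combination.
Their suitability maps are combined as a B-weighted mean, and the weighted
standard deviation across members is

    sqrt( sum_i B_i (HS_i - HS_WA)^2 / ( ((N-1)/N) * sum_i B_i ) )

which reduces to the ordinary sample SD when all weights are equal. Variable
importance uses the permutation convention 1 - cor(pred, pred_shuffled),
normalized per member to percent contributions and combined with the same
weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .models import FittedHSM
from .raster import Grid

__all__ = [
    "EnsembleMember", "ImportanceTable", "weighted_mean_map",
    "weighted_sd_map", "variable_importance", "weighted_importance_table",
    "select_curve_variables", "inflated_response_curves",
    "select_members",
]

B_CUTOFF = 0.7


class EmptyEnsembleError(RuntimeError):
    pass


@dataclass
class EnsembleMember:
    weight: float                # the member's SpBlockCV Boyce index B_i
    suitability: Grid            # HS_i raster
    model: FittedHSM | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("member weight must be non-negative")


def select_members(models_with_b: list[tuple[FittedHSM, float]],
                   predict_fn, cutoff: float = B_CUTOFF
                   ) -> list[EnsembleMember]:
    """Keep models with B >= cutoff and materialize their suitability maps."""
    members = []
    for model, b in models_with_b:
        if b is None or np.isnan(b) or b < cutoff:
            continue
        members.append(EnsembleMember(b, predict_fn(model), model))
    if not members:
        raise EmptyEnsembleError(
            f"no model reached the ensemble cutoff B >= {cutoff}")
    return members


def _check_members(members: list[EnsembleMember]) -> None:
    if not members:
        raise EmptyEnsembleError("empty ensemble")
    g0 = members[0].suitability
    for m in members[1:]:
        if not m.suitability.same_georef(g0):
            raise ValueError("ensemble member rasters are not co-registered")


def weighted_mean_map(members: list[EnsembleMember]) -> Grid:
    """Per-cell HS_WA = sum(B_i * HS_i) / sum(B_i)."""
    _check_members(members)
    w = np.array([m.weight for m in members])
    stack = np.stack([m.suitability.data for m in members])
    wa = np.tensordot(w, stack, axes=1) / w.sum()
    g0 = members[0].suitability
    return Grid(wa, g0.origin, g0.cell_size)


def weighted_sd_map(members: list[EnsembleMember]) -> Grid:
    """Per-cell B-weighted standard deviation of member suitabilities."""
    _check_members(members)
    n = len(members)
    if n < 2:
        raise ValueError("weighted SD undefined for a single member")
    w = np.array([m.weight for m in members])
    stack = np.stack([m.suitability.data for m in members])
    wa = np.tensordot(w, stack, axes=1) / w.sum()
    num = np.tensordot(w, (stack - wa) ** 2, axes=1)
    sd = np.sqrt(num / (((n - 1) / n) * w.sum()))
    g0 = members[0].suitability
    return Grid(sd, g0.origin, g0.cell_size)


# --------------------------------------------------------------------------
# variable importance
# --------------------------------------------------------------------------

def variable_importance(model: FittedHSM, sites: pd.DataFrame,
                        n_shuffles: int = 3, seed: int = 0) -> pd.Series:
    """Permutation importance: 1 - Pearson r between original predictions
    and predictions with one variable shuffled, averaged over shuffles.

    Values are clipped to >= 0. Constant predictions yield all-zero scores
    with a warning.
    """
    if len(sites) < 30:
        raise ValueError("need >= 30 sites for stable importance scores")
    rng = np.random.default_rng(seed)
    base = model.predict(sites)
    if np.std(base) == 0:
        warnings.warn("constant predictions; all importances set to 0")
        return pd.Series(0.0, index=model.variables)
    out = {}
    for v in model.variables:
        scores = []
        for _ in range(n_shuffles):
            shuffled = sites.copy()
            shuffled[v] = rng.permutation(shuffled[v].to_numpy())
            pred = model.predict(shuffled)
            if np.std(pred) == 0:
                scores.append(1.0)
                continue
            r = np.corrcoef(base, pred)[0, 1]
            scores.append(1.0 - r)
        out[v] = max(float(np.mean(scores)), 0.0)
    return pd.Series(out)


@dataclass
class ImportanceTable:
    table: pd.DataFrame     # columns: Weighted_Avg_Imp, Weighted_StdDev_Imp, CV

    def __post_init__(self) -> None:
        total = self.table["Weighted_Avg_Imp"].sum()
        if not np.isclose(total, 100.0, atol=1e-6):
            raise ValueError("Weighted_Avg_Imp must sum to 100%")


def weighted_importance_table(weights: list[float],
                              raw_scores: list[pd.Series]) -> ImportanceTable:
    """B-weighted percent importance with Eq.-1-style weighted SD and CV.

    Each member's raw scores are first normalized to percent contributions;
    members whose raw scores are all zero are excluded with a log warning.
    """
    keep_w, keep_s = [], []
    for w, s in zip(weights, raw_scores):
        tot = s.sum()
        if tot <= 0:
            warnings.warn("member with zero total raw importance excluded")
            continue
        keep_w.append(w)
        keep_s.append(100.0 * s / tot)
    if not keep_w:
        raise EmptyEnsembleError("no member with usable importance scores")
    w = np.array(keep_w)
    mat = pd.concat(keep_s, axis=1).to_numpy()   # (n_vars, n_members)
    avg = mat @ w / w.sum()
    n = len(keep_w)
    if n > 1:
        num = ((mat - avg[:, None]) ** 2) @ w
        sd = np.sqrt(num / (((n - 1) / n) * w.sum()))
    else:
        sd = np.zeros_like(avg)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(avg > 0, sd / avg, np.nan)
    index = keep_s[0].index
    table = pd.DataFrame({"Weighted_Avg_Imp": avg,
                          "Weighted_StdDev_Imp": sd,
                          "CV": cv}, index=index)
    return ImportanceTable(table)


def select_curve_variables(table: ImportanceTable) -> list[str]:
    """The 3 lowest-CV variables among the top-5 by weighted importance.

    Ties broken by name order; with fewer than 5 variables all are
    considered (warned).
    """
    df = table.table.copy()
    if len(df) < 5:
        warnings.warn("fewer than 5 variables; considering all")
    df = df.sort_values(["Weighted_Avg_Imp", "CV"],
                        ascending=[False, True],
                        kind="stable")
    # stable top-5 by Avg with name-order tie-break
    df["_name"] = df.index
    top5 = df.sort_values(["Weighted_Avg_Imp", "_name"],
                          ascending=[False, True], kind="stable").head(5)
    chosen = top5.sort_values(["CV", "_name"],
                              ascending=[True, True], kind="stable").head(3)
    return list(chosen.index)


# --------------------------------------------------------------------------
# inflated response curves
# --------------------------------------------------------------------------

PROFILE_STATS = ("min", "q1", "median", "mean", "q3", "max")


def _profile_values(x: pd.Series) -> dict:
    return {
        "min": x.min(), "q1": x.quantile(0.25), "median": x.median(),
        "mean": x.mean(), "q3": x.quantile(0.75), "max": x.max(),
    }


def inflated_response_curves(model: FittedHSM, variable: str,
                             sites: pd.DataFrame, grid: int = 100,
                             max_combinations: int = 50, seed: int = 0,
                             scale: str = "response") -> pd.DataFrame:
    """Suitability along one predictor under many profiles of the others.

    The other predictors take every combination of their
    {min, Q1, median, mean, Q3, max} training statistics (a seeded random
    subsample of at most ``max_combinations`` when the factorial is larger).
    Returns a long-format frame with columns (combination, x, suitability).
    """
    if variable not in model.variables:
        raise ValueError(f"{variable!r} is not among the model's predictors")
    others = [v for v in model.variables if v != variable]
    focal = sites[variable]
    xs = np.linspace(focal.min(), focal.max(), grid)
    if others:
        stats = {v: _profile_values(sites[v]) for v in others}
        combos = list(product(PROFILE_STATS, repeat=len(others)))
        if len(combos) > max_combinations:
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(combos), max_combinations, replace=False)
            combos = [combos[i] for i in sorted(idx)]
    else:
        combos = [()]
    frames = []
    for ci, combo in enumerate(combos):
        df = pd.DataFrame({variable: xs})
        for v, stat in zip(others, combo):
            df[v] = stats[v][stat]
        pred = model.predict(df, scale=scale)
        frames.append(pd.DataFrame({
            "combination": ci, "profile": ["|".join(combo)] * grid,
            "x": xs, "suitability": pred}))
    return pd.concat(frames, ignore_index=True)
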