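"""Habitat suitability models: binomial GAMs and gradient boosting.

GAMs are binomial GLMs over natural-cubic-spline bases with per-variable
smoothing degree at most 3. Starting from all variables at degree 3, a
stepwise search over the scope {excluded, linear, smooth df 2, smooth df 3}
moves single variables up or down one level, accepting the move that most
improves AIC, in both directions, until no move improves (so the returned
model's AIC never exceeds the start model's).

GBMs are depth-3 stochastic gradient boosting classifiers (bernoulli loss);
the tree count is selected by k-fold cross-validated deviance evaluated on a
stated grid of tree counts, capped at a configured maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .raster import Grid, PredictorStack

__all__ = ["FittedHSM", "fit_gam", "fit_gbm", "predict_suitability",
           "natural_spline_basis"]

GAM_SCOPE = ("out", "linear", "s2", "s3")   # per-variable term levels


class ConvergenceFlag(RuntimeError):
    pass


# --------------------------------------------------------------------------
# spline basis
# --------------------------------------------------------------------------

def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis with df = len(knots) - 1 columns.

    Standard truncated-power construction: N_1 = x and
    N_{k+1}(x) = d_k(x) - d_{K-1}(x) with
    d_k(x) = ((x - xi_k)_+^3 - (x - xi_K)_+^3) / (xi_K - xi_k).
    Linear beyond the boundary knots, so extrapolated predictions stay tame.
    """
    x = np.asarray(x, dtype=float)
    xi = np.asarray(knots, dtype=float)
    K = xi.size

    def d(k):
        num = (np.maximum(x - xi[k], 0.0) ** 3
               - np.maximum(x - xi[K - 1], 0.0) ** 3)
        return num / (xi[K - 1] - xi[k])

    cols = [x]
    dK1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK1)
    return np.column_stack(cols)


def _term_columns(x: np.ndarray, level: str, knots: dict) -> np.ndarray:
    if level == "linear":
        return x[:, None]
    return natural_spline_basis(x, knots[level])


def _knots_for(x: np.ndarray) -> dict:
    """Quantile knot vectors for each smooth level (df = len(knots) - 1)."""
    out = {}
    for level, df in (("s2", 2), ("s3", 3)):
        knots = np.quantile(x, np.linspace(0, 1, df + 1))
        # jitter degenerate knots so the basis stays full rank
        for i in range(1, knots.size):
            if knots[i] <= knots[i - 1]:
                knots[i] = knots[i - 1] + 1e-9
        out[level] = knots
    return out


# --------------------------------------------------------------------------
# fitted-model container
# --------------------------------------------------------------------------

@dataclass
class FittedHSM:
    """One fitted habitat suitability model plus its training context."""

    algorithm: str                       # "GAM" | "GBM"
    variables: list[str]                 # candidate predictors offered
    status: str = "ok"                   # "ok" | "failed:<reason>"
    # GAM internals
    gam_terms: Optional[dict] = None     # var -> level in GAM_SCOPE
    gam_result: object = None
    gam_knots: Optional[dict] = None     # var -> {level: knot vector}
    aic: Optional[float] = None
    # GBM internals
    gbm: object = None
    n_trees: Optional[int] = None
    # provenance
    train_values: Optional[pd.DataFrame] = None   # predictor values used
    tags: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def retained_terms(self) -> list[str]:
        if self.algorithm == "GAM":
            return [v for v, lvl in self.gam_terms.items() if lvl != "out"]
        return list(self.variables)

    # -- prediction -------------------------------------------------------
    def _gam_design(self, X: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(X))]
        for v in self.variables:
            lvl = self.gam_terms[v]
            if lvl == "out":
                continue
            cols.append(_term_columns(X[v].to_numpy(float), lvl,
                                      self.gam_knots[v]))
        return np.column_stack(cols)

    def predict(self, X: pd.DataFrame, scale: str = "response") -> np.ndarray:
        missing = [v for v in self.variables if v not in X.columns]
        if missing:
            raise ValueError(f"missing predictor(s) for prediction: {missing}")
        if not self.ok:
            raise ConvergenceFlag(f"model unusable: {self.status}")
        if self.algorithm == "GAM":
            design = self._gam_design(X)
            eta = design @ self.gam_result.params
            if scale == "link":
                return eta
            return expit(eta)
        raw = self.gbm.decision_function(X[self.variables].to_numpy(float))
        if scale == "link":
            return raw
        return expit(raw)


# --------------------------------------------------------------------------
# GAM
# --------------------------------------------------------------------------

def _fit_glm(y: np.ndarray, design: np.ndarray):
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
        res.aic  # force lazy evaluation inside the silenced context
    return res


def fit_gam(train: pd.DataFrame, predictors: list[str],
            label_col: str = "label") -> FittedHSM:
    """Binomial GAM with stepwise AIC term selection (both directions)."""
    y = train[label_col].to_numpy(int)
    if y.min() == y.max():
        return FittedHSM("GAM", list(predictors),
                         status="failed:single-class training data")
    knots = {v: _knots_for(train[v].to_numpy(float)) for v in predictors}
    levels = {v: "s3" for v in predictors}

    def design_for(lv: dict) -> np.ndarray:
        cols = [np.ones(len(train))]
        for v in predictors:
            if lv[v] == "out":
                continue
            cols.append(_term_columns(train[v].to_numpy(float), lv[v],
                                      knots[v]))
        return np.column_stack(cols)

    aic_cache: dict[tuple, float] = {}

    def aic_for(lv: dict) -> float:
        key = tuple(lv[v] for v in predictors)
        if key not in aic_cache:
            res = _fit_glm(y, design_for(lv))
            aic_cache[key] = (np.inf
                              if not np.all(np.isfinite(res.params))
                              else float(res.aic))
        return aic_cache[key]

    try:
        current_aic = aic_for(levels)
        if not np.isfinite(current_aic):
            # rich start can fail near separation; retry from all-linear
            levels = {v: "linear" for v in predictors}
            current_aic = aic_for(levels)
        if not np.isfinite(current_aic):
            raise ValueError("start model did not converge")
        improved = True
        while improved:
            improved = False
            best = (current_aic, None, None)
            for v in predictors:
                k = GAM_SCOPE.index(levels[v])
                for k2 in (k - 1, k + 1):       # adjacent scope moves
                    if not 0 <= k2 < len(GAM_SCOPE):
                        continue
                    trial = dict(levels, **{v: GAM_SCOPE[k2]})
                    a = aic_for(trial)
                    if a < best[0] - 1e-9:
                        best = (a, v, GAM_SCOPE[k2])
            if best[1] is not None:
                current_aic, levels = best[0], dict(
                    levels, **{best[1]: best[2]})
                improved = True
        res = _fit_glm(y, design_for(levels))
    except Exception as exc:   # separation / convergence failures are flagged
        return FittedHSM("GAM", list(predictors),
                         status=f"failed:{type(exc).__name__}: {exc}")
    return FittedHSM("GAM", list(predictors), gam_terms=levels,
                     gam_result=res, gam_knots=knots, aic=current_aic,
                     train_values=train[list(predictors)].copy())


# --------------------------------------------------------------------------
# GBM
# --------------------------------------------------------------------------

def _bernoulli_deviance(y: np.ndarray, raw: np.ndarray) -> float:
    p = 1.0 / (1.0 + np.exp(-raw))
    eps = 1e-12
    return float(-2.0 * np.mean(y * np.log(p + eps)
                                + (1 - y) * np.log(1 - p + eps)))


def fit_gbm(train: pd.DataFrame, predictors: list[str],
            label_col: str = "label", learning_rate: float = 0.001,
            max_trees: int = 10_000, tree_grid_step: int = 100,
            cv_folds: int = 5, max_depth: int = 3,
            seed: int = 0) -> FittedHSM:
    """Depth-3 GBM; tree count chosen by k-fold CV deviance on a grid."""
    y = train[label_col].to_numpy(int)
    if y.min() == y.max():
        return FittedHSM("GBM", list(predictors),
                         status="failed:single-class training data")
    X = train[list(predictors)].to_numpy(float)
    grid = np.arange(tree_grid_step, max_trees + 1, tree_grid_step)
    if grid.size == 0:
        grid = np.array([max_trees])
    try:
        skf = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
        cv_dev = np.zeros(grid.size)
        for tr, va in skf.split(X, y):
            g = GradientBoostingClassifier(
                learning_rate=learning_rate, n_estimators=int(grid[-1]),
                max_depth=max_depth, random_state=seed)
            g.fit(X[tr], y[tr])
            for gi, raw in enumerate(g.staged_decision_function(X[va])):
                stage = gi + 1
                hit = np.searchsorted(grid, stage)
                if hit < grid.size and grid[hit] == stage:
                    cv_dev[hit] += _bernoulli_deviance(y[va], raw.ravel())
        n_best = int(grid[int(np.argmin(cv_dev))])
        final = GradientBoostingClassifier(
            learning_rate=learning_rate, n_estimators=n_best,
            max_depth=max_depth, random_state=seed)
        final.fit(X, y)
    except Exception as exc:
        return FittedHSM("GBM", list(predictors),
                         status=f"failed:{type(exc).__name__}: {exc}")
    return FittedHSM("GBM", list(predictors), gbm=final, n_trees=n_best,
                     train_values=train[list(predictors)].copy())


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

def predict_suitability(model: FittedHSM,
                        sites: pd.DataFrame | PredictorStack
                        ) -> np.ndarray | Grid:
    """Suitability in [0, 1] at point sites (DataFrame) or across a stack."""
    if isinstance(sites, PredictorStack):
        missing = [v for v in model.variables if v not in sites.names]
        if missing:
            raise ValueError(f"missing predictor layer(s): {missing}")
        r, c = sites.valid_rc()
        table = pd.DataFrame(
            {v: sites.layer(v).data[r, c] for v in model.variables})
        vals = model.predict(table)
        out = np.full(sites.shape, np.nan)
        out[r, c] = vals
        return Grid(out, sites.origin, sites.cell_size)
    return model.predict(sites)
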