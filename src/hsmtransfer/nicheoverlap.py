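"""PCA-env niche quantification, Schoener's D, and permutation tests.

Environmental space is the plane of the first two principal components of
standardized background samples pooled across the study area. Each entity's
niche occupancy z is the kernel-smoothed density of its occurrences on an
R x R grid over that plane, corrected by the kernel-smoothed density of its
available background, and normalized to sum to one. Overlap between two
occupancies is Schoener's D = 1 - 0.5 * sum |z1 - z2|.

The equivalency test permutes occurrences between entities (sample sizes
preserved); the similarity test draws virtual occurrence sets from the other
entity's background. Both use the +1-corrected permutation p-value, so the
minimum attainable p is 1/(n_reps + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

__all__ = [
    "PcaEnv", "NicheGrid", "OverlapResult", "pca_env", "occupancy_grid",
    "schoeners_d", "equivalency_test", "similarity_test",
]


@dataclass
class PcaEnv:
    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray       # (2, n_vars)
    explained: np.ndarray        # variance fractions of the two axes
    variables: list[str]

    def transform(self, values: pd.DataFrame) -> np.ndarray:
        X = values[self.variables].to_numpy(float)
        Z = (X - self.mean) / self.scale
        return Z @ self.components.T


def pca_env(background: pd.DataFrame, n_axes: int = 2) -> PcaEnv:
    """PCA of standardized background environments (axes by variance)."""
    if len(background) < 3 or background.shape[1] < 2:
        raise ValueError("need >= 3 sites and >= 2 variables")
    cols = list(background.columns)
    X = background.to_numpy(float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"zero-variance variable(s) dropped: {dropped}")
        cols = [c for c, k in zip(cols, keep) if k]
        X = X[:, keep]
        sd = sd[keep]
    mean = X.mean(axis=0)
    Z = (X - mean) / sd
    p = PCA(n_components=n_axes, svd_solver="full").fit(Z)
    return PcaEnv(mean, sd, p.components_, p.explained_variance_ratio_, cols)


@dataclass
class NicheGrid:
    """Kernel-smoothed, availability-corrected occupancy on the PCA plane."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    occ_density: np.ndarray
    bg_density: np.ndarray
    z: np.ndarray                 # normalized occupancy; 0 off bg support
    support: np.ndarray           # bool: background available

    def same_grid(self, other: "NicheGrid") -> bool:
        return (self.z.shape == other.z.shape
                and np.allclose(self.x_edges, other.x_edges)
                and np.allclose(self.y_edges, other.y_edges))


def _grid_bounds(background_scores: np.ndarray, margin: float = 0.05):
    lo = background_scores.min(axis=0)
    hi = background_scores.max(axis=0)
    pad = margin * (hi - lo)
    return lo - pad, hi + pad


def occupancy_grid(occ_scores: np.ndarray, background_scores: np.ndarray,
                   R: int = 100,
                   bounds: Optional[tuple[np.ndarray, np.ndarray]] = None,
                   bw_method=None,
                   support_eps: float = 1e-4) -> NicheGrid:
    """Estimate niche occupancy z on an R x R grid over the PCA plane.

    z is proportional to occurrence density / background density where
    background density exceeds ``support_eps`` times its maximum (Gaussian
    kernels are positive everywhere; the threshold delimits the realistically
    available environment), zero elsewhere, and normalized to sum to 1.
    Kernel bandwidth follows the Scott plug-in rule unless overridden.
    """
    occ = np.asarray(occ_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if occ.shape[0] < 5:
        raise ValueError("need >= 5 occurrences")
    if bounds is None:
        bounds = _grid_bounds(bg)
    lo, hi = bounds
    x_edges = np.linspace(lo[0], hi[0], R + 1)
    y_edges = np.linspace(lo[1], hi[1], R + 1)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    pts = np.vstack([gx.ravel(), gy.ravel()])

    inside = ((occ[:, 0] >= lo[0]) & (occ[:, 0] <= hi[0])
              & (occ[:, 1] >= lo[1]) & (occ[:, 1] <= hi[1]))
    if not inside.any():
        raise ValueError("all occurrences fall outside the grid")

    occ_d = gaussian_kde(occ.T, bw_method=bw_method)(pts).reshape(R, R)
    bg_d = gaussian_kde(bg.T, bw_method=bw_method)(pts).reshape(R, R)
    support = bg_d >= support_eps * bg_d.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(support, occ_d / bg_d, 0.0)
    total = z.sum()
    if total <= 0:
        raise ValueError("occupancy has no mass on the background support")
    return NicheGrid(x_edges, y_edges, occ_d, bg_d, z / total, support)


def schoeners_d(z1: NicheGrid, z2: NicheGrid) -> float:
    """D = 1 - 0.5 * sum |z1 - z2|; 0 = disjoint niches, 1 = identical."""
    if not z1.same_grid(z2):
        raise ValueError("niche grids do not match")
    return float(1.0 - 0.5 * np.abs(z1.z - z2.z).sum())


@dataclass
class OverlapResult:
    d_observed: float
    d_simulated: np.ndarray
    test: str                    # "equivalency" | "similarity"
    alternative: str             # "divergence" | "conservatism" | "two-sided"
    p_value: float
    p_divergence: float = field(default=np.nan)
    p_conservatism: float = field(default=np.nan)


def _perm_p(d_obs: float, sims: np.ndarray) -> tuple[float, float]:
    n = sims.size
    p_low = (1 + np.sum(sims <= d_obs)) / (1 + n)    # divergence tail
    p_high = (1 + np.sum(sims >= d_obs)) / (1 + n)   # conservatism tail
    return float(p_low), float(p_high)


def equivalency_test(occ1_scores: np.ndarray, occ2_scores: np.ndarray,
                     bg1_scores: np.ndarray, bg2_scores: np.ndarray,
                     R: int = 100, n_reps: int = 1000,
                     seed: int = 0, **grid_kw) -> OverlapResult:
    """Niche equivalency by random reallocation of pooled occurrences.

    Each permutation splits the pooled occurrences into two pseudo-entities
    of the original sizes and recomputes D against the entities' own
    backgrounds. Equivalency is rejected for D_obs below the simulated 5th
    percentile; both tail p-values are reported.
    """
    if n_reps < 99:
        raise ValueError("n_reps must be >= 99")
    occ1 = np.asarray(occ1_scores, float)
    occ2 = np.asarray(occ2_scores, float)
    pooled = np.vstack([occ1, occ2])
    if pooled.shape[0] < 10:
        raise ValueError("pooled occurrence count must be >= 10")
    bounds = _grid_bounds(np.vstack([bg1_scores, bg2_scores]))

    def d_of(o1, o2):
        g1 = occupancy_grid(o1, bg1_scores, R, bounds, **grid_kw)
        g2 = occupancy_grid(o2, bg2_scores, R, bounds, **grid_kw)
        return schoeners_d(g1, g2)

    d_obs = d_of(occ1, occ2)
    rng = np.random.default_rng(seed)
    n1 = occ1.shape[0]
    sims = np.empty(n_reps)
    for i in range(n_reps):
        perm = rng.permutation(pooled.shape[0])
        sims[i] = d_of(pooled[perm[:n1]], pooled[perm[n1:]])
    p_div, p_cons = _perm_p(d_obs, sims)
    return OverlapResult(d_obs, sims, "equivalency", "two-sided",
                         min(1.0, 2 * min(p_div, p_cons)), p_div, p_cons)


def similarity_test(occ_focal_scores: np.ndarray, occ_other_scores: np.ndarray,
                    bg_focal_scores: np.ndarray, bg_other_scores: np.ndarray,
                    alternative: str = "divergence", R: int = 100,
                    n_reps: int = 1000, seed: int = 0,
                    **grid_kw) -> OverlapResult:
    """Niche similarity: virtual niches drawn from the other's background.

    Per repetition a virtual occurrence set of the other entity's size is
    drawn (with replacement) from the other entity's background points and
    its occupancy compared with the focal entity's real niche. Divergence is
    supported when D_obs falls below the simulated 5th percentile,
    conservatism when above the 95th.
    """
    occ_o = np.asarray(occ_other_scores, float)
    bg_o = np.asarray(bg_other_scores, float)
    if bg_o.shape[0] < occ_o.shape[0]:
        raise ValueError("background sample smaller than occurrence count")
    if alternative not in ("divergence", "conservatism"):
        raise ValueError("alternative must be divergence or conservatism")
    bounds = _grid_bounds(np.vstack([bg_focal_scores, bg_o]))
    g_focal = occupancy_grid(occ_focal_scores, bg_focal_scores, R, bounds,
                             **grid_kw)
    g_other = occupancy_grid(occ_o, bg_o, R, bounds, **grid_kw)
    d_obs = schoeners_d(g_focal, g_other)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_reps)
    n_virtual = occ_o.shape[0]
    for i in range(n_reps):
        idx = rng.integers(bg_o.shape[0], size=n_virtual)
        g_virt = occupancy_grid(bg_o[idx], bg_o, R, bounds, **grid_kw)
        sims[i] = schoeners_d(g_focal, g_virt)
    p_div, p_cons = _perm_p(d_obs, sims)
    p = p_div if alternative == "divergence" else p_cons
    return OverlapResult(d_obs, sims, "similarity", alternative, p,
                         p_div, p_cons)
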