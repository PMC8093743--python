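"""Synthetic landscapes, virtual species, and disjunct-cluster scenarios.

The downstream analysis contrasts habitat-suitability models calibrated on two
geographically disjunct population clusters (labelled ``A`` and ``B``). This
module generates seeded synthetic inputs with the statistical structure that
analysis assumes:

* two disjoint rectangular regions on a shared equal-area grid, everything
  between them nodata;
* spatially autocorrelated "bioclim-like" layers (smoothed white noise),
  with region A's background configurably more heterogeneous than B's;
* 12-layer monthly solar-radiation and wind-speed stacks with seasonal
  (sinusoid + noise) structure;
* a fine-resolution categorical land-cover raster for several epochs;
* a virtual species whose true suitability is known, with per-cluster niche
  breadth modifiers (cluster B can be configured as the narrow-niche analog);
* presence sampling proportional to true suitability, with an optional
  clustered sampling-bias kernel.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .raster import Grid, PredictorStack

__all__ = [
    "LandscapeConfig", "ScenarioConfig", "LandscapeBundle", "OccurrenceSet",
    "GaussianResponse", "LogisticResponse", "VirtualNiche", "BiasKernel",
    "Scenario", "make_landscape", "sample_occurrences",
    "make_disjunct_scenario", "truth_overlap",
]

Rect = tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)


class ConfigurationError(ValueError):
    pass


class SamplingError(RuntimeError):
    pass


def _rects_overlap(a: Rect, b: Rect) -> bool:
    return not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1])


@dataclass
class LandscapeConfig:
    """Geometry and stochastic structure of the synthetic landscape."""

    region_a: Rect = (0.0, 0.0, 100_000.0, 100_000.0)
    region_b: Rect = (160_000.0, 0.0, 260_000.0, 100_000.0)
    cell_size: float = 1_000.0
    n_bioclim_like: int = 19
    n_latent: int = 5              # shared climate gradients behind the layers
    latent_loading: float = 0.96   # how strongly layers track their gradient
    spatial_corr_range: float = 10_000.0   # meters; smoothing length of fields
    heterogeneity: tuple[float, float] = (1.0, 0.5)  # anomaly scale (A, B)
    mirror_regions: bool = False   # copy region A's values into B (controls)
    b_env_shift: float = 0.0       # additive shift (in layer SDs) in region B
    fine_factor: int = 10          # land-cover cells per predictor cell, 1D
    n_epochs: int = 5
    landcover_change_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if _rects_overlap(self.region_a, self.region_b):
            raise ConfigurationError("region rectangles overlap")
        if self.n_epochs < 2:
            raise ConfigurationError("need at least 2 land-cover epochs")


@dataclass
class OccurrenceSet:
    """Labelled presence points in projected meters."""

    x: np.ndarray
    y: np.ndarray
    cluster: np.ndarray                 # labels, e.g. "A"/"B"
    year: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.cluster = np.asarray(self.cluster)

    def __len__(self) -> int:
        return self.x.size

    def subset(self, label: str) -> "OccurrenceSet":
        m = self.cluster == label
        return OccurrenceSet(self.x[m], self.y[m], self.cluster[m],
                             None if self.year is None else self.year[m])

    def union(self, other: "OccurrenceSet") -> "OccurrenceSet":
        year = None
        if self.year is not None and other.year is not None:
            year = np.concatenate([self.year, other.year])
        return OccurrenceSet(
            np.concatenate([self.x, other.x]),
            np.concatenate([self.y, other.y]),
            np.concatenate([self.cluster, other.cluster]), year)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"x": self.x, "y": self.y, "cluster": self.cluster})
        if self.year is not None:
            df["year"] = self.year
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OccurrenceSet":
        year = df["year"].to_numpy() if "year" in df else None
        return cls(df["x"].to_numpy(), df["y"].to_numpy(),
                   df["cluster"].to_numpy(), year)


@dataclass
class LandscapeBundle:
    """All synthetic rasters for one landscape realization."""

    bioclim: PredictorStack            # n_bioclim_like layers
    srad: PredictorStack               # 12 monthly layers
    wind: PredictorStack               # 12 monthly layers
    landcover: list[Grid]              # fine categorical rasters, one per epoch
    region_a: Rect
    region_b: Rect

    def region_mask(self, label: str) -> np.ndarray:
        rect = self.region_a if label == "A" else self.region_b
        gx, gy = self.bioclim.grid_template().cell_centers()
        inside = ((gx >= rect[0]) & (gx < rect[2]) &
                  (gy >= rect[1]) & (gy < rect[3]))
        return inside & self.bioclim.mask


# --------------------------------------------------------------------------
# landscape generation
# --------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float
                  ) -> np.ndarray:
    """Unit-variance spatially autocorrelated field (smoothed white noise)."""
    z = rng.standard_normal(shape)
    if sigma_cells > 1e-9:
        z = gaussian_filter(z, sigma=sigma_cells, mode="nearest")
    s = z.std()
    return z / s if s > 0 else z


def _grid_geometry(cfg: LandscapeConfig):
    xmin = min(cfg.region_a[0], cfg.region_b[0])
    ymin = min(cfg.region_a[1], cfg.region_b[1])
    xmax = max(cfg.region_a[2], cfg.region_b[2])
    ymax = max(cfg.region_a[3], cfg.region_b[3])
    nc = int(round((xmax - xmin) / cfg.cell_size))
    nr = int(round((ymax - ymin) / cfg.cell_size))
    return (xmin, ymin), nr, nc


def _mask_and_regions(cfg: LandscapeConfig, origin, nr, nc):
    xs = origin[0] + (np.arange(nc) + 0.5) * cfg.cell_size
    ys = origin[1] + (np.arange(nr) + 0.5) * cfg.cell_size
    gx, gy = np.meshgrid(xs, ys)

    def inside(rect):
        return ((gx >= rect[0]) & (gx < rect[2]) &
                (gy >= rect[1]) & (gy < rect[3]))

    in_a, in_b = inside(cfg.region_a), inside(cfg.region_b)
    return in_a | in_b, in_a, in_b


def _apply_regional_structure(layer: np.ndarray, cfg: LandscapeConfig,
                              in_a, in_b, sd: float) -> np.ndarray:
    """Scale anomalies per region (heterogeneity) and shift region B."""
    out = layer.copy()
    out[in_a] *= cfg.heterogeneity[0]
    out[in_b] *= cfg.heterogeneity[1]
    if cfg.mirror_regions:
        a_vals = out[in_a]
        if a_vals.size != out[in_b].size:
            raise ConfigurationError(
                "mirror_regions requires equally sized regions")
        # both region masks enumerate cells row-major, so the copy is a
        # rigid translation of region A's pattern into region B
        out[in_b] = a_vals
    if cfg.b_env_shift != 0.0:
        out[in_b] += cfg.b_env_shift * sd
    return out


def make_landscape(cfg: LandscapeConfig) -> LandscapeBundle:
    """Generate all predictor rasters for one seeded landscape realization."""
    origin, nr, nc = _grid_geometry(cfg)
    valid, in_a, in_b = _mask_and_regions(cfg, origin, nr, nc)
    sigma = cfg.spatial_corr_range / cfg.cell_size
    ss = np.random.SeedSequence(cfg.seed)
    rng_bio, rng_srad, rng_wind, rng_lc = (
        np.random.default_rng(s) for s in ss.spawn(4))

    # bioclim-like layers: mixtures of a few shared latent gradients plus
    # idiosyncratic smooth noise, so the pool carries realistic collinearity
    # (temperature- and precipitation-like variable families)
    latents = [_smooth_field(rng_bio, (nr, nc), sigma)
               for _ in range(max(cfg.n_latent, 1))]
    bio = np.empty((cfg.n_bioclim_like, nr, nc))
    for k in range(cfg.n_bioclim_like):
        mean = rng_bio.uniform(-2.0, 2.0)
        sd = rng_bio.uniform(0.5, 2.0)
        lat = latents[k % len(latents)]
        sign = 1.0 if rng_bio.random() < 0.5 else -1.0
        load = cfg.latent_loading
        anom = (sign * load * lat
                + np.sqrt(max(1.0 - load ** 2, 0.0))
                * _smooth_field(rng_bio, (nr, nc), sigma))
        anom = _apply_regional_structure(anom, cfg, in_a, in_b, sd=1.0)
        bio[k] = mean + sd * anom
    bio[:, ~valid] = np.nan
    bioclim = PredictorStack(
        [f"bio{k + 1:02d}" for k in range(cfg.n_bioclim_like)],
        bio, origin, cfg.cell_size, valid)

    # monthly stacks: smooth baseline + seasonal sinusoid + monthly noise
    def monthly(rng, base_mean, base_sd, amp_mean, noise_sd, peak_month,
                floor):
        base = base_mean + base_sd * _apply_regional_structure(
            _smooth_field(rng, (nr, nc), sigma), cfg, in_a, in_b, base_sd)
        amp = amp_mean * (1.0 + 0.2 * _smooth_field(rng, (nr, nc), sigma))
        layers = np.empty((12, nr, nc))
        for m in range(12):
            season = np.cos(2 * np.pi * (m + 1 - peak_month) / 12.0)
            noise = noise_sd * _smooth_field(rng, (nr, nc), sigma)
            layers[m] = np.maximum(base + amp * season + noise, floor)
        layers[:, ~valid] = np.nan
        return layers

    months = [f"{m:02d}" for m in range(1, 13)]
    srad = PredictorStack(
        [f"srad_{m}" for m in months],
        monthly(rng_srad, 100.0, 10.0, 35.0, 4.0, peak_month=7, floor=0.0),
        origin, cfg.cell_size, valid)
    wind = PredictorStack(
        [f"wind_{m}" for m in months],
        monthly(rng_wind, 5.0, 1.0, 1.5, 0.4, peak_month=1, floor=0.1),
        origin, cfg.cell_size, valid)

    # fine-resolution categorical land cover: 0 other, 1 grasslands,
    # 2 rocks/sparsely vegetated; epochs perturb a fraction of cells
    f = cfg.fine_factor
    latent = _smooth_field(rng_lc, (nr * f, nc * f), sigma * f)
    fine_valid = np.kron(valid, np.ones((f, f), dtype=bool))
    vals = latent[fine_valid]
    q20, q70 = np.quantile(vals, [0.2, 0.7])
    base_lc = np.zeros_like(latent, dtype=float)
    base_lc[latent >= q70] = 1.0
    base_lc[latent < q20] = 2.0
    base_lc[~fine_valid] = np.nan
    fine_cs = cfg.cell_size / f
    epochs = [Grid(base_lc.copy(), origin, fine_cs)]
    n_fine_valid = int(fine_valid.sum())
    flat_idx = np.flatnonzero(fine_valid)
    for _ in range(cfg.n_epochs - 1):
        lc = base_lc.copy()
        n_change = int(round(cfg.landcover_change_fraction * n_fine_valid))
        if n_change > 0:
            chosen = rng_lc.choice(flat_idx, size=n_change, replace=False)
            lc.flat[chosen] = rng_lc.integers(0, 3, size=n_change)
        epochs.append(Grid(lc, origin, fine_cs))

    return LandscapeBundle(bioclim, srad, wind, epochs,
                           cfg.region_a, cfg.region_b)


# --------------------------------------------------------------------------
# virtual species
# --------------------------------------------------------------------------

@dataclass
class GaussianResponse:
    optimum: float
    breadth: float          # Gaussian SD in the predictor's units


@dataclass
class LogisticResponse:
    slope: float
    intercept: float


@dataclass
class VirtualNiche:
    """Known true suitability: per-predictor responses + combination rule.

    ``rule="product"`` multiplies Gaussian responses (each in (0, 1]);
    ``rule="additive-logistic"`` passes the sum of linear terms through a
    logistic link. ``cluster_modifiers`` scales Gaussian breadths per cluster
    so one cluster's realized niche can be made narrower than the other's.
    """

    responses: dict
    rule: str = "product"
    cluster_modifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rule not in ("product", "additive-logistic"):
            raise ConfigurationError(f"unknown combination rule {self.rule!r}")

    def _breadth_scale(self, cluster: Optional[str]) -> float:
        if cluster is None:
            return 1.0
        return float(self.cluster_modifiers.get(cluster, 1.0))

    def true_suitability(self, stack: PredictorStack,
                         cluster: Optional[str] = None) -> Grid:
        """Suitability grid in [0, 1]; nodata propagated from the stack."""
        scale = self._breadth_scale(cluster)
        if self.rule == "product":
            out = np.ones(stack.shape)
            for name, resp in self.responses.items():
                x = stack.layer(name).data
                b = resp.breadth * scale
                out *= np.exp(-0.5 * ((x - resp.optimum) / b) ** 2)
        else:
            lin = np.zeros(stack.shape)
            for name, resp in self.responses.items():
                x = stack.layer(name).data
                lin += resp.slope * x + resp.intercept
            out = expit(lin)
        out[~stack.mask] = np.nan
        return Grid(out, stack.origin, stack.cell_size)


@dataclass
class BiasKernel:
    """Clustered-sampling bias: mixture of Gaussian hotspots (default off)."""

    centers: list[tuple[float, float]]
    sd: float
    strength: float = 4.0

    def weights(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        w = np.ones_like(x, dtype=float)
        for cx, cy in self.centers:
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            w += self.strength * np.exp(-0.5 * d2 / self.sd ** 2)
        return w


def sample_occurrences(truth: VirtualNiche, stack: PredictorStack, n: int,
                       cluster: str = "A",
                       region_mask: Optional[np.ndarray] = None,
                       bias_spec: Optional[BiasKernel] = None,
                       seed: int = 0) -> OccurrenceSet:
    """Draw n presence cells with P(cell) proportional to true suitability."""
    if n < 1:
        raise SamplingError("n must be >= 1")
    suit = truth.true_suitability(stack, cluster).data
    mask = stack.mask if region_mask is None else (stack.mask & region_mask)
    r, c = np.nonzero(mask)
    x = stack.origin[0] + (c + 0.5) * stack.cell_size
    y = stack.origin[1] + (r + 0.5) * stack.cell_size
    w = suit[r, c].astype(float)
    if bias_spec is not None:
        w = w * bias_spec.weights(x, y)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise SamplingError("true suitability is zero everywhere in region")
    rng = np.random.default_rng(seed)  # accepts int, SeedSequence, Generator
    idx = rng.choice(w.size, size=n, replace=True, p=w / total)
    return OccurrenceSet(x[idx], y[idx], np.full(n, cluster, dtype=object))


# --------------------------------------------------------------------------
# disjunct-cluster scenario
# --------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Full study conditions for a two-cluster virtual-species experiment.

    Defaults mimic the structure of the motivating study: cluster A (the
    wide-niche, heterogeneous-background analog) contributes ~1,400 presences,
    cluster B (the narrow-niche analog) ~300; B's niche breadth is scaled to
    60% of A's, and B's background anomalies to 50% of A's.
    """

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    niche_vars: tuple[str, ...] = ("bio01", "bio04", "bio12")
    niche_breadth: float = 0.6  # Gaussian breadth as fraction of region-A SD
    cluster_modifiers: dict = field(
        default_factory=lambda: {"A": 1.0, "B": 0.6})
    n_occ_a: int = 1376
    n_occ_b: int = 302
    bias_spec: Optional[BiasKernel] = None
    seed: int = 0


@dataclass
class Scenario:
    config: ScenarioConfig
    landscape: LandscapeBundle
    niche: VirtualNiche
    occurrences: OccurrenceSet          # clusters A and B pooled

    def region_mask(self, label: str) -> np.ndarray:
        return self.landscape.region_mask(label)

    def occ(self, label: str) -> OccurrenceSet:
        return self.occurrences.subset(label)


def make_disjunct_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate landscape + virtual niche + occurrences for both clusters.

    The niche optimum is placed at the mean environment of region A so the
    wide cluster occupies the core of its available conditions; cluster B's
    realized niche is narrower (via ``cluster_modifiers``) and only partially
    overlapping (its region offers a shifted slice of environmental space
    unless ``mirror_regions`` is set).
    """
    land_cfg = LandscapeConfig(**{**cfg.landscape.__dict__,
                                  "seed": cfg.landscape.seed + cfg.seed})
    land = make_landscape(land_cfg)
    stack = land.bioclim
    in_a = land.region_mask("A")

    responses = {}
    for name in cfg.niche_vars:
        layer = stack.layer(name).data
        a_vals = layer[in_a]
        opt = float(np.nanmean(a_vals))
        breadth = cfg.niche_breadth * float(np.nanstd(a_vals))
        responses[name] = GaussianResponse(opt, max(breadth, 1e-6))
    niche = VirtualNiche(responses, "product", dict(cfg.cluster_modifiers))

    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    occ_a = sample_occurrences(niche, stack, cfg.n_occ_a, "A",
                               land.region_mask("A"), cfg.bias_spec,
                               seed=ss[0])
    occ_b = sample_occurrences(niche, stack, cfg.n_occ_b, "B",
                               land.region_mask("B"), cfg.bias_spec,
                               seed=ss[1])
    return Scenario(cfg, land, niche, occ_a.union(occ_b))


def truth_overlap(scenario: Scenario, n_bins: int = 30) -> float:
    """Schoener's D between the clusters' true niches in environment space.

    Each cluster's occupancy is the true-suitability-weighted histogram of
    its region's cells over the first two niche variables (shared binning).
    Identical regions with equal breadth modifiers give D = 1 exactly.
    """
    stack = scenario.landscape.bioclim
    v1, v2 = scenario.config.niche_vars[:2]
    l1, l2 = stack.layer(v1).data, stack.layer(v2).data
    pooled1 = l1[stack.mask]
    pooled2 = l2[stack.mask]
    edges1 = np.linspace(pooled1.min(), pooled1.max() + 1e-9, n_bins + 1)
    edges2 = np.linspace(pooled2.min(), pooled2.max() + 1e-9, n_bins + 1)

    def occupancy(label):
        m = scenario.region_mask(label)
        w = scenario.niche.true_suitability(stack, label).data[m]
        h, _, _ = np.histogram2d(l1[m], l2[m], bins=[edges1, edges2],
                                 weights=w)
        return h / h.sum()

    z_a, z_b = occupancy("A"), occupancy("B")
    return float(1.0 - 0.5 * np.abs(z_a - z_b).sum())
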