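"""Presence datasets and buffered pseudoabsence sampling.

Builds the six presence datasets of the factorial design — calibration group
in {A, B, Joint} crossed with occurrence data size in {Full, Thin} — and, for
each, 10 replicate sets of pseudoabsences drawn uniformly from an annulus
(1.5-120 km by default) around the presences, clipped to the study mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster import PredictorStack
from .synthio import OccurrenceSet

__all__ = [
    "PresPseudoAbsDataset", "spatial_thin", "buffered_pseudoabsences",
    "assemble_datasets",
]

GROUPS = ("A", "B", "Joint")
SIZES = ("Full", "Thin")


@dataclass
class PresPseudoAbsDataset:
    """One presence set joined with one pseudoabsence replicate.

    ``values`` holds extracted predictor values for all points, with a binary
    ``label`` column (1 = presence) and x/y coordinates.
    """

    group: str          # "A" | "B" | "Joint"
    size: str           # "Full" | "Thin"
    replicate: int      # pseudoabsence replicate, 1-based
    presence: OccurrenceSet
    pa_x: np.ndarray
    pa_y: np.ndarray
    values: pd.DataFrame

    @property
    def tag(self) -> str:
        return f"{self.group}-{self.size}-r{self.replicate:02d}"

    @property
    def n_presence(self) -> int:
        return len(self.presence)


def _pairwise_conflicts(x, y, min_dist):
    tree = cKDTree(np.column_stack([x, y]))
    pairs = tree.query_pairs(min_dist - 1e-9, output_type="ndarray")
    return pairs


def _thin_once(occ: OccurrenceSet, min_dist: float,
               rng: np.random.Generator) -> np.ndarray:
    """spThin-style thinning: repeatedly delete a random point among those
    with the most remaining conflicts, until no pair is closer than min_dist.
    Returns indices of retained points."""
    n = len(occ)
    alive = np.ones(n, dtype=bool)
    pairs = _pairwise_conflicts(occ.x, occ.y, min_dist)
    if pairs.size == 0:
        return np.arange(n)
    counts = np.bincount(pairs.ravel(), minlength=n)
    pair_alive = np.ones(len(pairs), dtype=bool)
    while counts.max() > 0:
        worst = counts.max()
        cands = np.flatnonzero((counts == worst) & alive)
        victim = rng.choice(cands)
        alive[victim] = False
        counts[victim] = 0
        involved = pair_alive & ((pairs[:, 0] == victim) |
                                 (pairs[:, 1] == victim))
        for a, b in pairs[involved]:
            other = b if a == victim else a
            counts[other] -= 1
        pair_alive &= ~involved
    return np.flatnonzero(alive)


def spatial_thin(occ: OccurrenceSet, min_dist: float = 1500.0,
                 replicates: int = 3, seed: int = 0) -> OccurrenceSet:
    """Spatial rarefaction to a minimum inter-point distance.

    Runs ``replicates`` stochastic thinning passes and returns the one
    retaining the most points (ties resolved by seed order), mirroring the
    select-the-largest-replicate convention.
    """
    if min_dist <= 0:
        raise ValueError("min_dist must be positive")
    if len(occ) == 0:
        return occ
    ss = np.random.SeedSequence(seed).spawn(replicates)
    best: np.ndarray | None = None
    for child in ss:
        kept = _thin_once(occ, min_dist, np.random.default_rng(child))
        if best is None or kept.size > best.size:
            best = kept
    year = None if occ.year is None else occ.year[best]
    return OccurrenceSet(occ.x[best], occ.y[best], occ.cluster[best], year)


def buffered_pseudoabsences(occ: OccurrenceSet, stack: PredictorStack,
                            study_mask: np.ndarray | None = None,
                            inner: float = 1500.0, outer: float = 120_000.0,
                            n: int = 1000, n_sets: int = 10,
                            seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw pseudoabsence sets from the clipped annulus around presences.

    Eligible cells are valid study cells whose distance to the nearest
    occurrence lies in [inner, outer]; presence cells are always excluded.
    Each of the ``n_sets`` sets draws ``n`` distinct cells (without
    replacement within a set, independently across sets).
    """
    if outer <= inner:
        raise ValueError("outer buffer must exceed inner buffer")
    if len(occ) == 0:
        raise ValueError("no occurrences to buffer around")
    mask = stack.mask if study_mask is None else (stack.mask & study_mask)
    if not mask.any():
        raise ValueError("empty study mask")
    r, c = np.nonzero(mask)
    cx = stack.origin[0] + (c + 0.5) * stack.cell_size
    cy = stack.origin[1] + (r + 0.5) * stack.cell_size
    tree = cKDTree(np.column_stack([occ.x, occ.y]))
    d_near, _ = tree.query(np.column_stack([cx, cy]))
    pr, pc = stack.cell_of(occ.x, occ.y)
    presence_cells = set(zip(pr.tolist(), pc.tolist()))
    on_presence = np.fromiter(
        ((ri, ci) in presence_cells for ri, ci in zip(r, c)),
        dtype=bool, count=r.size)
    eligible = (d_near >= inner) & (d_near <= outer) & ~on_presence
    n_eligible = int(eligible.sum())
    if n_eligible < n:
        raise ValueError(
            f"eligible annulus has only {n_eligible} cells, "
            f"{n} pseudoabsences requested (deficit {n - n_eligible})")
    ex, ey = cx[eligible], cy[eligible]
    sets = []
    for child in np.random.SeedSequence(seed).spawn(n_sets):
        rng = np.random.default_rng(child)
        idx = rng.choice(n_eligible, size=n, replace=False)
        sets.append((ex[idx], ey[idx]))
    return sets


def assemble_datasets(cluster_a: OccurrenceSet, cluster_b: OccurrenceSet,
                      stack: PredictorStack,
                      study_mask: np.ndarray | None = None,
                      thin_dist: float = 1500.0, thin_replicates: int = 3,
                      pa_inner: float = 1500.0, pa_outer: float = 120_000.0,
                      pa_n: int = 1000, pa_sets: int = 10,
                      seed: int = 0) -> list[PresPseudoAbsDataset]:
    """Build all presence-pseudoabsence datasets of the factorial design.

    Six presence datasets (A/B/Joint x Full/Thin; Joint-Thin is the union of
    the per-cluster thinned sets) each joined with ``pa_sets`` pseudoabsence
    replicates drawn from its own buffer annulus.
    """
    if len(cluster_a) == 0 or len(cluster_b) == 0:
        raise ValueError("both clusters must contain occurrences")
    ss = np.random.SeedSequence(seed)
    s_thin_a, s_thin_b, *s_pa = ss.spawn(2 + 6)
    thin_a = spatial_thin(cluster_a, thin_dist, thin_replicates, seed=s_thin_a.generate_state(1)[0] % (2**31))
    thin_b = spatial_thin(cluster_b, thin_dist, thin_replicates, seed=s_thin_b.generate_state(1)[0] % (2**31))
    presence_sets = {
        ("A", "Full"): cluster_a,
        ("A", "Thin"): thin_a,
        ("B", "Full"): cluster_b,
        ("B", "Thin"): thin_b,
        ("Joint", "Full"): cluster_a.union(cluster_b),
        ("Joint", "Thin"): thin_a.union(thin_b),
    }
    out: list[PresPseudoAbsDataset] = []
    for k, ((group, size), occ) in enumerate(presence_sets.items()):
        pa = buffered_pseudoabsences(
            occ, stack, study_mask, pa_inner, pa_outer, pa_n, pa_sets,
            seed=s_pa[k].generate_state(1)[0] % (2**31))
        pres_vals = stack.values_at(occ.x, occ.y)
        for rep, (px, py) in enumerate(pa, start=1):
            pa_vals = stack.values_at(px, py)
            values = pd.DataFrame(
                np.vstack([pres_vals, pa_vals]), columns=stack.names)
            values["label"] = np.r_[np.ones(len(occ), dtype=int),
                                    np.zeros(len(px), dtype=int)]
            values["x"] = np.r_[occ.x, px]
            values["y"] = np.r_[occ.y, py]
            out.append(PresPseudoAbsDataset(group, size, rep, occ,
                                            px, py, values))
    return out
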