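"""Conflict-point cleaning, spatial thinning and background-point generation.

Reported conflict locations are spatially clustered (repeat complaints from
the same household, town-level geocoding), so before model fitting they are
thinned to a minimum pairwise distance — 5 km here, the scale of a ~25 km²
black-bear home range. Thinning is the standard randomised greedy scheme:
repeatedly delete a random point among those with the most neighbours closer
than the minimum distance, until no close pair remains; the procedure is run
several times and the run keeping the most points wins.

"Non-conflict" background points are then drawn uniformly over the study
region after subtracting a buffer disc around every retained conflict point
(same radius), at a fixed available:used ratio — 5:1 in the study design.
Buffers are evaluated as exact Euclidean distance tests per candidate point,
not rasterised, so the 50 m grid introduces no artefacts at the buffer edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster import GridRaster, make_points

logger = logging.getLogger(__name__)

__all__ = ["ThinningResult", "BackgroundSpec", "filter_by_mask",
           "spatial_thin", "generate_background"]


@dataclass
class ThinningResult:
    """Outcome of randomised spatial thinning."""

    retained: pd.DataFrame
    removed: pd.DataFrame
    min_distance: float
    n_repetitions: int
    seed: int | None

    @property
    def n_retained(self) -> int:
        return len(self.retained)


@dataclass(frozen=True)
class BackgroundSpec:
    """Background ("non-conflict") sampling design: buffer radius (m) and
    available-per-used ratio."""

    buffer_radius: float = 5000.0
    ratio: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.buffer_radius < 0:
            raise ValueError("buffer_radius must be nonnegative")
        if self.ratio < 1:
            raise ValueError("ratio must be at least 1")


def filter_by_mask(points: pd.DataFrame, mask: GridRaster) -> pd.DataFrame:
    """Keep points whose containing cell is True in ``mask``; log the rest.

    Used to drop obviously mis-reported locations (outside the study region).
    An empty result is allowed but warned about.
    """
    grid = mask.grid
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    row, col = grid.xy_to_rowcol(x, y)
    inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    keep = inside.copy()
    keep[inside] = mask.values.astype(bool)[row[inside], col[inside]]
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("filter_by_mask: excluded %d point(s) outside the mask", n_excluded)
    if not keep.any():
        warnings.warn("filter_by_mask: no points remain inside the mask", stacklevel=2)
    return points.loc[keep].reset_index(drop=True)


def _count_close(xy: np.ndarray, min_distance: float) -> tuple[np.ndarray, list]:
    tree = cKDTree(xy)
    pairs = tree.query_pairs(min_distance, output_type="ndarray")
    # strictly-closer-than pairs only: query_pairs uses <=; drop exact ties at r
    if pairs.size:
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        pairs = pairs[d < min_distance]
    counts = np.zeros(len(xy), dtype=int)
    for a, b in pairs:
        counts[a] += 1
        counts[b] += 1
    return counts, pairs.tolist()


def _thin_once(xy: np.ndarray, min_distance: float,
               rng: np.random.Generator) -> np.ndarray:
    """One randomised greedy elimination pass; returns indices retained."""
    alive = np.ones(len(xy), dtype=bool)
    counts, pairs = _count_close(xy, min_distance)
    pairs = [(a, b) for a, b in pairs]
    while True:
        worst = counts[alive].max() if alive.any() else 0
        if worst == 0:
            break
        candidates = np.flatnonzero(alive & (counts == worst))
        drop = int(rng.choice(candidates))
        alive[drop] = False
        counts[drop] = 0
        for a, b in pairs:
            if a == drop and alive[b]:
                counts[b] -= 1
            elif b == drop and alive[a]:
                counts[a] -= 1
        pairs = [(a, b) for a, b in pairs if a != drop and b != drop]
    return np.flatnonzero(alive)


def spatial_thin(points: pd.DataFrame, min_distance: float,
                 n_repetitions: int = 100, seed: int | None = None) -> ThinningResult:
    """Randomised spatial thinning to a minimum pairwise distance.

    Runs the randomised greedy elimination ``n_repetitions`` times on
    independent RNG substreams and returns the run retaining the most points
    (ties broken by the lowest run index). Every pair of retained points is
    at least ``min_distance`` apart; retained and removed partition the input.
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be positive")
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be at least 1")
    xy = points[["x", "y"]].to_numpy(dtype=float)
    root = np.random.default_rng(seed)
    streams = root.spawn(n_repetitions)
    best_idx: np.ndarray | None = None
    for rep, rng in enumerate(streams):
        idx = _thin_once(xy, min_distance, rng)
        if best_idx is None or len(idx) > len(best_idx):
            best_idx = idx
    keep = np.zeros(len(points), dtype=bool)
    keep[best_idx] = True
    return ThinningResult(
        retained=points.loc[keep].reset_index(drop=True),
        removed=points.loc[~keep].reset_index(drop=True),
        min_distance=float(min_distance),
        n_repetitions=n_repetitions,
        seed=seed,
    )


def generate_background(region_mask: GridRaster, used: pd.DataFrame,
                        spec: BackgroundSpec,
                        max_proposals: int = 1_000_000) -> pd.DataFrame:
    """Draw ``ratio * n_used`` background points uniformly outside all buffers.

    Candidates are proposed uniformly over the region mask (uniform cell,
    uniform offset within it) and accepted iff their distance to every used
    point is at least ``buffer_radius`` — an exact per-point disc test.
    Raises if the buffers exhaust the eligible area (reporting the sampled
    buffer-coverage fraction) or the proposal cap is hit.
    """
    mask = region_mask.values.astype(bool)
    if not mask.any():
        raise ValueError("empty region mask")
    n_used = len(used)
    if n_used == 0:
        raise ValueError("no used points to anchor the background sample")
    n_target = spec.ratio * n_used
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.nonzero(mask)
    g = region_mask.grid
    tree = cKDTree(used[["x", "y"]].to_numpy(dtype=float))

    xs, ys = [], []
    n_have = n_proposed = n_rejected = 0
    while n_have < n_target:
        batch = min(max(4096, 2 * (n_target - n_have)), 200_000)
        if n_proposed + batch > max_proposals:
            batch = max_proposals - n_proposed
            if batch <= 0:
                frac = n_rejected / max(n_proposed, 1)
                raise RuntimeError(
                    "background sampling exhausted its proposal cap; buffers "
                    f"cover ~{frac:.1%} of the region — eligible area may be empty")
        n_proposed += batch
        k = rng.integers(0, len(rows), size=batch)
        u, v = rng.random(batch), rng.random(batch)
        x = g.origin[0] + (cols[k] + u) * g.cell_size
        y = g.origin[1] - (rows[k] + v) * g.cell_size
        d, _ = tree.query(np.column_stack([x, y]), k=1)
        ok = d >= spec.buffer_radius
        n_rejected += int((~ok).sum())
        xs.append(x[ok])
        ys.append(y[ok])
        n_have += int(ok.sum())
        if n_proposed >= max_proposals and n_have < n_target:
            frac = n_rejected / n_proposed
            raise RuntimeError(
                "background sampling exhausted its proposal cap; buffers "
                f"cover ~{frac:.1%} of the region — eligible area may be empty")
    x = np.concatenate(xs)[:n_target]
    y = np.concatenate(ys)[:n_target]
    return make_points(x, y, np.zeros(n_target, dtype=int))
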