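"""Synthetic landscapes with a known conflict-generating process.

The generator produces everything the downstream analysis consumes — a stack
of spatially autocorrelated continuous covariates, a categorical land-cover
layer, a region mask with a contiguous focal subregion, and "used" (conflict)
points drawn from a known logistic resource-selection probability function —
so the whole pipeline can be exercised against ground truth.

Continuous fields are smoothed Gaussian white noise: a moving-average
(uniform) kernel whose width is the field's *smoothing range* in cells, then
rescaled to the requested mean and standard deviation. Range 1 means no
smoothing (white noise); larger ranges raise the lag-1 spatial
autocorrelation. Land cover is obtained by slicing an independent latent
field at quantile breaks, which keeps classes spatially coherent.

Used points are drawn by rejection sampling: propose a uniform location over
the region mask, accept with probability w(x) — so w is honoured as an
absolute probability, exactly the RSPF reading, not merely a relative weight.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import (BOOLEAN, CATEGORICAL, CONTINUOUS, GridRaster, GridSpec,
                     RasterStack, make_points)
from .rspf import eval_w

__all__ = [
    "CovariateDef", "LandscapeSpec", "TrueModel", "SimulatedStudy",
    "simulate_covariate_field", "simulate_cover", "simulate_landscape",
    "simulate_conflicts", "make_focal_mask", "morans_i",
]


@dataclass(frozen=True)
class CovariateDef:
    """One continuous field: name, smoothing range (cells), target mean and sd."""

    name: str
    smoothing_range: int = 5
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.smoothing_range < 1:
            raise ValueError("smoothing range must be >= 1 cell")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for a synthetic landscape.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions in cells (each at least 8).
    cell_size
        Metres per cell.
    seed
        Base RNG seed; every derived field uses an independent substream.
    covariate_defs
        Continuous covariate definitions.
    n_cover_classes
        Number of land-cover classes (default 8, the reclassified scheme).
    class_breaks
        Strictly increasing quantile levels in (0, 1) cutting the latent
        cover field; defaults to equal shares for ``n_cover_classes``.
    """

    n_rows: int = 64
    n_cols: int = 64
    cell_size: float = 50.0
    seed: int = 0
    covariate_defs: tuple[CovariateDef, ...] = (
        CovariateDef("elevation", 8, 500.0, 150.0),
        CovariateDef("log_pop_density", 4, 1.0, 1.0),
        CovariateDef("dist_urban", 6, 3000.0, 1500.0),
    )
    n_cover_classes: int = 8
    class_breaks: tuple[float, ...] = field(default=())
    cover_name: str = "cover"

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8x8 cells")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.n_cover_classes < 2:
            raise ValueError("need at least 2 cover classes")
        breaks = self.class_breaks or tuple(
            i / self.n_cover_classes for i in range(1, self.n_cover_classes))
        if list(breaks) != sorted(set(breaks)):
            raise ValueError("class_breaks must be strictly increasing")
        object.__setattr__(self, "class_breaks", tuple(breaks))
        if len(self.class_breaks) != self.n_cover_classes - 1:
            raise ValueError("need n_cover_classes - 1 class breaks")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size, (0.0, 0.0))

    def covariate_names(self) -> list[str]:
        return [d.name for d in self.covariate_defs]


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth RSPF coefficients: intercept, continuous slopes and
    per-class cover effects (reference class 0 fixed at 0)."""

    beta0: float
    betas: dict[str, float]  # continuous covariate name -> slope
    cover_effects: dict[int, float] = field(default_factory=dict)  # class -> effect

    def __post_init__(self) -> None:
        vals = [self.beta0, *self.betas.values(), *self.cover_effects.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("true coefficients must be finite")


@dataclass
class SimulatedStudy:
    """A complete synthetic study: covariate stack, truth, masks and used points."""

    spec: LandscapeSpec
    stack: RasterStack
    truth: TrueModel
    region_mask: GridRaster
    focal_mask: GridRaster
    used_points: pd.DataFrame | None = None


def _field_rng(seed: int, name: str) -> np.random.Generator:
    # independent, reproducible substream per (seed, field-name)
    return np.random.default_rng([seed, *name.encode()])


def simulate_covariate_field(spec: LandscapeSpec, name: str,
                             seed: int | None = None) -> GridRaster:
    """Generate one continuous covariate raster from the spec's registry.

    Smoothed white noise: iid N(0,1) draws passed through a uniform
    moving-average kernel of width ``smoothing_range`` (reflect boundary),
    then rescaled to the covariate's mean and sd. Deterministic for a fixed
    (seed, name) pair.
    """
    defs = {d.name: d for d in spec.covariate_defs}
    if name not in defs:
        raise KeyError(f"unknown covariate {name!r}; registered: {sorted(defs)}")
    d = defs[name]
    rng = _field_rng(spec.seed if seed is None else seed, name)
    z = rng.standard_normal((spec.n_rows, spec.n_cols))
    if d.smoothing_range > 1:
        z = ndimage.uniform_filter(z, size=d.smoothing_range, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    vals = d.mean + d.sd * z
    return GridRaster(vals, spec.cell_size, (0.0, 0.0), kind=CONTINUOUS)


def simulate_cover(latent: GridRaster, class_breaks) -> GridRaster:
    """Slice a latent continuous field into ordered cover classes.

    ``class_breaks`` are strictly increasing quantile levels in (0, 1); class
    k occupies the cells between consecutive quantiles, so class shares match
    the break spacing up to ties in the latent field. A constant latent field
    collapses to a single class (with a warning).
    """
    breaks = list(class_breaks)
    if breaks != sorted(set(breaks)):
        raise ValueError("class_breaks must be strictly increasing")
    if any(not 0 < b < 1 for b in breaks):
        raise ValueError("class_breaks are quantile levels in (0, 1)")
    vals = latent.values
    if np.ptp(vals) == 0:
        warnings.warn("constant latent field: cover collapses to a single class",
                      stacklevel=2)
        codes = np.zeros(vals.shape, dtype=int)
    else:
        cuts = np.quantile(vals, breaks)
        codes = np.searchsorted(cuts, vals, side="right")
    return GridRaster(codes, latent.cell_size, latent.origin,
                      nodata=-1, kind=CATEGORICAL)


def simulate_landscape(spec: LandscapeSpec) -> RasterStack:
    """Build the full covariate stack: every continuous field plus land cover."""
    layers = {name: simulate_covariate_field(spec, name)
              for name in spec.covariate_names()}
    latent = simulate_covariate_field(
        LandscapeSpec(spec.n_rows, spec.n_cols, spec.cell_size, spec.seed,
                      covariate_defs=(CovariateDef("_cover_latent", 6),),
                      n_cover_classes=spec.n_cover_classes,
                      class_breaks=spec.class_breaks),
        "_cover_latent")
    layers[spec.cover_name] = simulate_cover(latent, spec.class_breaks)
    return RasterStack(layers)


def _linear_predictor(stack: RasterStack, truth: TrueModel,
                      cover_name: str = "cover") -> np.ndarray:
    eta = np.full(stack.grid.n_rows * stack.grid.n_cols, truth.beta0,
                  dtype=float).reshape(stack.grid.n_rows, stack.grid.n_cols)
    for name, b in truth.betas.items():
        eta += b * stack[name].values
    if truth.cover_effects:
        codes = stack[cover_name].values
        for code, eff in truth.cover_effects.items():
            eta += np.where(codes == code, eff, 0.0)
    return eta


def true_probability_surface(stack: RasterStack, truth: TrueModel,
                             cover_name: str = "cover") -> GridRaster:
    """Cell-wise true conflict probability w(x) under the generating model."""
    eta = _linear_predictor(stack, truth, cover_name)
    w = eval_w(np.array([0.0, 1.0]), np.column_stack([np.ones(eta.size), eta.ravel()]))
    g = stack.grid
    return GridRaster(w.reshape(eta.shape), g.cell_size, g.origin, kind=CONTINUOUS)


def simulate_conflicts(study: SimulatedStudy, n_used: int,
                       seed: int | None = None,
                       max_proposals: int = 10_000_000,
                       return_stats: bool = False):
    """Draw conflict ("used") points from the true RSPF by rejection sampling.

    Proposals are uniform over the region mask (uniform cell, uniform offset
    within the cell); each is accepted with probability w(x) of its cell.
    Returns exactly ``n_used`` labelled points with covariates extracted from
    the stack; with ``return_stats`` also a dict with the proposal count and
    empirical acceptance rate (which converges to the spatial mean of w over
    the mask).
    """
    if n_used <= 0:
        raise ValueError("n_used must be positive")
    mask = study.region_mask.values.astype(bool)
    if not mask.any():
        raise ValueError("empty region mask")
    w = true_probability_surface(study.stack, study.truth, study.spec.cover_name).values
    w_masked = np.where(mask, w, 0.0)
    if w_masked.max() <= 0:
        raise ValueError("w(x) vanishes everywhere on the mask: nothing to accept")
    rng = np.random.default_rng(study.spec.seed if seed is None else seed)
    rows, cols = np.nonzero(mask)
    g = study.stack.grid
    xs_out, ys_out = [], []
    n_have, n_proposed = 0, 0
    while n_have < n_used:
        batch = max(1024, int(1.5 * (n_used - n_have) / max(w_masked.mean(), 1e-6)))
        batch = min(batch, 1_000_000)
        n_proposed += batch
        if n_proposed > max_proposals:
            raise RuntimeError("rejection sampler exceeded the proposal cap")
        k = rng.integers(0, len(rows), size=batch)
        accept = rng.random(batch) < w[rows[k], cols[k]]
        k = k[accept]
        u, v = rng.random(k.size), rng.random(k.size)
        xs_out.append(g.origin[0] + (cols[k] + u) * g.cell_size)
        ys_out.append(g.origin[1] - (rows[k] + v) * g.cell_size)
        n_have += k.size
    x = np.concatenate(xs_out)[:n_used]
    y = np.concatenate(ys_out)[:n_used]
    pts = make_points(x, y, np.ones(n_used, dtype=int))
    from .raster import extract_values
    out = extract_values(study.stack, pts)
    if return_stats:
        return out, {"n_proposed": n_proposed, "n_accepted": n_have,
                     "acceptance_rate": n_have / n_proposed}
    return out


def make_focal_mask(region_mask: GridRaster, fraction: float,
                    seed_cell: tuple[int, int] | None = None) -> GridRaster:
    """Carve a contiguous focal subregion holding ≈ ``fraction`` of region cells.

    Breadth-first growth over 4-neighbour adjacency from a seed cell (default:
    the region cell nearest the region's centroid), stopping once the target
    cell count is reached. The result is always a subset of the region mask.
    """
    if not 0 < fraction < 1:
        if fraction == 1.0:
            return GridRaster(region_mask.values.astype(bool).copy(),
                              region_mask.cell_size, region_mask.origin, kind=BOOLEAN)
        raise ValueError("fraction must lie in (0, 1]")
    mask = region_mask.values.astype(bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty region mask")
    target = max(1, int(round(fraction * rows.size)))
    if seed_cell is None:
        cr, cc = rows.mean(), cols.mean()
        start = int(np.argmin((rows - cr) ** 2 + (cols - cc) ** 2))
        seed_cell = (int(rows[start]), int(cols[start]))
    focal = np.zeros_like(mask)
    seen = np.zeros_like(mask)
    q = deque([seed_cell])
    seen[seed_cell] = True
    count = 0
    while q and count < target:
        i, j = q.popleft()
        focal[i, j] = True
        count += 1
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                    and mask[ni, nj] and not seen[ni, nj]):
                seen[ni, nj] = True
                q.append((ni, nj))
    return GridRaster(focal, region_mask.cell_size, region_mask.origin, kind=BOOLEAN)


def morans_i(values: np.ndarray) -> float:
    """Lag-1 Moran's I on a grid (rook adjacency) — the autocorrelation
    diagnostic used to verify the smoothing ranges."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    num = (z[:-1, :] * z[1:, :]).sum() + (z[:, :-1] * z[:, 1:]).sum()
    n_pairs = z[:-1, :].size + z[:, :-1].size
    denom = (z ** 2).sum() / z.size
    if denom == 0:
        return 0.0
    return (num / n_pairs) / denom


def full_synthetic_study(spec: LandscapeSpec, truth: TrueModel,
                         n_used: int | None = None,
                         focal_fraction: float = 0.25) -> SimulatedStudy:
    """Convenience constructor: stack + full region mask + focal mask (+ points)."""
    stack = simulate_landscape(spec)
    region = GridRaster(np.ones((spec.n_rows, spec.n_cols), dtype=bool),
                        spec.cell_size, (0.0, 0.0), kind=BOOLEAN)
    focal = make_focal_mask(region, focal_fraction)
    study = SimulatedStudy(spec, stack, truth, region, focal)
    if n_used:
        study.used_points = simulate_conflicts(study, n_used)
    return study
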