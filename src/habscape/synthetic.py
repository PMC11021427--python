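"""Seeded neutral-landscape generator.

Produces everything the analysis consumes in place of classified
satellite imagery: clumped seven-class land-cover maps, binary threat
layers (agriculture, grazing, urban/rural settlement, mines, roads),
temporally evolving map pairs driven by a transition matrix, and NDVI
surfaces whose class-conditional distributions straddle the rangeland
condition thresholds.

Mechanism for land cover: a seeded white-noise field is smoothed with a
Gaussian kernel whose width is the ``clumping`` parameter, then classes
are assigned by rank (quantile slices), which matches the target class
proportions to within one cell.  ``clumping = 0`` gives spatially
independent cells; larger values give larger patches.  An optional
second clumping value turns the field into a west-to-east fragmentation
gradient, used by the pattern-vs-quality experiments.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .raster import (
    DEFAULT_LEGEND,
    RANGELAND_CODES,
    CategoricalRaster,
    ContinuousRaster,
    GridTransform,
    Legend,
)

__all__ = [
    "SyntheticConfig",
    "THREAT_NAMES",
    "generate_landcover",
    "generate_threat_layers",
    "evolve_landcover",
    "generate_ndvi",
]

#: The seven threat factors, in canonical order.
THREAT_NAMES = (
    "Agriculture land",
    "Livestock grazing",
    "Urban land",
    "Rural land",
    "Mining land",
    "Main roads",
    "Minor roads",
)

_BINARY_LEGEND = Legend([(0, "absent"), (1, "present")])

# Default class proportions loosely mirroring the study region at the
# first date: habitat classes (forest + rangelands) cover ~82% of the
# area, the rest is water, agriculture and built-up.
_DEFAULT_PROPORTIONS: dict[int, float] = {
    1: 0.14,  # Zagros forest
    2: 0.28,  # Rangeland/good
    3: 0.22,  # Rangeland/fair
    4: 0.18,  # Rangeland/poor
    5: 0.02,  # Water bodies
    6: 0.12,  # Agriculture
    7: 0.04,  # Build up area
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic landscape.

    ``cell_size`` defaults to 30 m (the Landsat pixel).  ``clumping`` is
    the Gaussian smoothing sigma in cells; ``clumping_east`` (optional)
    makes clumping vary linearly from ``clumping`` at the west edge to
    ``clumping_east`` at the east edge, producing a fragmentation
    gradient.
    """

    n_rows: int = 128
    n_cols: int = 128
    cell_size: float = 30.0
    class_proportions: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    clumping: float = 3.0
    clumping_east: float | None = None
    n_main_roads: int = 2
    n_minor_roads: int = 4
    n_mines: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid dimensions must be at least 8")
        props = dict(self.class_proportions)
        if any(p < 0 for p in props.values()):
            raise ValueError("class proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.clumping < 0:
            raise ValueError("clumping must be non-negative")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(0.0, self.n_rows * self.cell_size, self.cell_size)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else x - x.mean()


def _clumped_field(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal((config.n_rows, config.n_cols))
    if config.clumping_east is None:
        if config.clumping == 0:
            return noise
        return ndimage.gaussian_filter(noise, sigma=config.clumping)
    west = noise if config.clumping == 0 else ndimage.gaussian_filter(
        noise, sigma=config.clumping
    )
    east = noise if config.clumping_east == 0 else ndimage.gaussian_filter(
        noise, sigma=config.clumping_east
    )
    w = np.linspace(1.0, 0.0, config.n_cols)[None, :]
    return w * _zscore(west) + (1.0 - w) * _zscore(east)


def generate_landcover(config: SyntheticConfig) -> CategoricalRaster:
    """Clumped categorical landscape with the configured class mix.

    Classes are assigned by rank of the smoothed noise field, so achieved
    proportions match the targets to within one cell per class.
    """
    rng = _rng(config.seed, 0)
    fld = _clumped_field(config, rng)
    n = fld.size
    order = np.argsort(fld, axis=None, kind="stable")
    codes = sorted(config.class_proportions)
    targets = np.array([config.class_proportions[c] for c in codes])
    # cumulative cell counts per class; last class absorbs rounding
    bounds = np.rint(np.cumsum(targets) * n).astype(np.int64)
    bounds[-1] = n
    flat = np.empty(n, dtype=np.int64)
    start = 0
    for code, stop in zip(codes, bounds):
        flat[order[start:stop]] = code
        start = stop
    legend = Legend([(c, DEFAULT_LEGEND.name(c)) for c in codes]) if all(
        c in DEFAULT_LEGEND for c in codes
    ) else Legend([(c, f"class {c}") for c in codes])
    return CategoricalRaster(
        flat.reshape(fld.shape), legend, nodata=0, transform=config.transform
    )


# ---------------------------------------------------------------------------
# Threat layers


def _binary(mask: np.ndarray, template: CategoricalRaster) -> CategoricalRaster:
    return CategoricalRaster(
        mask.astype(np.int64),
        _BINARY_LEGEND,
        nodata=-1,
        transform=template.transform,
    )


def _draw_line(grid: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> None:
    """Rasterize a 1-cell-wide line segment (Bresenham walk)."""
    n = max(abs(r1 - r0), abs(c1 - c0)) + 1
    rows = np.rint(np.linspace(r0, r1, n)).astype(int)
    cols = np.rint(np.linspace(c0, c1, n)).astype(int)
    grid[rows, cols] = 1


def _random_boundary_point(rng: np.random.Generator, nr: int, nc: int) -> tuple[int, int]:
    side = rng.integers(4)
    if side == 0:
        return 0, int(rng.integers(nc))
    if side == 1:
        return nr - 1, int(rng.integers(nc))
    if side == 2:
        return int(rng.integers(nr)), 0
    return int(rng.integers(nr)), nc - 1


def generate_threat_layers(
    landcover: CategoricalRaster, config: SyntheticConfig
) -> dict[str, CategoricalRaster]:
    """Binary presence layer for each of the seven threat factors.

    Agriculture and grazing threats are the agriculture and rangeland
    cells themselves.  Built-up cells are partitioned into urban (the
    largest 8-connected component) and rural (the remainder).  Mines are
    seeded random point cells outside water; roads are seeded random
    polylines between boundary points, one cell wide.
    """
    lc = landcover.values
    nr, nc = lc.shape
    layers: dict[str, CategoricalRaster] = {}

    layers["Agriculture land"] = _binary(lc == 6, landcover)
    layers["Livestock grazing"] = _binary(np.isin(lc, RANGELAND_CODES), landcover)

    built = lc == 7
    urban = np.zeros_like(built)
    rural = np.zeros_like(built)
    if built.any():
        labels, n_comp = ndimage.label(built, structure=np.ones((3, 3)))
        sizes = ndimage.sum_labels(built, labels, index=np.arange(1, n_comp + 1))
        largest = int(np.argmax(sizes)) + 1
        urban = labels == largest
        rural = built & ~urban
    layers["Urban land"] = _binary(urban, landcover)
    layers["Rural land"] = _binary(rural, landcover)

    rng = _rng(config.seed, 1)
    mines = np.zeros((nr, nc), dtype=bool)
    candidates = np.flatnonzero(lc != 5)
    if config.n_mines > 0 and candidates.size:
        picks = rng.choice(candidates, size=min(config.n_mines, candidates.size),
                           replace=False)
        mines.flat[picks] = True
    layers["Mining land"] = _binary(mines, landcover)

    for key, count, stage in (("Main roads", config.n_main_roads, 2),
                              ("Minor roads", config.n_minor_roads, 3)):
        rng = _rng(config.seed, stage)
        grid = np.zeros((nr, nc), dtype=np.int64)
        for _ in range(count):
            r0, c0 = _random_boundary_point(rng, nr, nc)
            r1, c1 = _random_boundary_point(rng, nr, nc)
            _draw_line(grid, r0, c0, r1, c1)
        layers[key] = _binary(grid > 0, landcover)

    return layers


# ---------------------------------------------------------------------------
# Temporal evolution


def evolve_landcover(
    landcover: CategoricalRaster,
    tm,
    clumping_bias: float = 0.0,
    seed: int = 0,
) -> CategoricalRaster:
    """One stochastic transition step of every cell under a row-stochastic
    matrix, with optional contagious growth.

    With ``clumping_bias > 0`` the probability of moving into class ``c``
    is multiplied by ``1 + clumping_bias * f_c`` where ``f_c`` is the
    fraction of the cell's 8 neighbors already in ``c``, then the row is
    renormalized, so conversions aggregate around existing patches.
    """
    from .change import TransitionMatrix  # local import to avoid a cycle

    if isinstance(tm, TransitionMatrix):
        codes, probs = tm.legend.codes, tm.probs
    else:
        codes, probs = list(tm[0]), np.asarray(tm[1], dtype=float)
    lc = landcover.values
    present = set(int(c) for c in np.unique(lc[landcover.valid_mask]))
    if not present.issubset(codes):
        raise ValueError("transition matrix legend does not cover the raster")
    index = {c: i for i, c in enumerate(codes)}
    k = len(codes)

    idx = np.full(lc.shape, -1, dtype=np.int64)
    for c, i in index.items():
        idx[lc == c] = i
    valid = landcover.valid_mask

    p = probs[np.clip(idx, 0, k - 1)]  # (nr, nc, k)
    if clumping_bias > 0:
        kernel = np.ones((3, 3))
        kernel[1, 1] = 0
        frac = np.empty(p.shape)
        for i, c in enumerate(codes):
            neigh = ndimage.convolve(
                (lc == c).astype(float), kernel, mode="constant", cval=0.0
            )
            denom = ndimage.convolve(
                valid.astype(float), kernel, mode="constant", cval=0.0
            )
            frac[..., i] = np.divide(
                neigh, denom, out=np.zeros_like(neigh), where=denom > 0
            )
        p = p * (1.0 + clumping_bias * frac)
        p /= p.sum(axis=-1, keepdims=True)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10]))
    u = rng.random(lc.shape)
    cdf = np.cumsum(p, axis=-1)
    choice = (u[..., None] < cdf).argmax(axis=-1)
    out = np.array(codes, dtype=np.int64)[choice]
    out[~valid] = landcover.nodata
    return CategoricalRaster(
        out, landcover.legend, nodata=landcover.nodata, transform=landcover.transform
    )


# ---------------------------------------------------------------------------
# NDVI


# Class-conditional NDVI: mean (and truncation interval) per rangeland
# condition class, sd 0.01, chosen so thresholding recovers the
# generating class.
_NDVI_PARAMS = {
    2: (0.22, 0.1700001, 0.35),  # Rangeland/good -> "good" is open above 0.17
    3: (0.145, 0.12, 0.17),      # Rangeland/fair -> fair is [0.12, 0.17]
    4: (0.06, 0.01, 0.1199999),  # Rangeland/poor -> poor is [0.01, 0.12)
}
_NDVI_SD = 0.01


def generate_ndvi(landcover: CategoricalRaster, seed: int = 0) -> ContinuousRaster:
    """NDVI surface over rangeland cells: truncated Gaussians per
    condition class (good 0.22, fair 0.145, poor 0.06; sd 0.01), NaN
    elsewhere."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 20]))
    out = np.full(landcover.shape, np.nan)
    for code, (mean, lo, hi) in _NDVI_PARAMS.items():
        mask = landcover.values == code
        n = int(mask.sum())
        if n == 0:
            continue
        a, b = (lo - mean) / _NDVI_SD, (hi - mean) / _NDVI_SD
        out[mask] = truncnorm.rvs(a, b, loc=mean, scale=_NDVI_SD, size=n,
                                  random_state=rng)
    return ContinuousRaster(out, transform=landcover.transform)
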