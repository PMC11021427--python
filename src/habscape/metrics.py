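"""Landscape-level pattern metrics: NP, PD, SHDI, CONTAG.

Conventions follow the FRAGSTATS defaults: patches are 8-connected
same-class components; contagion adjacencies are 4-connected cell pairs,
double-counted (each pair once in each direction), with pairs touching
nodata excluded.  PD is patches per 100 ha.  CONTAG is undefined on a
single-class landscape and is reported as NaN there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import CategoricalRaster

__all__ = [
    "AdjacencyTable",
    "MetricsRecord",
    "label_patches",
    "patch_density",
    "shdi",
    "adjacency",
    "contag",
    "metrics_report",
]

_STRUCT_8 = np.ones((3, 3), dtype=int)
_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class AdjacencyTable:
    """Counts of 4-neighbor cell adjacencies between classes, double-
    counted (symmetric)."""

    counts: np.ndarray
    codes: list[int]

    def row_fractions(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(sums > 0, self.counts / sums, 0.0)
        return frac


@dataclass
class MetricsRecord:
    """Landscape-level metric bundle for one raster or analysis unit."""

    np_: int
    pd_: float
    shdi: float
    contag: float  # NaN when undefined (single-class landscape)

    def as_dict(self) -> dict[str, float]:
        return {"NP": self.np_, "PD": self.pd_, "SHDI": self.shdi,
                "CONTAG": self.contag}


def label_patches(
    landcover: CategoricalRaster, connectivity: int = 8
) -> tuple[np.ndarray, int]:
    """Label same-class connected components across all classes.

    Returns (patch-id raster, NP).  Ids are positive, 0 marks nodata;
    nodata splits patches.
    """
    valid = landcover.valid_mask
    if not valid.any():
        raise ValueError("all-nodata raster has no patches")
    struct = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    out = np.zeros(landcover.shape, dtype=np.int64)
    next_id = 1
    for code in np.unique(landcover.values[valid]):
        labels, n = ndimage.label(landcover.values == code, structure=struct)
        out[labels > 0] = labels[labels > 0] + (next_id - 1)
        next_id += n
    return out, next_id - 1


def patch_density(landcover: CategoricalRaster, connectivity: int = 8) -> float:
    """Patches per 100 ha of valid landscape area."""
    _, n_patches = label_patches(landcover, connectivity)
    area_m2 = landcover.valid_mask.sum() * landcover.cell_size**2
    if area_m2 == 0:
        raise ValueError("zero valid area")
    return n_patches / area_m2 * 10_000.0 * 100.0


def shdi(landcover: CategoricalRaster) -> float:
    """Shannon's diversity index over valid-cell class proportions,
    -sum p_i ln p_i (nats)."""
    props = np.array(list(landcover.composition().values()))
    if props.size == 0:
        raise ValueError("no valid cells")
    props = props[props > 0]
    return float(-(props * np.log(props)).sum())


def adjacency(landcover: CategoricalRaster) -> AdjacencyTable:
    """4-neighbor cell-pair adjacency counts, each unordered pair counted
    once in each direction; pairs touching nodata excluded."""
    vals = landcover.values
    valid = landcover.valid_mask
    codes = [int(c) for c in np.unique(vals[valid])]
    index = {c: i for i, c in enumerate(codes)}
    m = len(codes)
    g = np.zeros((m, m), dtype=np.int64)
    pairs = []
    pairs.append((vals[:-1, :], vals[1:, :], valid[:-1, :] & valid[1:, :]))
    pairs.append((vals[:, :-1], vals[:, 1:], valid[:, :-1] & valid[:, 1:]))
    for a, b, ok in pairs:
        ai = np.vectorize(index.__getitem__, otypes=[np.int64])(a[ok]) if ok.any() else []
        bi = np.vectorize(index.__getitem__, otypes=[np.int64])(b[ok]) if ok.any() else []
        if ok.any():
            np.add.at(g, (ai, bi), 1)
            np.add.at(g, (bi, ai), 1)  # double-count: both directions
    return AdjacencyTable(g, codes)


def contag(landcover: CategoricalRaster) -> float:
    """FRAGSTATS landscape contagion, percent in [0, 100].

    CONTAG = 100 * [1 + sum_ik p_ik ln p_ik / (2 ln m)] with
    p_ik = P_i * g_ik / sum_k g_ik over the m classes present.  High
    values mean an aggregated, well-connected landscape.  NaN when fewer
    than two classes are present.
    """
    comp = landcover.composition()
    if len(comp) < 2:
        return float("nan")
    adj = adjacency(landcover)
    P = np.array([comp[c] for c in adj.codes])
    p_ik = P[:, None] * adj.row_fractions()
    nz = p_ik > 0
    entropy = float((p_ik[nz] * np.log(p_ik[nz])).sum())
    m = len(adj.codes)
    value = 100.0 * (1.0 + entropy / (2.0 * np.log(m)))
    return float(np.clip(value, 0.0, 100.0))


def metrics_report(
    landcover: CategoricalRaster, connectivity: int = 8
) -> MetricsRecord:
    """NP, PD, SHDI and CONTAG for one landscape."""
    _, n_patches = label_patches(landcover, connectivity)
    return MetricsRecord(
        np_=n_patches,
        pd_=patch_density(landcover, connectivity),
        shdi=shdi(landcover),
        contag=contag(landcover),
    )
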