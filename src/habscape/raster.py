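"""Raster data model, GeoTIFF I/O and map-comparison statistics.

The package works on small, single-band, north-up rasters with square
pixels.  Categorical rasters carry an integer class legend (the default
legend is the seven-class land-cover scheme used throughout: Zagros
forest, three rangeland condition classes, water bodies, agriculture and
built-up area).  Continuous rasters use NaN as the nodata sentinel.

GeoTIFFs are written with :mod:`tifffile`, including the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA) so the
files open in GDAL-based tools; the legend travels in the
ImageDescription tag as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from scipy import stats as sstats

__all__ = [
    "GridTransform",
    "Legend",
    "DEFAULT_LEGEND",
    "NDVI_LEGEND",
    "CategoricalRaster",
    "ContinuousRaster",
    "ContingencyTable",
    "read_raster",
    "write_raster",
    "crosstab",
    "overall_accuracy",
    "kappa",
    "cramers_v",
    "classify_ndvi",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridTransform:
    """North-up affine georeference: x increases with column, y decreases
    with row.  ``(x0, y0)`` is the outer corner of the top-left pixel."""

    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 30.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        cs = self.cell_size
        return (self.x0 + (col + 0.5) * cs, self.y0 - (row + 0.5) * cs)


class Legend:
    """Ordered mapping of integer class codes to class names."""

    def __init__(self, entries: Sequence[tuple[int, str]]):
        codes = [int(c) for c, _ in entries]
        if len(set(codes)) != len(codes):
            raise ValueError("legend codes must be unique")
        self._entries: tuple[tuple[int, str], ...] = tuple(
            (int(c), str(n)) for c, n in entries
        )
        self._by_code = dict(self._entries)

    @property
    def codes(self) -> list[int]:
        return [c for c, _ in self._entries]

    @property
    def names(self) -> list[str]:
        return [n for _, n in self._entries]

    def name(self, code: int) -> str:
        return self._by_code[code]

    def code(self, name: str) -> int:
        for c, n in self._entries:
            if n == name:
                return c
        raise KeyError(name)

    def __contains__(self, code: int) -> bool:
        return code in self._by_code

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, Legend) and self._entries == other._entries

    def __repr__(self) -> str:
        return f"Legend({list(self._entries)!r})"

    def to_json(self) -> str:
        return json.dumps({"legend": [[c, n] for c, n in self._entries]})

    @classmethod
    def from_json(cls, text: str) -> "Legend":
        payload = json.loads(text)
        return cls([(int(c), n) for c, n in payload["legend"]])


#: Seven-class land-cover scheme (forest / rangeland condition classes /
#: water / agriculture / built-up) used by the synthetic generator and the
#: shipped habitat-sensitivity table.
DEFAULT_LEGEND = Legend(
    [
        (1, "Zagros forest"),
        (2, "Rangeland/good"),
        (3, "Rangeland/fair"),
        (4, "Rangeland/poor"),
        (5, "Water bodies"),
        (6, "Agriculture"),
        (7, "Build up area"),
    ]
)

#: Rangeland-condition legend produced by NDVI thresholding.
NDVI_LEGEND = Legend(
    [
        (1, "Non-rangeland"),
        (2, "Rangeland/poor"),
        (3, "Rangeland/fair"),
        (4, "Rangeland/good"),
    ]
)

#: Codes of the three rangeland condition classes in DEFAULT_LEGEND.
RANGELAND_CODES = (2, 3, 4)


@dataclass
class CategoricalRaster:
    """Integer-coded 2-D land-cover grid with nodata and a legend."""

    values: np.ndarray
    legend: Legend
    nodata: int = 0
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("raster grid must be 2-D and non-empty")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("categorical raster values must be integers")
        present = np.unique(self.values[self.values != self.nodata])
        missing = [int(c) for c in present if int(c) not in self.legend]
        if missing:
            raise ValueError(f"codes {missing} missing from legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_size(self) -> float:
        return self.transform.cell_size

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 10_000.0

    def aligned_with(self, other: "CategoricalRaster | ContinuousRaster") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
        )

    def class_counts(self) -> dict[int, int]:
        vals = self.values[self.valid_mask]
        codes, counts = np.unique(vals, return_counts=True)
        return {int(c): int(n) for c, n in zip(codes, counts)}

    def composition(self) -> dict[int, float]:
        counts = self.class_counts()
        total = sum(counts.values())
        return {c: n / total for c, n in counts.items()}


@dataclass
class ContinuousRaster:
    """2-D real-valued grid; NaN marks nodata."""

    values: np.ndarray
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("raster grid must be 2-D and non-empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_size(self) -> float:
        return self.transform.cell_size

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def aligned_with(self, other) -> bool:
        return self.shape == other.shape and self.transform == other.transform


def _require_aligned(a, b) -> None:
    if not a.aligned_with(b):
        raise ValueError(
            f"rasters are not aligned: {a.shape}/{a.transform} vs "
            f"{b.shape}/{b.transform}"
        )


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def write_raster(raster: CategoricalRaster | ContinuousRaster, path) -> None:
    """Write a single-band GeoTIFF with georeferencing tags."""
    path = Path(path)
    t = raster.transform
    meta: dict = {"kind": "continuous"}
    if isinstance(raster, CategoricalRaster):
        meta = {
            "kind": "categorical",
            "nodata": int(raster.nodata),
            "legend": [[c, n] for c, n in raster.legend],
        }
        data = raster.values.astype(np.int32)
        nodata_str = str(int(raster.nodata))
    else:
        data = raster.values.astype(np.float32)
        nodata_str = "nan"
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (t.cell_size, t.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_str),
    ]
    tifffile.imwrite(
        path, data, description=json.dumps(meta), extratags=extratags
    )


def read_raster(path) -> CategoricalRaster | ContinuousRaster:
    """Read a single-band GeoTIFF written by :func:`write_raster`.

    Categorical rasters (integer pixel type) come back with their legend
    and nodata code; float rasters come back as :class:`ContinuousRaster`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path} is not single-band (pages={len(tif.pages)})")
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(f"{path} is not single-band (shape={data.shape})")
        cell_size, x0, y0 = 1.0, 0.0, 0.0
        tag = page.tags.get(_TAG_PIXEL_SCALE)
        if tag is not None:
            cell_size = float(tag.value[0])
        tag = page.tags.get(_TAG_TIEPOINT)
        if tag is not None:
            x0, y0 = float(tag.value[3]), float(tag.value[4])
        transform = GridTransform(x0, y0, cell_size)
        meta = {}
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    if meta.get("kind") == "categorical" or np.issubdtype(data.dtype, np.integer):
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(f"{path}: categorical raster has non-integer values")
        nodata = int(meta.get("nodata", 0))
        if "legend" in meta:
            legend = Legend([(int(c), n) for c, n in meta["legend"]])
        else:
            codes = np.unique(data[data != nodata])
            legend = Legend([(int(c), f"class {int(c)}") for c in codes])
        return CategoricalRaster(
            data.astype(np.int64), legend, nodata=nodata, transform=transform
        )
    return ContinuousRaster(data.astype(np.float64), transform=transform)


# ---------------------------------------------------------------------------
# Contingency tables and agreement / association statistics


@dataclass
class ContingencyTable:
    """R x C cross-tabulation of two categorical maps or samples."""

    counts: np.ndarray
    row_labels: list[int]
    col_labels: list[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match counts shape")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def is_square(self) -> bool:
        return self.row_labels == self.col_labels

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.counts, index=self.row_labels, columns=self.col_labels
        ).to_csv(path, index_label="class")

    @classmethod
    def from_csv(cls, path) -> "ContingencyTable":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(
            df.to_numpy(dtype=np.int64),
            [int(i) for i in df.index],
            [int(c) for c in df.columns],
        )


def crosstab(a: CategoricalRaster, b: CategoricalRaster) -> ContingencyTable:
    """Cross-tabulate two aligned categorical rasters over jointly valid
    cells.  Labels are the union of both legends' codes, in legend order."""
    _require_aligned(a, b)
    joint = a.valid_mask & b.valid_mask
    labels = list(dict.fromkeys(a.legend.codes + b.legend.codes))
    index = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    av = a.values[joint]
    bv = b.values[joint]
    ai = np.vectorize(index.__getitem__, otypes=[np.int64])(av) if av.size else av
    bi = np.vectorize(index.__getitem__, otypes=[np.int64])(bv) if bv.size else bv
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (ai, bi), 1)
    return ContingencyTable(counts, labels, labels)


def overall_accuracy(t: ContingencyTable) -> float:
    """Fraction of correctly classified cells: trace / total."""
    if t.counts.shape[0] != t.counts.shape[1]:
        raise ValueError("overall accuracy requires a square table")
    if t.total == 0:
        raise ValueError("empty contingency table")
    return float(np.trace(t.counts)) / t.total


def kappa(t: ContingencyTable) -> float:
    """Cohen's kappa: chance-corrected agreement (P0 - Pe) / (1 - Pe)."""
    if t.counts.shape[0] != t.counts.shape[1]:
        raise ValueError("kappa requires a square table")
    n = t.total
    if n < 1:
        raise ValueError("empty contingency table")
    p0 = float(np.trace(t.counts)) / n
    pe = float(t.counts.sum(axis=1) @ t.counts.sum(axis=0)) / n**2
    if pe >= 1.0:
        raise ZeroDivisionError(
            "kappa undefined: chance agreement is 1 (single-category table)"
        )
    return (p0 - pe) / (1.0 - pe)


def cramers_v(t: ContingencyTable) -> float:
    """Cramer's V: sqrt(chi2 / (n * (min(R, C) - 1))), no continuity
    correction.  Zero rows/columns are dropped before the chi-square."""
    counts = t.counts
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    r, c = counts.shape
    if r < 2 or c < 2:
        raise ValueError("Cramer's V needs at least 2 non-empty rows and columns")
    n = counts.sum()
    chi2 = sstats.chi2_contingency(counts, correction=False).statistic
    v2 = chi2 / (n * (min(r, c) - 1))
    return float(np.sqrt(max(v2, 0.0)))


# NDVI condition thresholds for rangeland: good above 0.17, fair within
# 0.12-0.17, poor within 0.01-0.12.  Boundary convention: lower bound
# inclusive, upper bound exclusive, except "good" which is open above.
NDVI_POOR_FLOOR = 0.01
NDVI_FAIR_FLOOR = 0.12
NDVI_GOOD_FLOOR = 0.17


def classify_ndvi(ndvi: ContinuousRaster) -> CategoricalRaster:
    """Threshold an NDVI surface into rangeland condition classes.

    good: NDVI > 0.17; fair: 0.12 <= NDVI <= 0.17; poor: 0.01 <= NDVI
    < 0.12; below 0.01 is non-rangeland.  NaN cells become nodata.
    """
    v = ndvi.values
    out = np.zeros(v.shape, dtype=np.int64)
    finite = np.isfinite(v)
    out[finite & (v < NDVI_POOR_FLOOR)] = NDVI_LEGEND.code("Non-rangeland")
    out[finite & (v >= NDVI_POOR_FLOOR) & (v < NDVI_FAIR_FLOOR)] = NDVI_LEGEND.code(
        "Rangeland/poor"
    )
    out[finite & (v >= NDVI_FAIR_FLOOR) & (v <= NDVI_GOOD_FLOOR)] = NDVI_LEGEND.code(
        "Rangeland/fair"
    )
    out[finite & (v > NDVI_GOOD_FLOOR)] = NDVI_LEGEND.code("Rangeland/good")
    return CategoricalRaster(out, NDVI_LEGEND, nodata=0, transform=ndvi.transform)
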