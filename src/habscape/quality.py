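"""Habitat-quality model (InVEST-style degradation / half-saturation).

Each land-cover class j carries a habitat suitability H_j in [0, 1]
(0 = non-habitat) and a sensitivity S_jr in [0, 1] to each threat r.
A threat r is a binary presence raster with a maximum effective distance
d_rmax, an impact weight w_r and a decay kind.  The total degradation at
cell x with class j is the weight-normalized, sensitivity-scaled sum of
decayed threat influence,

    D_xj = sum_r sum_y (w_r / sum_r w_r) * r_y * i_rxy * beta_x * S_jr,

with the decay kernel either linear, i = 1 - d/d_rmax, or exponential,
i = exp(-2.99 d / d_rmax), both cut to 0 beyond d_rmax (the distance is
called "maximum effective" for a reason; the exponential alone never
reaches zero).  Quality follows the half-saturation transform

    Q_xj = H_j * (1 - D^z / (D^z + K^z)),

so Q = H_j where degradation is zero and Q = H_j / 2 where D equals the
half-saturation constant K.  The exponent z defaults to 2.5 and K, if
left on "auto", resolves to half the maximum degradation observed —
both conventional choices, both exposed as parameters.

Threats outside the raster do not exist: no padding is applied, so
degradation near the border is underestimated, mirroring the clipped-
watershed caveat of regional applications.

The inner sum is evaluated by FFT convolution of each binary threat
raster with its decay kernel; this is algebraically identical to the
literal double sum and is verified against a brute-force implementation
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .raster import CategoricalRaster, ContinuousRaster, Legend

__all__ = [
    "ThreatSpec",
    "SensitivityTable",
    "HQParams",
    "QualityRaster",
    "HQ_LEVELS",
    "load_threat_specs",
    "load_sensitivity",
    "decay_factor",
    "decay_kernel",
    "degradation",
    "resolve_half_saturation",
    "quality",
    "classify_hq",
    "mean_hq",
]

_EXP_DECAY_CONSTANT = 2.99


@dataclass(frozen=True)
class ThreatSpec:
    """One threat factor: maximum effective distance (km), impact weight
    and decay kind ('linear' or 'exponential')."""

    name: str
    max_dist_km: float
    weight: float
    decay: str

    def __post_init__(self) -> None:
        if self.max_dist_km <= 0:
            raise ValueError("max_dist_km must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if self.decay not in ("linear", "exponential"):
            raise ValueError(f"unknown decay kind {self.decay!r}")

    @property
    def max_dist_m(self) -> float:
        return self.max_dist_km * 1000.0


class SensitivityTable:
    """Habitat suitability H_j per class and sensitivity S_jr per class
    and threat, all in [0, 1], indexed by class name."""

    def __init__(self, frame: pd.DataFrame):
        if "habitat" not in frame.columns:
            raise ValueError("sensitivity table needs a 'habitat' column")
        vals = frame.to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("habitat and sensitivity values must lie in [0, 1]")
        self.frame = frame.astype(float)

    @property
    def threat_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != "habitat"]

    def habitat(self, class_name: str) -> float:
        return float(self.frame.at[class_name, "habitat"])

    def sensitivity(self, class_name: str, threat: str) -> float:
        return float(self.frame.at[class_name, threat])

    def habitat_vector(self, legend: Legend) -> np.ndarray:
        return np.array([self.habitat(n) for n in legend.names])

    def sensitivity_vector(self, legend: Legend, threat: str) -> np.ndarray:
        return np.array([self.sensitivity(n, threat) for n in legend.names])

    @classmethod
    def from_csv(cls, path) -> "SensitivityTable":
        return cls(pd.read_csv(path, index_col="lulc"))


def load_threat_specs(path: str | Path | None = None) -> list[ThreatSpec]:
    """The seven shipped threat factors, or a user CSV of the same
    schema (threat, max_dist_km, weight, decay)."""
    if path is None:
        src = resources.files("habscape.data") / "threat_factors.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return [
        ThreatSpec(r.threat, float(r.max_dist_km), float(r.weight), r.decay)
        for r in df.itertuples()
    ]


def load_sensitivity(path: str | Path | None = None) -> SensitivityTable:
    """The shipped class-by-threat sensitivity table, or a user CSV of
    the same schema."""
    if path is None:
        src = resources.files("habscape.data") / "sensitivity.csv"
        with resources.as_file(src) as p:
            return SensitivityTable.from_csv(p)
    return SensitivityTable.from_csv(path)


@dataclass
class HQParams:
    """Half-saturation constant K ('auto' = half the maximum observed
    degradation), sensitivity exponent z, optional accessibility raster
    beta in [0, 1] (default: fully accessible)."""

    half_saturation: float | str = "auto"
    z: float = 2.5
    accessibility: ContinuousRaster | None = None

    def __post_init__(self) -> None:
        if isinstance(self.half_saturation, str):
            if self.half_saturation != "auto":
                raise ValueError("half_saturation must be a number or 'auto'")
        elif self.half_saturation <= 0:
            raise ValueError("half_saturation must be positive")
        if self.z <= 0:
            raise ValueError("z must be positive")


@dataclass
class QualityRaster:
    """Per-cell degradation D >= 0 and quality Q in [0, 1]."""

    degradation: ContinuousRaster
    quality: ContinuousRaster
    half_saturation: float


# ---------------------------------------------------------------------------
# Decay kernels


def decay_factor(d: float | np.ndarray, spec: ThreatSpec) -> float | np.ndarray:
    """Distance-decay of a threat's influence at distance d metres, in
    [0, 1]; exactly 0 beyond the maximum effective distance."""
    d = np.asarray(d, dtype=float)
    dmax = spec.max_dist_m
    if spec.decay == "linear":
        out = np.clip(1.0 - d / dmax, 0.0, 1.0)
    else:
        out = np.where(d <= dmax, np.exp(-_EXP_DECAY_CONSTANT * d / dmax), 0.0)
    return float(out) if out.ndim == 0 else out


def decay_kernel(spec: ThreatSpec, cell_size: float) -> np.ndarray:
    """Centred square kernel of decay factors at cell-centre-to-centre
    Euclidean distances."""
    radius = int(np.floor(spec.max_dist_m / cell_size))
    offsets = np.arange(-radius, radius + 1)
    dist = np.hypot(offsets[:, None], offsets[None, :]) * cell_size
    return np.asarray(decay_factor(dist, spec))


# ---------------------------------------------------------------------------
# Degradation and quality


def degradation(
    landcover: CategoricalRaster,
    threats: dict[str, CategoricalRaster],
    specs: list[ThreatSpec],
    sens: SensitivityTable,
    accessibility: ContinuousRaster | None = None,
) -> ContinuousRaster:
    """Total degradation D per cell (weight-normalized over threats).

    ``threats`` maps threat names to binary presence rasters aligned with
    the land cover; every layer must have a spec and a sensitivity
    column.  Nodata land-cover cells get NaN.
    """
    spec_by_name = {s.name: s for s in specs}
    missing = set(threats) - set(spec_by_name)
    if missing:
        raise KeyError(f"no ThreatSpec for threat layers: {sorted(missing)}")
    for name in threats:
        if name not in sens.threat_names:
            raise KeyError(f"no sensitivity column for threat {name!r}")

    total_weight = sum(spec_by_name[name].weight for name in threats)
    if total_weight == 0:
        raise ValueError("all threat weights are zero")

    legend = landcover.legend
    valid = landcover.valid_mask
    # class index grid for sensitivity lookup
    code_index = {c: i for i, c in enumerate(legend.codes)}
    idx = np.zeros(landcover.shape, dtype=np.int64)
    for c, i in code_index.items():
        idx[landcover.values == c] = i

    D = np.zeros(landcover.shape)
    for name, layer in threats.items():
        if not landcover.aligned_with(layer):
            raise ValueError(f"threat layer {name!r} is not aligned")
        spec = spec_by_name[name]
        presence = (layer.values == 1).astype(float)
        if not presence.any():
            continue
        kernel = decay_kernel(spec, landcover.cell_size)
        influence = fftconvolve(presence, kernel, mode="same")
        influence = np.clip(influence, 0.0, None)  # FFT round-off
        s_vec = sens.sensitivity_vector(legend, name)
        D += (spec.weight / total_weight) * influence * s_vec[idx]

    if accessibility is not None:
        if not landcover.aligned_with(accessibility):
            raise ValueError("accessibility raster is not aligned")
        D *= accessibility.values
    D[~valid] = np.nan
    return ContinuousRaster(D, transform=landcover.transform)


def resolve_half_saturation(D: ContinuousRaster, params: HQParams) -> float:
    """Resolve K: the user value, or half the maximum observed
    degradation ('auto'; 0.5 when the landscape is degradation-free)."""
    if params.half_saturation != "auto":
        return float(params.half_saturation)
    dmax = np.nanmax(D.values) if np.isfinite(D.values).any() else 0.0
    return float(dmax / 2.0) if dmax > 0 else 0.5


def quality(
    landcover: CategoricalRaster,
    D: ContinuousRaster,
    sens: SensitivityTable,
    params: HQParams,
    K: float | None = None,
) -> QualityRaster:
    """Half-saturation quality transform Q = H_j (1 - D^z/(D^z + K^z))."""
    if K is None:
        K = resolve_half_saturation(D, params)
    if K <= 0:
        raise ValueError("half-saturation constant must be positive")
    h_vec = sens.habitat_vector(landcover.legend)
    code_index = {c: i for i, c in enumerate(landcover.legend.codes)}
    idx = np.zeros(landcover.shape, dtype=np.int64)
    for c, i in code_index.items():
        idx[landcover.values == c] = i
    H = h_vec[idx].astype(float)
    d = D.values
    with np.errstate(invalid="ignore"):
        dz = np.power(np.clip(d, 0.0, None), params.z)
        Q = H * (1.0 - dz / (dz + K**params.z))
    Q[~landcover.valid_mask] = np.nan
    return QualityRaster(
        degradation=D,
        quality=ContinuousRaster(Q, transform=landcover.transform),
        half_saturation=K,
    )


# ---------------------------------------------------------------------------
# Six-level classification and summaries

#: Quality levels: (code, name, lower-open bound, upper-closed bound).
#: Exactly 0 is "No habitat"; the remaining bands are half-open (lo, hi].
HQ_LEVELS = (
    (0, "No habitat", None, None),
    (1, "Poor", 0.0, 0.2),
    (2, "Relatively poor", 0.2, 0.4),
    (3, "Moderate", 0.4, 0.6),
    (4, "Relatively good", 0.6, 0.8),
    (5, "Good", 0.8, 1.0),
)

_HQ_LEGEND = Legend([(code, name) for code, name, _, _ in HQ_LEVELS])


def classify_hq(
    Q: ContinuousRaster,
) -> tuple[CategoricalRaster, pd.DataFrame]:
    """Classify quality into the six levels and tabulate area (ha).

    Returns the level raster (codes 0-5, nodata -1) and a table with one
    row per level; areas sum to the valid landscape area.
    """
    v = Q.values
    finite = np.isfinite(v)
    out = np.full(v.shape, -1, dtype=np.int64)
    out[finite & (v == 0.0)] = 0
    for code, _, lo, hi in HQ_LEVELS[1:]:
        out[finite & (v > lo) & (v <= hi)] = code
    raster = CategoricalRaster(out, _HQ_LEGEND, nodata=-1, transform=Q.transform)
    area = Q.cell_size**2 / 10_000.0
    rows = [
        {
            "level": code,
            "class": name,
            "cells": int((out == code).sum()),
            "area_ha": float((out == code).sum() * area),
        }
        for code, name, _, _ in HQ_LEVELS
    ]
    return raster, pd.DataFrame(rows)


def mean_hq(Q: ContinuousRaster, mask: np.ndarray | None = None) -> float:
    """Arithmetic mean quality over valid (optionally masked) cells."""
    v = Q.values
    sel = np.isfinite(v) if mask is None else (np.isfinite(v) & mask)
    if not sel.any():
        raise ValueError("no valid cells in mask")
    return float(v[sel].mean())
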