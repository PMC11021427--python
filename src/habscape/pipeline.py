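"""End-to-end scenario orchestration.

A scenario is three dated land-cover maps — an initial synthetic
landscape, one stochastic transition step, and a projected third date
obtained by Markov demand + suitability-ranked allocation — together
with threat layers, degradation/quality surfaces, six-level quality
areas, net-change tables, landscape metrics, and the per-tile
correlation between mean habitat quality and pattern metrics.

The correlation unit is the spatial tile: the landscape is partitioned
into square tiles (default 16x16 cells), each contributing one row of
(mean HQ, NP, PD, SHDI, CONTAG); correlations are computed within each
date and pooled over dates.  A master seed derives per-stage seeds by
hashing the stage name, so every stage is independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

from . import change as chg
from . import metrics as met
from . import quality as hq
from . import synthetic as syn
from .raster import CategoricalRaster, ContinuousRaster, write_raster

__all__ = [
    "AnalysisUnit",
    "ScenarioConfig",
    "CorrelationReport",
    "DEFAULT_TRANSITION_ROWS",
    "tile_landscape",
    "per_unit_stats",
    "pearson",
    "correlation_report",
    "study_scenario",
    "run_pipeline",
]

METRIC_COLUMNS = ("NP", "PD", "SHDI", "CONTAG")

# Default 30-year transition rows: habitat classes lose ground to
# agriculture and built-up area, echoing the observed decline of habitat
# share across the three dates (roughly 80% -> 65% -> 50%).
DEFAULT_TRANSITION_ROWS: dict[int, dict[int, float]] = {
    1: {6: 0.13, 7: 0.07},           # forest -> agriculture / built-up
    2: {3: 0.10, 6: 0.13, 7: 0.05},  # good rangeland degrades & converts
    3: {4: 0.08, 6: 0.16, 7: 0.06},
    4: {6: 0.20, 7: 0.10},
    5: {},                           # water persists
    6: {7: 0.08},                    # agriculture densifies to built-up
    7: {},                           # built-up persists
}


@dataclass(frozen=True)
class AnalysisUnit:
    """One spatial analysis unit: a cell mask over the landscape."""

    unit_id: int
    mask: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    def bounding_slices(self) -> tuple[slice, slice]:
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))


def tile_landscape(
    landcover: CategoricalRaster, tile_size: int = 16
) -> list[AnalysisUnit]:
    """Partition the valid area into square tiles.

    Trailing partial tiles are kept when they hold at least 25% of a full
    tile's cells and merged into their inner neighbor otherwise; units
    with no valid cell are dropped.
    """
    if tile_size < 4:
        raise ValueError("tile_size must be at least 4")
    nr, nc = landcover.shape
    min_cells = 0.25 * tile_size**2

    def edges(n: int) -> np.ndarray:
        es = list(range(0, n, tile_size))
        return np.array(es + [n])

    def bin_of(n: int) -> np.ndarray:
        e = edges(n)
        idx = np.searchsorted(e, np.arange(n), side="right") - 1
        # merge a trailing sliver (shorter than a quarter tile) inward
        if len(e) > 2 and (e[-1] - e[-2]) < 0.25 * tile_size:
            idx[idx == idx.max()] = idx.max() - 1
        return idx

    rbin = bin_of(nr)[:, None]
    cbin = bin_of(nc)[None, :]
    tile_id = rbin * (cbin.max() + 1) + cbin

    valid = landcover.valid_mask
    units: list[AnalysisUnit] = []
    ids = np.unique(tile_id)
    # merge under-filled tiles (per the 25%-valid-cells rule) into the
    # previous kept unit in raster order
    kept_masks: list[np.ndarray] = []
    for tid in ids:
        mask = (tile_id == tid) & valid
        n = int(mask.sum())
        if n == 0:
            continue
        full_tile = (tile_id == tid).sum() >= tile_size**2
        if n >= min_cells or full_tile or not kept_masks:
            kept_masks.append(mask)
        else:
            kept_masks[-1] = kept_masks[-1] | mask
    for i, mask in enumerate(kept_masks):
        units.append(AnalysisUnit(unit_id=i, mask=mask))
    if not units:
        raise ValueError("no valid cells to tile")
    return units


def per_unit_stats(
    Q: ContinuousRaster,
    landcover: CategoricalRaster,
    units: list[AnalysisUnit],
) -> pd.DataFrame:
    """One row per unit: mean habitat quality plus the four landscape
    metrics computed on the unit's sub-raster."""
    if not landcover.aligned_with(Q):
        raise ValueError("quality raster is not aligned with the land cover")
    rows = []
    for unit in units:
        if unit.n_cells == 0:
            raise ValueError(f"unit {unit.unit_id} is empty")
        rs, cs = unit.bounding_slices()
        sub_vals = landcover.values[rs, cs].copy()
        sub_vals[~unit.mask[rs, cs]] = landcover.nodata
        sub = CategoricalRaster(
            sub_vals, landcover.legend, nodata=landcover.nodata,
            transform=landcover.transform,
        )
        record = met.metrics_report(sub)
        rows.append(
            {
                "unit": unit.unit_id,
                "n_cells": unit.n_cells,
                "mean_hq": hq.mean_hq(Q, mask=unit.mask),
                **record.as_dict(),
            }
        )
    return pd.DataFrame(rows)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p (t distribution, n-2 df).

    Returns (nan, nan) when either input has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = sstats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationReport:
    """Pearson correlation of mean HQ against each landscape metric."""

    rows: pd.DataFrame  # columns: metric, r, p, n

    def r(self, metric: str) -> float:
        return float(self.rows.set_index("metric").at[metric, "r"])

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def correlation_report(stats: pd.DataFrame) -> CorrelationReport:
    """Correlate mean HQ with NP, PD, SHDI and CONTAG across units.

    Units where a metric is undefined (CONTAG on single-class tiles) are
    dropped for that metric's pair; the remaining count is reported.
    """
    rows = []
    for metric in METRIC_COLUMNS:
        sub = stats[["mean_hq", metric]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"too few units with defined {metric} (n={n})")
        r, p = pearson(sub["mean_hq"].to_numpy(), sub[metric].to_numpy())
        rows.append({"metric": metric, "r": r, "p": p, "n": n})
    return CorrelationReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Scenario configuration


@dataclass
class ScenarioConfig:
    """Everything one end-to-end run needs.

    The default synthetic grid is 128x128 at 500 m cells, so the
    synthetic extent (64 km across, ~410 000 ha) carries the same
    proportion between landscape size and the km-scale threat distances
    as a real regional watershed.
    """

    synthetic: syn.SyntheticConfig = field(
        default_factory=lambda: syn.SyntheticConfig(cell_size=500.0)
    )
    years: tuple[int, int, int] = (1991, 2021, 2051)
    tile_size: int = 16
    half_saturation: float | str = "auto"
    z: float = 2.5
    clumping_bias: float = 1.0
    transition_rows: dict[int, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRANSITION_ROWS.items()}
    )
    threat_csv: str | None = None
    sensitivity_csv: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.years[0] < self.years[1] < self.years[2]):
            raise ValueError("years must be strictly increasing")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn_kwargs = raw.pop("synthetic", {})
        if "class_proportions" in syn_kwargs:
            syn_kwargs["class_proportions"] = {
                int(k): float(v)
                for k, v in syn_kwargs["class_proportions"].items()
            }
        if "transition_rows" in raw:
            raw["transition_rows"] = {
                int(k): {int(kk): float(vv) for kk, vv in v.items()}
                for k, v in raw["transition_rows"].items()
            }
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        return cls(synthetic=syn.SyntheticConfig(**syn_kwargs), **raw)

    def to_dict(self) -> dict:
        d = {
            "synthetic": {
                "n_rows": self.synthetic.n_rows,
                "n_cols": self.synthetic.n_cols,
                "cell_size": self.synthetic.cell_size,
                "class_proportions": dict(self.synthetic.class_proportions),
                "clumping": self.synthetic.clumping,
                "clumping_east": self.synthetic.clumping_east,
                "n_main_roads": self.synthetic.n_main_roads,
                "n_minor_roads": self.synthetic.n_minor_roads,
                "n_mines": self.synthetic.n_mines,
                "seed": self.synthetic.seed,
            },
            "years": list(self.years),
            "tile_size": self.tile_size,
            "half_saturation": self.half_saturation,
            "z": self.z,
            "clumping_bias": self.clumping_bias,
            "transition_rows": {
                k: dict(v) for k, v in self.transition_rows.items()
            },
            "threat_csv": self.threat_csv,
            "sensitivity_csv": self.sensitivity_csv,
            "seed": self.seed,
        }
        return d


def study_scenario(seed: int = 0) -> ScenarioConfig:
    """The fragmentation-gradient scenario used by the headline
    experiment: clumped in the west, fragmented in the east, with the
    default habitat-to-agriculture/built-up transition regime."""
    return ScenarioConfig(
        synthetic=syn.SyntheticConfig(
            n_rows=128, n_cols=128, cell_size=500.0,
            clumping=6.0, clumping_east=0.8, seed=seed,
        ),
        seed=seed,
    )


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage name mixed with
    the master seed, kept below 2^31."""
    return (zlib.crc32(stage.encode()) ^ (int(master_seed) * 2654435761)) % (2**31)


# ---------------------------------------------------------------------------
# The full run


def run_pipeline(config: ScenarioConfig, out_dir) -> dict:
    """Run the whole scenario and write its artifact directory.

    Writes land-cover, threat, degradation and quality GeoTIFFs for the
    three dates, plus CSV tables (six-level quality areas, net change,
    landscape metrics, per-tile stats, correlations) and a YAML run log.
    Fully reproducible under the master seed.  Returns the in-memory
    results keyed by stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage label
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- land cover at three dates -------------------------------------
    syn_cfg = replace(config.synthetic, seed=stage_seed(seed, "landcover_t0"))
    lc0 = stage("landcover_t0", syn.generate_landcover, syn_cfg)
    tm_true = chg.TransitionMatrix.from_rows(
        lc0.legend, config.transition_rows,
        period_years=config.years[1] - config.years[0],
    )
    lc1 = stage(
        "landcover_t1", syn.evolve_landcover, lc0, tm_true,
        config.clumping_bias, stage_seed(seed, "landcover_t1"),
    )
    tm_est = stage(
        "transition_matrix", chg.transition_matrix, lc0, lc1,
        config.years[1] - config.years[0],
    )
    lc2 = stage(
        "landcover_t2", chg.allocate_change, lc1, tm_est, None, 1,
        stage_seed(seed, "landcover_t2"),
    )
    dates = dict(zip(config.years, (lc0, lc1, lc2)))

    # --- threats and habitat quality ------------------------------------
    specs = hq.load_threat_specs(config.threat_csv)
    sens = hq.load_sensitivity(config.sensitivity_csv)
    params = hq.HQParams(half_saturation=config.half_saturation, z=config.z)
    threats = {
        year: stage(f"threats_{year}", syn.generate_threat_layers, lc, syn_cfg)
        for year, lc in dates.items()
    }
    D = {
        year: stage(f"degradation_{year}", hq.degradation,
                    dates[year], threats[year], specs, sens)
        for year in dates
    }
    # one K across the three dates so quality is on a common scale
    if config.half_saturation == "auto":
        dmax = max(np.nanmax(D[y].values) for y in dates)
        K = dmax / 2.0 if dmax > 0 else 0.5
    else:
        K = float(config.half_saturation)
    Qs = {
        year: stage(f"quality_{year}", hq.quality, dates[year], D[year],
                    sens, params, K)
        for year in dates
    }

    # --- tables ----------------------------------------------------------
    area_tables = {}
    for year in dates:
        _, table = stage(f"classify_hq_{year}", hq.classify_hq, Qs[year].quality)
        table.insert(0, "year", year)
        area_tables[year] = table
    mean_hq_by_year = {
        year: hq.mean_hq(Qs[year].quality) for year in dates
    }

    periods = [(config.years[0], config.years[1]), (config.years[1], config.years[2])]
    net_tables = []
    for y0, y1 in periods:
        nc = stage(f"net_change_{y0}_{y1}", chg.net_change, dates[y0], dates[y1])
        net_tables.append(
            pd.DataFrame(
                {
                    "period": f"{y0}-{y1}",
                    "class_code": list(nc),
                    "class_name": [lc0.legend.name(c) for c in nc],
                    "net_change_ha": list(nc.values()),
                }
            )
        )
    net_change_table = pd.concat(net_tables, ignore_index=True)

    metric_rows = []
    for year in dates:
        rec = stage(f"metrics_{year}", met.metrics_report, dates[year])
        metric_rows.append({"year": year, **rec.as_dict()})
    metrics_table = pd.DataFrame(metric_rows)

    # --- per-tile statistics and correlations ---------------------------
    units = stage("tiles", tile_landscape, lc0, config.tile_size)
    unit_stats = []
    for year in dates:
        df = stage(f"unit_stats_{year}", per_unit_stats,
                   Qs[year].quality, dates[year], units)
        df.insert(0, "year", year)
        unit_stats.append(df)
    unit_stats = pd.concat(unit_stats, ignore_index=True)

    correlations = {}
    for year in dates:
        correlations[year] = stage(
            f"correlation_{year}", correlation_report,
            unit_stats[unit_stats["year"] == year],
        )
    correlations["pooled"] = stage(
        "correlation_pooled", correlation_report, unit_stats
    )

    # --- artifacts -------------------------------------------------------
    for year in dates:
        write_raster(dates[year], out / f"landcover_{year}.tif")
        write_raster(D[year], out / f"degradation_{year}.tif")
        write_raster(Qs[year].quality, out / f"quality_{year}.tif")
        for name, layer in threats[year].items():
            slug = name.lower().replace(" ", "_")
            write_raster(layer, out / f"threat_{slug}_{year}.tif")
    pd.concat(area_tables.values(), ignore_index=True).to_csv(
        out / "hq_class_areas.csv", index=False
    )
    net_change_table.to_csv(out / "net_change.csv", index=False)
    metrics_table.to_csv(out / "landscape_metrics.csv", index=False)
    unit_stats.to_csv(out / "per_unit_stats.csv", index=False)
    corr_rows = []
    for key, rep in correlations.items():
        block = rep.rows.copy()
        block.insert(0, "scope", str(key))
        corr_rows.append(block)
    pd.concat(corr_rows, ignore_index=True).to_csv(
        out / "correlations.csv", index=False
    )
    tm_est.to_csv(out / "transition_matrix.csv")
    pd.DataFrame(
        {"year": list(mean_hq_by_year), "mean_hq": list(mean_hq_by_year.values())}
    ).to_csv(out / "mean_hq.csv", index=False)
    log = {
        "config": config.to_dict(),
        "master_seed": seed,
        "half_saturation_resolved": float(K),
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))

    return {
        "landcover": dates,
        "threats": threats,
        "degradation": D,
        "quality": Qs,
        "half_saturation": K,
        "mean_hq": mean_hq_by_year,
        "hq_areas": area_tables,
        "net_change": net_change_table,
        "metrics": metrics_table,
        "unit_stats": unit_stats,
        "correlations": correlations,
        "transition_matrix": tm_est,
    }
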