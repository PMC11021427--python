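"""Land-change analysis and projection.

Transition probabilities are estimated by cross-tabulating two dated
maps; class demand at a future date is the Markov projection of the
composition; spatial allocation converts the highest-suitability donor
cells per transition (a deterministic, seeded stand-in for the neural
transition-potential modelling of full land-change packages).  Candidate
explanatory variables are screened with Cramer's V, influential above
0.15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import (
    CategoricalRaster,
    ContingencyTable,
    ContinuousRaster,
    Legend,
    cramers_v,
    crosstab,
)

__all__ = [
    "TransitionMatrix",
    "DriverReport",
    "CRAMERS_V_CUTOFF",
    "transition_matrix",
    "net_change",
    "project_demand",
    "suitability",
    "allocate_change",
    "screen_drivers",
]

#: A candidate driver variable is considered influential above this
#: Cramer's V value.
CRAMERS_V_CUTOFF = 0.15


@dataclass
class TransitionMatrix:
    """Row-stochastic class-transition probabilities with the cell counts
    they came from and the calibration period in years."""

    legend: Legend
    probs: np.ndarray
    counts: np.ndarray | None = None
    period_years: float = 30.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        k = len(self.legend)
        if self.probs.shape != (k, k):
            raise ValueError("probs must be KxK over the legend")
        if (self.probs < -1e-12).any():
            raise ValueError("probs must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each row of probs must sum to 1")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            if self.counts.shape != (k, k):
                raise ValueError("counts must be KxK over the legend")

    def to_frame(self) -> pd.DataFrame:
        codes = self.legend.codes
        return pd.DataFrame(self.probs, index=codes, columns=codes)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="from_class")

    @classmethod
    def from_rows(
        cls, legend: Legend, rows: dict[int, dict[int, float]],
        period_years: float = 30.0,
    ) -> "TransitionMatrix":
        """Build from a sparse {from: {to: prob}} mapping; unlisted mass
        stays in the source class."""
        codes = legend.codes
        idx = {c: i for i, c in enumerate(codes)}
        probs = np.eye(len(codes))
        for src, targets in rows.items():
            i = idx[src]
            probs[i] = 0.0
            moved = 0.0
            for dst, p in targets.items():
                probs[i, idx[dst]] += p
                moved += p
            probs[i, i] += max(0.0, 1.0 - moved)
        return cls(legend, probs, period_years=period_years)


def transition_matrix(
    map_t1: CategoricalRaster, map_t2: CategoricalRaster, period_years: float
) -> TransitionMatrix:
    """Estimate the transition matrix from two dated maps.

    Rows are normalized cross-tabulation counts; a class absent at the
    first date gets an identity row (it persists by convention).
    """
    table = crosstab(map_t1, map_t2)
    counts = table.counts
    legend_codes = table.row_labels
    names = {c: n for c, n in map_t1.legend}
    names.update({c: n for c, n in map_t2.legend})
    legend = Legend([(c, names.get(c, f"class {c}")) for c in legend_codes])
    row_sums = counts.sum(axis=1)
    probs = np.eye(len(legend_codes))
    nonzero = row_sums > 0
    probs[nonzero] = counts[nonzero] / row_sums[nonzero, None]
    return TransitionMatrix(legend, probs, counts=counts, period_years=period_years)


def net_change(
    map_t1: CategoricalRaster, map_t2: CategoricalRaster
) -> dict[int, float]:
    """Per-class signed area change in hectares between two dates."""
    if not map_t1.aligned_with(map_t2):
        raise ValueError("rasters are not aligned")
    area = map_t1.cell_area_ha
    c1 = map_t1.class_counts()
    c2 = map_t2.class_counts()
    codes = sorted(set(c1) | set(c2))
    return {c: (c2.get(c, 0) - c1.get(c, 0)) * area for c in codes}


def project_demand(
    tm: TransitionMatrix, composition: dict[int, float] | np.ndarray, n_steps: int
) -> dict[int, float]:
    """Markov projection of the class composition ``n_steps`` periods
    ahead: composition times the n-th matrix power."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    codes = tm.legend.codes
    if isinstance(composition, dict):
        vec = np.array([composition.get(c, 0.0) for c in codes], dtype=float)
        if set(composition) - set(codes):
            raise ValueError("composition contains classes outside the legend")
    else:
        vec = np.asarray(composition, dtype=float)
        if vec.shape != (len(codes),):
            raise ValueError("composition length does not match the legend")
    if not np.isclose(vec.sum(), 1.0, atol=1e-6):
        raise ValueError("composition must sum to 1")
    out = vec @ np.linalg.matrix_power(tm.probs, n_steps)
    return {c: float(p) for c, p in zip(codes, out)}


def suitability(
    covariates: list[ContinuousRaster], weights: list[float]
) -> ContinuousRaster:
    """Weighted linear suitability surface on [0, 1].

    Each covariate is min-max normalized; a constant covariate
    contributes a uniform 0.5.  The weighted sum is rescaled to [0, 1]
    (uniform 0.5 if it is constant, e.g. all weights zero).
    """
    if not covariates:
        raise ValueError("at least one covariate required")
    if len(weights) != len(covariates):
        raise ValueError("one weight per covariate required")
    ref = covariates[0]
    acc = np.zeros(ref.shape)
    for cov, w in zip(covariates, weights):
        if not ref.aligned_with(cov):
            raise ValueError("covariates are not aligned")
        v = cov.values
        lo, hi = np.nanmin(v), np.nanmax(v)
        norm = (v - lo) / (hi - lo) if hi > lo else np.full(v.shape, 0.5)
        acc = acc + w * norm
    lo, hi = np.nanmin(acc), np.nanmax(acc)
    out = (acc - lo) / (hi - lo) if hi > lo else np.full(acc.shape, 0.5)
    return ContinuousRaster(out, transform=ref.transform)


def allocate_change(
    map_t: CategoricalRaster,
    tm: TransitionMatrix,
    suitability_per_transition: dict[tuple[int, int], ContinuousRaster] | None = None,
    n_steps: int = 1,
    seed: int = 0,
) -> CategoricalRaster:
    """Spatially allocate the Markov demand onto the map.

    For each transition i -> j with positive expected count, the class-i
    cells ranked highest by the transition's suitability surface convert;
    ties break by a seeded shuffle.  Integer targets per donor row are
    obtained by largest-remainder rounding, so the final composition
    matches the projected demand to within one cell per transition.
    Demand that exceeds the available donor cells is allocated as far as
    possible.
    """
    codes = tm.legend.codes
    idx = {c: i for i, c in enumerate(codes)}
    lc = map_t.values
    counts = map_t.class_counts()
    n_valid = sum(counts.values())
    step = np.linalg.matrix_power(tm.probs, n_steps)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 30]))

    out = lc.copy()
    for src in codes:
        n_src = counts.get(src, 0)
        if n_src == 0:
            continue
        expected = n_src * step[idx[src]]
        targets = np.floor(expected).astype(np.int64)
        remainder = expected - targets
        short = n_src - targets.sum()
        for j in np.argsort(-remainder, kind="stable")[:short]:
            targets[j] += 1

        cells = np.flatnonzero(lc == src)
        cells = rng.permutation(cells)  # seeded tie-break
        taken = np.zeros(cells.size, dtype=bool)
        order_dst = sorted(
            (c for c in codes if c != src and targets[idx[c]] > 0),
            key=lambda c: -targets[idx[c]],
        )
        for dst in order_dst:
            want = int(targets[idx[dst]])
            avail = np.flatnonzero(~taken)
            if avail.size == 0:
                break
            surf = None
            if suitability_per_transition:
                surf = suitability_per_transition.get((src, dst))
            if surf is not None:
                scores = surf.values.ravel()[cells[avail]]
                pick = avail[np.argsort(-scores, kind="stable")[:want]]
            else:
                pick = avail[:want]
            out.flat[cells[pick]] = dst
            taken[pick] = True

    return CategoricalRaster(
        out, map_t.legend, nodata=map_t.nodata, transform=map_t.transform
    )


@dataclass
class DriverReport:
    """Cramer's V per candidate driver with the influence flag."""

    values: dict[str, float]

    @property
    def influential(self) -> dict[str, bool]:
        return {k: v > CRAMERS_V_CUTOFF for k, v in self.values.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "driver": list(self.values),
                "cramers_v": list(self.values.values()),
                "influential": list(self.influential.values()),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def screen_drivers(
    covariates: dict[str, ContinuousRaster],
    change_mask: CategoricalRaster,
    n_bins: int = 10,
) -> DriverReport:
    """Screen continuous driver variables against a binary change mask.

    Each covariate is decile-binned over jointly valid cells, crosstabbed
    against change/no-change, and scored with Cramer's V.  A constant
    covariate scores 0.
    """
    mask_vals = change_mask.values
    valid = change_mask.valid_mask
    report: dict[str, float] = {}
    for name, cov in covariates.items():
        if not change_mask.aligned_with(cov):
            raise ValueError(f"driver {name!r} is not aligned with the mask")
        joint = valid & cov.valid_mask
        x = cov.values[joint]
        y = mask_vals[joint]
        if np.unique(y).size < 2:
            raise ValueError("change mask must contain both classes")
        if np.unique(x).size < 2:
            report[name] = 0.0
            continue
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
        bins = np.digitize(x, edges)
        tab = pd.crosstab(bins, y).to_numpy()
        if min(tab.shape) < 2:
            report[name] = 0.0
            continue
        table = ContingencyTable(
            tab, list(range(tab.shape[0])), list(range(tab.shape[1]))
        )
        report[name] = cramers_v(table)
    return DriverReport(report)
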