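"""Estimators for experimental-format data.

Covers the wet-lab side of the study: effective growth rates from plate-
reader OD600 curves (threshold-crossing method), viable-count densities from
colony counts, ordinary least-squares fits (growth rate vs inoculum density,
antibiotic clearance), and rank-sum group comparisons.

The effective growth rate assumes exponential growth from the initial OD up
to a threshold (default OD 0.5/cm) and reports

    rate = log10(OD_threshold / OD_initial) / T_threshold

in decadal-log units per hour, where ``T_threshold`` is the first crossing
time of the threshold, linearly interpolated between bracketing samples.
Wells that never reach the threshold are flagged as censored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ODRecord",
    "GrowthRateEstimate",
    "CFURecord",
    "LinearFit",
    "RankSumResult",
    "effective_growth_rate",
    "growth_rate_table",
    "cfu_per_ml",
    "cfu_table_to_densities",
    "fit_linear",
    "wilcoxon_rank_sum",
]

#: Colony counts outside this per-plate window are statistically unreliable;
#: they are flagged, not rejected.
PLAUSIBLE_COLONY_RANGE = (3, 300)


@dataclass(frozen=True)
class ODRecord:
    """One well's OD600 time series with its metadata."""

    well: str
    strain: str
    initial_density: float  # CFU/ml
    smx: bool
    times: np.ndarray  # hours, strictly increasing
    od600: np.ndarray  # per cm, >= 0
    smx_concentration: float = 0.0  # ug/l

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if times.ndim != 1 or times.shape != od.shape:
            raise ValueError("times and od600 must be 1-D and aligned")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("od600 must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od600", od)


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Effective growth rate (log10 units per hour) or a censoring flag."""

    rate: Optional[float]
    t_threshold: Optional[float]
    od_threshold: float
    censored: bool


@dataclass(frozen=True)
class CFURecord:
    """One selective-plating observation."""

    cycle: int
    strain: str
    colonies: int
    dilution_factor: float
    plated_volume: float = 0.01  # ml

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def plausible(self) -> bool:
        lo, hi = PLAUSIBLE_COLONY_RANGE
        return lo <= self.colonies <= hi


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    stderr_slope: float
    n: int


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    pvalue: float
    method: str  # "exact" | "asymptotic"


def effective_growth_rate(
    record: ODRecord, od_threshold: float = 0.5
) -> GrowthRateEstimate:
    """Threshold-crossing effective growth rate of one well.

    Raises ``ValueError`` if the well is already at or past the threshold at
    time zero (the rate is then undefined).  Returns a censored estimate if
    the series never reaches the threshold within the observation horizon.
    """
    od = record.od600
    times = record.times
    if len(times) < 2:
        raise ValueError("need at least two time points")
    od_i = od[0]
    if od_i <= 0:
        raise ValueError("initial OD must be > 0")
    if od_i >= od_threshold:
        raise ValueError(
            f"initial OD {od_i} already at/above threshold {od_threshold}"
        )
    above = np.nonzero(od >= od_threshold)[0]
    if above.size == 0:
        return GrowthRateEstimate(None, None, od_threshold, censored=True)
    k = above[0]
    if od[k] == od_threshold:
        t_cross = times[k]
    else:
        # linear interpolation between the bracketing samples
        frac = (od_threshold - od[k - 1]) / (od[k] - od[k - 1])
        t_cross = times[k - 1] + frac * (times[k] - times[k - 1])
    rate = np.log10(od_threshold / od_i) / t_cross
    return GrowthRateEstimate(rate, t_cross, od_threshold, censored=False)


def growth_rate_table(
    od_table: pd.DataFrame, od_threshold: float = 0.5
) -> pd.DataFrame:
    """Per-well growth-rate estimates from a long-format OD table.

    Expects columns ``well, strain, initial_density, smx, time_h, od600``;
    returns one row per well with the estimate and a censoring flag.
    """
    required = {"well", "strain", "initial_density", "smx", "time_h", "od600"}
    missing = required - set(od_table.columns)
    if missing:
        raise ValueError(f"OD table missing columns: {sorted(missing)}")
    rows = []
    for well, grp in od_table.groupby("well", sort=True):
        grp = grp.sort_values("time_h")
        rec = ODRecord(
            well=str(well),
            strain=str(grp["strain"].iloc[0]),
            initial_density=float(grp["initial_density"].iloc[0]),
            smx=bool(grp["smx"].iloc[0]),
            times=grp["time_h"].to_numpy(),
            od600=grp["od600"].to_numpy(),
        )
        est = effective_growth_rate(rec, od_threshold=od_threshold)
        rows.append(
            {
                "well": rec.well,
                "strain": rec.strain,
                "initial_density": rec.initial_density,
                "smx": rec.smx,
                "rate": est.rate,
                "t_threshold": est.t_threshold,
                "censored": est.censored,
            }
        )
    return pd.DataFrame(rows)


def cfu_per_ml(record: CFURecord) -> Tuple[float, bool]:
    """Viable density from one plate: colonies * dilution / plated volume.

    Returns ``(density, below_detection)``; a zero-colony plate gives density
    0 with the below-detection flag set.
    """
    if record.plated_volume <= 0:
        raise ValueError("plated_volume must be > 0")
    density = record.colonies * record.dilution_factor / record.plated_volume
    return density, record.colonies == 0


def cfu_table_to_densities(cfu_table: pd.DataFrame) -> pd.DataFrame:
    """Add ``cfu_per_ml`` and ``below_detection`` columns to a count table."""
    required = {"cycle", "strain", "colonies", "dilution_factor", "plated_volume"}
    missing = required - set(cfu_table.columns)
    if missing:
        raise ValueError(f"CFU table missing columns: {sorted(missing)}")
    out = cfu_table.copy()
    out["cfu_per_ml"] = (
        out["colonies"] * out["dilution_factor"] / out["plated_volume"]
    )
    out["below_detection"] = out["colonies"] == 0
    return out


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least-squares line with the coefficient of determination.

    Requires n >= 3 complete pairs and non-degenerate x.  A constant y gives
    slope 0 and r-squared 0 (no variance explained).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing/non-finite values are not allowed")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    if np.ptp(y) == 0:
        return LinearFit(0.0, float(y[0]), 0.0, 0.0, len(x))
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr_slope=float(res.stderr),
        n=len(x),
    )


EXACT_MAX_N = 12


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when both groups have at most
    ``EXACT_MAX_N`` observations and there are no ties, and the tie-corrected
    normal approximation otherwise.  If every value in both groups is
    identical the test is degenerate and p = 1 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical in both groups; p = 1", stacklevel=2)
        return RankSumResult(len(x) * len(y) / 2.0, 1.0, "degenerate")
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankSumResult(float(res.statistic), float(min(res.pvalue, 1.0)), method)
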