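"""Skyline-trajectory ingestion and effective-population-size change
statistics.

A skyline trajectory is a table of (calendar year, median Ne, 95% HPD
bounds) exported from a coalescent skyline analysis; this module reads such
exports, computes signed percent reductions between time points, summarizes
erosion over a calendar window, and scans for bottleneck-like declines.
Trajectory inference itself (MCMC, tree priors, tip dating) is upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED = ("time", "median", "upper", "lower")


@dataclass
class SkylineTrajectory:
    """Rows of (time, ne_median, hpd_low, hpd_high), time strictly increasing."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = {"time", "ne_median", "hpd_low", "hpd_high"} - set(t.columns)
        if missing:
            raise ValueError(f"trajectory missing columns: {sorted(missing)}")
        if (t["ne_median"] <= 0).any():
            raise ValueError("ne_median must be positive")
        bad = (t["hpd_low"] > t["ne_median"]) | (t["ne_median"] > t["hpd_high"])
        if bad.any():
            raise ValueError("HPD bounds must bracket the median")
        if not t["time"].is_monotonic_increasing or t["time"].duplicated().any():
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].values

    @property
    def ne(self) -> np.ndarray:
        return self.table["ne_median"].values


@dataclass
class ReductionReport:
    start_year: float
    end_year: float
    ne_start: float
    ne_end: float

    @property
    def pct_change(self) -> float:
        """Signed percent reduction: positive for declines."""
        return percent_reduction(self.ne_start, self.ne_end)

    def to_dict(self) -> dict:
        return {
            "start_year": self.start_year,
            "end_year": self.end_year,
            "ne_start": self.ne_start,
            "ne_end": self.ne_end,
            "pct_change": self.pct_change,
        }


def read_skyline(path) -> SkylineTrajectory:
    """Read a tab-delimited skyline export.

    The header is matched order-free and case-insensitively: a time column,
    a median column, and upper/lower HPD columns are required (a mean column
    is tolerated and ignored). Non-monotone rows are sorted with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    colmap = {}
    for want in REQUIRED:
        hits = [c for c in df.columns if want in c.lower()]
        if not hits:
            raise ValueError(f"{path}: missing required column matching {want!r}")
        colmap[want] = hits[0]
    out = pd.DataFrame(
        {
            "time": df[colmap["time"]].astype(float),
            "ne_median": df[colmap["median"]].astype(float),
            "hpd_low": df[colmap["lower"]].astype(float),
            "hpd_high": df[colmap["upper"]].astype(float),
        }
    )
    if not out["time"].is_monotonic_increasing:
        logger.warning("read_skyline: %s has non-monotone times; sorting", path)
        out = out.sort_values("time", kind="stable")
    return SkylineTrajectory(out.reset_index(drop=True))


def write_skyline(traj: SkylineTrajectory, path) -> None:
    from .io import atomic_write_text

    out = traj.table.rename(
        columns={"ne_median": "median", "hpd_low": "lower", "hpd_high": "upper"}
    )
    atomic_write_text(path, out.to_csv(sep="\t", index=False))


def percent_reduction(ne_start: float, ne_end: float) -> float:
    """``100 * (1 - ne_end / ne_start)``: positive for declines, negative for
    growth. Together with percent retained this sums to exactly 100."""
    if ne_start <= 0:
        raise ValueError(f"ne_start must be positive, got {ne_start}")
    return 100.0 * (1.0 - ne_end / ne_start)


def erosion_summary(traj: SkylineTrajectory, start_year: float, end_year: float
                    ) -> ReductionReport:
    """Percent Ne reduction over a calendar window.

    The starting level is the plateau proxy — the maximum median within the
    first half of the window — and the end level the median at the last time
    point not after ``end_year``.
    """
    t = traj.table
    in_window = (t["time"] >= start_year) & (t["time"] <= end_year)
    if int(in_window.sum()) < 2:
        raise ValueError("fewer than 2 trajectory points in window")
    half = start_year + (end_year - start_year) / 2.0
    first_half = in_window & (t["time"] <= half)
    if not first_half.any():
        raise ValueError("no trajectory points in the first half of the window")
    ne_start = float(t.loc[first_half, "ne_median"].max())
    ne_end = float(t.loc[in_window, "ne_median"].iloc[-1])
    return ReductionReport(start_year, end_year, ne_start, ne_end)


def detect_declines(traj: SkylineTrajectory, min_drop_pct: float
                    ) -> list[tuple[tuple[float, float], float]]:
    """Left-to-right scan for bottleneck-like declines.

    The trajectory is segmented into maximal runs of consecutive points with
    strictly decreasing Ne; runs whose endpoint-to-endpoint reduction reaches
    ``min_drop_pct`` are reported as [((t_start, t_end), pct)], non-overlapping
    and in time order. Flat stretches separate declines, so two drops divided
    by a plateau are reported as two intervals.
    """
    if min_drop_pct <= 0:
        raise ValueError("min_drop_pct must be positive")
    times, ne = traj.times, traj.ne
    out = []
    n = len(times)
    i = 0
    while i < n - 1:
        if ne[i + 1] >= ne[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ne[j + 1] < ne[j]:
            j += 1
        pct = percent_reduction(ne[i], ne[j])
        if pct >= min_drop_pct:
            out.append(((float(times[i]), float(times[j])), pct))
        i = j
    return out
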