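"""Raw series -> clean second-by-second series over the analysis window.

Irregular per-breath/per-beat samples are linearly interpolated onto an
integer-second grid, truncated to the first ``n_bouts`` bout+rest periods,
and screened for instrument-artifact irregularities (long gaps, values
outside physiological range, flatline runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import RawSeries, WorkRateSchedule

#: analysis window: first four bouts of the standard protocol
ANALYSIS_T_END = 720

#: plausible physiological ranges per signal (same units as the data)
DEFAULT_RANGES = {
    "HR": (25.0, 250.0),
    "RR": (4.0, 120.0),
    "VO2": (0.0, 6000.0),
    "VCO2": (0.0, 7000.0),
}

EDGE_HOLD_S = 1.0  # constant-edge hold allowed at each end


class CoverageError(ValueError):
    """Series does not cover the requested window."""


@dataclass(frozen=True)
class UniformSeries:
    participant_id: str
    signal: str
    grid_s: np.ndarray  # integer seconds 0..t_end
    values: np.ndarray
    t_end: int

    def __post_init__(self) -> None:
        g = np.asarray(self.grid_s)
        if g.size != self.t_end + 1 or g[0] != 0 or g[-1] != self.t_end:
            raise ValueError("grid must be the integers 0..t_end")
        if np.any(np.diff(g) != 1):
            raise ValueError("grid step must be exactly 1 s")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


@dataclass(frozen=True)
class QCReport:
    participant_id: str
    excluded: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded must hold iff reasons is nonempty")


@dataclass(frozen=True)
class QCThresholds:
    gap_max_s: float = 10.0
    flat_max_s: float = 60.0
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))


def interpolate_to_seconds(raw: RawSeries, t_end: int) -> UniformSeries:
    """Linear interpolation at integer seconds 0..t_end.

    No extrapolation beyond the observed span except a constant-edge hold
    of at most 1 s at either end; insufficient coverage raises
    :class:`CoverageError` naming the missing region.
    """
    t, v = raw.times_s, raw.values
    if t[0] > EDGE_HOLD_S:
        raise CoverageError(
            f"{raw.participant_id}/{raw.signal}: first sample at t={t[0]:.2f}s "
            f"leaves [0, {t[0]:.2f}] uncovered"
        )
    if t[-1] < t_end - EDGE_HOLD_S:
        raise CoverageError(
            f"{raw.participant_id}/{raw.signal}: last sample at t={t[-1]:.2f}s "
            f"leaves [{t[-1]:.2f}, {t_end}] uncovered"
        )
    grid = np.arange(0, t_end + 1)
    vals = np.interp(grid, t, v)  # edge hold == np.interp clamping
    return UniformSeries(raw.participant_id, raw.signal, grid, vals, int(t_end))


def truncate_to_window(
    series: UniformSeries, schedule: WorkRateSchedule, n_bouts: int
) -> UniformSeries:
    """Keep [0, n_bouts * (bout + rest)] seconds; 4 bouts of the standard
    protocol give a 720-s window (721 samples)."""
    if n_bouts < 1 or n_bouts > schedule.n_bouts:
        raise ValueError(f"n_bouts must be in 1..{schedule.n_bouts}")
    t_end = int(round(n_bouts * (schedule.bout_duration_s + schedule.rest_duration_s)))
    if t_end > series.t_end:
        raise CoverageError(
            f"window [0, {t_end}] exceeds series coverage [0, {series.t_end}]"
        )
    return UniformSeries(
        series.participant_id,
        series.signal,
        series.grid_s[: t_end + 1],
        series.values[: t_end + 1],
        t_end,
    )


def qc_screen(raw: RawSeries, rules: QCThresholds | None = None) -> QCReport:
    """Flag irregular records; returns a report, never raises."""
    rules = rules or QCThresholds()
    reasons: list[str] = []
    gaps = np.diff(raw.times_s)
    if gaps.size and gaps.max() > rules.gap_max_s:
        reasons.append("gap")
    lo, hi = rules.ranges.get(raw.signal, (-np.inf, np.inf))
    if np.any((raw.values < lo) | (raw.values > hi)):
        reasons.append("range")
    if _longest_flatline_s(raw.times_s, raw.values) > rules.flat_max_s:
        reasons.append("flatline")
    return QCReport(raw.participant_id, bool(reasons), tuple(reasons))


def _longest_flatline_s(t: np.ndarray, v: np.ndarray) -> float:
    """Duration of the longest run of exactly-repeated values."""
    if v.size < 2:
        return 0.0
    change = np.r_[True, np.diff(v) != 0]
    starts = np.flatnonzero(change)
    longest = 0.0
    for i, s in enumerate(starts):
        end_idx = starts[i + 1] - 1 if i + 1 < starts.size else v.size - 1
        longest = max(longest, float(t[end_idx] - t[s]))
    return longest


def screen_cohort(
    series: list[RawSeries], rules: QCThresholds | None = None
) -> dict[str, QCReport]:
    """Participant-level QC: excluded iff any of their signals is excluded."""
    by_pid: dict[str, list[str]] = {}
    for s in series:
        rep = qc_screen(s, rules)
        by_pid.setdefault(s.participant_id, [])
        for r in rep.reasons:
            tag = f"{s.signal}:{r}"
            if tag not in by_pid[s.participant_id]:
                by_pid[s.participant_id].append(tag)
    return {
        pid: QCReport(pid, bool(rs), tuple(rs)) for pid, rs in by_pid.items()
    }


def raw_from_frame(series_df: pd.DataFrame) -> list[RawSeries]:
    """Long-format frame (participant_id, signal, time_s, value, units) ->
    RawSeries list, one per (participant, signal)."""
    out = []
    for (pid, sig), grp in series_df.groupby(["participant_id", "signal"], sort=True):
        grp = grp.sort_values("time_s")
        units = str(grp["units"].iloc[0]) if "units" in grp else "a.u."
        out.append(
            RawSeries(
                participant_id=str(pid),
                signal=str(sig),
                times_s=grp["time_s"].to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float),
                units=units,
            )
        )
    return out


def uniform_frame(series: list[UniformSeries]) -> pd.DataFrame:
    parts = [
        pd.DataFrame(
            {
                "participant_id": s.participant_id,
                "signal": s.signal,
                "time_s": s.grid_s,
                "value": s.values,
            }
        )
        for s in series
    ]
    return pd.concat(parts, ignore_index=True)
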