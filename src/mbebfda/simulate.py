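"""Synthetic MBEB cohort generation.

The MBEB (multiple brief exercise bouts) protocol is a square wave of
constant-work-rate cycling bouts separated by fixed rest periods.  Each
physiological signal (HR, RR, VO2, VCO2) is modelled with piecewise
first-order kinetics: within a bout the noise-free trajectory relaxes
exponentially toward ``baseline + amplitude`` with time constant
``tau_on_s``; during rest it relaxes toward ``baseline + drift_per_bout *
k`` (k bouts completed so far) with ``tau_off_s``.  Task-failure
participants receive a configurable amplitude shift and positive drift so
their mean curves sit above the completers'.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SIGNALS = ("HR", "RR", "VO2", "VCO2")

UNITS = {
    "HR": "beats/min",
    "RR": "breaths/min",
    "VO2": "mL/min",
    "VCO2": "mL/min",
}

#: full-scale protocol: ten 2-min bouts, 1-min rest after each
DEFAULT_N_BOUTS = 10
DEFAULT_BOUT_S = 120.0
DEFAULT_REST_S = 60.0
DEFAULT_INTENSITY = 0.8


class SimulationError(ValueError):
    """Raised on invalid simulation inputs."""


@dataclass(frozen=True)
class WorkRateSchedule:
    """Square-wave bout/rest timing and intensity pattern."""

    bouts: tuple[tuple[float, float], ...]
    rest_duration_s: float
    intensity_fraction: float
    total_duration_s: float

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)

    @property
    def bout_duration_s(self) -> float:
        if not self.bouts:
            return 0.0
        on, off = self.bouts[0]
        return off - on


@dataclass(frozen=True)
class KineticsParams:
    """First-order on/off kinetics for one signal in one label group."""

    baseline: float
    amplitude: float
    tau_on_s: float
    tau_off_s: float
    drift_per_bout: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_on_s <= 0 or self.tau_off_s <= 0:
            raise SimulationError("time constants must be positive")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be nonnegative")
        if self.drift_per_bout < 0:
            raise SimulationError("drift_per_bout must be nonnegative")


@dataclass(frozen=True)
class ParticipantMeta:
    participant_id: str
    sex: str  # "F" | "M"
    puberty: str  # "early" | "late"
    body_mass_kg: float
    bouts_completed: int
    label: int  # 1 = task failure, 0 = completer

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise SimulationError(f"sex must be F or M, got {self.sex!r}")
        if self.puberty not in ("early", "late"):
            raise SimulationError(f"puberty must be early or late, got {self.puberty!r}")
        if self.body_mass_kg <= 0:
            raise SimulationError("body_mass_kg must be positive")
        if not (1 <= self.bouts_completed <= 10):
            raise SimulationError("bouts_completed must be in 1..10")
        if self.label != int(self.bouts_completed < 10):
            raise SimulationError("label must be 1 iff bouts_completed < 10")


@dataclass(frozen=True)
class RawSeries:
    participant_id: str
    signal: str
    times_s: np.ndarray
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size < 2:
            raise SimulationError("a RawSeries needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise SimulationError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise SimulationError("values must be finite")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)


def default_kinetics() -> dict[tuple[str, int], KineticsParams]:
    """Default (signal, label) -> kinetics map.

    HR is the cleanest signal and RR the noisiest; failures carry a
    positive end-of-rest drift (incomplete recovery between bouts).
    """
    base = {
        "HR": KineticsParams(80.0, 70.0, 30.0, 45.0, 0.0, 2.0),
        "RR": KineticsParams(20.0, 20.0, 30.0, 40.0, 0.0, 4.0),
        "VO2": KineticsParams(300.0, 1200.0, 25.0, 40.0, 0.0, 60.0),
        "VCO2": KineticsParams(300.0, 1200.0, 35.0, 45.0, 0.0, 60.0),
    }
    drift = {"HR": 2.5, "RR": 0.8, "VO2": 40.0, "VCO2": 40.0}
    out: dict[tuple[str, int], KineticsParams] = {}
    for sig, kp in base.items():
        out[(sig, 0)] = kp
        out[(sig, 1)] = dataclasses.replace(kp, drift_per_bout=drift[sig])
    return out


DEFAULT_GROUP_MEAN_SHIFT = {"HR": 12.0, "RR": 3.0, "VO2": 180.0, "VCO2": 180.0}
DEFAULT_SAMPLING_GAP_S = {"HR": 1.0, "RR": 2.0, "VO2": 2.0, "VCO2": 2.0}
DEFAULT_AMPLITUDE_SD = {"HR": 5.0, "RR": 1.5, "VO2": 80.0, "VCO2": 80.0}
DEFAULT_BASELINE_SD = {"HR": 4.0, "RR": 1.5, "VO2": 30.0, "VCO2": 30.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to deterministically generate a cohort."""

    n_participants: int = 78
    schedule: WorkRateSchedule | None = None
    kinetics: dict[tuple[str, int], KineticsParams] = field(default_factory=default_kinetics)
    group_mean_shift: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MEAN_SHIFT)
    )
    sampling_gap_s: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLING_GAP_S)
    )
    amplitude_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDE_SD)
    )
    baseline_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_SD)
    )
    balanced: bool = True
    seed: int = 0

    def resolved_schedule(self) -> WorkRateSchedule:
        if self.schedule is not None:
            return self.schedule
        return generate_protocol(
            DEFAULT_N_BOUTS, DEFAULT_BOUT_S, DEFAULT_REST_S, DEFAULT_INTENSITY
        )


def generate_protocol(
    n_bouts: int,
    bout_duration_s: float,
    rest_duration_s: float,
    intensity_fraction: float = DEFAULT_INTENSITY,
) -> WorkRateSchedule:
    """Build the square-wave schedule: bout k spans
    [(k-1)(bout+rest), (k-1)(bout+rest)+bout), followed by a rest."""
    if n_bouts < 0 or int(n_bouts) != n_bouts:
        raise SimulationError(f"n_bouts must be a nonnegative integer, got {n_bouts}")
    if bout_duration_s <= 0 or rest_duration_s <= 0:
        raise SimulationError("durations must be positive")
    if not (0 < intensity_fraction <= 1):
        raise SimulationError("intensity_fraction must be in (0, 1]")
    period = bout_duration_s + rest_duration_s
    bouts = tuple(
        (k * period, k * period + bout_duration_s) for k in range(int(n_bouts))
    )
    return WorkRateSchedule(
        bouts=bouts,
        rest_duration_s=rest_duration_s,
        intensity_fraction=intensity_fraction,
        total_duration_s=n_bouts * period,
    )


def _segments(
    schedule: WorkRateSchedule, params: KineticsParams
) -> list[tuple[float, float, float, float]]:
    """(start, end, target, tau) for each bout/rest segment in order."""
    segs = []
    for k, (on, off) in enumerate(schedule.bouts):
        segs.append((on, off, params.baseline + params.amplitude, params.tau_on_s))
        rest_target = params.baseline + params.drift_per_bout * (k + 1)
        segs.append((off, off + schedule.rest_duration_s, rest_target, params.tau_off_s))
    return segs


def noise_free_trajectory(
    schedule: WorkRateSchedule, params: KineticsParams, t: np.ndarray
) -> np.ndarray:
    """Evaluate the continuous piecewise-exponential trajectory at times t.

    Within segment [t0, t1) with target m and time constant tau:
    ``y(t) = m + (y(t0) - m) * exp(-(t - t0)/tau)``; the initial value at
    protocol start is the baseline, so the trajectory is continuous.
    """
    t = np.asarray(t, dtype=float)
    y = np.full(t.shape, params.baseline, dtype=float)
    y0 = float(params.baseline)
    for t0, t1, target, tau in _segments(schedule, params):
        # right-closed on the final segment so t == total_duration is covered
        last = t1 >= schedule.total_duration_s
        mask = (t >= t0) & ((t <= t1) if last else (t < t1))
        if mask.any():
            y[mask] = target + (y0 - target) * np.exp(-(t[mask] - t0) / tau)
        y0 = target + (y0 - target) * np.exp(-(t1 - t0) / tau)
    return y


def simulate_signal(
    schedule: WorkRateSchedule,
    params: KineticsParams,
    grid: np.ndarray,
    rng: np.random.Generator,
    *,
    participant_id: str = "sim",
    signal: str = "HR",
) -> RawSeries:
    """Noise-free trajectory plus iid Gaussian noise, sampled at ``grid``."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise SimulationError("grid must be nonempty")
    if grid.min() < 0 or grid.max() > schedule.total_duration_s:
        raise SimulationError("grid must lie within [0, total_duration_s]")
    y = noise_free_trajectory(schedule, params, grid)
    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, size=grid.shape)
    return RawSeries(
        participant_id=participant_id,
        signal=signal,
        times_s=grid,
        values=y,
        units=UNITS.get(signal, "a.u."),
    )


def _irregular_grid(
    total_s: float, mean_gap_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Breath-by-breath style sampling: exponential inter-sample gaps,
    pinned at t=0 and t=total."""
    n_expect = int(total_s / mean_gap_s * 2) + 20
    gaps = rng.exponential(mean_gap_s, size=n_expect)
    # floor keeps times strictly increasing; cap keeps clean records within
    # the default QC gap threshold (a breath never pauses 4x the mean gap)
    t = np.cumsum(np.clip(gaps, 1e-3, 4.0 * mean_gap_s))
    t = t[t < total_s - 1e-9]
    while t.size and t[-1] < total_s - 3 * mean_gap_s:  # pragma: no cover
        extra = t[-1] + np.cumsum(np.maximum(rng.exponential(mean_gap_s, 50), 1e-3))
        t = np.r_[t, extra[extra < total_s - 1e-9]]
    return np.r_[0.0, t, total_s]


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[ParticipantMeta], list[RawSeries]]:
    """Generate a balanced failure/completer cohort, four signals each.

    Deterministic given ``config.seed``: each participant owns one spawned
    random stream, split again per signal, so adding a signal or
    participant never perturbs the draws of the others.
    """
    n = config.n_participants
    if n <= 0:
        raise SimulationError("n_participants must be positive")
    if config.balanced and n % 2:
        raise SimulationError("balanced cohorts need an even n_participants")
    schedule = config.resolved_schedule()
    if schedule.n_bouts < 4:
        raise SimulationError("protocol must have at least 4 bouts")

    root = np.random.SeedSequence(config.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    assign_rng.shuffle(labels)

    meta: list[ParticipantMeta] = []
    series: list[RawSeries] = []
    participant_seqs = root.spawn(n + 1)[1:]
    for i, (label, seq) in enumerate(zip(labels, participant_seqs)):
        streams = seq.spawn(len(SIGNALS) + 1)
        prng = np.random.default_rng(streams[0])
        pid = f"P{i + 1:03d}"
        sex = "F" if prng.random() < 0.5 else "M"
        puberty = "early" if prng.random() < 0.5 else "late"
        body_mass = float(np.clip(prng.normal(46.0, 13.0), 22.0, 95.0))
        if label == 1:
            bouts_completed = int(prng.integers(4, 10))  # {4..9}
        else:
            bouts_completed = 10
        meta.append(
            ParticipantMeta(pid, sex, puberty, body_mass, bouts_completed, int(label))
        )
        for sig, stream in zip(SIGNALS, streams[1:]):
            srng = np.random.default_rng(stream)
            kp = config.kinetics[(sig, int(label))]
            amp = kp.amplitude + srng.normal(0.0, config.amplitude_sd.get(sig, 0.0))
            if label == 1:
                amp += config.group_mean_shift.get(sig, 0.0)
            base = kp.baseline + srng.normal(0.0, config.baseline_sd.get(sig, 0.0))
            kp_i = dataclasses.replace(kp, amplitude=float(amp), baseline=float(base))
            grid = _irregular_grid(
                schedule.total_duration_s, config.sampling_gap_s.get(sig, 2.0), srng
            )
            series.append(
                simulate_signal(
                    schedule, kp_i, grid, srng, participant_id=pid, signal=sig
                )
            )
    return meta, series


def strong_effect_config(n_participants: int = 78, seed: int = 0) -> SimulationConfig:
    """Cohort with a failure-group amplitude shift well above two
    within-group SDs of the curve level, for power/recovery checks."""
    shift = {"HR": 25.0, "RR": 6.0, "VO2": 400.0, "VCO2": 400.0}
    return SimulationConfig(
        n_participants=n_participants, seed=seed, group_mean_shift=shift
    )


def null_config(n_participants: int = 78, seed: int = 0) -> SimulationConfig:
    """Cohort where labels are statistically independent of the curves:
    no amplitude shift and identical kinetics in both groups."""
    kin = default_kinetics()
    kin = {(sig, lab): kin[(sig, 0)] for sig in SIGNALS for lab in (0, 1)}
    return SimulationConfig(
        n_participants=n_participants,
        seed=seed,
        kinetics=kin,
        group_mean_shift={sig: 0.0 for sig in SIGNALS},
    )


# ---------------------------------------------------------------------------
# cohort <-> delimited text

def meta_frame(meta: list[ParticipantMeta]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(m) for m in meta])


def series_frame(series: list[RawSeries]) -> pd.DataFrame:
    parts = []
    for s in series:
        parts.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "signal": s.signal,
                    "time_s": s.times_s,
                    "value": s.values,
                    "units": s.units,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_cohort(
    meta: list[ParticipantMeta],
    series: list[RawSeries],
    outdir: str | Path,
    config: SimulationConfig | None = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_frame(meta).to_csv(outdir / "meta.csv", index=False)
    series_frame(series).to_csv(outdir / "series.csv", index=False)
    if config is not None:
        (outdir / "sim_config.json").write_text(config_to_json(config))


def read_cohort(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    indir = Path(indir)
    meta = pd.read_csv(indir / "meta.csv")
    series = pd.read_csv(indir / "series.csv")
    return meta, series


def config_to_json(config: SimulationConfig) -> str:
    d = dataclasses.asdict(config)
    d["kinetics"] = {
        f"{sig}:{lab}": dataclasses.asdict(kp)
        for (sig, lab), kp in config.kinetics.items()
    }
    if config.schedule is not None:
        d["schedule"] = dataclasses.asdict(config.schedule)
    return json.dumps(d, indent=2)


def config_from_json(text: str) -> SimulationConfig:
    d = json.loads(text)
    kin = {}
    for key, kp in d.pop("kinetics").items():
        sig, lab = key.rsplit(":", 1)
        kin[(sig, int(lab))] = KineticsParams(**kp)
    sched = d.pop("schedule", None)
    if sched is not None:
        sched["bouts"] = tuple(tuple(b) for b in sched["bouts"])
        sched = WorkRateSchedule(**sched)
    return SimulationConfig(schedule=sched, kinetics=kin, **d)
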