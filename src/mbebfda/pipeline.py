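"""End-to-end orchestration: raw cohort files -> QC -> uniform series ->
smoothed functional samples -> registration -> inference -> classification
-> report bundle.  Every stage's tuning values (lambda, df, gcv,
phase_ratio, seeds) are logged into the run report."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, inference, preprocess, registration, simulate
from .basis import (
    DEFAULT_LAMBDA_GRID,
    DEFAULT_OMEGA,
    FunctionalSample,
    harmonic_penalty,
    make_bspline_basis,
    smooth_sample,
)

SIGNALS = simulate.SIGNALS


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable configuration for one analysis run."""

    n_bouts: int = 4
    bout_duration_s: float = 120.0
    rest_duration_s: float = 60.0
    intensity_fraction: float = 0.8
    basis_order: int = 6
    breakpoint_spacing_s: float = 1.0
    omega: float = DEFAULT_OMEGA
    lambda_grid: list = field(default_factory=lambda: DEFAULT_LAMBDA_GRID.tolist())
    register: bool = True
    n_perm: int = 200
    n_boot: int = 500
    alpha: float = 0.05
    k_folds: int = 10
    seed: int = 0
    signals: tuple[str, ...] = SIGNALS
    include_body_mass: bool = False

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["signals"] = list(self.signals)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["signals"] = tuple(d.get("signals", SIGNALS))
        return cls(**d)


def prepare_uniform(
    meta_df: pd.DataFrame,
    series_df: pd.DataFrame,
    config: RunConfig,
    qc_rules: preprocess.QCThresholds | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict]:
    """QC-screen, interpolate and truncate the cohort.

    Returns (kept metadata, signal -> curve matrix, qc report dict); the
    curve matrices are aligned row-for-row with the metadata."""
    schedule = simulate.generate_protocol(
        max(config.n_bouts, 4),
        config.bout_duration_s,
        config.rest_duration_s,
        config.intensity_fraction,
    )
    raw = preprocess.raw_from_frame(series_df)
    if not raw:
        raise PipelineError("preprocess", "no series found in input")
    reports = preprocess.screen_cohort(raw, qc_rules)
    excluded = {pid for pid, r in reports.items() if r.excluded}

    t_end = int(round(config.n_bouts * (config.bout_duration_s + config.rest_duration_s)))
    full_end = int(max(series_df["time_s"].max(), t_end))
    by_pid_sig: dict[tuple[str, str], np.ndarray] = {}
    for r in raw:
        if r.participant_id in excluded:
            continue
        try:
            u = preprocess.interpolate_to_seconds(r, min(full_end, int(r.times_s[-1])))
            u = preprocess.truncate_to_window(u, schedule, config.n_bouts)
        except preprocess.CoverageError as e:
            excluded.add(r.participant_id)
            reports[r.participant_id] = preprocess.QCReport(
                r.participant_id, True, (f"{r.signal}:coverage",)
            )
            continue
        by_pid_sig[(r.participant_id, r.signal)] = u.values

    meta_df = meta_df[~meta_df["participant_id"].isin(excluded)].reset_index(drop=True)
    kept = [
        pid
        for pid in meta_df["participant_id"]
        if all((pid, sig) in by_pid_sig for sig in config.signals)
    ]
    meta_df = meta_df[meta_df["participant_id"].isin(kept)].reset_index(drop=True)
    matrices = {
        sig: np.vstack([by_pid_sig[(pid, sig)] for pid in meta_df["participant_id"]])
        for sig in config.signals
    }
    qc = {
        pid: {"excluded": r.excluded, "reasons": list(r.reasons)}
        for pid, r in reports.items()
    }
    return meta_df, matrices, qc


def smooth_cohort(
    meta_df: pd.DataFrame, matrices: dict[str, np.ndarray], config: RunConfig
) -> tuple[dict[str, FunctionalSample], dict]:
    t_end = config.n_bouts * (config.bout_duration_s + config.rest_duration_s)
    basis = make_bspline_basis(t_end, config.basis_order, config.breakpoint_spacing_s)
    penalty = harmonic_penalty(basis, config.omega)
    grid = np.arange(0.0, t_end + 0.5)
    samples, log = {}, {}
    for sig, Y in matrices.items():
        fs = smooth_sample(
            grid, Y, basis, penalty, np.asarray(config.lambda_grid), signal=sig,
            meta=meta_df,
        )
        samples[sig] = fs
        log[sig] = {
            "lambda": float(fs.lam[0]),
            "df": float(fs.df[0]),
            "mean_gcv": float(np.mean(fs.gcv)),
        }
    return samples, log


def analyze(
    meta_df: pd.DataFrame,
    series_df: pd.DataFrame,
    config: RunConfig,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full pipeline and return (and optionally persist) the report."""
    report: dict = {"config": json.loads(config.to_json())}
    meta_df, matrices, qc = prepare_uniform(meta_df, series_df, config)
    report["qc"] = qc
    labels = meta_df["label"].to_numpy(int)
    if min(np.sum(labels == 0), np.sum(labels == 1)) < 2:
        raise PipelineError("preprocess", "need at least 2 participants per class")

    samples, smooth_log = smooth_cohort(meta_df, matrices, config)
    report["smoothing"] = smooth_log

    if config.register:
        reg_log = {}
        for sig in list(samples):
            res = registration.register_to_mean(samples[sig])
            samples[sig] = res.registered
            reg_log[sig] = {
                "phase_ratio": res.phase_ratio,
                "mse_total": res.mse_total,
                "mse_phase": res.mse_phase,
                "mse_amp": res.mse_amp,
            }
        report["registration"] = reg_log

    coarse = np.arange(0.0, samples[config.signals[0]].basis.domain[1] + 0.5, 4.0)
    ttest_log, fanova_log = {}, {}
    for sig, fs in samples.items():
        res = inference.permutation_ttest(
            fs.subset(labels == 1),
            fs.subset(labels == 0),
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=config.seed,
            grid_s=coarse,
        )
        ttest_log[sig] = {
            "max_crit": res.max_crit,
            "reject_regions": [list(r) for r in res.reject_regions],
        }
        fres = inference.fanova(
            fs, labels, n_boot=config.n_boot, seed=config.seed, grid_s=coarse
        )
        fanova_log[sig] = fres.to_dict()
    report["ttest"] = ttest_log
    report["fanova"] = fanova_log

    specs = [
        classify.ClassifierSpec("GSAM", (sig,), ("sex", "puberty"))
        for sig in config.signals
    ] + [
        classify.ClassifierSpec(
            name,
            tuple(config.signals),
            ("sex", "puberty") + (("body_mass",) if config.include_body_mass else ()),
        )
        for name in classify.ALL_MODELS
    ]
    table = classify.run_model_battery(
        samples, meta_df, specs, k=config.k_folds, seed=config.seed
    )
    report["classification"] = table.to_dict(orient="records")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        table.to_csv(outdir / "classification.csv", index=False)
        (outdir / "run_config.json").write_text(config.to_json())
    return report
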