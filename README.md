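# mbebfda

Functional data analysis for multiple-brief-exercise-bout (MBEB) exercise
testing: predicting task failure in a ten-bout pediatric protocol from the
first four bouts of heart rate, respiratory rate, V̇O2 and V̇CO2 signals.

The package implements the full pipeline as reusable, tested components:

| Module | What it does |
| --- | --- |
| `mbebfda.simulate` | Synthetic MBEB cohorts: square-wave work-rate schedule (2-min bouts, 1-min rests), per-signal first-order on/off exponential kinetics, group-dependent amplitude shifts and bout-to-bout drift for task failures, heteroscedastic noise (RR noisiest, HR cleanest), balanced failure/completer labels. |
| `mbebfda.preprocess` | Linear interpolation to second-by-second grids, truncation to the first four bouts (720 s), QC screening (gaps, physiological range, flatlines). |
| `mbebfda.basis` | Order-6 B-spline bases (725 functions at 1-s breakpoints on [0, 720]), harmonic-acceleration roughness penalty `L = ω²D + D³`, penalized least-squares smoothing, GCV-driven λ selection. |
| `mbebfda.registration` | Continuous registration to the cross-sectional mean with monotone exponentiated-integral warps; phase/amplitude variance decomposition (`mse_phase + mse_amp = mse_total`). |
| `mbebfda.inference` | Functional permutation t-tests (pointwise Welch statistic, max-statistic familywise control) and one-way bootstrap FANOVA. |
| `mbebfda.classify` | FPCA score extraction, the generalized spectral additive classifier (spline smooths of FPC scores + linear scalar terms), six baseline classifiers, leak-free stratified k-fold CV, accuracy/precision/recall/F1. |
| `mbebfda.pipeline`, `mbebfda.cli` | End-to-end orchestration and the `mbebfda` command-line interface. |

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the release criteria (smoother/oracle
equivalence, penalty null space, GCV recovery, permutation/FANOVA
calibration and power, registration decomposition, classifier recovery,
metric identities).

## CLI

Generate a synthetic cohort (writes `series.csv`, `meta.csv` and a config
snapshot):

```bash
mbebfda simulate --n 78 --seed 1 --out cohort/
```

Run the full analysis (QC → smoothing → registration → permutation
t-tests / FANOVA → classifier battery; writes `report.json`,
`classification.csv`, `run_config.json`):

```bash
mbebfda analyze --series cohort/series.csv --meta cohort/meta.csv \
    --out report/ --seed 1
```

Useful flags: `--no-register`, `--signals HR,VO2`, `--n-perm`, `--n-boot`,
`--k-folds`, `--spacing` (breakpoint spacing in seconds; coarser is much
faster), `--config <run_config.json>`.

## Notes

- The smoothing parameter is selected per signal by minimizing the summed
  per-curve GCV `n·SSE/(n−df)²` over a log-spaced grid; ties break to the
  largest λ.
- The harmonic-acceleration frequency defaults to ω = 2π/180 rad/s (one
  cycle per bout+rest period) so protocol-frequency oscillation is never
  penalized; it is configurable.
- `body_mass` is available as a scalar covariate but off by default;
  binary sex and puberty enter as linear terms.
- All randomness funnels through explicit seeds; identical configs
  reproduce byte-identical cohorts and identical reports.
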