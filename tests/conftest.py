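import numpy as np
import pandas as pd
import pytest

from mbebfda.basis import (
    FunctionalSample,
    harmonic_penalty,
    make_bspline_basis,
    smooth_sample,
)
from mbebfda.simulate import (
    KineticsParams,
    generate_protocol,
    noise_free_trajectory,
)


@pytest.fixture(scope="session")
def protocol4():
    return generate_protocol(4, 120, 60, 0.8)


@pytest.fixture(scope="session")
def protocol10():
    return generate_protocol(10, 120, 60, 0.8)


@pytest.fixture(scope="session")
def small_basis():
    """Coarse basis on [0, 720] for fast smoothing tests."""
    return make_bspline_basis(720, 6, 30)


@pytest.fixture(scope="session")
def small_penalty(small_basis):
    return harmonic_penalty(small_basis)


def project_sample(Y, t, basis, penalty, lam=1.0, signal="HR", meta=None):
    """Light helper: smooth a value matrix at one fixed lambda."""
    return smooth_sample(t, Y, basis, penalty, np.array([lam]), signal=signal, meta=meta)


def hr_cohort_matrix(n, rng, shift=0.0, amp_sd=5.0, noise_sd=0.0, drift=0.0):
    """HR-like curves on the 0..720 s grid with participant-level amplitude
    variation; returns (t, Y)."""
    sched = generate_protocol(4, 120, 60, 0.8)
    t = np.arange(0.0, 721.0)
    rows = []
    for _ in range(n):
        amp = 70.0 + shift + rng.normal(0.0, amp_sd)
        kp = KineticsParams(80.0, float(amp), 30.0, 45.0, drift, 0.0)
        y = noise_free_trajectory(sched, kp, t)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, t.size)
        rows.append(y)
    return t, np.vstack(rows)


def make_meta(labels):
    labels = np.asarray(labels, int)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(labels.size)],
            "sex": ["F", "M"] * (labels.size // 2) + ["F"] * (labels.size % 2),
            "puberty": ["early", "late"] * (labels.size // 2)
            + ["early"] * (labels.size % 2),
            "body_mass_kg": 40.0 + np.arange(labels.size, dtype=float),
            "bouts_completed": np.where(labels == 1, 6, 10),
            "label": labels,
        }
    )


def sample_from_values(t, Y, basis, penalty, lam=1.0, labels=None, signal="HR"):
    meta = make_meta(labels) if labels is not None else None
    return smooth_sample(t, Y, basis, penalty, np.array([lam]), signal=signal, meta=meta)


@pytest.fixture(scope="session")
def grid721():
    return np.arange(0.0, 721.0)


__all__ = [
    "project_sample",
    "hr_cohort_matrix",
    "make_meta",
    "sample_from_values",
]
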