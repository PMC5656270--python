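"""Shared fixtures: small deterministic signals and the evaluation cohort.

The heavier artefacts (the 30-meal cohort, its epoch features, the
calibration probe cohort) are session-scoped so the pipeline-level tests
share one build.
"""

from __future__ import annotations

import numpy as np
import pytest

from chewmeter import (
    CohortSpec,
    SensorSignal,
    build_epoch_dataset,
    generate_alpha_probe_cohort,
    generate_cohort,
)

FS = 1000.0


@pytest.fixture
def fs() -> float:
    return FS


@pytest.fixture
def sine_signal() -> SensorSignal:
    """10 s of a unit 1.5 Hz sinusoid at 1 kHz."""
    t = np.arange(10_000) / FS
    return SensorSignal(np.sin(2 * np.pi * 1.5 * t), FS, "s1", "v1")


@pytest.fixture
def clean_spec() -> CohortSpec:
    """Degradation-free cohort conditions (exact ground-truth recovery)."""
    return CohortSpec(
        noise_sd=0.0, amp_jitter=0.0, drift_amplitude=0.0, artifact_rate=0.0, seed=0
    )


@pytest.fixture(scope="session")
def cohort():
    """The 30-meal synthetic cohort at default (10 dB bout SNR) conditions."""
    return generate_cohort(CohortSpec(seed=42))


@pytest.fixture(scope="session")
def cohort_epoch_dataset(cohort):
    """Per-subject (features, labels) for the evaluation cohort."""
    return build_epoch_dataset(cohort)


@pytest.fixture(scope="session")
def probe_cohort():
    """Calibration cohort whose error-vs-alpha curves share a 0.90 minimum."""
    return generate_alpha_probe_cohort(n_visits=20)
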