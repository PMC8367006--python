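"""Shared fixtures: scaled synthetic cohorts for pipeline-level tests.

Cohorts here use a reduced sampling rate (250 Hz or 1 kHz instead of the
study's 4 kHz) so pipeline tests stay within desk-scale time and memory;
cohort structure (class imbalance, blocked sequences, events) is unchanged.
Band-pass edges are adjusted below the reduced Nyquist accordingly.
"""

import numpy as np
import pytest

from emgweight import SimConfig, pipeline_features, simulate_cohort

SMALL_COUNTS = {f"s{i:02d}": {165: 20, 330: 27, 660: 16} for i in (1, 2, 3)}


def small_config(noise_sd=0.1, seed=7, **kwargs):
    """3-subject cohort with study-like imbalance at 250 Hz."""
    defaults = dict(
        n_subjects=3,
        class_counts={k: dict(v) for k, v in SMALL_COUNTS.items()},
        sampling_rate_hz=250.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return pipeline_features(small_cohort, high_hz=100.0)


@pytest.fixture(scope="session")
def one_subject_features():
    cfg = SimConfig(
        n_subjects=1,
        class_counts={"s01": {165: 20, 330: 27, 660: 16}},
        sampling_rate_hz=250.0,
        noise_sd=0.0,
        seed=1,
    )
    return pipeline_features(simulate_cohort(cfg), high_hz=100.0)
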