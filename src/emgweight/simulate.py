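"""Synthetic data: manifold fixtures and EMG cohorts with known ground truth.

Two kinds of generators live here. The manifold fixtures (unit sphere,
Swiss roll) are the standard benchmarks for nonlinear dimensionality
reduction. The EMG cohort simulator emulates the statistical structure of a
12-subject reach-grasp-lift study: 5 muscles sampled at 4 kHz, three object
weights (165/330/660 g) with imbalanced per-subject trial counts, a blocked
trial sequence in which the weight tends to repeat, and optional anticipatory
pre-touch activity driven by the previous trial's weight.

Generative model per trial and muscle::

    x(t) = b_m * s_m * c(t) * env(t) + noise_sd * eps(t)

where c(t) is a band-limited unit-variance Gaussian carrier (the stochastic
surface-EMG interference pattern, independent across trials), env(t) is a
sum of smooth Hann bumps (contact burst of fixed amplitude, lift/hold bump
scaled by the weight-dependent class gain, optional anticipation bump
before touch), b_m a per-muscle base gain, s_m a log-normal per-subject
gain, and eps(t) white measurement noise.

The post-touch bumps are amplitude-modulated by a contact-locked grip
tremor at a weight-specific frequency (heavier objects lower the tremor
frequency). This is the reproducible, load-dependent part of the
activation: full-wave rectification passes an amplitude modulation
linearly (E|x| = E|c| * env), so trials of the same weight share a
deterministic waveform that survives the preprocessing chain. The carrier
alone carries the label only in its variance profile, and Euclidean
neighborhoods cannot see variance-coded labels (every trial would pick the
lowest-energy trials as neighbors). The contact burst is weight-independent
while the hold bump scales with weight, so the label also survives
per-channel peak normalization (which cancels any single per-channel gain)
and is present from the first post-touch window.

Bumps start 50 ms after touch onset, emulating the electromechanical delay
between contact and the EMG burst; before touch the envelope is exactly
zero, so with ``noise_sd=0`` and anticipation off the pre-touch signal
carries no label information by construction. Touch-onset jitter is kept
small (±15 ms) so that trial-start-aligned features remain phase-coherent
within a weight class; real cohorts show larger timing variability (a
documented simplification).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .data import Cohort, EmgTrial, STUDY_CLASS_COUNTS, WEIGHT_CLASSES

__all__ = [
    "SimConfig",
    "make_sphere",
    "make_swiss_roll",
    "simulate_cohort",
    "weight_sequence",
]

#: Per-muscle base gains (arbitrary units).
MUSCLE_BASE_GAIN = np.array([1.0, 0.8, 0.9, 0.7, 0.6])
#: Per-muscle exponents of the weight scaling of the lift/hold bump; each
#: muscle's gain grows monotonically with weight at a muscle-specific rate,
#: so the cross-muscle activation pattern, not only its scale, encodes weight.
HOLD_EXPONENTS = np.array([0.5, 0.7, 0.9, 1.1, 1.3])
HOLD_BASE_AMPLITUDE = 3.0  # hold bump dominates the contact burst (amp 1)

# Envelope timing relative to touch onset (seconds). The 50 ms guard before
# any bump models electromechanical delay and keeps zero-phase filter smear
# of post-touch activity out of the pre-touch interval.
GRASP_BUMP = (0.05, 0.45)
HOLD_BUMP_START = 0.20
ANTICIPATION_BUMP = (-0.65, -0.05)

#: Contact-locked grip-tremor frequency per object weight (Hz); inertial
#: loading lowers tremor frequency, so heavier weights oscillate slower.
TREMOR_FREQ_HZ = {165: 10.0, 330: 8.0, 660: 6.0}
#: AM depth of the tremor modulation on the hold bump varies per trial
#: (grip steadiness fluctuates); weakly modulated trials of different
#: weights resemble each other, which keeps the trial neighbor graph
#: connected across classes the way overlapping real classes are.
TREMOR_DEPTH_RANGE = (0.2, 0.7)
TREMOR_DEPTH_GRASP = 0.9  # deeper modulation of the brief contact burst


def default_class_gain(n_channels: int = 5) -> dict[int, np.ndarray]:
    """Default weight -> per-muscle lift/hold amplitude multipliers."""
    exps = HOLD_EXPONENTS[:n_channels]
    return {
        w: HOLD_BASE_AMPLITUDE * (w / 330.0) ** exps for w in WEIGHT_CLASSES
    }


@dataclass
class SimConfig:
    """Configuration of the synthetic EMG cohort generator.

    Defaults mirror the study cohort: 12 subjects with the published
    per-subject class counts, 5 muscles at 4 kHz, 10 s trials (so the 8 s
    segmentation and the 0.74 s / 1.82 s event-aligned windows always fit).
    ``p_repeat`` controls the blocked design (probability the next trial
    keeps the previous weight); ``anticipation_gain`` scales pre-touch
    activity by the *previous* trial's weight, so pre-touch decodability can
    arise only through blocked repetition.
    """

    n_subjects: int = 12
    class_counts: dict[str, dict[int, int]] | None = None
    sampling_rate_hz: float = 4000.0
    trial_duration_s: float = 10.0
    n_channels: int = 5
    class_gain: dict[int, np.ndarray] | None = None
    noise_sd: float = 0.1
    subject_gain_sd: float = 0.3
    p_repeat: float = 0.5
    anticipation_gain: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.class_counts is None:
            subjects = sorted(STUDY_CLASS_COUNTS)[: self.n_subjects]
            self.class_counts = {s: dict(STUDY_CLASS_COUNTS[s]) for s in subjects}
        if len(self.class_counts) != self.n_subjects:
            raise ValueError(
                f"class_counts has {len(self.class_counts)} subjects, expected {self.n_subjects}"
            )
        if self.class_gain is None:
            self.class_gain = default_class_gain(self.n_channels)
        self.class_gain = {int(w): np.asarray(g, dtype=float) for w, g in self.class_gain.items()}
        if not 0.0 <= self.p_repeat <= 1.0:
            raise ValueError("p_repeat must be in [0, 1]")
        if self.noise_sd < 0 or self.subject_gain_sd < 0 or self.anticipation_gain < 0:
            raise ValueError("noise_sd, subject_gain_sd and anticipation_gain must be >= 0")
        gains = np.stack([self.class_gain[w] for w in sorted(self.class_gain)])
        if gains.shape[1] != self.n_channels:
            raise ValueError("class_gain vectors must have length n_channels")
        strictly_up = (np.diff(gains, axis=0) > 0).all(axis=0)
        if not strictly_up.any():
            raise ValueError(
                "class_gain must be strictly increasing in weight for at least one muscle"
            )


def make_sphere(n_points: int, seed: int) -> np.ndarray:
    """Uniform random points on the unit sphere in R^3."""
    if n_points < 4:
        raise ValueError("make_sphere requires n_points >= 4 (graph construction degenerate)")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_points, 3))
    norms = np.linalg.norm(x, axis=1)
    while (norms < 1e-12).any():  # pragma: no cover - probability ~0
        bad = norms < 1e-12
        x[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(x, axis=1)
    return x / norms[:, None]


def make_swiss_roll(n_points: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random Swiss-roll sample: 3-D points plus intrinsic (t, h) coordinates.

    Standard parameterization (t cos t, h, t sin t) with t in
    [1.5*pi, 4.5*pi] and height h in [0, 21].
    """
    if n_points < 4:
        raise ValueError("make_swiss_roll requires n_points >= 4")
    rng = np.random.default_rng(seed)
    t = 1.5 * np.pi * (1.0 + 2.0 * rng.uniform(size=n_points))
    h = 21.0 * rng.uniform(size=n_points)
    points = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
    return points, np.column_stack([t, h])


def weight_sequence(
    counts: dict[int, int], p_repeat: float, rng: np.random.Generator
) -> list[int]:
    """Blocked trial sequence matching ``counts`` exactly.

    With probability ``p_repeat`` the next trial keeps the previous weight
    (while any remain); otherwise a different weight is drawn with
    probability proportional to its remaining count. Tail trials fall back
    to whatever classes remain, so the empirical repeat frequency matches
    ``p_repeat`` closely only away from exhaustion.
    """
    remaining = {int(w): int(n) for w, n in counts.items() if n > 0}
    seq: list[int] = []
    prev: int | None = None
    total = sum(remaining.values())
    for _ in range(total):
        if prev is not None and remaining.get(prev, 0) > 0 and rng.uniform() < p_repeat:
            choice = prev
        else:
            others = {w: n for w, n in remaining.items() if w != prev and n > 0}
            pool = others if others else remaining
            ws = sorted(pool)
            p = np.array([pool[w] for w in ws], dtype=float)
            choice = int(rng.choice(ws, p=p / p.sum()))
        seq.append(choice)
        remaining[choice] -= 1
        if remaining[choice] == 0:
            del remaining[choice]
        prev = choice
    return seq


def _hann_bump(t: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Smooth sin^2 bump supported exactly on [start, stop]."""
    out = np.zeros_like(t)
    inside = (t >= start) & (t <= stop)
    out[inside] = np.sin(np.pi * (t[inside] - start) / (stop - start)) ** 2
    return out


def _carrier(rng: np.random.Generator, n_channels: int, n_samples: int, rate: float) -> np.ndarray:
    """Band-limited unit-variance Gaussian carrier per channel."""
    high = min(450.0, 0.4 * rate)
    low = min(20.0, high / 3.0)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal((n_channels, n_samples)), axis=1)
    sd = x.std(axis=1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _simulate_subject(
    config: SimConfig, subject_id: str, subject_index: int
) -> list[EmgTrial]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_index]))
    rate = config.sampling_rate_hz
    n_samples = int(round(config.trial_duration_s * rate))
    t_axis = np.arange(n_samples) / rate
    base = MUSCLE_BASE_GAIN[: config.n_channels]
    subject_gain = np.exp(rng.normal(0.0, config.subject_gain_sd, size=config.n_channels))

    weights = weight_sequence(config.class_counts[subject_id], config.p_repeat, rng)
    trials: list[EmgTrial] = []
    prev_weight: int | None = None
    for idx, w in enumerate(weights):
        led_on = rng.uniform(0.3, 0.7)
        touch = 2.0 + rng.uniform(-0.015, 0.015)  # tight, cue-locked contact
        led_off = min(touch + rng.uniform(3.5, 4.5), config.trial_duration_s)

        carrier = _carrier(rng, config.n_channels, n_samples, rate)
        grasp = _hann_bump(t_axis, touch + GRASP_BUMP[0], touch + GRASP_BUMP[1])
        hold = _hann_bump(t_axis, touch + HOLD_BUMP_START, led_off)
        gain_w = config.class_gain[w][:, None]
        # Weight-specific tremor enters as amplitude modulation of the whole
        # post-touch envelope, so full-wave rectification passes it linearly
        # (E|x| = E|c| * env) and it survives the 5 Hz high-pass.
        osc_w = np.sin(2 * np.pi * TREMOR_FREQ_HZ[w] * (t_axis - touch))
        depth = rng.uniform(*TREMOR_DEPTH_RANGE)
        env = (
            grasp * (1.0 + TREMOR_DEPTH_GRASP * osc_w)
            + gain_w * (hold * (1.0 + depth * osc_w))[None, :]
        )
        if config.anticipation_gain > 0 and prev_weight is not None:
            antic = _hann_bump(
                t_axis, touch + ANTICIPATION_BUMP[0], touch + ANTICIPATION_BUMP[1]
            )
            tremor_prev = 1.0 + depth * np.sin(
                2 * np.pi * TREMOR_FREQ_HZ[prev_weight] * (t_axis - touch)
            )
            env = env + (
                config.anticipation_gain
                * config.class_gain[prev_weight][:, None]
                * (antic * tremor_prev)[None, :]
            )
        signal = (base * subject_gain)[:, None] * carrier * env
        if config.noise_sd > 0:
            signal = signal + config.noise_sd * rng.standard_normal(signal.shape)

        trials.append(
            EmgTrial(
                subject_id=subject_id,
                trial_index=idx,
                signal=signal,
                sampling_rate_hz=rate,
                weight_label=w,
                events={"led_on": led_on, "touch_onset": touch, "led_off": led_off},
            )
        )
        prev_weight = w
    return trials


def simulate_cohort(config: SimConfig | None = None) -> Cohort:
    """Simulate a full cohort; identical configs give bit-identical cohorts."""
    config = config or SimConfig()
    trials: list[EmgTrial] = []
    for i, subject_id in enumerate(sorted(config.class_counts)):
        trials.extend(_simulate_subject(config, subject_id, i))
    return Cohort(trials)
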