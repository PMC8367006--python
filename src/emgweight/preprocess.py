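"""Preprocessing: raw trials -> fixed-length feature vectors.

The chain is full-wave rectification, per-channel peak normalization, then a
zero-phase 4th-order Butterworth band-pass (5-450 Hz at the study's 4 kHz
rate). Trials are truncated to their first 8 s and subsampled by taking
every 5th sample, yielding 5 x 8 x 800 = 32,000 features per trial at study
scale. Feature vectors are the channel-wise concatenation of the subsampled
traces, stacked into a trials x features matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .data import Cohort, EmgTrial, EVENT_NAMES

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Trials x features array with aligned labels and provenance.

    ``values[i]`` is the feature vector x_i in R^l of trial i; ``labels[i]``
    its weight in grams; ``subject_ids[i]`` its subject. ``feature_layout``
    records (n_channels, segment_s, subsample_step, post_rate_hz) so that
    l = n_channels * segment_s * post_rate_hz is reconstructible.
    """

    values: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    feature_layout: dict

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if not np.isfinite(self.values).all():
            raise ValueError("FeatureMatrix rows must be finite")
        if len(self.labels) != len(self.values) or len(self.subject_ids) != len(self.values):
            raise ValueError("labels/subject_ids misaligned with rows")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def for_subject(self, subject_id: str) -> "FeatureMatrix":
        mask = self.subject_ids == subject_id
        return FeatureMatrix(
            self.values[mask], self.labels[mask], self.subject_ids[mask], dict(self.feature_layout)
        )


def rectify(signal: np.ndarray) -> np.ndarray:
    """Full-wave rectification: elementwise absolute value."""
    signal = np.asarray(signal, dtype=np.float64)
    if not np.isfinite(signal).all():
        raise ValueError("rectify: signal contains non-finite values")
    return np.abs(signal)


def normalize(signal: np.ndarray) -> np.ndarray:
    """Divide each channel by its own per-trial maximum absolute value."""
    signal = np.asarray(signal, dtype=np.float64)
    peaks = np.max(np.abs(signal), axis=-1, keepdims=True)
    silent = np.flatnonzero(peaks.ravel() == 0)
    if silent.size:
        raise ValueError(f"normalize: silent channel(s) {silent.tolist()} (all zeros)")
    return signal / peaks


def bandpass(
    signal: np.ndarray,
    rate_hz: float,
    low_hz: float = 5.0,
    high_hz: float = 450.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied per channel.

    Zero-phase (forward-backward) filtering keeps event-aligned windows
    aligned with the underlying bursts.
    """
    nyquist = rate_hz / 2.0
    if high_hz >= nyquist:
        raise ValueError(f"bandpass: high_hz={high_hz} must be below Nyquist ({nyquist})")
    if not 0 < low_hz < high_hz:
        raise ValueError("bandpass: need 0 < low_hz < high_hz")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=np.float64), axis=-1)


def preprocess_trial(
    trial: EmgTrial,
    low_hz: float = 5.0,
    high_hz: float = 450.0,
    order: int = 4,
) -> EmgTrial:
    """Rectify, peak-normalize, then band-pass one trial."""
    out = bandpass(normalize(rectify(trial.signal)), trial.sampling_rate_hz, low_hz, high_hz, order)
    return replace(trial, signal=out, preprocessed=True)


def segment_first(trial: EmgTrial, seconds: float = 8.0) -> EmgTrial:
    """Keep the first ``seconds`` of a trial; drop events beyond the cut.

    Shorter trials are rejected rather than padded (padding would fabricate
    signal).
    """
    n_keep = int(round(seconds * trial.sampling_rate_hz))
    if trial.n_samples < n_keep:
        raise ValueError(
            f"segment_first: trial {trial.subject_id}/{trial.trial_index} lasts "
            f"{trial.duration_s:.3f} s < requested {seconds} s"
        )
    kept_events = {}
    for ev in EVENT_NAMES:
        if ev in trial.events:
            if trial.events[ev] <= seconds:
                kept_events[ev] = trial.events[ev]
            else:
                logger.info(
                    "segment_first: dropping event %s=%.3f s beyond %.3f s cut (trial %s/%d)",
                    ev, trial.events[ev], seconds, trial.subject_id, trial.trial_index,
                )
    return replace(trial, signal=trial.signal[:, :n_keep].copy(), events=kept_events)


def assemble_features(trials: list[EmgTrial], subsample_step: int = 5) -> FeatureMatrix:
    """Subsample every ``subsample_step``-th sample per channel, concatenate
    channels in channel order, and stack trials as rows."""
    if not trials:
        raise ValueError("assemble_features: empty trial list")
    first = trials[0]
    layout = (first.n_channels, first.n_samples, first.sampling_rate_hz)
    for t in trials:
        if (t.n_channels, t.n_samples, t.sampling_rate_hz) != layout:
            raise ValueError(
                f"assemble_features: trial {t.subject_id}/{t.trial_index} layout "
                f"{(t.n_channels, t.n_samples, t.sampling_rate_hz)} != {layout}"
            )
    rows = [t.signal[:, ::subsample_step].reshape(-1) for t in trials]
    return FeatureMatrix(
        values=np.vstack(rows),
        labels=np.array([t.weight_label for t in trials]),
        subject_ids=np.array([t.subject_id for t in trials]),
        feature_layout={
            "n_channels": first.n_channels,
            "segment_s": first.n_samples / first.sampling_rate_hz,
            "subsample_step": subsample_step,
            "post_rate_hz": first.sampling_rate_hz / subsample_step,
        },
    )


def pipeline_features(
    cohort: Cohort,
    segment_s: float = 8.0,
    subsample_step: int = 5,
    low_hz: float = 5.0,
    high_hz: float = 450.0,
    order: int = 4,
) -> FeatureMatrix:
    """Full preprocessing chain for a cohort: preprocess, segment, assemble."""
    processed = [
        segment_first(preprocess_trial(t, low_hz, high_hz, order), segment_s)
        for t in cohort.trials
    ]
    return assemble_features(processed, subsample_step)
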