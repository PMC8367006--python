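"""Domain types and interchange I/O for multi-channel surface-EMG trials.

The package works on reach-grasp-lift recordings: each trial is a
channel x time matrix of muscle activity with a weight label (165, 330 or
660 g) and three behavioural event markers (LED on, touch onset, LED off).
Cohorts are collections of trials across subjects, stored either in a
neutral HDF5 layout or, for tiny fixtures, as a directory of CSV files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

logger = logging.getLogger(__name__)

WEIGHT_CLASSES = (165, 330, 660)
EVENT_NAMES = ("led_on", "touch_onset", "led_off")
CHANNEL_NAMES = (
    "Anterior Deltoid",
    "Brachioradialis",
    "Flexor Digitorum",
    "Common Extensor Digitorum",
    "First Dorsal Interosseous",
)
FORMAT_VERSION = "1.0"

#: Per-subject trial counts of the 12-subject reach-grasp-lift study cohort,
#: by object weight in grams. Row sums are 220 or 221 trials per subject;
#: column sums are 840 / 1122 / 683 for a grand total of 2645 trials.
STUDY_CLASS_COUNTS: dict[str, dict[int, int]] = {
    "subject01": {165: 70, 330: 93, 660: 57},
    "subject02": {165: 70, 330: 94, 660: 57},
    "subject03": {165: 70, 330: 93, 660: 57},
    "subject04": {165: 70, 330: 94, 660: 57},
    "subject05": {165: 70, 330: 94, 660: 57},
    "subject06": {165: 70, 330: 93, 660: 56},
    "subject07": {165: 70, 330: 94, 660: 57},
    "subject08": {165: 70, 330: 93, 660: 57},
    "subject09": {165: 70, 330: 93, 660: 57},
    "subject10": {165: 70, 330: 94, 660: 57},
    "subject11": {165: 70, 330: 94, 660: 57},
    "subject12": {165: 70, 330: 93, 660: 57},
}


class ValidationError(ValueError):
    """A trial or cohort violates a structural invariant."""


class ParseError(ValueError):
    """An interchange file is missing required structure."""


@dataclass
class EmgTrial:
    """One trial's multi-channel EMG signal with label and event times.

    Parameters
    ----------
    subject_id : str
        Identifier of the recorded subject.
    trial_index : int
        Position of the trial within the subject's session (>= 0).
    signal : ndarray of shape (n_channels, n_samples)
        EMG amplitudes; arbitrary units before normalization, unitless after.
    sampling_rate_hz : float
        Sampling rate (study value: 4000 Hz).
    weight_label : int
        Object weight in grams, one of 165 / 330 / 660.
    events : dict
        Mapping of event name (``led_on``, ``touch_onset``, ``led_off``) to
        time in seconds from trial start. May be partial after segmentation.
    preprocessed : bool
        Set by the preprocessing chain; raw trials are False.
    """

    subject_id: str
    trial_index: int
    signal: np.ndarray
    sampling_rate_hz: float
    weight_label: int
    events: dict[str, float] = field(default_factory=dict)
    preprocessed: bool = False

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.validate()

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def validate(self) -> None:
        name = f"trial {self.subject_id}/{self.trial_index}"
        if self.signal.ndim != 2 or self.n_channels < 1:
            raise ValidationError(f"{name}: signal must be (n_channels, n_samples) with n_channels >= 1")
        if not np.isfinite(self.signal).all():
            raise ValidationError(f"{name}: signal contains non-finite values")
        if not self.sampling_rate_hz > 0:
            raise ValidationError(f"{name}: sampling_rate_hz must be positive")
        if int(self.weight_label) not in WEIGHT_CLASSES:
            raise ValidationError(
                f"{name}: weight_label {self.weight_label!r} not in {WEIGHT_CLASSES}"
            )
        unknown = set(self.events) - set(EVENT_NAMES)
        if unknown:
            raise ValidationError(f"{name}: unknown event names {sorted(unknown)}")
        # Ordering among the events that are present, then within duration.
        times = [self.events[e] for e in EVENT_NAMES if e in self.events]
        for t in times:
            if not (0.0 <= t <= self.duration_s + 1e-12):
                raise ValidationError(f"{name}: event time {t} outside [0, {self.duration_s}]")
        if any(b < a - 1e-12 for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"{name}: events must satisfy led_on <= touch_onset <= led_off, got {self.events}"
            )

    def event_sample(self, name: str) -> int:
        """Sample index of an event, rounding half-up at the sampling rate."""
        t = self.events[name]
        return int(np.floor(t * self.sampling_rate_hz + 0.5))


@dataclass
class Cohort:
    """Ordered collection of :class:`EmgTrial` across subjects.

    Trial order within each subject is preserved (the blocked-design analyses
    depend on it). Subject order follows first appearance in ``trials``.
    """

    trials: list[EmgTrial]

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.subject_id, None)
        return list(seen)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def subject_trials(self, subject_id: str) -> list[EmgTrial]:
        return [t for t in self.trials if t.subject_id == subject_id]

    @property
    def per_subject_class_counts(self) -> dict[str, dict[int, int]]:
        counts: dict[str, dict[int, int]] = {}
        for t in self.trials:
            sub = counts.setdefault(t.subject_id, {w: 0 for w in WEIGHT_CLASSES})
            sub[int(t.weight_label)] += 1
        return counts

    def validate(self) -> None:
        for t in self.trials:
            t.validate()


def imbalance_ratio(counts: dict[int, int]) -> float:
    """Smallest class count divided by the largest.

    Motivates F1 over raw accuracy: the study cohort's worst per-subject
    ratio is 0.61. All counts must be positive.
    """
    values = list(counts.values())
    if not values:
        raise ValueError("imbalance_ratio: empty class-count mapping")
    if any(v <= 0 for v in values):
        raise ValueError(f"imbalance_ratio undefined for empty class: {counts}")
    return min(values) / max(values)


# --------------------------------------------------------------------------
# HDF5 interchange layout:
#   /subjects/<id>/trials/<idx>  dataset [n_channels, n_samples], float64
#       attrs: sampling_rate_hz, weight_label, led_on_s, touch_onset_s,
#              led_off_s (event attrs present only if the event is)
#   root attrs: format_version, channel_names, subject_order
# --------------------------------------------------------------------------

def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to the package's HDF5 layout (lossless round-trip)."""
    cohort.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["channel_names"] = list(CHANNEL_NAMES)
        f.attrs["subject_order"] = cohort.subjects
        subjects = f.create_group("subjects")
        for sid in cohort.subjects:
            trials = subjects.create_group(sid).create_group("trials")
            for t in cohort.subject_trials(sid):
                d = trials.create_dataset(str(t.trial_index), data=t.signal)
                d.attrs["sampling_rate_hz"] = float(t.sampling_rate_hz)
                d.attrs["weight_label"] = int(t.weight_label)
                d.attrs["preprocessed"] = bool(t.preprocessed)
                for ev in EVENT_NAMES:
                    if ev in t.events:
                        d.attrs[f"{ev}_s"] = float(t.events[ev])


def _read_h5(path: Path) -> Cohort:
    trials: list[EmgTrial] = []
    with h5py.File(path, "r") as f:
        if "subjects" not in f:
            raise ParseError(f"{path}: missing required group 'subjects'")
        order = list(f.attrs.get("subject_order", sorted(f["subjects"])))
        for sid in order:
            grp = f["subjects"][sid]
            if "trials" not in grp:
                raise ParseError(f"{path}: subject {sid!r} missing group 'trials'")
            tgrp = grp["trials"]
            for idx in sorted(tgrp, key=int):
                d = tgrp[idx]
                for attr in ("sampling_rate_hz", "weight_label"):
                    if attr not in d.attrs:
                        raise ParseError(
                            f"{path}: trial {sid}/{idx} missing required attribute {attr!r}"
                        )
                events = {
                    ev: float(d.attrs[f"{ev}_s"]) for ev in EVENT_NAMES if f"{ev}_s" in d.attrs
                }
                trials.append(
                    EmgTrial(
                        subject_id=str(sid),
                        trial_index=int(idx),
                        signal=d[()],
                        sampling_rate_hz=float(d.attrs["sampling_rate_hz"]),
                        weight_label=int(d.attrs["weight_label"]),
                        events=events,
                        preprocessed=bool(d.attrs.get("preprocessed", False)),
                    )
                )
    return Cohort(trials)


# CSV fallback: one <subject>_<index>.csv per trial (one column per channel)
# plus a single metadata.json sidecar holding the per-trial attributes.

def write_cohort_csv(cohort: Cohort, directory: str | Path) -> None:
    cohort.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta: dict[str, dict] = {}
    for t in cohort.trials:
        fname = f"{t.subject_id}_{t.trial_index:04d}.csv"
        np.savetxt(directory / fname, t.signal.T, delimiter=",")
        meta[fname] = {
            "subject_id": t.subject_id,
            "trial_index": t.trial_index,
            "sampling_rate_hz": t.sampling_rate_hz,
            "weight_label": int(t.weight_label),
            "events": t.events,
            "preprocessed": t.preprocessed,
        }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1))


def _read_csv_dir(directory: Path) -> Cohort:
    meta_path = directory / "metadata.json"
    if not meta_path.exists():
        raise ParseError(f"{directory}: missing sidecar metadata.json")
    meta = json.loads(meta_path.read_text())
    trials = []
    for fname, m in meta.items():
        table = np.loadtxt(directory / fname, delimiter=",", ndmin=2)
        trials.append(
            EmgTrial(
                subject_id=m["subject_id"],
                trial_index=int(m["trial_index"]),
                signal=table.T,  # columns are channels
                sampling_rate_hz=float(m["sampling_rate_hz"]),
                weight_label=int(m["weight_label"]),
                events={k: float(v) for k, v in m["events"].items()},
                preprocessed=bool(m.get("preprocessed", False)),
            )
        )
    trials.sort(key=lambda t: (t.subject_id, t.trial_index))
    return Cohort(trials)


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort from the HDF5 layout or the CSV-directory fallback."""
    path = Path(path)
    cohort = _read_csv_dir(path) if path.is_dir() else _read_h5(path)
    cohort.validate()
    return cohort
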