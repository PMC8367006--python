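"""Event-aligned sliding-window decoding.

Runs the embedding + classification pipeline inside short windows tiled
around touch onset: by default 100 ms windows stepped by 40 ms over the
0.74 s before and 1.82 s after touch, the minimum spans a cohort can
guarantee around the event. Each window offset gets an independent
pipeline run (graph, embedding, Nystrom extension, classifier); per-window
macro F1 is aggregated as mean +/- SE across subjects. 100 ms is the
connectivity floor: narrower windows disconnect the neighbor graph, and the
configuration rejects them up front.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from .data import Cohort, EmgTrial
from .evaluate import ClassifierSpec, EmbeddingSpec, classify, f1_scores
from .manifold import GraphConnectivityError, SingularExtensionError

logger = logging.getLogger(__name__)

MIN_WINDOW_S = 0.100


@dataclass
class WindowConfig:
    """Sliding-window geometry plus the per-window pipeline configuration."""

    width_s: float = 0.100
    step_s: float = 0.040
    pre_touch_span_s: float = 0.74
    post_touch_span_s: float = 1.82
    subsample_step: int = 5
    embedding: EmbeddingSpec = field(
        default_factory=lambda: EmbeddingSpec(kind="le", n_components=120, n_neighbors=8)
    )
    classifier: ClassifierSpec = field(default_factory=lambda: ClassifierSpec(kind="knn", knn_k=8))

    def __post_init__(self):
        if self.width_s < MIN_WINDOW_S - 1e-12:
            raise GraphConnectivityError(
                f"window width {self.width_s * 1000:.0f} ms is below the 100 ms "
                "connectivity floor: narrower windows leave the neighbor graph "
                "disconnected"
            )
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")
        if min(self.pre_touch_span_s, self.post_touch_span_s) <= self.width_s:
            raise ValueError("pre/post spans must exceed the window width")

    def offsets(self) -> tuple[np.ndarray, list[str]]:
        """Window start offsets relative to touch onset, with segment tags.

        Left-aligned tiling: pre-touch windows start at -pre_span,
        -pre_span + step, ... while they end at or before touch; post-touch
        windows start at 0, step, ... while they end within the post span.
        Partial last windows are dropped.
        """
        n_pre = int(np.floor((self.pre_touch_span_s - self.width_s) / self.step_s + 1e-9)) + 1
        pre = -self.pre_touch_span_s + self.step_s * np.arange(n_pre)
        n_post = int(np.floor((self.post_touch_span_s - self.width_s) / self.step_s + 1e-9)) + 1
        post = self.step_s * np.arange(n_post)
        offsets = np.concatenate([pre, post])
        tags = ["pre_touch"] * n_pre + ["post_touch"] * n_post
        return offsets, tags


@dataclass
class WindowSeries:
    """Per-window decoding results aggregated across subjects."""

    offsets: np.ndarray  # window starts, seconds relative to touch onset
    tags: list[str]  # pre_touch / post_touch per window
    per_subject_f1: np.ndarray  # (n_windows, n_subjects); NaN where failed
    subjects: list[str]
    failed: np.ndarray  # bool per (window, subject)

    @property
    def mean_f1(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.per_subject_f1, axis=1)

    @property
    def se_f1(self) -> np.ndarray:
        ok = np.sum(~self.failed, axis=1)
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(self.per_subject_f1, axis=1, ddof=1)
        return sd / np.sqrt(np.maximum(ok, 1))

    def segment_mean(self, tag: str) -> float:
        mask = np.array([t == tag for t in self.tags])
        return float(np.nanmean(self.mean_f1[mask]))

    @property
    def n_failed(self) -> int:
        return int(self.failed.sum())


def extract_windows(trial: EmgTrial, config: WindowConfig) -> tuple[np.ndarray, np.ndarray]:
    """Slice one preprocessed trial into event-aligned feature vectors.

    Returns (offsets, matrix) where row i of the matrix is the
    channel-concatenated, subsampled content of the window starting at
    ``offsets[i]`` seconds relative to touch onset — exactly the assembly
    used by the full-trial pipeline, at window scale.
    """
    if "touch_onset" not in trial.events:
        raise ValueError(f"trial {trial.subject_id}/{trial.trial_index} lacks touch_onset")
    rate = trial.sampling_rate_hz
    touch = trial.events["touch_onset"]
    offsets, _ = config.offsets()
    if touch - config.pre_touch_span_s < 0 or touch + config.post_touch_span_s > trial.duration_s:
        raise ValueError(
            f"trial {trial.subject_id}/{trial.trial_index} does not span "
            f"[-{config.pre_touch_span_s}, +{config.post_touch_span_s}] s around touch"
        )
    width_n = int(round(config.width_s * rate))
    rows = []
    for off in offsets:
        start = int(np.floor((touch + off) * rate + 0.5))
        seg = trial.signal[:, start : start + width_n]
        rows.append(seg[:, :: config.subsample_step].reshape(-1))
    return offsets, np.vstack(rows)


def windowed_decoding(
    cohort: Cohort, config: WindowConfig | None = None, seed: int = 0
) -> WindowSeries:
    """Per-window embedding + classification across a preprocessed cohort.

    For each subject a single stratified 90/10 split is drawn and reused at
    every offset (so the time course is measured on a fixed test set); the
    embedding is re-fit independently per window. The embedding dimension is
    clamped to n_train - 2 where the trial count is small. Windows whose
    neighbor graph is disconnected are marked failed, not silently skipped.
    """
    config = config or WindowConfig()
    offsets, tags = config.offsets()
    subjects = Cohort(cohort.trials).subjects
    n_w = len(offsets)
    per_subject = np.full((n_w, len(subjects)), np.nan)
    failed = np.zeros((n_w, len(subjects)), dtype=bool)

    for j, sid in enumerate(subjects):
        trials = cohort.subject_trials(sid)
        if not all(t.preprocessed for t in trials):
            raise ValueError(f"windowed_decoding: subject {sid} has unpreprocessed trials")
        y = np.array([t.weight_label for t in trials])
        stacks = np.stack([extract_windows(t, config)[1] for t in trials])  # (trials, windows, f)
        sss = StratifiedShuffleSplit(n_splits=1, test_size=0.1, random_state=seed)
        train_idx, test_idx = next(sss.split(stacks[:, 0, :], y))
        m = min(config.embedding.n_components, len(train_idx) - 2)
        spec = replace(config.embedding, n_components=m)
        for i in range(n_w):
            X = stacks[:, i, :]
            try:
                emb = spec.build()
                train_coords = emb.fit_transform(X[train_idx], y[train_idx])
                test_coords = emb.transform(X[test_idx])
                pred = classify(train_coords, y[train_idx], test_coords, config.classifier)
                per_subject[i, j] = f1_scores(y[test_idx], pred)["macro_f1"]
            except (GraphConnectivityError, SingularExtensionError) as exc:
                logger.warning("window %.3f s failed for subject %s: %s", offsets[i], sid, exc)
                failed[i, j] = True
    return WindowSeries(
        offsets=offsets, tags=tags, per_subject_f1=per_subject,
        subjects=subjects, failed=failed,
    )
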