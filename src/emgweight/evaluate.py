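"""Classification and evaluation on embedded EMG features.

Implements the per-subject protocol of the pipeline: a stratified 90/10
train/test split, hyperparameter selection by stratified 10-fold
cross-validation on the training set only, a final embedding fit on the
full training set, Nystrom (or projection) extension of the held-out
trials, and per-class / macro F1 scoring. Also provides the cross-method
repeated-measures statistics used to compare embeddings and classifiers.

k-NN is implemented here directly (Euclidean majority vote with
deterministic tie-breaking); SVMs and Random Forests are scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

from .manifold import GraphConnectivityError, SingularExtensionError, make_embedder
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Specs and reports
# ---------------------------------------------------------------------------

@dataclass
class ClassifierSpec:
    """Classifier choice and hyperparameters (study defaults)."""

    kind: str = "knn"  # knn | linear_svm | rbf_svm | random_forest
    knn_k: int = 8
    svm_C: float = 32.0
    svm_gamma: float = 0.01
    rf_trees: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("knn", "linear_svm", "rbf_svm", "random_forest"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if min(self.knn_k, self.svm_C, self.svm_gamma, self.rf_trees) <= 0:
            raise ValueError("classifier hyperparameters must be positive")


@dataclass
class EmbeddingSpec:
    """Dimensionality-reduction choice: method, dimension, graph parameters."""

    kind: str = "le"  # le | pca | lda | lle | isomap
    n_components: int = 10
    n_neighbors: int = 8
    weights: str = "simple"
    sigma: float = 10.0
    seed: int = 0

    def build(self):
        return make_embedder(
            self.kind, self.n_components, self.n_neighbors,
            self.weights, self.sigma, random_state=self.seed,
        )


@dataclass
class Protocol:
    """Train/test and cross-validation protocol parameters."""

    test_fraction: float = 0.1
    n_folds: int = 10
    seed: int = 0


@dataclass
class SubjectReport:
    subject_id: str
    per_class: dict
    macro_f1: float
    macro_precision: float
    macro_recall: float
    n_train: int
    n_test: int
    test_fraction: float
    n_folds: int
    chosen: EmbeddingSpec | None = None
    audit: list = field(default_factory=list)


@dataclass
class EvalReport:
    """Per-subject reports with the across-subject mean and standard error."""

    subjects: list[SubjectReport]

    @property
    def macro_f1s(self) -> np.ndarray:
        return np.array([r.macro_f1 for r in self.subjects])

    @property
    def mean_f1(self) -> float:
        return float(self.macro_f1s.mean())

    @property
    def se_f1(self) -> float:
        s = self.macro_f1s
        return float(s.std(ddof=1) / np.sqrt(len(s))) if len(s) > 1 else 0.0


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def f1_scores(y_true, y_pred, classes=None) -> dict:
    """One-vs-rest precision/recall/F1 per class plus unweighted macro means.

    F1 is the harmonic mean 2 P R / (P + R); a class absent from both the
    true and predicted labels has no defined score and is excluded from the
    macro average (with a log note).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("f1_scores: label sequences must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    per_class = {}
    excluded = []
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        if tp + fp + fn == 0:
            excluded.append(c)
            continue
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[c] = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1,
        }
    if excluded:
        logger.info("f1_scores: classes %s absent from truth and predictions; "
                    "excluded from macro average", excluded)
    if not per_class:
        raise ValueError("f1_scores: no class present in either label sequence")
    return {
        "per_class": per_class,
        "macro_precision": float(np.mean([v["precision"] for v in per_class.values()])),
        "macro_recall": float(np.mean([v["recall"] for v in per_class.values()])),
        "macro_f1": float(np.mean([v["f1"] for v in per_class.values()])),
        "excluded": excluded,
    }


def chance_band(
    labels, n_permutations: int = 200, seed: int = 0, quantiles=(2.5, 97.5)
) -> tuple[float, float]:
    """Macro-F1 band attainable by label-independent predictors.

    Monte-Carlo permutations of the true labels give the central part of the
    null distribution; the constant per-class predictors (the degenerate
    label-independent strategies a tie-breaking classifier can collapse to)
    are folded into the band edges.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    scores = [
        f1_scores(labels, rng.permutation(labels))["macro_f1"] for _ in range(n_permutations)
    ]
    constant = [
        f1_scores(labels, np.full_like(labels, c))["macro_f1"] for c in np.unique(labels)
    ]
    lo = min(float(np.percentile(scores, quantiles[0])), min(constant))
    hi = max(float(np.percentile(scores, quantiles[1])), max(constant))
    return lo, hi


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def knn_predict(train_X, train_y, test_X, k: int) -> np.ndarray:
    """Euclidean k-NN majority vote.

    Vote ties are broken by the smallest summed distance to the tied label's
    neighbors among the k, then by the lower label value.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    test_X = np.atleast_2d(np.asarray(test_X, dtype=np.float64))
    train_y = np.asarray(train_y)
    if len(train_X) < k:
        raise ValueError(f"knn_predict: k={k} exceeds {len(train_X)} training points")
    d = cdist(test_X, train_X)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    out = []
    for i in range(len(test_X)):
        idx = order[i]
        labels, counts = np.unique(train_y[idx], return_counts=True)
        best = labels[counts == counts.max()]
        if len(best) > 1:
            sums = {
                lab: d[i, idx[train_y[idx] == lab]].sum() for lab in best
            }
            smallest = min(sums.values())
            best = sorted(lab for lab, s in sums.items() if s <= smallest + 1e-15)
        out.append(best[0])
    return np.array(out)


def classify(train_X, train_y, test_X, spec: ClassifierSpec) -> np.ndarray:
    """Predict test labels with the requested classifier."""
    if spec.kind == "knn":
        return knn_predict(train_X, train_y, test_X, spec.knn_k)
    if spec.kind == "linear_svm":
        est = SVC(kernel="linear", C=spec.svm_C, random_state=spec.seed)
    elif spec.kind == "rbf_svm":
        est = SVC(kernel="rbf", C=spec.svm_C, gamma=spec.svm_gamma, random_state=spec.seed)
    else:
        est = RandomForestClassifier(n_estimators=spec.rf_trees, random_state=spec.seed)
    return est.fit(np.asarray(train_X), np.asarray(train_y)).predict(np.asarray(test_X))


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------

def _embed_split(values, labels, train_idx, test_idx, embed_spec: EmbeddingSpec):
    """Fit the embedding on the training rows only; extend the test rows."""
    emb = embed_spec.build()
    train_coords = emb.fit_transform(values[train_idx], labels[train_idx])
    test_coords = emb.transform(values[test_idx])
    return train_coords, test_coords


def _cv_score(values, labels, embed_spec, clf_spec, n_folds, seed, audit=None):
    """Mean CV macro-F1 of one hyperparameter cell on the given rows."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, va in skf.split(values, labels):
        if audit is not None:
            audit.append(("cv_fold", tuple(tr), tuple(va)))
        tr_c, va_c = _embed_split(values, labels, tr, va, embed_spec)
        pred = classify(tr_c, labels[tr], va_c, clf_spec)
        scores.append(f1_scores(labels[va], pred)["macro_f1"])
    return float(np.mean(scores))


@dataclass
class GridResult:
    cells: list[dict]
    best: EmbeddingSpec
    best_score: float
    n_failed: int


def grid_search(
    features: FeatureMatrix,
    embed_spec: EmbeddingSpec,
    clf_spec: ClassifierSpec,
    grid: dict | None = None,
    protocol: Protocol | None = None,
    audit: list | None = None,
) -> GridResult:
    """Exhaustive CV grid search over (n_neighbors, sigma, m).

    ``grid`` maps any of ``n_neighbors`` / ``sigma`` / ``n_components`` to
    value lists; missing axes stay at the ``embed_spec`` value. Ties go to
    the smaller embedding dimension, then fewer neighbors, then smaller
    sigma. Cells whose neighbor graph is disconnected are recorded as
    failed and excluded from the argmax.
    """
    protocol = protocol or Protocol()
    grid = grid or {}
    axis_m = list(grid.get("n_components", [embed_spec.n_components]))
    axis_k = list(grid.get("n_neighbors", [embed_spec.n_neighbors]))
    axis_s = list(grid.get("sigma", [embed_spec.sigma]))
    if not (axis_m and axis_k and axis_s):
        raise ValueError("grid_search: empty grid axis")
    cells = []
    for m in axis_m:
        for k in axis_k:
            for s in axis_s:
                cell_spec = replace(embed_spec, n_components=m, n_neighbors=k, sigma=s)
                cell = {"n_components": m, "n_neighbors": k, "sigma": s}
                try:
                    cell["score"] = _cv_score(
                        features.values, features.labels, cell_spec, clf_spec,
                        protocol.n_folds, protocol.seed, audit,
                    )
                    cell["failed"] = False
                except (GraphConnectivityError, SingularExtensionError, ValueError) as exc:
                    logger.info("grid cell %s failed: %s", cell, exc)
                    cell["score"] = np.nan
                    cell["failed"] = True
                cells.append(cell)
    ok = [c for c in cells if not c["failed"]]
    if not ok:
        raise RuntimeError("grid_search: every grid cell failed")
    best = max(
        ok, key=lambda c: (c["score"], -c["n_components"], -c["n_neighbors"], -c["sigma"])
    )
    return GridResult(
        cells=cells,
        best=replace(embed_spec, n_components=best["n_components"],
                     n_neighbors=best["n_neighbors"], sigma=best["sigma"]),
        best_score=best["score"],
        n_failed=len(cells) - len(ok),
    )


def evaluate_subject(
    features: FeatureMatrix,
    embed_spec: EmbeddingSpec,
    clf_spec: ClassifierSpec,
    protocol: Protocol | None = None,
    grid: dict | None = None,
) -> SubjectReport:
    """Run the full per-subject protocol on one subject's feature matrix.

    The audit log records which row indices each stage read; held-out test
    rows appear only in the final scoring entry, never in hyperparameter
    selection (no-leakage invariant).
    """
    protocol = protocol or Protocol()
    y = features.labels
    if len(y) < 20:
        raise ValueError(f"evaluate_subject: need >= 20 trials, got {len(y)}")
    subjects = np.unique(features.subject_ids)
    if len(subjects) != 1:
        raise ValueError(f"evaluate_subject: expected one subject, got {list(subjects)}")
    audit: list = []
    sss = StratifiedShuffleSplit(
        n_splits=1, test_size=protocol.test_fraction, random_state=protocol.seed
    )
    train_idx, test_idx = next(sss.split(features.values, y))
    audit.append(("split", tuple(train_idx), tuple(test_idx)))

    chosen = embed_spec
    if grid:
        train_features = FeatureMatrix(
            features.values[train_idx], y[train_idx],
            features.subject_ids[train_idx], dict(features.feature_layout),
        )
        chosen = grid_search(train_features, embed_spec, clf_spec, grid, protocol, audit).best

    audit.append(("final_fit", tuple(train_idx), ()))
    train_coords, test_coords = _embed_split(features.values, y, train_idx, test_idx, chosen)
    pred = classify(train_coords, y[train_idx], test_coords, clf_spec)
    audit.append(("score", (), tuple(test_idx)))
    scores = f1_scores(y[test_idx], pred)
    return SubjectReport(
        subject_id=str(subjects[0]),
        per_class=scores["per_class"],
        macro_f1=scores["macro_f1"],
        macro_precision=scores["macro_precision"],
        macro_recall=scores["macro_recall"],
        n_train=len(train_idx),
        n_test=len(test_idx),
        test_fraction=protocol.test_fraction,
        n_folds=protocol.n_folds,
        chosen=chosen,
        audit=audit,
    )


def evaluate_cohort(
    features: FeatureMatrix,
    embed_spec: EmbeddingSpec,
    clf_spec: ClassifierSpec,
    protocol: Protocol | None = None,
    grid: dict | None = None,
) -> EvalReport:
    """Per-subject evaluation across a cohort-level feature matrix."""
    reports = []
    for sid in dict.fromkeys(features.subject_ids.tolist()):
        reports.append(
            evaluate_subject(features.for_subject(sid), embed_spec, clf_spec, protocol, grid)
        )
    return EvalReport(reports)


# ---------------------------------------------------------------------------
# Cross-method statistics
# ---------------------------------------------------------------------------

def compare_methods(scores: np.ndarray, method_names: list[str] | None = None) -> dict:
    """One-way repeated-measures ANOVA across methods with subjects as blocks,
    pairwise paired t-tests, and Shapiro-Wilk checks on pairwise differences.

    ``scores`` is a complete (n_subjects x n_methods) matrix; missing cells
    are an error (no imputation).
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] < 3 or scores.shape[1] < 2:
        raise ValueError("compare_methods: need >= 3 subjects and >= 2 methods")
    if not np.isfinite(scores).all():
        raise ValueError("compare_methods: missing cells are not allowed")
    n_sub, n_meth = scores.shape
    names = method_names or [f"method{j}" for j in range(n_meth)]

    grand = scores.mean()
    ss_method = n_sub * np.sum((scores.mean(axis=0) - grand) ** 2)
    ss_subject = n_meth * np.sum((scores.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((scores - grand) ** 2)
    ss_error = ss_total - ss_method - ss_subject
    df_method = n_meth - 1
    df_error = (n_meth - 1) * (n_sub - 1)
    if ss_method <= 1e-12 * max(ss_total, 1.0):
        F = 0.0  # no method effect at all (identical columns up to offsets)
    elif ss_error > 0:
        F = (ss_method / df_method) / (ss_error / df_error)
    else:
        F = np.inf
    p = float(stats.f.sf(F, df_method, df_error))

    pairwise = {}
    shapiro = {}
    for a in range(n_meth):
        for b in range(a + 1, n_meth):
            key = (names[a], names[b])
            t, tp = stats.ttest_rel(scores[:, a], scores[:, b])
            pairwise[key] = {"t": float(t), "p": float(tp)}
            diff = scores[:, a] - scores[:, b]
            if np.ptp(diff) > 0:
                w, wp = stats.shapiro(diff)
                shapiro[key] = {"W": float(w), "p": float(wp)}
            else:
                shapiro[key] = {"W": np.nan, "p": np.nan}
    return {
        "anova": {"F": float(F), "df": (df_method, df_error), "p": p,
                  "ss_method": float(ss_method), "ss_subject": float(ss_subject),
                  "ss_error": float(ss_error)},
        "pairwise_t": pairwise,
        "shapiro": shapiro,
    }
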