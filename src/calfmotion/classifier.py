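"""Boosted-tree behaviour classification, evaluation and feature ranking.

Multi-class classification of postures (lying/standing) and behaviours
(7-state ethogram) with an AdaBoost ensemble of depth-limited decision
trees, evaluated by stratified 5-fold cross-validation with per-class
confusion-derived metrics (accuracy, specificity, recall, precision,
F-score) plus Cohen's kappa.  Also provides ReliefF feature ranking and
the sampling-frequency degradation study (100 Hz vs 50/20/10/4 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .balancing import BalanceSpec, balance
from .features import FeatureCatalogue, build_feature_frame, default_catalogue
from .signal_core import ImuSeries, LabelTrack, downsample

METRIC_NAMES = ("accuracy", "specificity", "recall", "precision", "f_score")


@dataclass
class EnsembleParams:
    """AdaBoost-over-trees hyperparameters.

    The weak learner is a CART tree limited to ``max_splits`` internal
    splits (``max_leaf_nodes = max_splits + 1``) with ``min_leaf_size``
    samples per leaf.  Boosting is the multi-class SAMME scheme.
    """

    n_learners: int = 100
    min_leaf_size: int = 5
    max_splits: int = 20
    learning_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")
        if self.min_leaf_size < 1:
            raise ValueError("min_leaf_size must be >= 1")
        if self.max_splits < 1:
            raise ValueError("max_splits must be >= 1")

    def build(self) -> AdaBoostClassifier:
        tree = DecisionTreeClassifier(
            min_samples_leaf=self.min_leaf_size,
            max_leaf_nodes=self.max_splits + 1,
            random_state=self.seed,
        )
        return AdaBoostClassifier(
            estimator=tree,
            n_estimators=self.n_learners,
            learning_rate=self.learning_rate,
            random_state=self.seed,
        )


def train(X: np.ndarray, y: np.ndarray, params: EnsembleParams) -> AdaBoostClassifier:
    """Fit the boosted ensemble; deterministic under ``params.seed``."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"training requires >= 2 classes, got only {classes.tolist()}"
        )
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    model = params.build()
    model.fit(X, y)
    return model


# ---------------------------------------------------------------------------
# Confusion-matrix metrics.


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be square and match classes")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_labels(
        cls, y_true: Sequence, y_pred: Sequence, classes: Sequence[str] | None = None
    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        classes = list(classes)
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        return cls(counts, classes)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("cannot pool confusion matrices over different classes")
        return ConfusionMatrix(self.counts + other.counts, self.classes)


@dataclass
class PerformanceReport:
    """Per-class and overall confusion-derived metrics.

    Per-class values are one-vs-rest; ``macro_*`` are unweighted means of
    the per-class values; ``kappa`` is Cohen's chance-corrected agreement.
    ``flags`` lists '<class>:<metric>' entries whose denominator was zero
    (the value is reported as 0 in that case).
    """

    per_class: dict[str, dict[str, float]]
    overall_accuracy: float
    macro: dict[str, float]
    kappa: float
    flags: list[str] = field(default_factory=list)


def metrics_from_confusion(cm: ConfusionMatrix) -> PerformanceReport:
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []

    def safe_div(num: float, den: float, tag: str) -> float:
        if den == 0:
            flags.append(tag)
            return 0.0
        return num / den

    per_class: dict[str, dict[str, float]] = {}
    for i, c in enumerate(cm.classes):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        recall = safe_div(tp, tp + fn, f"{c}:recall")
        precision = safe_div(tp, tp + fp, f"{c}:precision")
        specificity = safe_div(tn, tn + fp, f"{c}:specificity")
        accuracy = (tp + tn) / total
        f_score = safe_div(2 * precision * recall, precision + recall, f"{c}:f_score")
        per_class[c] = {
            "accuracy": accuracy,
            "specificity": specificity,
            "recall": recall,
            "precision": precision,
            "f_score": f_score,
        }
    overall_accuracy = counts.trace() / total
    macro = {
        m: float(np.mean([per_class[c][m] for c in cm.classes])) for m in METRIC_NAMES
    }
    p_o = overall_accuracy
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / total**2
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return PerformanceReport(per_class, float(overall_accuracy), macro, float(kappa), flags)


def _mean_reports(reports: list[PerformanceReport]) -> PerformanceReport:
    classes = list(reports[0].per_class)
    per_class = {
        c: {m: float(np.mean([r.per_class[c][m] for r in reports])) for m in METRIC_NAMES}
        for c in classes
    }
    macro = {m: float(np.mean([r.macro[m] for r in reports])) for m in METRIC_NAMES}
    flags = sorted({f for r in reports for f in r.flags})
    return PerformanceReport(
        per_class,
        float(np.mean([r.overall_accuracy for r in reports])),
        macro,
        float(np.mean([r.kappa for r in reports])),
        flags,
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    params: EnsembleParams,
    k: int = 5,
    seed: int = 0,
) -> tuple[PerformanceReport, ConfusionMatrix]:
    """Stratified k-fold evaluation.

    Every sample is tested exactly once.  The report is the mean of the
    per-fold metric values; the pooled confusion matrix (summed over held-out
    folds) is returned alongside for count-level audits.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    counts = pd.Series(y).value_counts()
    thin = counts[counts < k]
    if not thin.empty:
        raise ValueError(
            f"class(es) {thin.index.tolist()} have fewer than k={k} samples"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports = []
    pooled: ConfusionMatrix | None = None
    for train_idx, test_idx in skf.split(X, y):
        model = train(X[train_idx], y[train_idx], params)
        pred = model.predict(X[test_idx])
        cm = ConfusionMatrix.from_labels(y[test_idx], pred, classes)
        fold_reports.append(metrics_from_confusion(cm))
        pooled = cm if pooled is None else pooled + cm
    assert pooled is not None
    return _mean_reports(fold_reports), pooled


# ---------------------------------------------------------------------------
# ReliefF feature ranking.


def relieff_rank(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 10,
    n_iterations: int | None = None,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """ReliefF feature weights: reward features that separate near-misses,
    penalise features that separate near-hits.

    Features are min-max scaled to [0, 1] internally; neighbourhoods use
    the Manhattan distance on the scaled features.  With ``n_iterations``
    None every sample serves as an anchor (deterministic); otherwise a
    seeded random subset of anchors is used.  Miss contributions are
    weighted by the class prior among the non-anchor classes.  Weights lie
    in [-1, 1]; a constant feature receives weight 0.

    Returns a DataFrame (feature, weight, rank) sorted by descending weight.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, m = X.shape
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(m)]
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("ReliefF requires >= 2 classes")

    span = X.max(axis=0) - X.min(axis=0)
    nonconst = span > 0
    Xs = np.zeros_like(X)
    Xs[:, nonconst] = (X[:, nonconst] - X.min(axis=0)[nonconst]) / span[nonconst]

    rng = np.random.default_rng(seed)
    if n_iterations is None or n_iterations >= n:
        anchors = np.arange(n)
    else:
        anchors = rng.choice(n, size=n_iterations, replace=False)

    priors = np.bincount(y_idx, minlength=len(classes)) / n
    # Full pairwise Manhattan distances; datasets here are post-balancing
    # (hundreds of windows), so O(n^2 m) is affordable.
    D = np.abs(Xs[:, None, :] - Xs[None, :, :]).sum(axis=2)
    np.fill_diagonal(D, np.inf)

    W = np.zeros(m)
    for i in anchors:
        ci = y_idx[i]
        same = np.nonzero(y_idx == ci)[0]
        same = same[same != i]
        if len(same) == 0:
            continue
        kh = min(k_neighbors, len(same))
        hits = same[np.argsort(D[i, same], kind="stable")[:kh]]
        W -= np.abs(Xs[hits] - Xs[i]).sum(axis=0) / kh
        for cj in range(len(classes)):
            if cj == ci:
                continue
            others = np.nonzero(y_idx == cj)[0]
            if len(others) == 0:
                continue
            km = min(k_neighbors, len(others))
            misses = others[np.argsort(D[i, others], kind="stable")[:km]]
            w_cls = priors[cj] / (1.0 - priors[ci])
            W += w_cls * np.abs(Xs[misses] - Xs[i]).sum(axis=0) / km
    W /= len(anchors)

    order = np.argsort(-W, kind="stable")
    out = pd.DataFrame(
        {
            "feature": np.asarray(feature_names)[order],
            "weight": W[order],
            "rank": np.arange(1, m + 1),
        }
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sampling-frequency degradation study.


def frequency_study(
    dataset: Sequence[tuple[ImuSeries, LabelTrack]],
    params: EnsembleParams,
    window_s: float = 3.0,
    frequencies: Sequence[int] = (50, 20, 10, 4),
    catalogue: FeatureCatalogue | None = None,
    balance_spec: BalanceSpec | None = None,
    k: int = 5,
    seed: int = 0,
    relative: bool = True,
) -> pd.DataFrame:
    """Per-behaviour percentage decrease in performance when down-sampling.

    For each target frequency the raw 100 Hz recordings are stride
    down-sampled, features are recomputed, the dataset re-balanced (same
    spec and seed) and the classifier re-evaluated by k-fold CV.  The
    decrease for behaviour b and metric m at frequency f is

        100 * (m_100(b) - m_f(b)) / m_100(b)      (relative, default)
        m_100(b) - m_f(b), in percentage points   (relative=False)

    Returns a long-format DataFrame with columns
    (behaviour, metric, frequency_hz, value_100hz, value, decrease_pct).
    """
    if catalogue is None:
        catalogue = default_catalogue()
    if balance_spec is None:
        balance_spec = BalanceSpec(seed=seed)

    def evaluate(freq: int) -> PerformanceReport:
        if freq == 100:
            ds = dataset
        else:
            ds = [(downsample(series, freq), track) for series, track in dataset]
        frame = build_feature_frame(ds, window_s=window_s, catalogue=catalogue)
        frame = frame.dropna(subset=["behaviour"])
        balanced = balance(frame, balance_spec)
        X = balanced[catalogue.names].to_numpy()
        y = balanced["behaviour"].to_numpy()
        report, _ = cross_validate(X, y, params, k=k, seed=seed)
        return report

    base = evaluate(100)
    rows = []
    for freq in frequencies:
        rep = evaluate(int(freq))
        for b in base.per_class:
            for metric in METRIC_NAMES:
                m100 = base.per_class[b][metric]
                mf = rep.per_class.get(b, {}).get(metric, 0.0)
                if relative:
                    dec = 0.0 if m100 == 0 else 100.0 * (m100 - mf) / m100
                else:
                    dec = 100.0 * (m100 - mf)
                rows.append(
                    {
                        "behaviour": b,
                        "metric": metric,
                        "frequency_hz": int(freq),
                        "value_100hz": m100,
                        "value": mf,
                        "decrease_pct": dec,
                    }
                )
    return pd.DataFrame(rows)
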