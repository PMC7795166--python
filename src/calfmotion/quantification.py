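"""Adjusted-count prevalence estimation for a rare behaviour.

A classifier applied to an unlabelled stream and naively counted
("classify and count", CC) overestimates the prevalence of a rare
positive class whenever its false-positive rate is nonzero: with true
prevalence p, the expected fraction of predicted positives is

    p0' = p * tpr + (1 - p) * fpr.

The adjusted-count (AC) estimator inverts this relation,

    p' = (p0' - fpr) / (tpr - fpr),    clipped to [0, 1],

using tpr/fpr estimated by k-fold cross-validation on the training set.
Because AC degrades when the training set is extremely imbalanced, the
binary classifier is trained under a sweep of training conditions —
p positive play windows (p = 10, 20, ..., 190) against NP = 10,000
non-play windows — and the condition maximising tpr - fpr is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import EnsembleParams, train

PLAY = "play"
NON_PLAY = "non-play"
DEFAULT_P_GRID = tuple(range(10, 200, 10))


@dataclass
class TrainingCondition:
    """One cell of the training-condition sweep."""

    p: int
    np_negatives: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("need at least one positive instance")
        if self.np_negatives < self.p:
            raise ValueError("np_negatives must be >= p")


@dataclass
class RateEstimates:
    """Cross-validated tpr/fpr with their pooled counts."""

    tpr: float
    fpr: float
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0
    fold_tpr: list[float] = field(default_factory=list)
    fold_fpr: list[float] = field(default_factory=list)


@dataclass
class QuantifyConfig:
    p_grid: tuple[int, ...] = DEFAULT_P_GRID
    np_negatives: int = 10_000
    k_folds: int = 5
    ensemble: EnsembleParams = field(default_factory=EnsembleParams)
    seed: int = 0


@dataclass
class QuantificationResult:
    n_test: int
    raw_count: int                 # classify-and-count predicted positives
    cc_prevalence: float           # p0'
    condition: TrainingCondition
    rates: RateEstimates
    adjusted_prevalence: float     # p'
    adjusted_count: int            # round(p' * n_test)
    observed_count: int | None = None
    overestimation_count: int | None = None
    overestimation_pct: float | None = None
    per_file: pd.DataFrame | None = None
    sweep_table: pd.DataFrame | None = None


def overestimation(observed_count: int, predicted_count: int) -> tuple[int, float]:
    """Absolute and percentage over/underestimation of a count estimate.

    Returns (predicted - observed, 100 * (predicted - observed)/observed);
    the percentage is +/-inf when observed is 0 but predicted is not, and 0
    when both are 0.
    """
    if observed_count < 0:
        raise ValueError("observed count must be nonnegative")
    absolute = predicted_count - observed_count
    if observed_count == 0:
        percent = 0.0 if absolute == 0 else float(np.sign(absolute)) * np.inf
    else:
        percent = 100.0 * absolute / observed_count
    return absolute, percent


def adjust_prevalence(p0_prime: float, tpr: float, fpr: float) -> float:
    """Adjusted-count correction p' = (p0' - fpr)/(tpr - fpr), clipped to [0, 1]."""
    for name, v in (("p0_prime", p0_prime), ("tpr", tpr), ("fpr", fpr)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if tpr <= fpr:
        raise ValueError(
            f"uninformative classifier: tpr ({tpr:.4f}) <= fpr ({fpr:.4f})"
        )
    return float(np.clip((p0_prime - fpr) / (tpr - fpr), 0.0, 1.0))


def _condition_subset(
    X: np.ndarray, y: np.ndarray, condition: TrainingCondition
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded subsample of p positives and NP negatives for one condition."""
    pos = np.nonzero(y == PLAY)[0]
    neg = np.nonzero(y != PLAY)[0]
    if len(pos) < condition.p:
        raise ValueError(
            f"training subset holds {len(pos)} positives, condition needs {condition.p}"
        )
    if len(neg) < condition.np_negatives:
        raise ValueError(
            f"training subset holds {len(neg)} negatives, condition needs "
            f"{condition.np_negatives}"
        )
    rng = np.random.default_rng([condition.seed, condition.p])
    take_pos = rng.choice(pos, size=condition.p, replace=False)
    take_neg = rng.choice(neg, size=condition.np_negatives, replace=False)
    idx = np.concatenate([take_pos, take_neg])
    yb = np.where(np.isin(idx, take_pos), PLAY, NON_PLAY)
    return X[idx], yb


def estimate_rates(
    X: np.ndarray,
    y: np.ndarray,
    condition: TrainingCondition,
    params: EnsembleParams,
    k: int = 5,
) -> RateEstimates:
    """tpr/fpr of the binary play classifier under one training condition.

    Rates are pooled over the held-out folds of a stratified k-fold CV on
    the condition's subsample (tp summed across folds, then divided), so
    every subsampled window contributes exactly once.
    """
    from sklearn.model_selection import StratifiedKFold

    Xc, yc = _condition_subset(np.asarray(X, float), np.asarray(y), condition)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=condition.seed)
    tp = fn = fp = tn = 0
    fold_tpr, fold_fpr = [], []
    for tr, te in skf.split(Xc, yc):
        model = train(Xc[tr], yc[tr], params)
        pred = model.predict(Xc[te])
        truth = yc[te]
        f_tp = int(np.sum((truth == PLAY) & (pred == PLAY)))
        f_fn = int(np.sum((truth == PLAY) & (pred != PLAY)))
        f_fp = int(np.sum((truth != PLAY) & (pred == PLAY)))
        f_tn = int(np.sum((truth != PLAY) & (pred != PLAY)))
        tp, fn, fp, tn = tp + f_tp, fn + f_fn, fp + f_fp, tn + f_tn
        fold_tpr.append(f_tp / (f_tp + f_fn) if f_tp + f_fn else 0.0)
        fold_fpr.append(f_fp / (f_fp + f_tn) if f_fp + f_tn else 0.0)
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    return RateEstimates(tpr, fpr, tp, fn, fp, tn, fold_tpr, fold_fpr)


def sweep_conditions(
    X: np.ndarray,
    y: np.ndarray,
    config: QuantifyConfig,
) -> tuple[TrainingCondition, RateEstimates, pd.DataFrame]:
    """Evaluate every training condition; select the argmax of tpr - fpr.

    Ties are broken toward the smaller p (the cheapest labelling effort).
    Conditions infeasible for the available data are recorded in the sweep
    table with NaN rates and skipped.
    """
    if not config.p_grid:
        raise ValueError("empty condition grid")
    rows = []
    best: tuple[float, int] | None = None
    best_cond: TrainingCondition | None = None
    best_rates: RateEstimates | None = None
    for p in config.p_grid:
        cond = TrainingCondition(int(p), config.np_negatives, config.seed)
        try:
            rates = estimate_rates(X, y, cond, config.ensemble, k=config.k_folds)
        except ValueError as exc:
            rows.append({"p": p, "np_negatives": config.np_negatives,
                         "tpr": np.nan, "fpr": np.nan, "tpr_minus_fpr": np.nan,
                         "note": str(exc)})
            continue
        score = rates.tpr - rates.fpr
        rows.append({"p": p, "np_negatives": config.np_negatives,
                     "tpr": rates.tpr, "fpr": rates.fpr,
                     "tpr_minus_fpr": score, "note": ""})
        key = (score, -p)  # larger score wins; ties -> smaller p
        if best is None or key > best:
            best, best_cond, best_rates = key, cond, rates
    table = pd.DataFrame(rows)
    if best_cond is None or best_rates is None:
        raise ValueError("no feasible training condition in the grid")
    return best_cond, best_rates, table


def quantify(
    train_frame: pd.DataFrame,
    test_frame: pd.DataFrame,
    config: QuantifyConfig,
    feature_cols: list[str],
    label_col: str = "behaviour",
    file_col: str = "animal_id",
    positive_label: str = "locomotor play",
) -> QuantificationResult:
    """End-to-end adjusted-count quantification of a rare behaviour.

    ``train_frame`` must carry complete play/non-play labels (rows whose
    label is anything but ``positive_label`` — including unlabelled rows —
    count as non-play).  ``test_frame`` may be unlabelled; when its labels
    are present the result additionally reports the observed count and the
    over/underestimation, overall and per file.
    """
    Xtr = train_frame[feature_cols].to_numpy(float)
    ytr = np.where(train_frame[label_col] == positive_label, PLAY, NON_PLAY)
    cond, rates, sweep = sweep_conditions(Xtr, ytr, config)

    # Final model trained on the winning condition's subsample.
    Xc, yc = _condition_subset(Xtr, ytr, cond)
    model = train(Xc, yc, config.ensemble)

    Xte = test_frame[feature_cols].to_numpy(float)
    pred = model.predict(Xte)
    n_test = len(Xte)
    raw_count = int(np.sum(pred == PLAY))
    p0_prime = raw_count / n_test if n_test else 0.0
    p_prime = adjust_prevalence(p0_prime, rates.tpr, rates.fpr)
    adjusted_count = int(round(p_prime * n_test))

    result = QuantificationResult(
        n_test=n_test,
        raw_count=raw_count,
        cc_prevalence=p0_prime,
        condition=cond,
        rates=rates,
        adjusted_prevalence=p_prime,
        adjusted_count=adjusted_count,
        sweep_table=sweep,
    )

    if label_col in test_frame.columns and test_frame[label_col].notna().any():
        observed_mask = (test_frame[label_col] == positive_label).to_numpy()
        observed = int(observed_mask.sum())
        abs_over, pct_over = overestimation(observed, adjusted_count)
        result.observed_count = observed
        result.overestimation_count = abs_over
        result.overestimation_pct = pct_over

        per_file_rows = []
        pred_play = pred == PLAY
        for fid, grp_idx in test_frame.groupby(file_col, observed=True).indices.items():
            obs_f = int(observed_mask[grp_idx].sum())
            raw_f = int(pred_play[grp_idx].sum())
            n_f = len(grp_idx)
            p0_f = raw_f / n_f if n_f else 0.0
            adj_f = int(round(adjust_prevalence(p0_f, rates.tpr, rates.fpr) * n_f))
            per_file_rows.append(
                {file_col: fid, "n_windows": n_f, "observed": obs_f,
                 "raw_predicted": raw_f, "adjusted_predicted": adj_f,
                 "over_under": adj_f - obs_f}
            )
        result.per_file = pd.DataFrame(per_file_rows)
    return result


def split_even(
    frame: pd.DataFrame,
    seed: int,
    label_col: str = "behaviour",
    positive_label: str = "locomotor play",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random 50/50 train/test split, stratified on the play label.

    Stratification keeps the rare positives represented in both halves,
    which a plain random split of a 0.27%-prevalence class may not.
    """
    rng = np.random.default_rng(seed)
    is_pos = (frame[label_col] == positive_label).to_numpy()
    train_mask = np.zeros(len(frame), dtype=bool)
    for mask in (is_pos, ~is_pos):
        idx = np.nonzero(mask)[0]
        perm = rng.permutation(idx)
        train_mask[perm[: len(idx) // 2]] = True
    return frame.iloc[train_mask].copy(), frame.iloc[~train_mask].copy()
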