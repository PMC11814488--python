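"""Evaluation, weight-based feature selection, and subsite ratio statistics.

Covers the thresholded classification metrics (accuracy, precision,
recall, F1), Monte-Carlo cross-validation (repeated stratified 80/20
resplits), feature ranking by input-group weight norms with
top-fraction retraining curves, and the signed mean-ratio statistic

    ratio(x) =  x_pos_mean / x_neg_mean   if x_pos_mean >= x_neg_mean
             = -x_neg_mean / x_pos_mean   otherwise

whose sign says which class is enriched for a feature at a subsite and
whose magnitude says by how much.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .dataset import Dataset, oversample_positives, split_train_test
from .srnn import (
    RegularizedModelSpec,
    TrainedModel,
    build_model,
    classify,
    predict_proba,
    train,
)

ONE_HOT_PREFIX = "aa_"


# ---------------------------------------------------------------------------
# confusion counts and metrics

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Fractions in [0, 1]; multiply by 100 for the conventional % scale."""

    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_percent(self) -> dict[str, float]:
        return {
            "accuracy": 100 * self.accuracy,
            "precision": 100 * self.precision,
            "recall": 100 * self.recall,
            "f1": 100 * self.f1,
        }


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Standard 2x2 tally of binary labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be 0/1")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1; 0/0 ratios resolve to 0."""
    if counts.total == 0:
        raise ValueError("no samples to evaluate")
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return MetricsReport(
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=precision,
        recall=recall,
        f1=f1,
    )


# ---------------------------------------------------------------------------
# feature ranking

@dataclass
class FeatureRanking:
    """(feature, importance) pairs, descending; ties broken by name."""

    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: (-e[1], e[0]))

    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def feature_importance(
    trained: TrainedModel, feature_names: list[str] | None = None
) -> FeatureRanking:
    """Rank input features by the L2 norm of their input weight group.

    Feature k's group is its input column across the four LSTM gate
    matrices; a zeroed group means the feature was selected away.
    """
    names = feature_names or trained.feature_names
    if names is None:
        names = [f"feature_{k}" for k in range(trained.spec.input_dim)]
    if len(names) != trained.spec.input_dim:
        raise ValueError("feature_names length must equal input_dim")
    flat = trained.model.get_flat()
    groups = trained.model.parameter_groups().input_groups
    return FeatureRanking(
        [(name, float(np.linalg.norm(flat[g]))) for name, g in zip(names, groups)]
    )


def select_top_fraction(ranking: FeatureRanking, fraction: float) -> list[str]:
    """The first ceil(fraction * total) features of the ranking."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    return ranking.names()[: math.ceil(fraction * len(ranking))]


def env_feature_names(feature_names: list[str]) -> list[str]:
    """Local-environment columns (everything outside the one-hot block)."""
    return [n for n in feature_names if not n.startswith(ONE_HOT_PREFIX)]


# ---------------------------------------------------------------------------
# training wrappers

def _fit_on_split(
    train_ds: Dataset, spec: RegularizedModelSpec, seed: int
) -> TrainedModel:
    """Carve a validation slice, oversample the rest, train."""
    fit_ds, val_ds = split_train_test(train_ds, 0.2, seed)
    balanced = oversample_positives(fit_ds, seed)
    spec = replace(spec, input_dim=len(train_ds.feature_names), seed=seed)
    return train(
        build_model(spec), balanced, val_ds, spec,
        feature_names=list(train_ds.feature_names),
    )


def evaluate_model(trained: TrainedModel, test_ds: Dataset, threshold: float = 0.5):
    pred = classify(predict_proba(trained, test_ds), threshold)
    return metrics(confusion_counts(test_ds.y, pred))


# ---------------------------------------------------------------------------
# top-fraction retraining curves

@dataclass
class RankingCurve:
    fractions: list[float]
    f1_at_fraction: list[float]  # percent
    baseline_f1_all_features: float  # percent
    n_features: list[int]


def f1_vs_fraction_curve(
    dataset: Dataset,
    fractions,
    spec: RegularizedModelSpec,
    seed: int,
    mask_only: bool = False,
) -> RankingCurve:
    """Test-set F1 after keeping only top-ranked local-environment features.

    One regularized model is trained on the training split to produce the
    ranking; for each fraction the dataset is restricted to the one-hot
    block plus the selected top local-environment features and the model is
    retrained from scratch (or, with ``mask_only``, the ranking model is
    reused with dropped features zeroed).  The baseline is an unregularized
    model on all features.
    """
    fractions = [float(f) for f in fractions]
    if fractions != sorted(fractions):
        raise ValueError("fractions must be ascending")
    train_ds, test_ds = split_train_test(dataset, 0.2, seed)

    ranker = _fit_on_split(train_ds, spec, seed)
    env_names = env_feature_names(dataset.feature_names)
    env_ranking = FeatureRanking(
        [e for e in feature_importance(ranker).entries if e[0] in set(env_names)]
    )

    baseline_spec = replace(spec, reg_input="none", reg_hidden="none", lam=0.0)
    baseline = evaluate_model(_fit_on_split(train_ds, baseline_spec, seed), test_ds)

    onehot_names = [n for n in dataset.feature_names if n.startswith(ONE_HOT_PREFIX)]
    f1s, nfeats = [], []
    for frac in fractions:
        keep_env = select_top_fraction(env_ranking, frac)
        nfeats.append(len(keep_env))
        keep = onehot_names + keep_env
        if mask_only:
            masked = _mask_features(test_ds, keep)
            report = evaluate_model(ranker, masked)
        else:
            sub_train = train_ds.restrict_features(keep)
            sub_test = test_ds.restrict_features(keep)
            report = evaluate_model(_fit_on_split(sub_train, spec, seed), sub_test)
        f1s.append(100 * report.f1)
    return RankingCurve(
        fractions=fractions,
        f1_at_fraction=f1s,
        baseline_f1_all_features=100 * baseline.f1,
        n_features=nfeats,
    )


def _mask_features(ds: Dataset, keep: list[str]) -> Dataset:
    from .dataset import SampleWindow

    mask = np.array([n in set(keep) for n in ds.feature_names], dtype=float)
    return Dataset(
        [SampleWindow(s.window, s.features * mask, s.label) for s in ds.samples],
        list(ds.feature_names),
        ds.scaler_bounds,
        dict(ds.meta),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation

def monte_carlo_cv(
    dataset: Dataset,
    repeats: int,
    spec: RegularizedModelSpec,
    base_seed: int,
) -> tuple[list[MetricsReport], dict[str, float], dict[str, float]]:
    """Repeated stratified 80/20 resplitting (paper protocol: 5 repeats).

    Each repeat oversamples its training split, trains afresh, and
    evaluates on the untouched test split.  Returns the per-repeat
    reports plus the mean and standard deviation of each metric.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    reports = []
    for r in range(repeats):
        seed = base_seed + r
        train_ds, test_ds = split_train_test(dataset, 0.2, seed)
        reports.append(evaluate_model(_fit_on_split(train_ds, spec, seed), test_ds))
    keys = ("accuracy", "precision", "recall", "f1")
    mean = {k: float(np.mean([getattr(rep, k) for rep in reports])) for k in keys}
    std = {k: float(np.std([getattr(rep, k) for rep in reports])) for k in keys}
    return reports, mean, std


# ---------------------------------------------------------------------------
# mean-ratio subsite profiles

def mean_ratio(mean_pos: float, mean_neg: float) -> float:
    """Signed ratio of class means; equality gives +1, zero denominators
    give signed infinity (callers treat non-finite values as flagged)."""
    if not (np.isfinite(mean_pos) and np.isfinite(mean_neg)):
        raise ValueError("class means must be finite")
    if mean_pos == mean_neg:
        return 1.0
    if mean_pos > mean_neg:
        return math.inf if mean_neg == 0 else mean_pos / mean_neg
    return -math.inf if mean_pos == 0 else -mean_neg / mean_pos


@dataclass
class RatioProfile:
    feature: str
    positions: np.ndarray  # subsites -N..+N
    ratios: np.ndarray
    flags: np.ndarray  # True where the ratio is a signed infinity

    def peak_position(self) -> int:
        finite = np.where(self.flags, -np.inf, np.abs(self.ratios))
        return int(self.positions[int(np.argmax(finite))])


def ratio_profile(dataset: Dataset, feature: str, half_width: int | None = None) -> RatioProfile:
    """Per-subsite signed mean ratio of one feature, positive vs negative class.

    Ratios are computed on unscaled feature values (scaler bounds are
    inverted when present); pad positions are excluded from the class means.
    """
    if feature not in dataset.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    j = dataset.feature_names.index(feature)
    N = dataset.half_width if half_width is None else half_width
    y = dataset.y
    X = dataset.X[:, :, j]
    if dataset.scaler_bounds is not None:
        lo, hi = dataset.scaler_bounds
        X = lo[j] + X * (hi[j] - lo[j])
    pads = np.stack([s.window.pad_mask() for s in dataset.samples])

    positions = np.arange(-N, N + 1)
    ratios = np.empty(2 * N + 1)
    for row in range(2 * N + 1):
        ok = ~pads[:, row]
        pos_vals = X[ok & (y == 1), row]
        neg_vals = X[ok & (y == 0), row]
        ratios[row] = mean_ratio(float(pos_vals.mean()), float(neg_vals.mean()))
    flags = ~np.isfinite(ratios)
    return RatioProfile(feature=feature, positions=positions, ratios=ratios, flags=flags)
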