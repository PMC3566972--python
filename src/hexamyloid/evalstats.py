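"""Classifier evaluation: confusion metrics, ROC/AUC, and the resampled
comparison protocol.

Point metrics follow the usual confusion-matrix definitions with the
amyloidogenic class as positive:

    TPR = TP / (TP + FN),  TNR = TN / (TN + FP),
    Acc = (TP + TN) / (TP + TN + FP + FN).

Ranking quality is the area under the ROC curve built from descending
score thresholds with ties grouped; the trapezoid area equals the
Mann-Whitney probability that a random positive outranks a random
negative, ties counted one half.

Method comparison runs k train/test resamples (default 10) of an
unstratified 66/34 split, trains every method on identical splits, and
tests per-run AUC differences with the corrected resampled t-test

    t = mean(d) / sqrt((1/k + n_test/n_train) * var(d)),   df = k - 1,

whose variance inflation accounts for the overlap of training sets
across runs (a plain paired t-test would be badly anti-conservative
here). Pairwise outcomes aggregate into a wins/draws/losses table at a
5% significance level.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hexdata import HexDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    tpr: float
    tnr: float
    acc: float


def confusion_metrics(
    truth: Sequence[bool], predicted: Sequence[bool]
) -> tuple[ConfusionCounts, MetricSet]:
    """TPR/TNR/Acc from paired truth and prediction labels.

    With no positives (or no negatives) in the truth the corresponding
    rate is undefined and reported as NaN with a warning.
    """
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("truth and prediction lengths differ")
    counts = ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
        tn=int((~t & ~p).sum()),
    )
    n_pos = counts.tp + counts.fn
    n_neg = counts.tn + counts.fp
    if n_pos == 0:
        logger.warning("no positives in truth: TPR undefined")
    if n_neg == 0:
        logger.warning("no negatives in truth: TNR undefined")
    tpr = counts.tp / n_pos if n_pos else float("nan")
    tnr = counts.tn / n_neg if n_neg else float("nan")
    acc = (counts.tp + counts.tn) / counts.total
    return counts, MetricSet(tpr=tpr, tnr=tnr, acc=acc)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class ROCCurve:
    """ROC points from descending-score thresholds, plus trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_auc(truth: Sequence[bool], scores: Sequence[float]) -> ROCCurve:
    """ROC curve and AUC of a ranking score (higher = more positive).

    Tied scores are grouped into a single threshold, which makes the
    trapezoid area equal to the Mann-Whitney estimate with ties counted
    one half. Requires both classes present.
    """
    t = np.asarray(truth, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    # last index of each tie group
    distinct = np.nonzero(np.diff(s_sorted))[0]
    group_ends = np.r_[distinct, len(s_sorted) - 1]
    cum_tp = np.cumsum(t_sorted)[group_ends]
    cum_fp = np.cumsum(~t_sorted)[group_ends]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[group_ends]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def evaluate_classifier(
    clf, test_sequences: Sequence[str], test_labels: Sequence[bool]
) -> dict[str, float]:
    """Table-style metric row {TPR, TNR, Acc, AUC} for a fitted classifier."""
    truth = np.asarray(test_labels, dtype=bool)
    _, metrics = confusion_metrics(truth, clf.classify(test_sequences))
    curve = roc_auc(truth, clf.scores(test_sequences))
    return {"TPR": metrics.tpr, "TNR": metrics.tnr, "Acc": metrics.acc, "AUC": curve.auc}


# ---------------------------------------------------------------------------
# resampled comparison protocol


@dataclass
class ResamplingResult:
    """Per-run AUC of each method on shared 66/34 splits."""

    auc: pd.DataFrame  # rows = runs, columns = method names
    n_train: int
    n_test: int
    seeds: list[int]


def _split_indices(
    n: int,
    train_frac: float,
    seed: int,
    labels: np.ndarray,
    stratified: bool,
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    if stratified:
        train_idx: list[int] = []
        test_idx: list[int] = []
        for cls in (False, True):
            idx = np.flatnonzero(labels == cls)
            idx = rng.permutation(idx)
            cut = int(round(train_frac * len(idx)))
            train_idx.extend(idx[:cut])
            test_idx.extend(idx[cut:])
        return np.array(sorted(train_idx)), np.array(sorted(test_idx))
    perm = rng.permutation(n)
    cut = int(round(train_frac * n))
    return perm[:cut], perm[cut:]


def resampling_experiment(
    methods: Mapping[str, Callable[[], object]],
    data: HexDataset,
    k: int = 10,
    train_frac: float = 0.66,
    seeds: Sequence[int] | None = None,
    stratified: bool = False,
) -> ResamplingResult:
    """k train/test runs on random 66/34 splits, all methods per split.

    Each run shuffles the dataset with its seed, trains every method on
    the first 66% and records test-set AUC. A degenerate split missing a
    class is redrawn with an incremented seed (logged). Seeds default to
    0..k-1.
    """
    if seeds is None:
        seeds = list(range(k))
    if len(seeds) != k:
        raise ValueError("need exactly k seeds")
    sequences = data.sequences
    labels = data.labels
    n = len(data)
    rows = []
    for run, seed in enumerate(seeds):
        attempt_seed = int(seed)
        while True:
            train_idx, test_idx = _split_indices(
                n, train_frac, attempt_seed, labels, stratified
            )
            y_train = labels[train_idx]
            y_test = labels[test_idx]
            if 0 < y_train.sum() < len(y_train) and 0 < y_test.sum() < len(y_test):
                break
            attempt_seed += 1
            logger.warning("run %d: degenerate split, redrawing with seed %d", run, attempt_seed)
        seq_train = [sequences[i] for i in train_idx]
        seq_test = [sequences[i] for i in test_idx]
        row = {}
        for name, factory in methods.items():
            clf = factory().fit(seq_train, y_train)
            row[name] = roc_auc(y_test, clf.scores(seq_test)).auc
        rows.append(row)
    auc = pd.DataFrame(rows, index=pd.RangeIndex(k, name="run"))
    cut = int(round(train_frac * n))
    return ResamplingResult(auc=auc, n_train=cut, n_test=n - cut, seeds=[int(s) for s in seeds])


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False  # zero variance with non-zero mean


def corrected_paired_ttest(
    diffs: Sequence[float], n_train: int, n_test: int
) -> TTestResult:
    """Corrected resampled t-test on per-run metric differences.

    The classical paired t statistic is recovered when the correction
    ratio n_test/n_train is 0. Zero variance with zero mean is a draw
    (t=0, p=1); zero variance with non-zero mean is reported as p=0 with
    the degenerate flag set.
    """
    d = np.asarray(diffs, dtype=float)
    k = d.size
    if k < 2:
        raise ValueError("need at least 2 runs")
    mean = float(d.mean())
    var = float(d.var(ddof=1))
    df = k - 1
    if var == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, p=1.0, df=df)
        logger.warning("zero variance with non-zero mean difference")
        return TTestResult(t=float(np.sign(mean)) * float("inf"), p=0.0, df=df, degenerate=True)
    t = mean / np.sqrt((1.0 / k + n_test / n_train) * var)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), p=p, df=df)


def wins_draws_losses(result: ResamplingResult, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise corrected t-tests on AUC -> wins/draws/losses per method."""
    names = list(result.auc.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 methods to compare")
    table = pd.DataFrame(0, index=names, columns=["Wins", "Draws", "Losses"])
    for a in names:
        for b in names:
            if a == b:
                continue
            d = result.auc[a].to_numpy() - result.auc[b].to_numpy()
            res = corrected_paired_ttest(d, result.n_train, result.n_test)
            if res.p < alpha and d.mean() > 0:
                table.loc[a, "Wins"] += 1
            elif res.p < alpha and d.mean() < 0:
                table.loc[a, "Losses"] += 1
            else:
                table.loc[a, "Draws"] += 1
    return table


# ---------------------------------------------------------------------------
# report writers


def write_metrics_table(path, rows: Mapping[str, Mapping[str, float]]) -> None:
    """TSV with one row per method and columns TPR / TNR / Acc / AUC."""
    df = pd.DataFrame(rows).T
    df.index.name = "Method"
    df.to_csv(path, sep="\t", float_format="%.4f")


def write_comparison_table(path, table: pd.DataFrame) -> None:
    out = table.copy()
    out.index.name = "Method"
    out.to_csv(path, sep="\t")
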