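"""Model evaluation: ROC AUC, cross-validation, threshold scans, grid search.

AUC is the Mann-Whitney pair statistic (ties half-weighted), computed on raw
B-scores: under the mid-rank Pa/Pi calibration, B and Pa - Pi are monotone
equivalent, so ranking by B keeps the metric independent of the calibration
convention.  Model selection follows the source method: a grid over window
length x descriptor level, each cell scored by leave-one-out AUC (averaged
across endpoints when several are modelled), best cell by maximal average
with ties broken toward the smaller level, then the smaller length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import mna, spr
from .mna import DescriptorVocabulary
from .molgraph import graphs_for_dataset
from .spr import PredictionResult
from .windows import (LabeledDataset, ProteinSequence, SubstitutionRecord,
                      build_dataset)

DEFAULT_LENGTHS = tuple(range(3, 32, 2))
DEFAULT_LEVELS = tuple(range(1, 16))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, balanced accuracy); errors on empty margins."""
    if cm.tp + cm.fn == 0:
        raise ValueError("no positive instances: sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise ValueError("no negative instances: specificity undefined")
    sen = cm.tp / (cm.tp + cm.fn)
    sp = cm.tn / (cm.tn + cm.fp)
    return sen, sp, (sen + sp) / 2.0


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    return float(
        (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def loo_auc(dataset: LabeledDataset, level: int) -> float:
    """AUC over leave-one-out B-scores of a labeled window dataset."""
    model = spr.train_model(dataset, level)
    return auc(model.calibration.scores, model.calibration.labels)


def _stratified_folds(labels: np.ndarray, k: int, seed: int
                      ) -> np.ndarray:
    """Fold id per structure: classes shuffled separately, dealt round-robin."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(labels), dtype=np.int64)
    start = 0
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        fold[idx] = (start + np.arange(len(idx))) % k
        start += len(idx)  # offset so small remainders spread over folds
    return fold


def kfold_auc(dataset: LabeledDataset, level: int, k: int = 20,
              seed: int = 0) -> float:
    """Pooled AUC over stratified k-fold held-out B-scores."""
    if k < 2:
        raise ValueError("k-fold cross-validation requires k >= 2")
    labels = np.asarray(dataset.labels, dtype=bool)
    if k > len(labels):
        raise ValueError(f"k={k} exceeds dataset size {len(labels)}")
    vocab = DescriptorVocabulary()
    graphs = graphs_for_dataset(dataset)
    keys = mna.encode_graphs(graphs, [level], vocab)[level]
    folds = _stratified_folds(labels, k, seed)
    scores = np.empty(len(labels), dtype=float)
    for f in range(k):
        test = folds == f
        train_keys = [keys[i] for i in np.flatnonzero(~test)]
        counts = spr.fit(train_keys, labels[~test], vocab)
        for i in np.flatnonzero(test):
            scores[i] = spr.b_score(keys[i], counts).b
    return auc(scores, labels)


def loo_predictions(model: spr.SPRModel) -> list[PredictionResult]:
    """Per-training-structure predictions under each structure's own LOO score.

    Mirrors the screening protocol in which every known variant is predicted
    by a model whose counts exclude it; Pa/Pi come from the model's
    calibration tables.
    """
    out = []
    for b in model.calibration.scores:
        pa, pi = spr.pa_pi(float(b), model.calibration)
        out.append(PredictionResult(b=float(b), pa=pa, pi=pi,
                                    n_descriptors=0, n_new_descriptors=0))
    return out


DEFAULT_THRESHOLDS = ("pa>pi", 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def threshold_scan(predictions: list[PredictionResult], labels,
                   thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Confusion counts and metrics at the default rule and fixed Pa cut-offs."""
    labels = np.asarray(labels, dtype=bool)
    pa = np.array([p.pa for p in predictions])
    pi = np.array([p.pi for p in predictions])
    rows = []
    for thr in thresholds:
        if isinstance(thr, str):
            if thr.replace(" ", "").lower() != "pa>pi":
                raise ValueError(f"unknown threshold rule {thr!r}")
            pred = pa > pi
            name = "Pa > Pi"
        else:
            pred = pa > float(thr)
            name = f"Pa > {thr:g}"
        cm = ConfusionMatrix(
            tp=int((pred & labels).sum()), fp=int((pred & ~labels).sum()),
            tn=int((~pred & ~labels).sum()), fn=int((~pred & labels).sum()))
        # a missing class leaves the corresponding rate undefined, not fatal
        sen = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else float("nan")
        sp = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else float("nan")
        bal = (sen + sp) / 2.0
        rows.append({"threshold": name, "TP": cm.tp, "FP": cm.fp,
                     "TN": cm.tn, "FN": cm.fn, "sensitivity": sen,
                     "specificity": sp, "balanced_accuracy": bal})
    return pd.DataFrame(rows)


@dataclass
class GridResult:
    """Length x level grid of LOO AUCs, per endpoint plus averages."""

    table: pd.DataFrame  # columns: length, level, endpoint, auc
    averages: pd.DataFrame  # columns: length, level, average_auc
    best_cell: tuple[int, int]  # (length, level)
    best_auc: float


def grid_search(
    seq: ProteinSequence,
    records: list[SubstitutionRecord],
    endpoints: list[str],
    lengths=DEFAULT_LENGTHS,
    levels=DEFAULT_LEVELS,
) -> GridResult:
    """LOO AUC for every (window length, MNA level) cell and endpoint.

    The cell score is the arithmetic mean of per-endpoint LOO AUCs; the best
    cell maximizes it, ties broken by smaller level then smaller length.
    Descriptors are encoded once per length for all levels.
    """
    if not endpoints:
        raise ValueError("at least one endpoint required")
    levels = sorted(levels)
    rows = []
    for length in lengths:
        datasets = {ep: build_dataset(seq, records, ep, length)
                    for ep in endpoints}
        vocab = DescriptorVocabulary()
        graphs = graphs_for_dataset(datasets[endpoints[0]])
        keys_by_level = mna.encode_graphs(graphs, levels, vocab)
        for level in levels:
            keys = keys_by_level[level]
            for ep in endpoints:
                labels = np.asarray(datasets[ep].labels, dtype=bool)
                counts = spr.fit(keys, labels, vocab)
                cal = spr.calibrate_loo(keys, labels, counts)
                rows.append({"length": length, "level": level,
                             "endpoint": ep,
                             "auc": auc(cal.scores, labels)})
    table = pd.DataFrame(rows)
    averages = (table.groupby(["length", "level"], as_index=False)["auc"]
                .mean().rename(columns={"auc": "average_auc"}))
    best = averages.sort_values(
        ["average_auc", "level", "length"],
        ascending=[False, True, True]).iloc[0]
    return GridResult(
        table=table,
        averages=averages,
        best_cell=(int(best["length"]), int(best["level"])),
        best_auc=float(best["average_auc"]),
    )
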