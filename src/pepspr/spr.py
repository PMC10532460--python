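"""PASS-style naive-Bayes classifier over MNA descriptor sets.

For a class A (here: drug-resistant) a structure with descriptors D1..Dm is
scored by

    S0 = 2 P(A) - 1,
    S  = sin( mean_i asin(2 P(A|Di) - 1) ),
    B  = (S - S0) / (1 - S * S0),

with the simplest frequency estimates P(A) = Nk/N and P(A|Di) = Nik/Ni over
the training set.  Descriptors never seen in training have no defined
conditional probability; they are excluded from the mean and surfaced as the
"new descriptor" count, a crude applicability-domain measure.

Pa and Pi calibrate B against the leave-one-out score distributions of the
two training classes, as mid-rank empirical CDFs: Pa is the fraction of
positive-class LOO scores below B, Pi the fraction of negative-class LOO
scores above B (ties half-weighted).  The default decision rule is Pa > Pi.

Leave-one-out is exact and cheap because the counts are additive: removing
structure s with label y changes N -> N-1, Nk -> Nk-y, and for each of s's
own descriptors Ni -> Ni-1, Nik -> Nik-y.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import mna
from .mna import DescriptorSet, DescriptorVocabulary
from .molgraph import MolecularGraph, graphs_for_dataset
from .windows import LabeledDataset

MODEL_FORMAT = "pepspr-model"
MODEL_VERSION = 1


@dataclass
class TrainingCounts:
    """Frequency tallies over unique descriptors per structure."""

    n: int
    n_pos: int
    ni: np.ndarray   # structures containing descriptor id
    nik: np.ndarray  # positive structures containing descriptor id
    vocabulary: DescriptorVocabulary = field(repr=False, default=None)

    @property
    def prior(self) -> float:
        return self.n_pos / self.n

    def validate(self) -> None:
        if np.any(self.nik > self.ni) or np.any(self.nik > self.n_pos):
            raise AssertionError("inconsistent training counts")


@dataclass(frozen=True)
class ScoreComponents:
    s0: float
    s: float
    b: float
    m: int  # query descriptors known to the model

    @property
    def no_known_descriptors(self) -> bool:
        return self.m == 0


@dataclass
class CalibrationTable:
    """LOO B-scores of the training set, split and sorted by class."""

    positive_scores: np.ndarray  # sorted, length Nk
    negative_scores: np.ndarray  # sorted, length N - Nk
    scores: np.ndarray           # in training order
    labels: np.ndarray           # bool, in training order


@dataclass(frozen=True)
class PredictionResult:
    b: float
    pa: float
    pi: float
    n_descriptors: int
    n_new_descriptors: int

    @property
    def out_of_domain(self) -> bool:
        return self.n_new_descriptors == self.n_descriptors

    @property
    def predicted_resistant(self) -> bool:
        return self.pa > self.pi


def _as_keys(x) -> np.ndarray:
    if isinstance(x, DescriptorSet):
        return x.keys
    return np.asarray(x, dtype=np.int64)


def fit(structures, labels, vocabulary: DescriptorVocabulary
        ) -> TrainingCounts:
    """Tally descriptor frequencies.

    ``structures`` is a list of DescriptorSets or sorted unique id arrays,
    ``labels`` the binary class per structure.  Requires both classes.
    """
    labels = np.asarray(labels, dtype=bool)
    if len(structures) != len(labels):
        raise ValueError("structures and labels differ in length")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError(
            "training requires at least one structure of each class "
            f"(got {n_pos} positives of {len(labels)})")
    size = len(vocabulary)
    ni = np.zeros(size, dtype=np.int64)
    nik = np.zeros(size, dtype=np.int64)
    for keys, y in zip(structures, labels):
        keys = _as_keys(keys)
        ni[keys] += 1
        if y:
            nik[keys] += 1
    counts = TrainingCounts(n=len(labels), n_pos=n_pos, ni=ni, nik=nik,
                            vocabulary=vocabulary)
    counts.validate()
    return counts


def _combine(s: float, s0: float) -> float:
    denom = 1.0 - s * s0
    if abs(denom) < 1e-15:
        return 0.0 if s == s0 else math.copysign(1.0, s)
    b = (s - s0) / denom
    return min(1.0, max(-1.0, b))


def b_score(query, counts: TrainingCounts) -> ScoreComponents:
    """Score one structure against fitted counts.

    Only query descriptors present in the training set enter the arcsine
    mean; with no known descriptors the evidence is void and B = 0.
    """
    keys = _as_keys(query)
    s0 = 2.0 * counts.prior - 1.0
    in_vocab = keys[keys < len(counts.ni)]
    known = in_vocab[counts.ni[in_vocab] > 0]
    m = len(known)
    if m == 0:
        return ScoreComponents(s0=s0, s=s0, b=0.0, m=0)
    p = counts.nik[known] / counts.ni[known]
    s = math.sin(float(np.mean(np.arcsin(2.0 * p - 1.0))))
    return ScoreComponents(s0=s0, s=s, b=_combine(s, s0), m=m)


def count_new_descriptors(query, counts: TrainingCounts) -> int:
    keys = _as_keys(query)
    in_vocab = keys[keys < len(counts.ni)]
    known = int((counts.ni[in_vocab] > 0).sum())
    return len(keys) - known


def loo_score(index: int, structures, labels,
              counts: TrainingCounts) -> ScoreComponents:
    """Score structure ``index`` with itself removed from the counts.

    Uses the decrement identity instead of refitting; exact because the
    tallies are additive.  Descriptors whose Ni drops to zero become unseen
    and leave the mean.
    """
    labels = np.asarray(labels, dtype=bool)
    y = int(labels[index])
    keys = _as_keys(structures[index])
    n = counts.n - 1
    n_pos = counts.n_pos - y
    if n <= 0:
        raise AssertionError("cannot leave one out of a singleton set")
    s0 = 2.0 * n_pos / n - 1.0
    ni = counts.ni[keys] - 1
    nik = counts.nik[keys] - y
    if np.any(ni < 0) or np.any(nik < 0) or np.any(nik > ni):
        raise AssertionError("LOO decrement produced invalid counts")
    keep = ni > 0
    m = int(keep.sum())
    if m == 0:
        return ScoreComponents(s0=s0, s=s0, b=0.0, m=0)
    p = nik[keep] / ni[keep]
    s = math.sin(float(np.mean(np.arcsin(2.0 * p - 1.0))))
    return ScoreComponents(s0=s0, s=s, b=_combine(s, s0), m=m)


def calibrate_loo(structures, labels, counts: TrainingCounts
                  ) -> CalibrationTable:
    """Leave-one-out B-score of every training structure, split by class."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.array([
        loo_score(i, structures, labels, counts).b
        for i in range(len(labels))
    ])
    return CalibrationTable(
        positive_scores=np.sort(scores[labels]),
        negative_scores=np.sort(scores[~labels]),
        scores=scores,
        labels=labels,
    )


def _midrank_fraction_below(sorted_scores: np.ndarray, b: float) -> float:
    lo = np.searchsorted(sorted_scores, b, side="left")
    hi = np.searchsorted(sorted_scores, b, side="right")
    return (lo + 0.5 * (hi - lo)) / len(sorted_scores)


def pa_pi(b: float, calibration: CalibrationTable) -> tuple[float, float]:
    pa = _midrank_fraction_below(calibration.positive_scores, b)
    pi = 1.0 - _midrank_fraction_below(calibration.negative_scores, b)
    return pa, pi


@dataclass
class SPRModel:
    """A trained, LOO-calibrated sequence-structure classifier."""

    counts: TrainingCounts
    calibration: CalibrationTable
    level: int
    nominal_length: int
    endpoint: str

    @property
    def vocabulary(self) -> DescriptorVocabulary:
        return self.counts.vocabulary

    def predict_keys(self, keys) -> PredictionResult:
        keys = _as_keys(keys)
        comp = b_score(keys, self.counts)
        pa, pi = pa_pi(comp.b, self.calibration)
        n_new = count_new_descriptors(keys, self.counts)
        return PredictionResult(b=comp.b, pa=pa, pi=pi,
                                n_descriptors=len(keys),
                                n_new_descriptors=n_new)

    def predict_graph(self, graph: MolecularGraph) -> PredictionResult:
        keys = self.vocabulary.encode(graph, self.level)
        return self.predict_keys(keys)

    def predict(self, query) -> PredictionResult:
        if isinstance(query, MolecularGraph):
            return self.predict_graph(query)
        return self.predict_keys(query)

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        vocab_size = len(self.counts.ni)
        nodes = [
            [mark, None if children is None else list(children)]
            for mark, children in self.vocabulary.nodes[:vocab_size]
        ]
        doc = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "endpoint": self.endpoint,
            "level": self.level,
            "nominal_length": self.nominal_length,
            "n": self.counts.n,
            "n_pos": self.counts.n_pos,
            "nodes": nodes,
            "ni": self.counts.ni.tolist(),
            "nik": self.counts.nik.tolist(),
            "loo_scores": self.calibration.scores.tolist(),
            "labels": [int(v) for v in self.calibration.labels],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "SPRModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != MODEL_FORMAT:
            raise ValueError(f"{path} is not a {MODEL_FORMAT} file")
        vocab = DescriptorVocabulary()
        for mark, children in doc["nodes"]:
            vocab.intern(mark, None if children is None else tuple(children))
        counts = TrainingCounts(
            n=doc["n"], n_pos=doc["n_pos"],
            ni=np.asarray(doc["ni"], dtype=np.int64),
            nik=np.asarray(doc["nik"], dtype=np.int64),
            vocabulary=vocab,
        )
        labels = np.asarray(doc["labels"], dtype=bool)
        scores = np.asarray(doc["loo_scores"], dtype=float)
        calibration = CalibrationTable(
            positive_scores=np.sort(scores[labels]),
            negative_scores=np.sort(scores[~labels]),
            scores=scores,
            labels=labels,
        )
        return cls(counts=counts, calibration=calibration,
                   level=doc["level"], nominal_length=doc["nominal_length"],
                   endpoint=doc["endpoint"])


# ---------------------------------------------------------------------------
# training pipelines

def train_model_from_graphs(
    graphs: list[MolecularGraph],
    labels,
    level: int,
    endpoint: str = "resistance",
    nominal_length: int = 0,
    vocabulary: DescriptorVocabulary | None = None,
) -> SPRModel:
    vocab = vocabulary or DescriptorVocabulary()
    keys = mna.encode_graphs(graphs, [level], vocab)[level]
    counts = fit(keys, labels, vocab)
    calibration = calibrate_loo(keys, labels, counts)
    return SPRModel(counts=counts, calibration=calibration, level=level,
                    nominal_length=nominal_length, endpoint=endpoint)


def train_model(dataset: LabeledDataset, level: int,
                vocabulary: DescriptorVocabulary | None = None) -> SPRModel:
    """Windows -> molecular graphs -> descriptor sets -> fitted model."""
    graphs = graphs_for_dataset(dataset)
    return train_model_from_graphs(
        graphs, dataset.labels, level,
        endpoint=dataset.endpoint, nominal_length=dataset.nominal_length,
        vocabulary=vocabulary,
    )
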