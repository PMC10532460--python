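"""The Bayes-like scorer: counts, B-scores, exact LOO, Pa/Pi calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepspr import spr
from pepspr.mna import DescriptorVocabulary
from pepspr.molgraph import graphs_for_dataset
from pepspr.spr import (SPRModel, TrainingCounts, b_score, calibrate_loo,
                        count_new_descriptors, fit, loo_score, pa_pi,
                        train_model)


def toy_structures(rng, n=20, vocab_size=30, size=8):
    """Random key-set structures over a synthetic vocabulary of marks."""
    vocab = DescriptorVocabulary()
    for i in range(vocab_size):
        vocab.intern(f"-X{i}", None)
    structures = [np.unique(rng.integers(0, vocab_size, size=size))
                  for _ in range(n)]
    labels = rng.random(n) < 0.4
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    return structures, labels, vocab


def naive_refit_loo(structures, labels, vocab):
    """Oracle: retrain from scratch with each structure held out."""
    out = []
    for i in range(len(structures)):
        rest = [s for j, s in enumerate(structures) if j != i]
        rest_labels = [l for j, l in enumerate(labels) if j != i]
        counts = fit(rest, rest_labels, vocab)
        out.append(b_score(structures[i], counts).b)
    return np.array(out)


class TestFit:
    def test_prior_is_class_fraction(self):
        rng = np.random.default_rng(0)
        structures, labels, vocab = toy_structures(rng)
        counts = fit(structures, labels, vocab)
        assert counts.prior == labels.sum() / len(labels)

    def test_descriptor_in_every_structure(self):
        vocab = DescriptorVocabulary()
        d = vocab.intern("-C", None)
        structures = [np.array([d])] * 4
        counts = fit(structures, [1, 0, 1, 0], vocab)
        assert counts.ni[d] == 4
        assert counts.nik[d] / counts.ni[d] == counts.prior

    def test_descriptor_unique_to_one_positive(self):
        vocab = DescriptorVocabulary()
        d0, d1 = vocab.intern("-C", None), vocab.intern("-N", None)
        structures = [np.array([d0, d1]), np.array([d0]), np.array([d0])]
        counts = fit(structures, [1, 0, 0], vocab)
        assert counts.ni[d1] == 1 and counts.nik[d1] == 1

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        structures, _, vocab = toy_structures(rng, n=5)
        with pytest.raises(ValueError, match="each class"):
            fit(structures, [1, 1, 1, 1, 1], vocab)


def make_counts(n, n_pos, ni, nik):
    return TrainingCounts(n=n, n_pos=n_pos,
                          ni=np.asarray(ni, dtype=np.int64),
                          nik=np.asarray(nik, dtype=np.int64))


class TestBScore:
    def test_balanced_evidence_cancels(self):
        """P = 0.75 and 0.25 around a 0.5 prior: arcsines cancel, B = 0."""
        counts = make_counts(4, 2, ni=[4, 4], nik=[3, 1])
        comp = b_score(np.array([0, 1]), counts)
        assert comp.s0 == 0.0
        assert comp.s == pytest.approx(0.0, abs=1e-15)
        assert comp.b == pytest.approx(0.0, abs=1e-15)

    def test_prior_matching_descriptors_give_zero(self):
        counts = make_counts(10, 3, ni=[10, 10], nik=[3, 3])
        comp = b_score(np.array([0, 1]), counts)
        assert comp.b == pytest.approx(0.0, abs=1e-12)

    def test_perfect_descriptor_saturates(self):
        counts = make_counts(10, 3, ni=[4], nik=[4])
        comp = b_score(np.array([0]), counts)
        assert comp.s == pytest.approx(1.0)
        assert comp.b == pytest.approx(1.0)

    def test_unseen_descriptors_excluded_and_counted(self):
        counts = make_counts(6, 2, ni=[3, 0], nik=[1, 0])
        keys = np.array([0, 1, 7])  # id 1 never seen, id 7 beyond vocab
        comp = b_score(keys, counts)
        assert comp.m == 1
        assert count_new_descriptors(keys, counts) == 2

    def test_no_known_descriptors_flagged(self):
        counts = make_counts(6, 2, ni=[0], nik=[0])
        comp = b_score(np.array([0, 5]), counts)
        assert comp.b == 0.0 and comp.no_known_descriptors

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_b_in_unit_interval_on_fuzzed_counts(self, data):
        n = data.draw(st.integers(2, 40))
        n_pos = data.draw(st.integers(1, n - 1))
        size = data.draw(st.integers(1, 8))
        ni = data.draw(st.lists(st.integers(0, n), min_size=size,
                                max_size=size))
        nik = [data.draw(st.integers(0, min(v, n_pos))) for v in ni]
        comp = b_score(np.arange(size), make_counts(n, n_pos, ni, nik))
        assert -1.0 <= comp.b <= 1.0


class TestLeaveOneOut:
    def test_decrement_equals_naive_refit_exactly(self):
        rng = np.random.default_rng(42)
        structures, labels, vocab = toy_structures(rng, n=20)
        counts = fit(structures, labels, vocab)
        fast = calibrate_loo(structures, labels, counts).scores
        naive = naive_refit_loo(structures, labels, vocab)
        assert np.array_equal(fast, naive)

    def test_calibration_list_lengths(self):
        rng = np.random.default_rng(1)
        structures, labels, vocab = toy_structures(rng)
        counts = fit(structures, labels, vocab)
        cal = calibrate_loo(structures, labels, counts)
        assert len(cal.positive_scores) == counts.n_pos
        assert len(cal.negative_scores) == counts.n - counts.n_pos

    def test_identical_structures_score_constant_within_class(self):
        vocab = DescriptorVocabulary()
        a = vocab.intern("-C", None)
        b = vocab.intern("-N", None)
        structures = [np.array([a])] * 3 + [np.array([b])] * 3
        labels = [1, 1, 1, 0, 0, 0]
        counts = fit(structures, labels, vocab)
        cal = calibrate_loo(structures, labels, counts)
        assert len(set(cal.scores[:3])) == 1
        assert len(set(cal.scores[3:])) == 1
        assert cal.scores[0] != cal.scores[3]

    def test_label_inversion_antisymmetry(self):
        rng = np.random.default_rng(9)
        structures, labels, vocab = toy_structures(rng, n=12)
        c1 = fit(structures, labels, vocab)
        c2 = fit(structures, ~labels, vocab)
        for keys in structures:
            b1 = b_score(keys, c1).b
            b2 = b_score(keys, c2).b
            assert b2 == pytest.approx(-b1, abs=1e-12)

    def test_counts_restored_after_calibration(self):
        rng = np.random.default_rng(3)
        structures, labels, vocab = toy_structures(rng)
        counts = fit(structures, labels, vocab)
        ni_before = counts.ni.copy()
        calibrate_loo(structures, labels, counts)
        assert np.array_equal(counts.ni, ni_before)


class TestPrediction:
    def _model(self, seed=0):
        rng = np.random.default_rng(seed)
        structures, labels, vocab = toy_structures(rng, n=24)
        counts = fit(structures, labels, vocab)
        cal = calibrate_loo(structures, labels, counts)
        return SPRModel(counts=counts, calibration=cal, level=0,
                        nominal_length=3, endpoint="drug"), structures, labels

    def test_extreme_score_has_pa_one_pi_zero(self):
        model, _, _ = self._model()
        top = max(model.calibration.scores) + 1.0
        pa, pi = pa_pi(top, model.calibration)
        assert (pa, pi) == (1.0, 0.0)

    def test_pa_monotone_pi_antitone_in_b(self):
        model, _, _ = self._model()
        grid = np.linspace(-1, 1, 201)
        pas, pis = zip(*(pa_pi(float(b), model.calibration) for b in grid))
        assert all(a <= b for a, b in zip(pas, pas[1:]))
        assert all(a >= b for a, b in zip(pis, pis[1:]))
        assert all(0 <= v <= 1 for v in pas + pis)

    def test_prediction_reproduces_own_loo_score(self):
        model, structures, labels = self._model()
        for i in range(len(structures)):
            comp = loo_score(i, structures, labels, model.counts)
            assert comp.b == model.calibration.scores[i]

    def test_query_of_only_unseen_descriptors_is_out_of_domain(self):
        model, _, _ = self._model()
        vocab = model.vocabulary
        new = np.array([vocab.intern("-S[+1]", None),
                        vocab.intern("-ZZZ", None)])
        res = model.predict_keys(new)
        assert res.b == 0.0
        assert res.n_new_descriptors == res.n_descriptors == 2
        assert res.out_of_domain

    def test_save_load_roundtrip_bit_exact(self, tmp_path):
        model, structures, _ = self._model()
        path = tmp_path / "model.json"
        model.save(path)
        back = SPRModel.load(path)
        assert np.array_equal(back.calibration.scores,
                              model.calibration.scores)
        assert np.array_equal(back.counts.ni, model.counts.ni)
        assert back.counts.n == model.counts.n
        for keys in structures[:5]:
            a = model.predict_keys(keys)
            b = back.predict_keys(keys)
            assert (a.b, a.pa, a.pi) == (b.b, b.pa, b.pi)
            assert a.n_new_descriptors == b.n_new_descriptors


class TestEndToEnd:
    def test_motif_positive_gets_pa_above_pi(self, planted_set):
        """A held-out positive carrying the planted context scores Pa > Pi."""
        spec, seq, records = planted_set
        from pepspr.windows import build_dataset
        length = 2 * spec.motif_radius + 1
        positives = [r for r in records
                     if r.labels[spec.endpoint]
                     and any(c in spec.motif_residues
                             for c in seq.residues[max(0, r.position - 1
                                                       - spec.motif_radius):
                                                   r.position - 1]
                             + seq.residues[r.position:
                                            r.position + spec.motif_radius])]
        held_out = positives[0]
        rest = [r for r in records if r is not held_out]
        ds = build_dataset(seq, rest, spec.endpoint, length)
        model = train_model(ds, level=3)
        from pepspr.windows import extract_window
        from pepspr.molgraph import assemble_peptide_graph
        query = assemble_peptide_graph(
            extract_window(seq, held_out, length))
        res = model.predict_graph(query)
        assert res.pa > res.pi
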