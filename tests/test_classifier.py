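"""Length binning, segmentation, ensemble training and score aggregation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mobclass as m
from mobclass.benchmark_sim import LabeledFragment
from mobclass.classifier import EnsembleModel, MobClassScores

N_CLASSES = len(m.CLASS_ORDER)


class TestLengthBin:
    @pytest.mark.parametrize(
        "length,expected",
        [(1, "B1"), (50, "B1"), (100, "B1"), (400, "B1"), (401, "B2"),
         (800, "B2"), (801, "B3"), (1200, "B3"), (1201, "B4"), (1600, "B4")],
    )
    def test_boundaries(self, length, expected):
        assert m.assign_length_bin(length) == expected

    def test_out_of_contract(self):
        with pytest.raises(ValueError):
            m.assign_length_bin(1601)
        with pytest.raises(ValueError):
            m.assign_length_bin(0)


class TestSegmentation:
    def test_4000_bp_example(self):
        segs = m.segment_fragment("A" * 4000)
        assert [len(s) for s in segs] == [1600, 1600, 800]

    def test_exact_multiple_has_no_remainder(self):
        assert [len(s) for s in m.segment_fragment("A" * 1600)] == [1600]
        assert [len(s) for s in m.segment_fragment("A" * 3200)] == [1600, 1600]

    def test_5000_bp(self):
        assert [len(s) for s in m.segment_fragment("C" * 5000)] == [1600, 1600, 1600, 200]

    @given(st.integers(min_value=1, max_value=12_000))
    def test_concatenation_round_trip(self, L):
        rng = np.random.default_rng(L)
        seq = "".join(rng.choice(list("ACGT"), size=L))
        segs = m.segment_fragment(seq)
        assert "".join(segs) == seq
        assert all(len(s) == 1600 for s in segs[:-1])


class _StubForest:
    """Fixed-probability forest standing in for a trained model."""

    def __init__(self, probs):
        self.classes_ = np.arange(N_CLASSES)
        self._p = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        return np.tile(self._p, (len(X), 1))


def _vec(hot, p=0.8):
    v = np.full(N_CLASSES, (1 - p) / (N_CLASSES - 1))
    v[hot] = p
    return v


@pytest.fixture()
def stub_model(toy_embedding):
    per_bin = {
        "B1": _StubForest(_vec(0)),
        "B2": _StubForest(_vec(1)),
        "B3": _StubForest(_vec(2)),
        "B4": _StubForest(_vec(3)),
    }
    return EnsembleModel(
        per_bin_models=per_bin,
        embedding=toy_embedding,
        class_order=m.CLASS_ORDER,
        seed=0,
    )


class TestPredictionArithmetic:
    def test_short_fragment_is_raw_bin_output(self, stub_model):
        sc = m.predict_fragment("A" * 500, stub_model)  # B2
        assert np.allclose(sc.scores, _vec(1))

    def test_segment_weighting_hand_case(self, stub_model):
        # 2400 bp -> segments 1600 (B4) and 800 (B2)
        sc = m.predict_fragment("A" * 2400, stub_model)
        expected = (1600 * _vec(3) + 800 * _vec(1)) / 2400
        assert np.allclose(sc.scores, expected)

    def test_identical_segment_scores_pass_through(self, toy_embedding):
        per_bin = {name: _StubForest(_vec(5)) for name in ("B1", "B2", "B3", "B4")}
        model = EnsembleModel(per_bin, toy_embedding, m.CLASS_ORDER, 0)
        sc = m.predict_fragment("G" * 4000, model)
        assert np.allclose(sc.scores, _vec(5))

    def test_bin_weighting_hand_case(self, stub_model):
        # members of 100 bp (B1 -> p) and 700 bp (B2 -> q)
        pred = m.predict_bin([("f1", "A" * 100), ("f2", "A" * 700)], "bin1", stub_model)
        expected = (100 * _vec(0) + 700 * _vec(1)) / 800
        assert np.allclose(pred.scores.scores, expected)
        assert pred.member_count == 2
        assert pred.total_length == 800

    def test_single_member_bin_equals_fragment(self, stub_model):
        pred = m.predict_bin([("f1", "A" * 900)], "b", stub_model)
        sc = m.predict_fragment("A" * 900, stub_model)
        assert np.allclose(pred.scores.scores, sc.scores)

    def test_empty_or_unclassifiable_bin_is_none(self, stub_model):
        assert m.predict_bin([], "b", stub_model) is None
        assert m.predict_bin([("f1", "NNNN")], "b", stub_model) is None

    def test_unfeaturizable_fragment_signals(self, stub_model):
        with pytest.raises(m.FeaturizationError):
            m.predict_fragment("NNNNNN", stub_model)
        out = m.predict_fragments(["AAAA", "NNNN"], stub_model)
        assert out[0] is not None and out[1] is None


class TestScoreVector:
    def test_validation(self):
        with pytest.raises(ValueError):
            MobClassScores(np.ones(N_CLASSES))  # sums to 11
        with pytest.raises(ValueError):
            MobClassScores(np.ones(5) / 5)

    def test_tie_breaks_to_first_class_in_order(self):
        v = np.zeros(N_CLASSES)
        v[2] = v[7] = 0.5
        assert MobClassScores(v).predicted_class == m.CLASS_ORDER[2]

    def test_as_dict_keys_follow_class_order(self):
        v = np.full(N_CLASSES, 1 / N_CLASSES)
        assert list(MobClassScores(v).as_dict()) == list(m.CLASS_ORDER)


class TestTrainedEnsemble:
    def test_separable_toy_training_is_perfect(self, toy_embedding):
        # two classes with disjoint single-base composition: A-only vs C-only
        frs = []
        rng = np.random.default_rng(0)
        for i in range(30):
            L = int(rng.integers(100, 401))
            frs.append(LabeledFragment(f"a{i}", "A" * L, "MOBB", "gA", "train", "B1"))
            frs.append(LabeledFragment(f"c{i}", "C" * L, "MOBC", "gC", "train", "B1"))
            for name, (lo, hi) in list(m.LENGTH_BINS.items())[1:]:
                L2 = int(rng.integers(lo, hi + 1))
                frs.append(LabeledFragment(f"a{name}{i}", "A" * L2, "MOBB", "gA", "train", name))
                frs.append(LabeledFragment(f"c{name}{i}", "C" * L2, "MOBC", "gC", "train", name))
        model = m.train_ensemble(frs, toy_embedding, n_trees=20, seed=0)
        preds = m.predict_fragments([fr.sequence for fr in frs], model)
        assert all(p.predicted_class == fr.true_class for p, fr in zip(preds, frs))

    def test_single_class_bin_refused(self, toy_embedding):
        frs = [
            LabeledFragment(f"f{i}", "A" * (100 + i), "MOBB", "g", "train", "B1")
            for i in range(10)
        ] + [
            LabeledFragment(f"g{i}", "C" * (500 + i), "MOBC", "g", "train", "B2")
            for i in range(10)
        ]
        with pytest.raises(ValueError):
            m.train_ensemble(frs, toy_embedding, n_trees=5, seed=0)

    def test_same_seed_identical_predictions(self, train_fragments, tiny_embedding, tiny_bench):
        m1 = m.train_ensemble(train_fragments, tiny_embedding, n_trees=20, seed=5)
        m2 = m.train_ensemble(train_fragments, tiny_embedding, n_trees=20, seed=5)
        probe = [fr.sequence for fr in tiny_bench["test_fragments"]["A"][:30]]
        p1 = m.predict_fragments(probe, m1)
        p2 = m.predict_fragments(probe, m2)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.scores, b.scores)

    def test_tree_count_respected(self, tiny_ensemble):
        assert all(rf.n_estimators == 50 for rf in tiny_ensemble.per_bin_models.values())

    def test_score_vectors_are_distributions(self, tiny_ensemble, tiny_bench):
        frs = tiny_bench["test_fragments"]["A"][:50]
        for sc in m.predict_fragments([fr.sequence for fr in frs], tiny_ensemble):
            assert sc.scores.min() >= 0
            assert abs(sc.scores.sum() - 1) < 1e-9


class TestPersistence:
    def test_round_trip_predictions_identical(self, tmp_path, tiny_ensemble, tiny_bench):
        path = tmp_path / "model.joblib"
        m.save_model(tiny_ensemble, path)
        loaded = m.load_model(path)
        probe = [fr.sequence for fr in tiny_bench["test_fragments"]["A"][:20]]
        for a, b in zip(
            m.predict_fragments(probe, tiny_ensemble),
            m.predict_fragments(probe, loaded),
        ):
            assert np.array_equal(a.scores, b.scores)

    def test_checksum_mismatch_refused(self, tmp_path, tiny_ensemble):
        import joblib

        path = tmp_path / "model.joblib"
        m.save_model(tiny_ensemble, path)
        payload = joblib.load(path)
        tok = next(iter(payload["embedding_vectors"]))
        payload["embedding_vectors"][tok] = payload["embedding_vectors"][tok] + 1.0
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="checksum"):
            m.load_model(path)
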