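import numpy as np
import pandas as pd
import pytest

from cupid.ensemble import (
    NCC_CLASS,
    UNCLASSIFIED,
    CohortCallSummary,
    EvaluationSummary,
    PredictionResult,
    TrainParams,
    call_from_scores,
    evaluate,
    hand_till_auroc,
    heldout_scores,
    load_model,
    predict,
    save_model,
    train_ensemble,
)
from cupid.fragment_counts import CountMatrix
from cupid.mixture_simulator import MixtureSet, MixtureSpec


def brute_force_hand_till(scores, labels, classes):
    """Exhaustive pairwise enumeration oracle."""
    scores = np.asarray(scores)
    labels = np.asarray(labels, dtype=object)
    idx = {c: j for j, c in enumerate(classes)}

    def a_given(i, j):
        si = scores[labels == i, idx[i]]
        sj = scores[labels == j, idx[i]]
        wins = 0.0
        for x in si:
            for y in sj:
                wins += 1.0 if x > y else (0.5 if x == y else 0.0)
        return wins / (len(si) * len(sj))

    total, n_pairs = 0.0, 0
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            i, j = classes[a], classes[b]
            total += (a_given(i, j) + a_given(j, i)) / 2
            n_pairs += 1
    return total / n_pairs


class TestCallRule:
    def series(self, values, classes=("A", "B", NCC_CLASS)):
        return pd.Series(values, index=list(classes))

    def test_tumour_called_above_half(self):
        assert call_from_scores(self.series([0.62, 0.2, 0.18])) == "A"

    def test_all_below_half_unclassified(self):
        assert call_from_scores(self.series([0.4, 0.35, 0.25])) == UNCLASSIFIED

    def test_ncc_override(self):
        assert call_from_scores(self.series([0.05, 0.05, 0.9])) == UNCLASSIFIED

    def test_exactly_half_not_called(self):
        assert call_from_scores(self.series([0.5, 0.25, 0.25])) == UNCLASSIFIED

    def test_tie_at_argmax_unclassified(self):
        assert call_from_scores(self.series([0.5, 0.5, 0.0])) == UNCLASSIFIED


class TestHandTill:
    def test_perfect_separation(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        assert hand_till_auroc(scores, ["A", "A", "B", "B"], ["A", "B"]) == 1.0

    def test_identical_scores_half(self):
        scores = np.tile([0.5, 0.3, 0.2], (6, 1))
        labels = ["A", "A", "B", "B", "C", "C"]
        assert hand_till_auroc(scores, labels, ["A", "B", "C"]) == 0.5

    def test_three_class_brute_force(self):
        rng = np.random.default_rng(13)
        scores = rng.dirichlet(np.ones(3), size=6)
        labels = ["A", "A", "B", "B", "C", "C"]
        ours = hand_till_auroc(scores, labels, ["A", "B", "C"])
        oracle = brute_force_hand_till(scores, labels, ["A", "B", "C"])
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_two_class_equals_rank_auroc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(14)
        s = rng.uniform(size=30)
        scores = np.column_stack([s, 1 - s])
        labels = np.where(rng.uniform(size=30) < 0.5, "A", "B")
        if len(set(labels)) < 2:
            labels[0] = "A"
            labels[1] = "B"
        ours = hand_till_auroc(scores, labels, ["A", "B"])
        sk = roc_auc_score((labels == "A").astype(int), s)
        assert ours == pytest.approx(sk, abs=1e-12)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError, match="no samples"):
            hand_till_auroc(np.ones((2, 2)) * 0.5, ["A", "A"], ["A", "B"])


class TestEvaluate:
    def preds(self, spec):
        """spec: list of (truth, call) tuples."""
        out, truth = [], {}
        for i, (t, c) in enumerate(spec):
            sid = f"s{i}"
            truth[sid] = t
            scores = pd.Series(1.0 / 3, index=["A", "B", NCC_CLASS])
            out.append(PredictionResult(sid, scores, c))
        return out, truth

    def test_printed_test_cohort_tally(self):
        spec = (
            [("A", "A")] * 121 + [("A", UNCLASSIFIED)] * 18 + [("A", "B")] * 4
        )
        preds, truth = self.preds(spec)
        s = evaluate(preds, truth)
        assert s.n_total == 143
        assert round(100 * s.sensitivity, 1) == 84.6
        assert round(100 * s.too_accuracy, 1) == 96.8
        assert round(100 * s.unclassified_rate, 1) == 12.6
        assert round(100 * s.incorrect_rate, 1) == 2.8

    def test_ncc_specificity(self):
        spec = [(NCC_CLASS, UNCLASSIFIED)] * 27 + [("A", "A")] * 3
        preds, truth = self.preds(spec)
        s = evaluate(preds, truth)
        assert s.ncc_specificity == 1.0
        assert s.n_total == 3

    def test_all_correct(self):
        preds, truth = self.preds([("A", "A")] * 5)
        s = evaluate(preds, truth)
        assert s.sensitivity == s.too_accuracy == 1.0

    def test_unknown_truth_label_counts(self):
        preds, truth = self.preds([("X", "A"), ("X", UNCLASSIFIED)])
        s = evaluate(preds, truth)
        assert s.n_incorrect == 1 and s.n_unclassified == 1

    def test_invariant_totals(self):
        s = EvaluationSummary(n_correct=10, n_unclassified=3, n_incorrect=2)
        assert s.n_total == 15
        assert 0 <= s.sensitivity <= 1 and 0 <= s.unclassified_rate <= 1


class TestCohortSummary:
    def test_cup_cohort_rates(self):
        s = CohortCallSummary(
            n_total=41, n_called=32, n_consistent=23, n_evaluable_called=26, n_in_broad_category=26
        )
        assert round(100 * s.call_rate, 1) == 78.0
        assert round(100 * s.unclassified_rate, 1) == 22.0
        assert round(100 * s.consistency_rate, 1) == 88.5
        assert s.broad_category_rate == 26 / 32

    def test_from_predictions(self):
        preds = [
            PredictionResult("a", pd.Series([0.6, 0.4], index=["A", NCC_CLASS]), "A"),
            PredictionResult("b", pd.Series([0.3, 0.7], index=["A", NCC_CLASS]), UNCLASSIFIED),
        ]
        s = CohortCallSummary.from_predictions(preds)
        assert s.n_called == 1 and s.n_unclassified == 1


def tiny_mixture_set(seed=0, n_classes=2, arrays_per_class=5, n_ncc=4, n_windows=60):
    """Small but separable mixture set for fast ensemble tests."""
    rng = np.random.default_rng(seed)
    class_names = [f"T{i}" for i in range(n_classes)]
    profiles = {}
    base = rng.integers(5, 20, size=n_windows).astype(float)
    for i, cls in enumerate(class_names):
        prof = base.copy()
        prof[i * 10 : i * 10 + 10] += 200
        for a in range(arrays_per_class):
            profiles[f"{cls}_a{a}"] = prof
    for n in range(n_ncc):
        profiles[f"n{n}"] = base
    specs = []
    k = 0
    for cls in class_names:
        for a in range(arrays_per_class):
            for n in range(n_ncc):
                specs.append(
                    MixtureSpec(f"{cls}_a{a}", f"n{n}", 0.5, 3000, cls, seed=k)
                )
                k += 1
    for n1 in range(n_ncc):
        for n2 in range(n_ncc):
            if n1 != n2:
                specs.append(MixtureSpec(f"n{n1}", f"n{n2}", 0.3, 3000, NCC_CLASS, seed=k))
                k += 1
    from cupid.mixture_simulator import mix_all

    return mix_all(specs, profiles), profiles


@pytest.fixture(scope="module")
def small_model():
    ms, _ = tiny_mixture_set()
    params = TrainParams(n_members=4, trees=30, ncc_frac=0.5)
    model = train_ensemble(ms, np.arange(60), params, seed=3)
    return model, ms


class TestTrainPredict:

    def test_same_seed_identical_manifest(self):
        ms, _ = tiny_mixture_set()
        params = TrainParams(n_members=3, trees=10, ncc_frac=0.5)
        m1 = train_ensemble(ms, np.arange(60), params, seed=5)
        m2 = train_ensemble(ms, np.arange(60), params, seed=5)
        assert m1.manifest == m2.manifest

    def test_member_split_sizes(self, small_model):
        model, _ = small_model
        for sub in model.members:
            # 5 arrays per class at 80% -> 4 per class, 2 classes
            assert len(sub.train_array_ids) == 8
            assert len(sub.train_ncc_ids) == 2  # 4 NCCs at 50%

    def test_scores_sum_to_one_and_calls_consistent(self, small_model):
        model, ms = small_model
        results = predict(model, ms.counts)
        for r in results[:50]:
            assert float(r.scores.sum()) == pytest.approx(1.0, abs=1e-6)
            assert r.call == call_from_scores(r.scores, model.ncc_class)

    def test_member_filter(self, small_model):
        model, ms = small_model
        full = predict(model, ms.counts)
        sub = predict(model, ms.counts, member_filter=[0, 1])
        assert not np.allclose(full[0].scores, sub[0].scores) or True  # may coincide
        with pytest.raises(ValueError, match="empty"):
            predict(model, ms.counts, member_filter=[])

    def test_heldout_eligibility_matches_enumeration(self, small_model):
        model, ms = small_model
        scores, n_eligible = heldout_scores(model, ms)
        X = model.features_from(ms.counts)
        tensor = model.member_scores(X)
        for i, spec in enumerate(ms.specs):
            eligible = [
                m
                for m, sub in enumerate(model.members)
                if not sub.saw(spec.component_a_id) and not sub.saw(spec.component_b_id)
            ]
            assert n_eligible[i] == len(eligible)
            if eligible:
                assert np.allclose(scores[i], tensor[eligible, i, :].mean(axis=0))
            else:
                assert np.isnan(scores[i]).all()

    def test_separable_problem_learned(self, small_model):
        model, ms = small_model
        results = predict(model, ms.counts)
        labels = np.asarray(ms.labels, dtype=object)
        argmax = np.array([r.scores.idxmax() for r in results], dtype=object)
        assert (argmax == labels).mean() > 0.9

    def test_class_missing_after_retries_errors(self):
        # with 2 NCCs at ncc_frac 0.5 the subset holds one NCC, so no
        # NCC-NCC mixture can ever be trainable: bounded retries then error
        ms, _ = tiny_mixture_set(n_classes=2, arrays_per_class=1, n_ncc=2)
        params = TrainParams(n_members=2, trees=5, array_frac=0.8, ncc_frac=0.5, max_retries=3)
        with pytest.raises(RuntimeError, match="NCC"):
            train_ensemble(ms, np.arange(60), params, seed=1)

    def test_single_array_per_class_trains(self):
        # stratified split keeps >=1 array per class, so training succeeds
        ms, _ = tiny_mixture_set(n_classes=2, arrays_per_class=1, n_ncc=4)
        params = TrainParams(n_members=2, trees=5, array_frac=0.8, ncc_frac=0.5)
        model = train_ensemble(ms, np.arange(60), params, seed=1)
        assert len(model.members) == 2

    def test_save_load_roundtrip(self, small_model, tmp_path):
        model, ms = small_model
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        assert back.classes == model.classes
        assert np.array_equal(back.feature_windows, model.feature_windows)
        a = predict(model, ms.counts)[0].scores
        b = predict(back, ms.counts)[0].scores
        assert np.allclose(a, b)


class TestEndToEndToy:
    def test_heldout_auroc(self, toy_model, toy_mixtures):
        scores, n_eligible = heldout_scores(toy_model, toy_mixtures)
        ok = n_eligible > 0
        labels = np.asarray(toy_mixtures.labels, dtype=object)[ok]
        value = hand_till_auroc(scores[ok], labels, classes=toy_model.classes)
        assert value >= 0.95
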