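import dataclasses
from itertools import product

import joblib
import numpy as np
import pytest

from crforest.classifier import (LABEL_RANDOM, LABEL_REPEAT, ClassifierModel,
                                 EvalMetrics, MarkovModel, TrainConfig,
                                 classify_candidate, classify_repeat,
                                 evaluate, fit_markov, load_model,
                                 sample_negatives, save_model, split_dataset,
                                 train_classifier, train_pipeline)
from crforest.repeat_scan import CandidateArray, consensus
from crforest.structure_features import FEATURE_NAMES

_NT = "ACGT"


class _ScriptedVotes(ClassifierModel):
    """Test double whose tree-vote fraction is the first feature value."""

    def votes(self, X):
        return np.atleast_2d(np.asarray(X, dtype=float))[:, 0]


def _scripted(threshold=0.5):
    return _ScriptedVotes(ensemble=None, feature_order=FEATURE_NAMES,
                          config=TrainConfig(vote_threshold=threshold))


def _padded(v):
    row = np.zeros(32)
    row[0] = v
    return row


class TestMarkov:
    def test_degenerate_single_state_chain(self):
        m = fit_markov(["AA", "AA"])
        assert m.transition[0, 0] == 1.0 and m.initial[0] == 1.0

    def test_two_bigrams_counted_by_hand(self):
        m = fit_markov(["AC", "CA"])
        assert m.initial[0] == m.initial[1] == 0.5
        assert m.transition[0, 1] == 1.0  # A -> C
        assert m.transition[1, 0] == 1.0  # C -> A

    def test_unseen_rows_get_uniform_smoothing(self):
        m = fit_markov(["ACAC"])
        assert np.allclose(m.transition[2], 0.25)  # G never seen

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_markov([])

    def test_forced_outcome_sampling(self):
        m = fit_markov(["AA", "AA"])
        assert sample_negatives(m, 3, rng_seed=1) == ["AA", "AA", "AA"]

    def test_sampling_is_seeded_and_lengths_come_from_pool(self):
        m = fit_markov(["ACGTACGTAC", "ACGTAC"])
        a = sample_negatives(m, 20, rng_seed=5)
        b = sample_negatives(m, 20, rng_seed=5)
        assert a == b
        assert {len(s) for s in a} <= {6, 10}
        assert sample_negatives(m, 0, rng_seed=5) == []

    def test_sampled_bigrams_match_transitions(self):
        true = MarkovModel(initial=np.full(4, 0.25),
                           transition=np.array([[0.7, 0.1, 0.1, 0.1],
                                                [0.1, 0.7, 0.1, 0.1],
                                                [0.25, 0.25, 0.25, 0.25],
                                                [0.4, 0.1, 0.4, 0.1]]),
                           length_pool=[40])
        refit = fit_markov(sample_negatives(true, 3000, rng_seed=9))
        assert np.max(np.abs(refit.transition - true.transition)) < 0.02


class TestSplit:
    def test_reference_class_sizes(self):
        train, test = split_dataset(list(range(11407)),
                                    list(range(11407, 23407)))
        tr_pos = sum(lab == LABEL_REPEAT for _, lab in train)
        te_pos = sum(lab == LABEL_REPEAT for _, lab in test)
        assert (tr_pos, len(train) - tr_pos) == (9126, 9600)
        assert (te_pos, len(test) - te_pos) == (2281, 2400)

    def test_exact_division(self):
        train, test = split_dataset(list(range(10)), list(range(10)))
        assert len(train) == 16 and len(test) == 4

    def test_partitions_are_disjoint_and_exhaustive(self):
        pos, neg = list(range(100)), list(range(100, 220))
        train, test = split_dataset(pos, neg)
        items = [x for x, _ in train] + [x for x, _ in test]
        assert sorted(items) == pos + neg

    def test_same_seed_gives_identical_partitions(self):
        args = (list(range(50)), list(range(50, 120)),
                TrainConfig(rng_seed=42))
        assert split_dataset(*args) == split_dataset(*args)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1], [1, 2, 3])


class TestTrainClassify:
    def _separable(self, n=50):
        e1, e2 = np.zeros(32), np.zeros(32)
        e1[0] = 1.0
        e2[1] = 1.0
        return ([(e1, LABEL_REPEAT)] * n) + ([(e2, LABEL_RANDOM)] * n)

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        train = self._separable()
        model = train_classifier(train, TrainConfig(ntree=50, rng_seed=0))
        metrics = evaluate(model, train)
        assert metrics.accuracy == 1.0 and metrics.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_classifier([(np.zeros(32), LABEL_REPEAT)] * 4)

    def test_feature_width_enforced(self):
        model = train_classifier(self._separable(),
                                 TrainConfig(ntree=10, rng_seed=0))
        with pytest.raises(ValueError):
            classify_repeat(model, np.zeros(16))

    def test_training_is_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        data = [(rng.random(32), LABEL_REPEAT if i % 2 else LABEL_RANDOM)
                for i in range(80)]
        probe = rng.random((20, 32))
        m1 = train_classifier(data, TrainConfig(ntree=60, rng_seed=7))
        m2 = train_classifier(data, TrainConfig(ntree=60, rng_seed=7))
        assert np.array_equal(m1.votes(probe), m2.votes(probe))

    def test_vote_threshold_rule_ties_go_to_repeat(self):
        model = _scripted()
        assert classify_repeat(model, _padded(1.0)) == (LABEL_REPEAT, 1.0)
        assert classify_repeat(model, _padded(0.5))[0] == LABEL_REPEAT
        assert classify_repeat(model, _padded(0.49))[0] == LABEL_RANDOM


class TestEvaluate:
    def test_perfect_predictions(self):
        test = [(_padded(0.9), LABEL_REPEAT), (_padded(0.8), LABEL_REPEAT),
                (_padded(0.1), LABEL_RANDOM), (_padded(0.2), LABEL_RANDOM)]
        m = evaluate(_scripted(), test)
        assert m == EvalMetrics(accuracy=1.0, sensitivity=1.0,
                                specificity=1.0, precision=1.0, auc=1.0)

    def test_hand_computed_rank_statistic(self):
        interleaved = [(_padded(0.9), LABEL_REPEAT),
                       (_padded(0.1), LABEL_REPEAT),
                       (_padded(0.8), LABEL_RANDOM),
                       (_padded(0.2), LABEL_RANDOM)]
        assert evaluate(_scripted(), interleaved).auc == pytest.approx(0.5)

    def test_auc_equals_concordant_pair_count(self):
        rng = np.random.default_rng(31)
        votes_pos = rng.integers(0, 10, 40) / 10
        votes_neg = rng.integers(0, 10, 35) / 10
        test = [(_padded(v), LABEL_REPEAT) for v in votes_pos] + \
               [(_padded(v), LABEL_RANDOM) for v in votes_neg]
        concordant = sum((p > n) + 0.5 * (p == n)
                         for p, n in product(votes_pos, votes_neg))
        expected = concordant / (len(votes_pos) * len(votes_neg))
        assert evaluate(_scripted(), test).auc == pytest.approx(expected,
                                                                abs=1e-12)

    def test_one_class_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_scripted(), [(_padded(0.9), LABEL_REPEAT)] * 3)


def _toy_candidate(repeat, spacers):
    pos, rep_iv, sp_iv = 0, [], []
    n = len(spacers) + 1
    for i in range(n):
        rep_iv.append((pos, pos + len(repeat)))
        pos += len(repeat)
        if i < len(spacers):
            sp_iv.append((pos, pos + len(spacers[i])))
            pos += len(spacers[i])
    return CandidateArray(genome_id="g", repeat_intervals=rep_iv,
                          spacer_intervals=sp_iv, repeat_seqs=[repeat] * n,
                          spacer_seqs=list(spacers),
                          consensus_repeat=consensus([repeat] * n))


class TestCandidateClassification:
    def test_identical_consensus_gives_identical_result(self, trained_model):
        c1 = _toy_candidate("GGGCGCAATGCCTATAGGCATTGCGCC" + "TAGGC",
                            ["A" * 20, "C" * 20])
        c2 = _toy_candidate(c1.consensus_repeat, ["T" * 25, "G" * 25])
        assert classify_candidate(trained_model, c1) == \
            classify_candidate(trained_model, c2)

    def test_majority_mode_runs(self, trained_model):
        cand = _toy_candidate("GGGCGCAATGCCTATAGGCATTGCGCC",
                              ["ACGTACGTACGTACGTACGT"] * 2)
        label, vote = classify_candidate(trained_model, cand,
                                         mode="majority")
        assert label in (LABEL_REPEAT, LABEL_RANDOM) and 0 <= vote <= 1

    def test_unknown_mode_rejected(self, trained_model):
        with pytest.raises(ValueError):
            classify_candidate(trained_model, _toy_candidate(
                "GGGCGCAATGCCTATAGGCATTGCGCC", ["A" * 20] * 2), mode="best")


class TestTrainPipelineAndPersistence:
    def test_end_to_end_training_is_reproducible(self):
        from crforest.synthetic_data import make_training_repeats
        pos = make_training_repeats(80, rng_seed=2)
        cfg = TrainConfig(ntree=40, rng_seed=9)
        m1, met1, sum1 = train_pipeline(pos, config=cfg)
        m2, met2, sum2 = train_pipeline(pos, config=cfg)
        assert met1 == met2 and sum1 == sum2
        probe = np.random.default_rng(1).random((10, 32))
        assert np.array_equal(m1.votes(probe), m2.votes(probe))

    def test_negatives_default_to_markov_ratio(self):
        from crforest.synthetic_data import make_training_repeats
        pos = make_training_repeats(100, rng_seed=3)
        model, _, _ = train_pipeline(pos, config=TrainConfig(ntree=20,
                                                             rng_seed=4))
        assert model.provenance["n_negative_input"] == 105

    def test_save_load_round_trip(self, trained_model, tmp_path):
        path = tmp_path / "model.crf"
        save_model(trained_model, path)
        loaded = load_model(path)
        probe = np.random.default_rng(8).random((5, 32))
        assert np.array_equal(loaded.votes(probe), trained_model.votes(probe))
        assert loaded.config == trained_model.config

    def test_feature_order_mismatch_is_a_hard_error(self, trained_model,
                                                    tmp_path):
        path = tmp_path / "model.crf"
        save_model(trained_model, path)
        blob = joblib.load(path)
        blob["feature_order"] = blob["feature_order"][::-1]
        joblib.dump(blob, path)
        with pytest.raises(ValueError, match="feature order"):
            load_model(path)
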