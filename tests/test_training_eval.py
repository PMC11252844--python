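"""Loss, metrics against brute-force oracles, and the training loop."""

import math

import numpy as np
import pytest

import eqppis as eq
from eqppis.training_eval import Adam, ReduceLROnPlateau, ce_loss, metrics_from_counts


# -- independent oracles -----------------------------------------------------

def pairwise_auroc(labels, scores):
    """Mann-Whitney definition: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def step_auprc(labels, scores):
    """Average precision summed over distinct thresholds (samples with equal
    scores enter the ranking together)."""
    n_pos = labels.sum()
    tp = fp = 0
    prev_recall = 0.0
    ap = 0.0
    for s in sorted(set(scores), reverse=True):
        at = scores == s
        tp += int(labels[at].sum())
        fp += int((1 - labels[at]).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def brute_counts(labels, scores, thr):
    tp = tn = fp = fn = 0
    for y, s in zip(labels, scores):
        call = 1 if s >= thr else 0
        if call and y:
            tp += 1
        elif call and not y:
            fp += 1
        elif not call and y:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


# -- loss ---------------------------------------------------------------------

class TestCELoss:
    def test_uniform_binary_prediction_costs_ln2(self):
        p = np.full((10, 2), 0.5)
        y = np.zeros((10, 2))
        y[:, 1] = 1
        assert math.isclose(ce_loss(p, y), math.log(2.0), rel_tol=1e-12)

    def test_perfect_prediction_costs_zero(self):
        y = np.eye(2)[np.array([0, 1, 1, 0])]
        assert ce_loss(y, y) == 0.0

    def test_matches_per_sample_summation_oracle(self, rng):
        for _ in range(20):
            n, m = int(rng.integers(1, 30)), int(rng.integers(2, 5))
            p = rng.dirichlet(np.ones(m), size=n)
            y = np.eye(m)[rng.integers(0, m, size=n)]
            expected = np.mean(
                [-sum(y[i, c] * math.log(max(p[i, c], 1e-12)) for c in range(m))
                 for i in range(n)]
            )
            assert math.isclose(ce_loss(p, y), expected, rel_tol=1e-12)

    def test_nonnegative_and_clipped_for_zero_probability(self):
        p = np.array([[0.0, 1.0]])
        y = np.array([[1.0, 0.0]])
        loss = ce_loss(p, y)
        assert 0 < loss <= -math.log(1e-12) + 1e-9

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ce_loss(np.ones((2, 2)), np.ones((3, 2)))


# -- evaluation ---------------------------------------------------------------

class TestEvaluate:
    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 80))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            thr = float(rng.choice([0.3, 0.5, 0.7]))
            rep = eq.evaluate(scores, labels, threshold=thr)
            tp, tn, fp, fn = brute_counts(labels, scores, thr)
            assert (rep.tp, rep.tn, rep.fp, rep.fn) == (tp, tn, fp, fn)
            m = metrics_from_counts(tp, tn, fp, fn)
            for k in ("acc", "precision", "recall", "f1", "mcc"):
                assert math.isclose(getattr(rep, k), m[k], abs_tol=1e-9)
            assert math.isclose(rep.auroc, pairwise_auroc(labels, scores), abs_tol=1e-6)
            assert math.isclose(rep.auprc, step_auprc(labels, scores), abs_tol=1e-6)

    def test_interface_case_counts_give_expected_rates(self):
        # a 107-residue chain with 14 TP / 70 TN / 14 FP / 9 FN
        tp, tn, fp, fn = 14, 70, 14, 9
        labels = np.array([1] * tp + [0] * tn + [0] * fp + [1] * fn)
        scores = np.array([0.9] * tp + [0.1] * tn + [0.9] * fp + [0.1] * fn)
        rep = eq.evaluate(scores, labels)
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (tp, tn, fp, fn)
        assert math.isclose(rep.precision, 14 / 28, abs_tol=1e-12)
        assert math.isclose(rep.recall, 14 / 23, abs_tol=1e-12)
        denom = math.sqrt(28 * 23 * 84 * 79)
        assert math.isclose(rep.mcc, (14 * 70 - 14 * 9) / denom, abs_tol=1e-12)

    def test_perfect_predictions(self):
        labels = np.array([0, 1, 1, 0, 1])
        rep = eq.evaluate(labels.astype(float), labels)
        assert rep.acc == rep.f1 == rep.mcc == 1.0

    def test_random_scores_give_half_auroc(self, rng):
        labels = rng.integers(0, 2, size=200)
        scores = rng.random(200)
        rep = eq.evaluate(scores, labels)
        assert abs(rep.auroc - 0.5) < 0.12  # ~3 sigma of the U statistic

    def test_single_class_reports_undefined_areas(self):
        rep = eq.evaluate(np.array([0.2, 0.8]), np.array([1, 1]))
        assert rep.auroc is None and rep.auprc is None

    def test_per_chain_counts_sum_to_pooled_table(self, rng):
        scores = [rng.random(20), rng.random(30)]
        labels = [rng.integers(0, 2, 20), rng.integers(0, 2, 30)]
        rep = eq.evaluate(scores, labels, chain_ids=["a", "b"])
        assert len(rep.per_chain) == 2
        assert sum(c[1] for c in rep.per_chain) == rep.tp
        assert rep.tp + rep.tn + rep.fp + rep.fn == 50

    def test_macro_averaging_runs(self, rng):
        scores = [rng.random(20), rng.random(30)]
        labels = [rng.integers(0, 2, 20), rng.integers(0, 2, 30)]
        pooled = eq.evaluate(scores, labels)
        macro = eq.evaluate(scores, labels, macro=True)
        assert 0 <= macro.acc <= 1 and macro.tp == pooled.tp

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            eq.evaluate([np.zeros(3)], [np.zeros(4, dtype=int)])


# -- optimiser / scheduler -----------------------------------------------------

class TestScheduler:
    def test_plateau_halves_learning_rate(self):
        opt = Adam([], lr=0.1)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=2, min_lr=1e-6)
        sched.step(1.0)
        for _ in range(3):
            sched.step(1.0)  # no improvement
        assert opt.lr == 0.05

    def test_learning_rate_never_below_floor(self):
        opt = Adam([], lr=1e-5)
        sched = ReduceLROnPlateau(opt, factor=0.1, patience=0, min_lr=1e-6)
        for _ in range(10):
            sched.step(1.0)
        assert opt.lr == 1e-6


# -- training loop --------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_dataset():
    return eq.generate_dataset(6, eq.SyntheticSpec(), seed=31, residue_range=(20, 30))


class TestTrain:

    def test_loss_decreases_on_planted_signal(self, tiny_dataset):
        mc = eq.ModelConfig(seed=3)
        tc = eq.TrainConfig(seed=3, epochs=6)
        _, history = eq.train(tiny_dataset.train, mc, tc)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_training_is_deterministic(self, tiny_dataset):
        mc = eq.ModelConfig(seed=5)
        tc = eq.TrainConfig(seed=5, epochs=2)
        _, h1 = eq.train(tiny_dataset.train[:2], mc, tc)
        _, h2 = eq.train(tiny_dataset.train[:2], mc, tc)
        assert [r["train_loss"] for r in h1] == [r["train_loss"] for r in h2]

    def test_single_graph_memorisation(self):
        chain = eq.generate_chain(eq.SyntheticSpec(n_residues=20, seed=41))
        mc = eq.ModelConfig(seed=2)
        tc = eq.TrainConfig(seed=2, epochs=60, val_fraction=0.0)
        _, history = eq.train([chain.graph], mc, tc)
        assert min(r["train_loss"] for r in history) < 0.05

    def test_unlabelled_graph_rejected(self, tiny_dataset):
        g = tiny_dataset.train[0]
        bare = eq.ProteinGraph(
            coords=g.coords, features=g.features, adjacency=g.adjacency
        )
        with pytest.raises(ValueError):
            eq.train([bare], eq.ModelConfig(), eq.TrainConfig(epochs=1))
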