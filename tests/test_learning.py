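"""Tests of the correlation-based structural-plasticity learning rule."""

import numpy as np
import pytest

import dendritic as dn
from dendritic.data import BinaryPatternSet
from dendritic.learning import Trainer, margin_stats
from dendritic.model import branch_nonlinearity


def _patterns(X, labels, n_classes):
    return BinaryPatternSet(np.asarray(X), np.asarray(labels), n_classes)


def correlation_oracle(model, patterns, mu, side):
    """Brute-force per-pattern loop implementing the learning signal."""
    tp = model.trees[mu]
    cm = tp.pdt if side == "pdt" else tp.ndt
    zleak = tp.zleak_pdt if side == "pdt" else tp.zleak_ndt
    c = np.zeros((cm.m, cm.d))
    for p in range(patterns.P):
        x = patterns.X[p].astype(float)
        y = dn.margin_outputs(model, x, patterns.labels[p])
        y_d = 1.0 if patterns.labels[p] == mu else 0.0
        sgn = np.sign(y_d - y[mu])
        for j in range(cm.m):
            b_j = branch_nonlinearity(float(cm.W[j] @ x), zleak[j])
            for i in range(cm.d):
                c[j, i] += x[i] * b_j * sgn
    c /= patterns.P
    return c if side == "pdt" else -c


class TestCorrelationMap:
    def test_all_correct_gives_zero(self, rng):
        model = dn.init_model(2, 6, 1, 2, rng)
        X = rng.integers(0, 2, (20, 6))
        labels = model.predict(X)  # every pattern labeled by the model itself
        # drop score ties: a tied pattern has y = 0.5 != y_d, i.e. not correct
        o = model.scores_batch(X)
        _, _, sat = margin_stats(o, labels, model.margins)
        X, labels = X[sat], labels[sat]
        assert len(X) > 0
        ps = _patterns(X, labels, 2)
        for mu in range(2):
            for side in ("pdt", "ndt"):
                assert (dn.correlation_map(model, ps, mu, side) == 0).all()

    def test_single_pattern_hand_value(self):
        # one dendrite w=[2,0], x=[1,1]: z=2, b=(2-0)^2=4; pattern of class 0
        # misclassified (y^0=0) -> sgn=+1; c_PDT[0,0]=1*4, c_NDT flips sign
        pdt = dn.ConnectionMatrix(np.array([[2, 0]]), k=2)
        ndt = dn.ConnectionMatrix(np.array([[0, 2]]), k=2)
        # NDT sees x -> z=2, b=4, so o^0 = 0; second class outscores it
        pdt1 = dn.ConnectionMatrix(np.array([[1, 1]]), k=2)
        ndt1 = dn.ConnectionMatrix(np.array([[2, 0]]), k=2)
        trees = [dn.TreePair(pdt, ndt, np.zeros(1), np.zeros(1)),
                 dn.TreePair(pdt1, ndt1, np.zeros(1), np.full(1, 99.0))]
        model = dn.ClassifierModel(trees, [0.0, 0.0], d=2, k=2)
        ps = _patterns([[1, 1]], [0], 2)
        o = model.scores_batch(ps.X)[0]
        assert o[0] == 0.0 and o[1] == 4.0  # class 0 loses -> sgn = +1
        c_pdt = dn.correlation_map(model, ps, 0, "pdt")
        c_ndt = dn.correlation_map(model, ps, 0, "ndt")
        assert c_pdt[0, 0] == 4.0
        assert c_ndt[0, 0] == -4.0

    def test_silent_input_column_is_zero(self, rng):
        model = dn.init_model(2, 5, 2, 2, rng)
        X = rng.integers(0, 2, (10, 5))
        X[:, 3] = 0
        ps = _patterns(X, rng.integers(0, 2, 10), 2)
        for side in ("pdt", "ndt"):
            assert (dn.correlation_map(model, ps, 0, side)[:, 3] == 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P, d, n_c = 15, 8, 3
        X = rng.integers(0, 2, (P, d))
        model = dn.init_model(n_c, d, 2, 3, rng, X=X)
        model.margins = rng.uniform(0, 2, n_c)
        ps = _patterns(X, rng.integers(0, n_c, P), n_c)
        for mu in range(n_c):
            for side in ("pdt", "ndt"):
                fast = dn.correlation_map(model, ps, mu, side)
                slow = correlation_oracle(model, ps, mu, side)
                assert np.allclose(fast, slow)


class TestPickTarget:
    def test_exhaustive_set_finds_global_minimum(self, rng):
        W = np.array([[1, 2, 0], [0, 1, 2]])
        c = np.array([[0.5, 0.1, 9.0], [9.0, -0.3, 0.2]])
        i, j = dn.pick_target(W, c, n_T=6, rng=rng)
        assert (i, j) == (1, 1)  # smallest c among *active* slots

    def test_single_synapse(self, rng):
        W = np.array([[1]])
        assert dn.pick_target(W, np.array([[0.7]]), 1, rng) == (0, 0)

    def test_deterministic_under_seed(self):
        W = np.array([[2, 1, 1, 0, 1], [1, 0, 2, 1, 1]])
        c = np.random.default_rng(0).normal(size=W.shape)
        picks = {dn.pick_target(W, c, 3, np.random.default_rng(42))
                 for _ in range(5)}
        assert len(picks) == 1

    def test_rejects_oversized_candidate_set(self, rng):
        with pytest.raises(ValueError):
            dn.pick_target(np.array([[1, 1]]), np.zeros((1, 2)), 3, rng)


class TestProposeReplacement:
    def test_single_candidate(self, rng):
        r = dn.propose_replacement(np.array([0.3, 0.1, 0.9]), 1, rng)
        assert r in (0, 1, 2)

    def test_argmax_with_full_candidate_set(self, rng):
        c_row = np.array([0.1, 0.9, 0.4])
        assert dn.propose_replacement(c_row, 3, rng) == 1

    def test_all_equal_takes_first_candidate(self):
        rng = np.random.default_rng(3)
        first = rng.choice(4, size=4, replace=False)[0]
        r = dn.propose_replacement(np.zeros(4), 4, np.random.default_rng(3))
        assert r == first


class TestAttemptSwap:
    def test_noop_swap_is_accepted(self, rng):
        model = dn.init_model(2, 6, 2, 2, rng)
        ps = _patterns(rng.integers(0, 2, (6, 6)), rng.integers(0, 2, 6), 2)
        W = model.trees[0].pdt.W
        j, i = next(zip(*np.nonzero(W)))
        err0 = dn.margin_error(model, ps.X, ps.labels)
        accepted, err = dn.attempt_swap(model, ps, 0, "pdt", i, j, i)
        assert accepted and err == err0

    def test_row_sums_preserved_either_way(self, rng):
        model = dn.init_model(2, 6, 2, 3, rng)
        ps = _patterns(rng.integers(0, 2, (10, 6)), rng.integers(0, 2, 10), 2)
        for _ in range(20):
            side = "pdt" if rng.random() < 0.5 else "ndt"
            cm = model.trees[0].pdt if side == "pdt" else model.trees[0].ndt
            js, is_ = np.nonzero(cm.W)
            pick = rng.integers(len(js))
            dn.attempt_swap(model, ps, 0, side,
                            int(is_[pick]), int(js[pick]),
                            int(rng.integers(6)))
            cm.validate()

    def test_beneficial_swap_fixes_the_error(self):
        # class 0 must respond to afferent 0, but its PDT listens to line 2
        pdt = dn.ConnectionMatrix(np.array([[0, 0, 1]]), k=1)
        ndt = dn.ConnectionMatrix(np.array([[0, 1, 0]]), k=1)
        silent = np.full(1, 99.0)
        trees = [dn.TreePair(pdt, ndt, np.zeros(1), silent.copy()),
                 dn.TreePair(dn.ConnectionMatrix(np.array([[0, 1, 0]]), k=1),
                             dn.ConnectionMatrix(np.array([[0, 0, 1]]), k=1),
                             np.zeros(1), silent.copy())]
        model = dn.ClassifierModel(trees, [0.0, 0.0], d=3, k=1)
        ps = _patterns([[1, 0, 0], [0, 1, 0]], [0, 1], 2)
        assert dn.margin_error(model, ps.X, ps.labels) == 0.5
        accepted, err = dn.attempt_swap(model, ps, 0, "pdt", 2, 0, 0)
        assert accepted and err == 0.0


class TestMargins:
    def test_zero_errors_zero_margins(self, rng):
        model = dn.init_model(2, 8, 2, 2, rng)
        X = rng.integers(0, 2, (10, 8))
        ps = _patterns(X, model.predict(X), 2)
        delta, alphas = dn.set_margins(model, ps)
        assert (delta == 0).all()
        assert all(len(a) == 0 for a in alphas.values())

    def test_margin_is_max_score_deficit(self, rng):
        model = dn.init_model(3, 10, 2, 3, rng, X=rng.integers(0, 2, (20, 10)))
        X = rng.integers(0, 2, (30, 10))
        o = model.scores_batch(X)
        pred = np.argmax(o, axis=1)
        # label everything class 0: deficits are o[pred]-o[0] on errors
        ps = _patterns(X, np.zeros(30, dtype=int), 3)
        delta, alphas = dn.set_margins(model, ps)
        wrong = pred != 0
        if wrong.any():
            expected = np.max(o[wrong, pred[wrong]] - o[wrong, 0])
            assert delta[0] == pytest.approx(expected)
        assert delta[1] == 0 and delta[2] == 0  # no patterns of those classes

    def test_empty_validation_set_rejected(self, rng):
        model = dn.init_model(2, 4, 1, 2, rng)
        with pytest.raises(ValueError):
            dn.set_margins(model, _patterns(np.zeros((0, 4)), [], 2))


class TestTrainLoop:
    def _orthogonal_task(self):
        # 4 mutually orthogonal patterns, one class each
        X = np.zeros((4, 16), dtype=int)
        for c in range(4):
            X[c, 4 * c: 4 * c + 4] = 1
        return _patterns(X, np.arange(4), 4)

    def test_memorizes_orthogonal_patterns(self):
        ps = self._orthogonal_task()
        rng = np.random.default_rng(0)
        model = dn.init_model(4, 16, 2, 2, rng, X=ps.X)
        params = dn.LearnParams(n_T=4, n_R=16, n_ch=20, n_min=50)
        best, hist = dn.train(model, ps, params, rng=rng)
        assert dn.hard_error(best, ps.X, ps.labels) == 0.0
        assert hist.stop_reason == "memorized"

    def test_zero_budget_returns_initial_model(self, rng):
        ps = self._orthogonal_task()
        model = dn.init_model(4, 16, 2, 2, rng, X=ps.X)
        params = dn.LearnParams(n_T=4, n_R=16, n_min=0)
        best, hist = dn.train(model, ps, params, seed=0)
        assert hist.iterations == 0
        for tp_a, tp_b in zip(best.trees, model.trees):
            assert (tp_a.pdt.W == tp_b.pdt.W).all()
            assert (tp_a.ndt.W == tp_b.ndt.W).all()

    def test_same_seed_identical_runs(self):
        ps = self._orthogonal_task()
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            model = dn.init_model(4, 16, 2, 2, rng, X=ps.X)
            params = dn.LearnParams(n_T=4, n_R=16, n_ch=10, n_min=20)
            best, hist = dn.train(model, ps, params, rng=rng)
            runs.append((best, hist))
        (m1, h1), (m2, h2) = runs
        assert h1.error == h2.error and h1.minima == h2.minima
        for tp_a, tp_b in zip(m1.trees, m2.trees):
            assert (tp_a.pdt.W == tp_b.pdt.W).all()

    def test_best_error_nonincreasing_and_row_sums_hold(self):
        rng = np.random.default_rng(4)
        train, _ = dn.make_benchmark(seed=4)
        model = dn.init_model(4, 64, 4, 5, rng, X=train.X)
        params = dn.LearnParams(n_ch=10, n_min=15)
        best, hist = dn.train(model, train, params, rng=rng)
        assert (np.diff(hist.best_error) <= 0).all()
        for tp in best.trees:
            tp.pdt.validate()
            tp.ndt.validate()

    def test_forced_swap_escapes_and_counts_minima(self):
        # contradictory labels: identical patterns in both classes, error
        # can never reach zero, so stagnation minima must accumulate
        X = np.tile(np.array([[1, 0, 1, 0]]), (4, 1))
        ps = _patterns(X, [0, 0, 1, 1], 2)
        rng = np.random.default_rng(1)
        model = dn.init_model(2, 4, 1, 2, rng, X=ps.X)
        params = dn.LearnParams(n_T=2, n_R=4, n_ch=5, n_min=10)
        best, hist = dn.train(model, ps, params, rng=rng)
        assert hist.stop_reason == "n_min"
        assert hist.minima == 10
        assert dn.margin_error(best, ps.X, ps.labels) >= 0.5


class TestGreedyLimit:
    def test_full_sets_match_exhaustive_best_swap_oracle(self):
        """With n_T = s and n_R = d the target is the global active minimum
        of c and the replacement the global argmax of its dendrite row."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            W = dn.random_connection_matrix(2, 6, 2, rng).W
            c = rng.normal(size=(2, 6))
            i_t, j_t = dn.pick_target(W, c, int(W.sum()),
                                      np.random.default_rng(seed + 100))
            active = [(j, i) for j, i in zip(*np.nonzero(W))]
            j_best, i_best = min(active, key=lambda ji: c[ji[0], ji[1]])
            assert (i_t, j_t) == (i_best, j_best)
            r = dn.propose_replacement(c[j_t], 6,
                                       np.random.default_rng(seed + 200))
            assert r == int(np.argmax(c[j_t]))


def test_margin_stats_consistency(rng):
    o = rng.normal(size=(12, 4))
    labels = rng.integers(0, 4, 12)
    margins = rng.uniform(0, 1, 4)
    alpha, nu, sat = margin_stats(o, labels, margins)
    for p in range(12):
        others = np.delete(o[p], labels[p])
        assert alpha[p] == pytest.approx(o[p, labels[p]] - others.max())
        assert nu[p] != labels[p]
        assert sat[p] == (alpha[p] > 0 and alpha[p] >= margins[labels[p]])
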