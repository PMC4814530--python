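"""Tests of the spike encoders, PSC kernel, LIF dynamics and the spiking
classification path."""

import numpy as np
import pytest

import dendritic as dn
from dendritic.spiking import (LIFParams, PSCParams, afferent_currents,
                               spike_scores, time_grid)


class TestPSCKernel:
    def test_zero_at_onset_and_before(self):
        p = PSCParams()
        assert dn.psc_kernel(5.0, 5.0, p) == 0.0
        assert dn.psc_kernel(4.0, 5.0, p) == 0.0
        t = np.linspace(0, 4.9, 50)
        assert (dn.psc_kernel(t, 5.0, p) == 0).all()

    def test_positive_after_onset(self):
        p = PSCParams()
        t = np.linspace(5.01, 100, 500)
        assert (dn.psc_kernel(t, 5.0, p) > 0).all()

    def test_peak_time_matches_closed_form(self):
        p = PSCParams(tau_f=10.0, tau_r=2.0)
        t = np.arange(0, 60, 1e-3)
        k = dn.psc_kernel(t, 0.0, p)
        t_peak = t[np.argmax(k)]
        expected = p.tau_f * p.tau_r / (p.tau_f - p.tau_r) * np.log(p.tau_f / p.tau_r)
        assert t_peak == pytest.approx(expected, abs=2e-3)
        assert dn.psc_peak_time(p) == pytest.approx(expected)

    def test_integral_closed_form(self):
        p = PSCParams(i0=2.0, tau_f=8.0, tau_r=1.5)
        t = np.arange(0, 400, 0.01)  # long window: tails negligible
        integral = np.trapezoid(dn.psc_kernel(t, 0.0, p), t)
        assert integral == pytest.approx(p.i0 * (p.tau_f - p.tau_r), rel=1e-3)

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            PSCParams(tau_f=2.0, tau_r=5.0)


class TestEncoders:
    def test_single_spike_noiseless_at_t_syn(self):
        pat = dn.encode_single_spike(np.array([1, 0, 1]))
        assert pat.trains[0].tolist() == [100.0]
        assert pat.trains[1].size == 0
        assert pat.trains[2].tolist() == [100.0]

    def test_jitter_window(self, rng):
        for _ in range(20):
            pat = dn.encode_single_spike(np.array([1]), jitter=10.0, rng=rng)
            assert 95.0 <= pat.trains[0][0] <= 105.0

    def test_window_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            dn.encode_single_spike(np.array([1]), t_syn=10.0, jitter=30.0)

    def test_poisson_rates_match_nominal(self):
        rng = np.random.default_rng(7)
        n_trials, T = 1000, 200.0
        counts_hi, counts_lo = [], []
        for _ in range(n_trials):
            pat = dn.encode_poisson(np.array([1, 0]), f_high=250.0, f_low=1.0,
                                    duration=T, rng=rng)
            counts_hi.append(pat.trains[0].size)
            counts_lo.append(pat.trains[1].size)
        for counts, rate in [(counts_hi, 250.0), (counts_lo, 1.0)]:
            mean_expected = rate * T / 1000.0
            se = np.sqrt(mean_expected / n_trials)  # Poisson SE of the mean
            assert abs(np.mean(counts) - mean_expected) <= 3 * se

    def test_zero_duration_empty(self):
        pat = dn.encode_poisson(np.array([1, 1]), duration=0.0)
        assert pat.n_spikes == 0

    def test_spike_times_validated(self):
        with pytest.raises(ValueError):
            dn.SpikePattern([np.array([250.0])], duration=200.0)


class TestInputCurrent:
    def _tree(self, rng, m=2, d=4, k=2):
        pdt = dn.random_connection_matrix(m, d, k, rng)
        ndt = dn.random_connection_matrix(m, d, k, rng)
        return dn.TreePair(pdt, ndt, np.zeros(m), np.zeros(m))

    def test_no_spikes_no_current(self, rng):
        tree = self._tree(rng)
        pat = dn.SpikePattern([np.array([])] * 4, duration=50.0)
        t = time_grid(50.0, 0.5)
        i_plus, i_minus = dn.input_current(tree, pat, t)
        assert (i_plus == 0).all() and (i_minus == 0).all()

    def test_identical_trees_cancel(self, rng):
        pdt = dn.random_connection_matrix(2, 4, 2, rng)
        tree = dn.TreePair(pdt, pdt.copy(), np.zeros(2), np.zeros(2))
        pat = dn.SpikePattern([np.array([10.0]), np.array([]),
                               np.array([5.0, 20.0]), np.array([])],
                              duration=50.0)
        t = time_grid(50.0, 0.5)
        i_plus, i_minus = dn.input_current(tree, pat, t)
        assert np.allclose(i_plus, 0) and np.allclose(i_minus, 0)

    def test_single_synapse_single_spike_hand_value(self):
        psc = PSCParams()
        pdt = dn.ConnectionMatrix(np.array([[2]]), k=2)
        ndt = dn.ConnectionMatrix(np.array([[2]]), k=2)
        # huge NDT leak level silences the NDT wherever the leak trace is on
        tree = dn.TreePair(pdt, ndt, np.zeros(1), np.full(1, 1e9))
        pat = dn.SpikePattern([np.array([10.0])], duration=40.0)
        t = np.array([5.0, 15.0, 30.0])
        i_plus, _ = dn.input_current(tree, pat, t, psc, t_syn=10.0)
        for n, tv in enumerate(t):
            z = 2 * dn.psc_kernel(tv, 10.0, psc)
            assert i_plus[n] == pytest.approx(dn.branch_nonlinearity(z, 0.0))


class TestLIF:
    def test_silent_under_zero_input(self):
        assert dn.lif_simulate(np.zeros(5000)) == 0

    def test_subthreshold_constant_input(self):
        # steady state of the membrane equation with u = 0 is V = I
        p = LIFParams()
        i_const = np.full(20000, 0.9 * p.v_thr)
        n, trace = dn.lif_simulate(i_const, p, record=True)
        assert n == 0
        assert trace.max() < p.v_thr

    def test_strong_input_spikes_and_counts_grow_with_t(self):
        p = LIFParams()
        n_short = dn.lif_simulate(np.full(1000, 1.0), p)
        n_long = dn.lif_simulate(np.full(4000, 1.0), p)
        assert 0 < n_short < n_long

    def test_halving_dt_changes_count_by_at_most_one(self):
        # PSC-driven currents, the regime the classifier actually operates in
        psc = PSCParams()
        for scale in (1.0, 2.0, 5.0, 8.0):
            counts = []
            for dt in (0.1, 0.05):
                t = time_grid(200.0, dt)
                i_in = scale * dn.psc_kernel(t, 100.0, psc) ** 2
                counts.append(dn.lif_simulate(i_in, LIFParams(dt=dt)))
            assert abs(counts[0] - counts[1]) <= 1

    def test_sustained_drive_rate_is_step_size_robust(self):
        # long suprathreshold drive: counts agree to a few percent
        n1 = dn.lif_simulate(np.full(2000, 1.0), LIFParams(dt=0.1))
        n2 = dn.lif_simulate(np.full(4000, 1.0), LIFParams(dt=0.05))
        assert abs(n1 - n2) / n2 < 0.05

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            LIFParams(dt=0.0)
        with pytest.raises(ValueError):
            LIFParams(v_reset=0.1)


class TestSpikingClassification:
    def test_all_zero_pattern_ties_to_lowest_class(self, trained_model):
        pat = dn.encode_single_spike(np.zeros(trained_model.d))
        y = dn.classify_spikes(trained_model, pat)
        assert y.tolist() == [1, 0, 0, 0]

    def test_noiseless_agreement_with_rate_path(self, trained_model,
                                                benchmark):
        _, test = benchmark
        X = test.X[:40]
        rate_pred = trained_model.predict(X)
        agree = 0
        for p, x in enumerate(X):
            pat = dn.encode_single_spike(x)
            o = spike_scores(trained_model, pat)
            agree += int(np.argmax(o) == rate_pred[p])
        assert agree / len(X) >= 0.9

    def test_jitter_degrades_gracefully(self, trained_model, benchmark):
        """Spike-time jitter should cost accuracy smoothly, not break the
        classifier (single small network; no ensemble averaging here)."""
        _, test = benchmark
        rng = np.random.default_rng(5)
        X, labels = test.X[:100], test.labels[:100]
        err0, _ = dn.evaluate_spiking(trained_model, X, labels,
                                      encoder="single", jitter=0.0, rng=rng)
        err10, _ = dn.evaluate_spiking(trained_model, X, labels,
                                       encoder="single", jitter=10.0, rng=rng)
        err20, _ = dn.evaluate_spiking(trained_model, X[:50], labels[:50],
                                       encoder="single", jitter=20.0, rng=rng)
        assert err10 <= err0 + 0.2
        assert err20 < 0.5  # still far better than the 0.75 chance level


def test_afferent_currents_shape_and_superposition(rng):
    pat = dn.SpikePattern([np.array([5.0, 10.0]), np.array([])],
                          duration=30.0)
    t = time_grid(30.0, 0.5)
    S = afferent_currents(pat, t)
    assert S.shape == (2, t.shape[0])
    manual = dn.psc_kernel(t, 5.0) + dn.psc_kernel(t, 10.0)
    assert np.allclose(S[0], manual)
    assert (S[1] == 0).all()
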