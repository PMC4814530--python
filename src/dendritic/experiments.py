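"""Canned studies on the synthetic benchmarks.

These reproduce, at desk scale, the qualitative behaviours of the dendritic
classifier: memorization by structural plasticity, ensemble gain, difficulty-
driven dendrite allocation, rate/spike consistency, and noise sensitivity.
Study sizes are chosen so each runs in seconds to a couple of minutes on one
CPU core; see docs/methods.md for the rationale behind the conditions.
"""

from __future__ import annotations

import numpy as np

from . import data, ensemble, growth, learning, spiking

__all__ = [
    "memorization_study",
    "ensemble_study",
    "growth_study",
    "spike_agreement_study",
    "noise_sweep",
]


def memorization_study(n_seeds: int = 10, m: int = 10, k: int = 5,
                       seed0: int = 0):
    """Hard-threshold structural learning on the default benchmark: does it
    drive the training error to zero within the local-minima budget?

    Returns per-seed training errors and the memorized fraction.
    """
    from .model import init_model

    errors, minima = [], []
    for i in range(n_seeds):
        train, _ = data.make_benchmark(seed=seed0 + i)
        rng = np.random.default_rng(seed0 + i)
        model = init_model(train.n_classes, train.d, m, k, rng, X=train.X)
        best, hist = learning.train(model, train, rng=rng)
        errors.append(learning.hard_error(best, train.X, train.labels))
        minima.append(hist.minima)
    errors = np.array(errors)
    return {
        "train_errors": errors,
        "minima": np.array(minima),
        "memorized_fraction": float(np.mean(errors == 0)),
    }


def ensemble_study(n_members: int = 20, group_size: int = 5, m: int = 5,
                   k: int = 5, seed: int = 0):
    """Train ``n_members`` classifiers from different seeds on one benchmark
    and compare the mean member test error against the mean test error of
    disjoint ``group_size``-member ensembles."""
    train, test = data.make_benchmark(seed=seed)
    members = []
    single_errors = []
    for i in range(n_members):
        mdl, _ = learning.fit(train, m, k, seed=seed * 1000 + i)
        members.append(mdl)
        single_errors.append(learning.hard_error(mdl, test.X, test.labels))
    ensemble_errors = []
    for g in range(n_members // group_size):
        ens = ensemble.EnsembleModel(
            members[g * group_size:(g + 1) * group_size])
        pred = ensemble.ensemble_predict(ens, test.X)
        ensemble_errors.append(float(np.mean(pred != test.labels)))
    return {
        "single_errors": np.array(single_errors),
        "ensemble_errors": np.array(ensemble_errors),
        "mean_single": float(np.mean(single_errors)),
        "mean_ensemble": float(np.mean(ensemble_errors)),
    }


def growth_study(n_seeds: int = 10, seed0: int = 0, init_m: int = 2,
                 k: int = 5, n_ch: int = 25, n_min: int = 150):
    """Adaptive scheme-2 training on the uneven benchmark (one class is a
    union of many prototypes): how often does the hard class end up with
    strictly the largest dendrite count?"""
    m_lists, top = [], []
    params = learning.LearnParams(n_ch=n_ch, n_min=n_min)
    for i in range(n_seeds):
        train, _ = data.make_uneven_benchmark(seed=seed0 + i, hard_class=0)
        _, state = growth.adaptive_train(train, k=k, init_m=init_m, scheme=2,
                                         params=params, seed=seed0 + i)
        m = state.m_per_class
        m_lists.append(m.tolist())
        top.append(bool((m[0] > np.delete(m, 0)).all()))
    return {
        "m_per_class": m_lists,
        "hard_class_largest": np.array(top),
        "hard_class_largest_fraction": float(np.mean(top)),
    }


def spike_agreement_study(seed: int = 1, m: int = 10, k: int = 5,
                          n_patterns: int = 200):
    """Noiseless single-spike evaluation of a rate-trained classifier:
    fraction of test patterns on which the spiking and rate decisions agree."""
    train, test = data.make_benchmark(seed=seed)
    model, _ = learning.fit(train, m, k, seed=seed)
    X = test.X[:n_patterns]
    labels = test.labels[:n_patterns]
    rate_pred = model.predict(X)
    rng = np.random.default_rng(seed)
    spike_err, spike_pred = spiking.evaluate_spiking(
        model, X, labels, encoder="single", jitter=0.0, rng=rng)
    return {
        "agreement": float(np.mean(spike_pred == rate_pred)),
        "rate_error": float(np.mean(rate_pred != labels)),
        "spike_error": spike_err,
    }


def noise_sweep(seed: int = 1, m: int = 10, k: int = 5,
                jitters=(0.0, 5.0, 10.0, 20.0),
                poisson: bool = True, n_patterns: int = 100):
    """Noise-sensitivity harness: test error of one rate-trained classifier
    under jittered single-spike inputs (several window widths) and under
    Poisson rate coding (f_high = 250 Hz, f_low = 1 Hz)."""
    train, test = data.make_benchmark(seed=seed)
    model, _ = learning.fit(train, m, k, seed=seed)
    X, labels = test.X[:n_patterns], test.labels[:n_patterns]
    rng = np.random.default_rng(seed)
    out = {"binary_error": learning.hard_error(model, X, labels)}
    out["jitter_errors"] = {
        float(j): spiking.evaluate_spiking(model, X, labels,
                                           encoder="single", jitter=j,
                                           rng=rng)[0]
        for j in jitters
    }
    if poisson:
        out["poisson_error"] = spiking.evaluate_spiking(
            model, X, labels, encoder="poisson", rng=rng)[0]
    return out
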