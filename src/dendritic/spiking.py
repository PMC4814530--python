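"""Spike-domain evaluation of a trained dendritic classifier.

A rate-trained model is mapped onto an equivalent spiking network for
testing: input spikes evoke double-exponential postsynaptic currents (PSC),
each dendrite applies the quadratic nonlinearity to its time-resolved
synaptic activation, and the tree currents drive a pair of leaky
integrate-and-fire (LIF) neurons per class — a (+) neuron on
I_PDT - I_NDT and a (-) neuron on its negation.  The decision is a
winner-take-all over the per-class spike-count differences
o_spk^mu = n_spk^mu+ - n_spk^mu-.

Encoders: binary patterns map either to single (optionally jittered) spikes
at T_syn for active afferents, or to homogeneous Poisson trains at a high
rate for 1s and a low rate for 0s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ClassifierModel, TreePair, branch_nonlinearity

__all__ = [
    "SpikePattern",
    "PSCParams",
    "LIFParams",
    "psc_kernel",
    "psc_peak_time",
    "encode_single_spike",
    "encode_poisson",
    "afferent_currents",
    "input_current",
    "lif_simulate",
    "classify_spikes",
    "spike_scores",
    "evaluate_spiking",
]


@dataclass
class SpikePattern:
    """Per-afferent spike-time lists (ms) over a window [0, duration]."""

    trains: list  # list of 1-D arrays, one per afferent
    duration: float = 200.0

    def __post_init__(self) -> None:
        self.trains = [np.sort(np.asarray(t, dtype=float)) for t in self.trains]
        for t in self.trains:
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError("spike time outside [0, duration]")

    @property
    def d(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))


@dataclass
class PSCParams:
    """Double-exponential PSC: I0 (exp(-t/tau_f) - exp(-t/tau_r))."""

    i0: float = 1.0
    tau_f: float = 10.0  # fall time constant, ms
    tau_r: float = 2.0   # rise time constant, ms

    def __post_init__(self) -> None:
        if not (self.tau_f > self.tau_r > 0):
            raise ValueError("need tau_f > tau_r > 0")


@dataclass
class LIFParams:
    """Leaky integrate-and-fire with a slow hyperpolarization variable u.

    tau_v d(V)/dt = (u - V) + I_in;  tau_u du/dt = -u;
    on V >= v_thr: V -> v_reset, u -> v_reset (< 0), count a spike.
    Units: ms and mV; defaults follow the spike-model parameter table
    (tau_v = 5 ms, tau_u = 200 ms, v_thr = 0.1 mV).
    """

    tau_v: float = 5.0
    tau_u: float = 200.0
    v_thr: float = 0.1
    v_reset: float = -0.1
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.tau_v <= 0 or self.tau_u <= 0 or self.dt <= 0:
            raise ValueError("time constants and dt must be positive")
        if self.v_reset >= 0:
            raise ValueError("v_reset must be negative")


def psc_kernel(t, t_spike: float, params: PSCParams | None = None):
    """PSC waveform at times ``t`` for a spike at ``t_spike``; causal
    (identically zero for t <= t_spike)."""
    params = params or PSCParams()
    t = np.asarray(t, dtype=float)
    dt = t - t_spike
    out = np.where(
        dt > 0,
        params.i0 * (np.exp(-np.clip(dt, 0, None) / params.tau_f)
                     - np.exp(-np.clip(dt, 0, None) / params.tau_r)),
        0.0,
    )
    return out if out.ndim else float(out)


def psc_peak_time(params: PSCParams | None = None) -> float:
    """Delay from spike to PSC peak: tau_f tau_r / (tau_f - tau_r) * ln(tau_f/tau_r)."""
    p = params or PSCParams()
    return p.tau_f * p.tau_r / (p.tau_f - p.tau_r) * np.log(p.tau_f / p.tau_r)


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------


def encode_single_spike(
    x: np.ndarray,
    t_syn: float = 100.0,
    jitter: float = 0.0,
    duration: float = 200.0,
    rng: np.random.Generator | None = None,
) -> SpikePattern:
    """Place/synchrony code: active afferents fire one spike uniformly in
    [t_syn - jitter/2, t_syn + jitter/2]; silent afferents stay silent."""
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    if t_syn - jitter / 2 < 0 or t_syn + jitter / 2 > duration:
        raise ValueError("jitter window falls outside [0, duration]")
    x = np.asarray(x)
    rng = rng or np.random.default_rng()
    trains = []
    for xi in x:
        if xi:
            t = t_syn if jitter == 0 else rng.uniform(t_syn - jitter / 2,
                                                      t_syn + jitter / 2)
            trains.append(np.array([t]))
        else:
            trains.append(np.array([]))
    return SpikePattern(trains, duration=duration)


def encode_poisson(
    x: np.ndarray,
    f_high: float = 250.0,
    f_low: float = 1.0,
    duration: float = 200.0,
    rng: np.random.Generator | None = None,
) -> SpikePattern:
    """Rate code: homogeneous Poisson trains at f_high Hz for 1s, f_low Hz
    for 0s, over [0, duration] ms."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if f_low < 0 or f_high < f_low:
        raise ValueError("need f_high >= f_low >= 0")
    x = np.asarray(x)
    rng = rng or np.random.default_rng()
    trains = []
    for xi in x:
        rate = f_high if xi else f_low
        n = rng.poisson(rate * duration / 1000.0)
        trains.append(np.sort(rng.uniform(0, duration, size=n)))
    return SpikePattern(trains, duration=duration)


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------


def time_grid(duration: float, dt: float) -> np.ndarray:
    return np.arange(0.0, duration + dt / 2, dt)


def afferent_currents(
    pattern: SpikePattern, t: np.ndarray, psc: PSCParams | None = None
) -> np.ndarray:
    """Per-afferent summed PSC traces: (d, len(t))."""
    psc = psc or PSCParams()
    S = np.zeros((pattern.d, t.shape[0]))
    for i, train in enumerate(pattern.trains):
        for ts in train:
            S[i] += psc_kernel(t, ts, psc)
    return S


def _zleak_traces(zleak: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Time-resolved leak: the stored per-branch mean activation scaled by the
    reference single-spike PSC course (exact for the noiseless single-spike
    encoding used to calibrate the rate model)."""
    return zleak[:, None] * ref[None, :]


def input_current(
    tree: TreePair,
    pattern: SpikePattern,
    t: np.ndarray,
    psc: PSCParams | None = None,
    t_syn: float = 100.0,
    S: np.ndarray | None = None,
    ref: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-resolved input currents (I_in+, I_in-) of one class's neuron pair.

    I_in+ = I_PDT - I_NDT and I_in- is its negation, where each tree current
    sums the branch nonlinearity applied to the branch activations
    z_j(t) = sum_i w_ij * sum_spikes K(t - t_ij).
    """
    psc = psc or PSCParams()
    if pattern.d != tree.pdt.d:
        raise ValueError("pattern dimension does not match the tree")
    if S is None:
        S = afferent_currents(pattern, t, psc)
    if ref is None:
        ref = psc_kernel(t, t_syn, psc)
    i_dt = {}
    for side, cm, zl in (("pdt", tree.pdt, tree.zleak_pdt),
                         ("ndt", tree.ndt, tree.zleak_ndt)):
        Z = cm.W @ S                      # (m, n_t)
        L = _zleak_traces(zl, ref)
        i_dt[side] = branch_nonlinearity(Z, L).sum(axis=0)
    i_plus = i_dt["pdt"] - i_dt["ndt"]
    return i_plus, -i_plus


# ---------------------------------------------------------------------------
# LIF dynamics
# ---------------------------------------------------------------------------


def lif_simulate(
    i_in: np.ndarray, params: LIFParams | None = None, record: bool = False
):
    """Forward-Euler integration of the LIF pair dynamics for one neuron.

    ``i_in`` is the current sampled on the dt grid.  Returns the spike count,
    or ``(n_spk, V_trace)`` with ``record=True``.  Threshold crossings are
    handled at step boundaries.
    """
    p = params or LIFParams()
    i_in = np.asarray(i_in, dtype=float)
    v = 0.0
    u = 0.0
    n_spk = 0
    trace = np.empty(i_in.shape[0]) if record else None
    for n, i_t in enumerate(i_in):
        v += p.dt / p.tau_v * ((u - v) + i_t)
        u += p.dt / p.tau_u * (-u)
        if v >= p.v_thr:
            v = p.v_reset
            u = p.v_reset
            n_spk += 1
        if record:
            trace[n] = v
    return (n_spk, trace) if record else n_spk


def spike_scores(
    model: ClassifierModel,
    pattern: SpikePattern,
    lif: LIFParams | None = None,
    psc: PSCParams | None = None,
    t_syn: float = 100.0,
) -> np.ndarray:
    """Per-class spike-count differences o_spk^mu = n_spk^mu+ - n_spk^mu-."""
    lif = lif or LIFParams()
    psc = psc or PSCParams()
    t = time_grid(pattern.duration, lif.dt)
    S = afferent_currents(pattern, t, psc)
    ref = psc_kernel(t, t_syn, psc)
    o = np.zeros(model.n_classes)
    for mu, tree in enumerate(model.trees):
        i_plus, i_minus = input_current(tree, pattern, t, psc, t_syn,
                                        S=S, ref=ref)
        o[mu] = lif_simulate(i_plus, lif) - lif_simulate(i_minus, lif)
    return o


def classify_spikes(
    model: ClassifierModel,
    pattern: SpikePattern,
    lif: LIFParams | None = None,
    psc: PSCParams | None = None,
    t_syn: float = 100.0,
) -> np.ndarray:
    """One-hot WTA decision over the spike-count differences (lowest-index
    tie rule, as in the rate path)."""
    o = spike_scores(model, pattern, lif, psc, t_syn)
    y = np.zeros(model.n_classes)
    y[int(np.argmax(o))] = 1.0
    return y


def evaluate_spiking(
    model: ClassifierModel,
    X: np.ndarray,
    labels: np.ndarray,
    encoder: str = "single",
    jitter: float = 0.0,
    f_high: float = 250.0,
    f_low: float = 1.0,
    t_syn: float = 100.0,
    duration: float = 200.0,
    lif: LIFParams | None = None,
    psc: PSCParams | None = None,
    rng: np.random.Generator | None = None,
):
    """Spike-domain test pass over a batch of binary patterns.

    Returns ``(error_rate, predictions)``; ``encoder`` is 'single' (jittered
    single spikes) or 'poisson'.
    """
    rng = rng or np.random.default_rng()
    preds = np.empty(len(labels), dtype=np.int64)
    for p, x in enumerate(np.asarray(X)):
        if encoder == "single":
            pat = encode_single_spike(x, t_syn=t_syn, jitter=jitter,
                                      duration=duration, rng=rng)
        elif encoder == "poisson":
            pat = encode_poisson(x, f_high=f_high, f_low=f_low,
                                 duration=duration, rng=rng)
        else:
            raise ValueError("encoder must be 'single' or 'poisson'")
        o = spike_scores(model, pat, lif, psc, t_syn)
        preds[p] = int(np.argmax(o))
    return float(np.mean(preds != np.asarray(labels))), preds
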