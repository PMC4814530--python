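"""Theoretical storage capacity of neurons with nonlinear dendrites, and the
optimal tree topology at a fixed synapse budget.

Function counting over sparse connectivity configurations gives the capacity
of a neuron with m dendrites of k synapses drawn from d afferents as

    C_NL = 2 * log2( C(f + m - 1, m) )   bits,   f = C(k + d - 1, k),

where f counts the distinct branch functions (multisets of k afferents) and
the outer binomial counts multisets of m branches.  For a fixed total synapse
count s = m * k the capacity as a function of the factorization (m, k) has an
interior maximum: many short branches beat both the perceptron (m = 1) and
overly fine trees.  ``optimal_topology`` scans the integer divisor pairs of s
and is used to convert an adaptively grown tree (s fixed per class) to its
capacity-maximizing shape for retraining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .model import ClassifierModel

__all__ = [
    "CapacityResult",
    "capacity_bits",
    "capacity_bits_exact",
    "log2_branch_functions",
    "optimal_topology",
    "capacity_curve",
    "convert_model_topology",
]

_LN2 = math.log(2.0)


@dataclass
class CapacityResult:
    s: int
    m_opt: int
    k_opt: int
    bits: float
    log2_f: float  # distinct branch functions of the optimal (k_opt, d), log2


def _check_positive(**kwargs) -> None:
    for name, v in kwargs.items():
        if int(v) != v or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v}")


def log2_branch_functions(k: int, d: int) -> float:
    """log2 f with f = C(k + d - 1, k), the number of distinct branch
    functions (multisets of k afferents out of d)."""
    _check_positive(k=k, d=d)
    return (gammaln(k + d) - gammaln(k + 1) - gammaln(d)) / _LN2


def _ln_binom_shifted(ln_f: float, m: int) -> float:
    """ln C(f + m - 1, m) given ln f, stable for astronomically large f."""
    # ln prod_{t=0}^{m-1} (f + t) = sum logaddexp(ln f, ln t)
    terms = np.logaddexp(ln_f, np.log(np.arange(1, m, dtype=float))) if m > 1 \
        else np.array([])
    return float(ln_f + terms.sum() - gammaln(m + 1))


def capacity_bits(m: int, k: int, d: int) -> float:
    """Capacity C_NL in bits of an m-dendrite, k-synapse-per-branch neuron on
    d afferents; evaluated in the log domain (log-gamma), overflow-free."""
    _check_positive(m=m, k=k, d=d)
    ln_f = log2_branch_functions(k, d) * _LN2
    return 2.0 * _ln_binom_shifted(ln_f, m) / _LN2

def capacity_bits_exact(m: int, k: int, d: int) -> float:
    """Exact big-integer evaluation (small-case oracle for capacity_bits)."""
    _check_positive(m=m, k=k, d=d)
    f = math.comb(k + d - 1, k)
    n = math.comb(f + m - 1, m)
    # exact log2 of an arbitrarily large integer
    bl = n.bit_length()
    shift = max(0, bl - 64)
    return 2.0 * (math.log2(n >> shift) + shift)


def optimal_topology(s: int, d: int) -> tuple[int, int]:
    """Capacity-maximizing divisor pair (m, k) with m * k = s.

    Ties resolve toward the larger m (flatter, more branched tree).
    """
    _check_positive(s=s, d=d)
    best = None
    for m in sorted(_divisors(s)):
        bits = capacity_bits(m, s // m, d)
        if best is None or bits > best[2] or (bits == best[2] and m > best[0]):
            best = (m, s // m, bits)
    return best[0], best[1]


def capacity_curve(s: int, d: int) -> list[tuple[int, int, float]]:
    """(m, k, C_NL bits) for every factorization m * k = s, m ascending."""
    _check_positive(s=s, d=d)
    return [(m, s // m, capacity_bits(m, s // m, d))
            for m in sorted(_divisors(s))]


def _divisors(s: int) -> list[int]:
    out = set()
    for i in range(1, int(math.isqrt(s)) + 1):
        if s % i == 0:
            out.update((i, s // i))
    return sorted(out)


def convert_model_topology(
    model: ClassifierModel | None = None,
    m_per_class=None,
    k: int | None = None,
    d: int | None = None,
) -> list[CapacityResult]:
    """Per-class optimal topologies at the synapse counts an adaptive run
    allocated: s^mu = m^mu * k is preserved, and each class is assigned its
    capacity-maximizing (m_opt, k_opt) for retraining from scratch."""
    if model is not None:
        m_per_class = model.dendrite_counts
        k = model.k
        d = model.d
    if m_per_class is None or k is None or d is None:
        raise ValueError("pass a model, or m_per_class with k and d")
    results = []
    for m_mu in np.asarray(m_per_class, dtype=int):
        s = int(m_mu) * int(k)
        m_opt, k_opt = optimal_topology(s, d)
        results.append(CapacityResult(
            s=s, m_opt=m_opt, k_opt=k_opt,
            bits=capacity_bits(m_opt, k_opt, d),
            log2_f=log2_branch_functions(k_opt, d),
        ))
    return results
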