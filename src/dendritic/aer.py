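"""Two-tier address-event connectivity memory and its size accounting.

In an address-event representation (AER) system the sparse connection matrix
lives in digital memory.  The two-tier layout stores, per input afferent, a
pointer into a flat dendrite-address array (CSR-style, with the leading 0
implicit so exactly d pointer entries are kept): an incoming event with
address i reads pointers a_i, a_{i+1}; their difference n_i is the number of
synapses on that input, and the n_i consecutive dendrite addresses d_p ...
d_{q-1} are the routing destinations.

Size accounting compares a conventional dense crossbar of b-bit weights,

    NOB_conv = b*H*d + b*H*C          (~ b*H*d for C << d),

with the two-tier scheme,

    NOB_prop = d*ceil(log2(H*k)) + H*k*ceil(log2(H)),

for H total dendrites, d inputs, C classes, k synapses per dendrite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ClassifierModel

__all__ = [
    "LayoutAER",
    "MemoryReport",
    "encode_two_tier",
    "decode_two_tier",
    "route_event",
    "stack_model_connectivity",
    "nob_conventional",
    "nob_proposed",
    "stored_bits",
    "area_report",
    "crossover_d",
]


def _ceil_log2(n: int) -> int:
    if n < 1:
        raise ValueError("argument must be >= 1")
    return int(math.ceil(math.log2(n))) if n > 1 else 0


@dataclass
class LayoutAER:
    """Pointer array + dendrite-address array for H dendrites of k synapses.

    ``pointers`` holds the d stored cumulative counts a_1..a_d (a_0 = 0 is
    implicit); ``destinations`` lists dendrite indices grouped by afferent.
    """

    pointers: np.ndarray       # (d,) cumulative synapse counts
    destinations: np.ndarray   # (n_connections,) dendrite indices
    H: int
    k: int
    d: int

    def __post_init__(self) -> None:
        self.pointers = np.asarray(self.pointers, dtype=np.int64)
        self.destinations = np.asarray(self.destinations, dtype=np.int64)
        if self.pointers.shape != (self.d,):
            raise ValueError("pointer array must have exactly d entries")
        if (np.diff(self.pointers) < 0).any() or (
            self.d > 0 and self.pointers[0] < 0
        ):
            raise ValueError("pointer entries must be non-decreasing")
        total = int(self.pointers[-1]) if self.d else 0
        if total != self.destinations.shape[0]:
            raise ValueError("final pointer must equal the connection count")
        if total > self.H * self.k:
            raise ValueError("more connections than H*k slots")
        if self.destinations.size and (
            self.destinations.min() < 0 or self.destinations.max() >= self.H
        ):
            raise ValueError("destination dendrite index out of range")

    @property
    def pointer_bits(self) -> int:
        return _ceil_log2(self.H * self.k)

    @property
    def destination_bits(self) -> int:
        return _ceil_log2(self.H)


def encode_two_tier(W: np.ndarray, k: int) -> LayoutAER:
    """Build the two-tier layout from a stacked (H, d) connection matrix.

    Connection multiplicities expand to repeated destination entries; within
    one afferent, destinations are stored in increasing dendrite order.
    """
    W = np.asarray(W, dtype=np.int64)
    if W.ndim != 2:
        raise ValueError("W must be (H, d)")
    if (W < 0).any():
        raise ValueError("multiplicities must be non-negative")
    H, d = W.shape
    counts = W.sum(axis=0)                     # synapses per afferent
    if counts.sum() > H * k:
        raise ValueError("more connections than H*k slots")
    dest_chunks = []
    for i in range(d):
        col = W[:, i]
        js = np.nonzero(col)[0]
        dest_chunks.append(np.repeat(js, col[js]))
    destinations = (np.concatenate(dest_chunks)
                    if dest_chunks else np.array([], dtype=np.int64))
    pointers = np.cumsum(counts)
    return LayoutAER(pointers, destinations, H=H, k=k, d=d)


def decode_two_tier(layout: LayoutAER) -> np.ndarray:
    """Dense (H, d) connection matrix reconstructed from the layout."""
    W = np.zeros((layout.H, layout.d), dtype=np.int64)
    start = 0
    for i in range(layout.d):
        stop = int(layout.pointers[i])
        for j in layout.destinations[start:stop]:
            W[j, i] += 1
        start = stop
    return W


def route_event(layout: LayoutAER, afferent: int) -> np.ndarray:
    """Destination dendrites of one input event: the n_i = a_{i+1} - a_i
    consecutive entries d_p .. d_{q-1}; empty when the input has no synapses."""
    if not (0 <= afferent < layout.d):
        raise ValueError("afferent address out of range")
    p = int(layout.pointers[afferent - 1]) if afferent > 0 else 0
    q = int(layout.pointers[afferent])
    return layout.destinations[p:q].copy()


def stack_model_connectivity(model: ClassifierModel) -> tuple[np.ndarray, int]:
    """All PDT and NDT rows of a classifier stacked to one (H, d) matrix."""
    rows = []
    for tp in model.trees:
        rows.append(tp.pdt.W)
        rows.append(tp.ndt.W)
    return np.vstack(rows), model.k


# ---------------------------------------------------------------------------
# memory accounting
# ---------------------------------------------------------------------------


@dataclass
class MemoryReport:
    nob_conv: int
    nob_prop: int
    weight_count_conv: int
    area_conv: float     # um^2, crossbar approximation b*H*d
    area_prop: float     # um^2
    ratio: float         # area_conv / area_prop


def nob_conventional(b: int, H: int, d: int, C: int) -> tuple[int, int]:
    """Bits of a dense b-bit weight memory for a d->H->C two-layer network.

    Returns ``(bits, weight_count)`` with bits = b*H*d + b*H*C.
    """
    for name, v in dict(b=b, H=H, d=d, C=C).items():
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    weights = H * d + H * C
    return b * weights, weights


def nob_proposed(d: int, H: int, k: int) -> int:
    """Bits of the two-tier layout: d pointer entries of ceil(log2(H*k)) bits
    plus H*k destination entries of ceil(log2(H)) bits."""
    for name, v in dict(d=d, H=H, k=k).items():
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    return d * _ceil_log2(H * k) + H * k * _ceil_log2(H)


def stored_bits(layout: LayoutAER) -> int:
    """Physical bits a layout occupies; the second memory is sized at H*k
    entries regardless of fill, so this equals nob_proposed(d, H, k)."""
    return layout.d * layout.pointer_bits \
        + layout.H * layout.k * layout.destination_bits


def area_report(
    d: int, H: int, k: int, b: int = 4, C: int = 10,
    area_per_bit: float = 0.15,
) -> MemoryReport:
    """Silicon-area comparison at a given SRAM density (um^2 per bit).

    The conventional area uses the crossbar approximation b*H*d (valid for
    C << d); the proposed area prices the full two-tier layout.
    """
    if area_per_bit <= 0:
        raise ValueError("area_per_bit must be positive")
    nob_c, weights = nob_conventional(b, H, d, C)
    nob_p = nob_proposed(d, H, k)
    area_c = b * H * d * area_per_bit
    area_p = nob_p * area_per_bit
    return MemoryReport(
        nob_conv=nob_c, nob_prop=nob_p, weight_count_conv=weights,
        area_conv=area_c, area_prop=area_p, ratio=area_c / area_p,
    )


def crossover_d(b: int, H: int, k: int, C: int = 10, d_max: int = 4096) -> int:
    """Smallest d at which the two-tier layout beats the dense crossbar
    (NOB_prop <= NOB_conv), found by bisection over d in [1, d_max]."""
    def gain(d):
        return nob_conventional(b, H, d, C)[0] - nob_proposed(d, H, k)
    if gain(d_max) < 0:
        raise ValueError("no crossover below d_max")
    lo, hi = 1, d_max
    if gain(lo) >= 0:
        return lo
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if gain(mid) >= 0:
            hi = mid
        else:
            lo = mid
    return hi
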