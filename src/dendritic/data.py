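"""Synthetic pattern generation, image thresholding, IDX reading, and
DVS-style event handling.

The synthetic generator draws random binary prototypes per class and emits
noisy copies by independent bit flips — a stand-in for thresholded digit
images with controllable class structure and noise.  The event utilities
convert an event stream from a dynamic vision sensor (lists of (x, y, t)
events) into per-pixel count frames and crop the most active patch, the
standard preprocessing for frame-based training on DVS recordings.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BinaryPatternSet",
    "SynthSpec",
    "EventStream",
    "generate_patterns",
    "make_benchmark",
    "make_uneven_benchmark",
    "threshold_image",
    "read_idx",
    "write_idx",
    "synthesize_events",
    "events_to_frame",
    "crop_max_activity",
    "render_weight_map",
]


@dataclass
class BinaryPatternSet:
    """Binary patterns with integer class labels in {0..n_classes-1}."""

    X: np.ndarray          # (P, d) entries in {0, 1}
    labels: np.ndarray     # (P,)
    n_classes: int
    # provenance of generated sets (None for data read from files)
    prototypes: list | None = None
    proto_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.X.ndim != 2 or self.X.shape[0] < 1 or self.X.shape[1] < 1:
            raise ValueError("X must be a non-empty (P, d) matrix")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("patterns must be binary")
        if self.labels.shape != (self.X.shape[0],):
            raise ValueError("one label per pattern required")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.labels.min() < 0 or self.labels.max() >= self.n_classes:
            raise ValueError("labels out of range")

    @property
    def P(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def onehot(self) -> np.ndarray:
        """Desired-output matrix: one 1 per row at the pattern's class."""
        Y = np.zeros((self.P, self.n_classes))
        Y[np.arange(self.P), self.labels] = 1.0
        return Y


@dataclass
class SynthSpec:
    """Specification of the prototype-plus-bit-flip synthetic task.

    Defaults give the benchmark used throughout the test-suite: 4 classes of
    64-dimensional patterns, 2 prototypes per class, 5% independent flip
    noise, 50 patterns per class (200 total) — sized so that full train/test
    cycles run in seconds.
    """

    n_classes: int = 4
    d: int = 64
    prototypes_per_class: int = 2
    noise: float = 0.05
    patterns_per_class: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.noise < 0.5):
            raise ValueError("noise rate must lie in [0, 0.5)")
        if self.d < 1 or self.n_classes < 2:
            raise ValueError("degenerate spec")
        if self.prototypes_per_class < 1 or self.patterns_per_class < 1:
            raise ValueError("degenerate spec")


def _emit(prototypes_by_class, per_class, noise, rng, n_classes, d):
    X, labels, pids = [], [], []
    for c, protos in enumerate(prototypes_by_class):
        for i in range(per_class):
            proto = protos[i % len(protos)]
            flips = rng.random(d) < noise
            X.append(np.where(flips, 1 - proto, proto))
            labels.append(c)
            pids.append(i % len(protos))
    order = rng.permutation(len(X))
    return BinaryPatternSet(
        np.array(X)[order], np.array(labels)[order], n_classes,
        prototypes=prototypes_by_class, proto_ids=np.array(pids)[order],
    )


def generate_patterns(
    spec: SynthSpec, rng: np.random.Generator | None = None
) -> BinaryPatternSet:
    """Draw class prototypes and emit noisy copies; deterministic under seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    protos = [
        [rng.integers(0, 2, size=spec.d) for _ in range(spec.prototypes_per_class)]
        for _ in range(spec.n_classes)
    ]
    return _emit(protos, spec.patterns_per_class, spec.noise, rng,
                 spec.n_classes, spec.d)


def make_benchmark(seed: int = 0, spec: SynthSpec | None = None):
    """Train/test pair drawn from the same prototypes (default SynthSpec)."""
    spec = spec or SynthSpec()
    rng = np.random.default_rng(seed)
    protos = [
        [rng.integers(0, 2, size=spec.d) for _ in range(spec.prototypes_per_class)]
        for _ in range(spec.n_classes)
    ]
    train = _emit(protos, spec.patterns_per_class, spec.noise, rng,
                  spec.n_classes, spec.d)
    test = _emit(protos, spec.patterns_per_class, spec.noise, rng,
                 spec.n_classes, spec.d)
    return train, test


def make_uneven_benchmark(
    seed: int = 0,
    hard_class: int = 0,
    hard_prototypes: int = 24,
    n_classes: int = 4,
    d: int = 64,
    noise: float = 0.15,
    patterns_per_class: int = 100,
):
    """Benchmark where one class is a union of several prototypes while the
    others are single prototypes, making it deliberately harder to learn.

    The defaults are sized for growth studies: the hard class's 24-prototype
    structure exceeds the capacity of a small initial dendritic tree, so the
    adaptive learner must add dendrites to it.
    """
    rng = np.random.default_rng(seed)
    protos = [
        [rng.integers(0, 2, size=d)
         for _ in range(hard_prototypes if c == hard_class else 1)]
        for c in range(n_classes)
    ]
    train = _emit(protos, patterns_per_class, noise, rng, n_classes, d)
    test = _emit(protos, patterns_per_class, noise, rng, n_classes, d)
    return train, test


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def threshold_image(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Flatten a grayscale image to a binary vector: pixel > threshold -> 1.

    Row-major flattening; the default threshold is the midpoint of the image
    dtype's value range (or of [min, max] for floats).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if threshold is None:
        if np.issubdtype(image.dtype, np.integer):
            info = np.iinfo(image.dtype)
            threshold = (int(info.min) + int(info.max)) / 2
        else:
            threshold = (float(image.min()) + float(image.max())) / 2
    return (image > threshold).astype(np.uint8).ravel(order="C")


_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2",
               0x0C: ">i4", 0x0D: ">f4", 0x0E: ">f8"}


def read_idx(path: str | Path) -> np.ndarray:
    """Read an array in IDX format (the de facto digit-dataset layout)."""
    raw = Path(path).read_bytes()
    if len(raw) < 4 or raw[0] != 0 or raw[1] != 0:
        raise ValueError("not an IDX file")
    dtype, ndim = raw[2], raw[3]
    if dtype not in _IDX_DTYPES:
        raise ValueError(f"unknown IDX type code 0x{dtype:02x}")
    shape = struct.unpack(f">{ndim}i", raw[4:4 + 4 * ndim])
    data = np.frombuffer(raw, dtype=_IDX_DTYPES[dtype], offset=4 + 4 * ndim,
                         count=int(np.prod(shape)))
    return data.reshape(shape).astype(data.dtype.newbyteorder("="))


def write_idx(path: str | Path, array: np.ndarray) -> None:
    """Write a uint8 array in IDX format (testing/interchange helper)."""
    array = np.ascontiguousarray(array, dtype=np.uint8)
    header = bytes([0, 0, 0x08, array.ndim])
    header += struct.pack(f">{array.ndim}i", *array.shape)
    Path(path).write_bytes(header + array.tobytes())


# ---------------------------------------------------------------------------
# DVS-style event streams
# ---------------------------------------------------------------------------


@dataclass
class EventStream:
    """Events from a (height x width) sensor: columns x, rows y, times t [ms]."""

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    width: int = 128
    height: int = 128
    duration: float = 2000.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        if not (self.x.shape == self.y.shape == self.t.shape):
            raise ValueError("x, y, t must have equal length")
        if self.x.size:
            if self.x.min() < 0 or self.x.max() >= self.width:
                raise ValueError("x outside sensor")
            if self.y.min() < 0 or self.y.max() >= self.height:
                raise ValueError("y outside sensor")
            if self.t.min() < 0 or self.t.max() > self.duration:
                raise ValueError("event time outside stream duration")


def synthesize_events(
    image: np.ndarray,
    rng: np.random.Generator,
    rate_on: float = 50.0,
    rate_off: float = 0.5,
    duration: float = 2000.0,
    width: int | None = None,
    height: int | None = None,
    offset: tuple[int, int] = (0, 0),
) -> EventStream:
    """Synthetic DVS-style stream: each bright pixel of a binary image emits a
    Poisson event train at ``rate_on`` (Hz), dark pixels at ``rate_off``,
    optionally embedded at ``offset`` (row, col) inside a larger sensor."""
    image = np.asarray(image)
    h, w = image.shape
    height = height or h
    width = width or w
    xs, ys, ts = [], [], []
    for r in range(h):
        for c in range(w):
            rate = rate_on if image[r, c] else rate_off
            n = rng.poisson(rate * duration / 1000.0)
            if n:
                xs.append(np.full(n, c + offset[1]))
                ys.append(np.full(n, r + offset[0]))
                ts.append(rng.uniform(0, duration, size=n))
    if xs:
        x = np.concatenate(xs); y = np.concatenate(ys); t = np.concatenate(ts)
        order = np.argsort(t)
        x, y, t = x[order], y[order], t[order]
    else:
        x = y = np.array([], dtype=np.int64); t = np.array([])
    return EventStream(x, y, t, width=width, height=height, duration=duration)


def events_to_frame(stream: EventStream, window: tuple[float, float]) -> np.ndarray:
    """Per-pixel event counts restricted to a time window [t0, t1]."""
    t0, t1 = window
    if not (0 <= t0 < t1 <= stream.duration):
        raise ValueError("window must be a non-empty interval within the stream")
    mask = (stream.t >= t0) & (stream.t <= t1)
    frame = np.zeros((stream.height, stream.width), dtype=np.int64)
    np.add.at(frame, (stream.y[mask], stream.x[mask]), 1)
    return frame


def crop_max_activity(frame: np.ndarray, patch: int | tuple[int, int]):
    """Exhaustive stride-1 scan for the patch with maximal total event count.

    Returns ``(patch_array, (row, col))``; ties resolve to the top-left-most
    placement (row-major scan order).
    """
    frame = np.asarray(frame)
    ph, pw = (patch, patch) if np.isscalar(patch) else patch
    H, W = frame.shape
    if ph > H or pw > W:
        raise ValueError("patch larger than image")
    # integral image -> O(1) window sums
    S = np.zeros((H + 1, W + 1), dtype=np.int64)
    S[1:, 1:] = frame.cumsum(0).cumsum(1)
    sums = S[ph:, pw:] - S[:-ph or None, pw:] - S[ph:, :-pw or None] \
        + S[:H - ph + 1, :W - pw + 1]
    idx = int(np.argmax(sums))  # first max in row-major order = top-left-most
    r, c = divmod(idx, sums.shape[1])
    return frame[r:r + ph, c:c + pw].copy(), (r, c)


def render_weight_map(weights: np.ndarray, side: int | None = None) -> np.ndarray:
    """Reshape a length-d dendrite weight row (or a mean over rows) into a
    square map for visual inspection of the learned input features."""
    weights = np.asarray(weights)
    if weights.ndim != 1:
        raise ValueError("pass a single weight vector (row or mean of rows)")
    d = weights.shape[0]
    if side is None:
        side = int(round(d ** 0.5))
        if side * side != d:
            raise ValueError("d is not a perfect square; pass side explicitly")
    if side * side != d:
        raise ValueError("side^2 must equal d")
    return weights.reshape(side, side)
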