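"""Rate-based neuron model with nonlinear dendrites and binary synapses.

A nonlinear-dendrite (NLD) neuron has ``m`` dendritic branches carrying ``k``
synaptic contacts each, drawn from ``d`` input afferents.  Synapses are binary:
learning selects *which* afferents connect, not analog weights, so a branch is
described by a row of non-negative integer connection multiplicities that sums
to exactly ``k``.  Each branch applies a lumped quadratic nonlinearity

    b(z) = (z - z_leak)^2   if z > z_leak, else 0

to its summed synaptic activation ``z``, where ``z_leak`` is the mean
activation of that branch under its *initial* random connectivity (a balancing
inhibition term, frozen thereafter).  A class is scored by a pair of trees —
an excitatory positive dendritic tree (PDT) and an inhibitory negative
dendritic tree (NDT) — as ``o = a_PDT - a_NDT``, and a winner-take-all (WTA)
over the per-class scores makes the multiclass decision.

During training a soft margin output ``g_margin`` with a per-class half-width
``delta`` replaces the hard WTA threshold; at test time decisions are always
hard argmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ConnectionMatrix",
    "TreePair",
    "ClassifierModel",
    "branch_nonlinearity",
    "tree_output",
    "class_scores",
    "wta_decision",
    "g_margin",
    "margin_outputs",
    "compute_zleak",
    "random_connection_matrix",
    "init_model",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class ConnectionMatrix:
    """Integer connection-multiplicity matrix of one dendritic tree.

    ``W[j, i]`` is the number of contacts afferent ``i`` makes on dendrite
    ``j``.  Every row sums to exactly ``k`` (fixed synapse count per branch);
    multiple contacts from one afferent are allowed.
    """

    W: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.int64)
        if self.W.ndim != 2:
            raise ValueError("W must be a 2-D (m, d) matrix")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        self.validate()

    def validate(self) -> None:
        if (self.W < 0).any():
            raise ValueError("connection multiplicities must be non-negative")
        rowsums = self.W.sum(axis=1)
        if not (rowsums == self.k).all():
            raise ValueError(
                f"every dendrite must carry exactly k={self.k} synapses; "
                f"row sums were {rowsums.tolist()}"
            )

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def d(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "ConnectionMatrix":
        return ConnectionMatrix(self.W.copy(), self.k)


@dataclass
class TreePair:
    """PDT/NDT connection matrices of one class, with per-branch leak levels."""

    pdt: ConnectionMatrix
    ndt: ConnectionMatrix
    zleak_pdt: np.ndarray
    zleak_ndt: np.ndarray

    def __post_init__(self) -> None:
        self.zleak_pdt = np.asarray(self.zleak_pdt, dtype=float)
        self.zleak_ndt = np.asarray(self.zleak_ndt, dtype=float)
        if self.pdt.m != self.ndt.m:
            raise ValueError("PDT and NDT must have equal dendrite counts")
        if self.pdt.d != self.ndt.d:
            raise ValueError("PDT and NDT must share the afferent dimension")
        if len(self.zleak_pdt) != self.pdt.m or len(self.zleak_ndt) != self.ndt.m:
            raise ValueError("zleak length must match dendrite count")
        if (self.zleak_pdt < 0).any() or (self.zleak_ndt < 0).any():
            raise ValueError("zleak levels must be non-negative")

    @property
    def m(self) -> int:
        return self.pdt.m

    def copy(self) -> "TreePair":
        return TreePair(
            self.pdt.copy(), self.ndt.copy(),
            self.zleak_pdt.copy(), self.zleak_ndt.copy(),
        )


@dataclass
class ClassifierModel:
    """A multiclass NLD classifier: one PDT/NDT tree pair per class.

    ``margins[mu]`` is the per-class margin half-width delta used by the
    soft output function during training (0 = hard threshold).
    """

    trees: list[TreePair]
    margins: np.ndarray
    d: int
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.margins = np.asarray(self.margins, dtype=float)
        if len(self.trees) < 1:
            raise ValueError("model needs at least one class")
        if len(self.margins) != len(self.trees):
            raise ValueError("one margin per class required")
        if (self.margins < 0).any():
            raise ValueError("margins must be non-negative")
        for tp in self.trees:
            if tp.pdt.d != self.d or tp.pdt.k != self.k or tp.ndt.k != self.k:
                raise ValueError("all trees must share d and k")

    @property
    def n_classes(self) -> int:
        return len(self.trees)

    @property
    def dendrite_counts(self) -> np.ndarray:
        """Per-class dendrite count m (identical for PDT and NDT)."""
        return np.array([tp.m for tp in self.trees])

    def scores(self, x: np.ndarray) -> np.ndarray:
        return class_scores(self, x)

    def scores_batch(self, X: np.ndarray) -> np.ndarray:
        """Class scores for a batch: returns a (P, n_classes) array."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.d:
            raise ValueError(f"X must be (P, {self.d})")
        out = np.empty((X.shape[0], self.n_classes))
        for mu, tp in enumerate(self.trees):
            a_p = _tree_output_batch(tp.pdt.W, tp.zleak_pdt, X)
            a_n = _tree_output_batch(tp.ndt.W, tp.zleak_ndt, X)
            out[:, mu] = a_p - a_n
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard WTA class labels (0-based) for a batch of binary patterns."""
        return np.argmax(self.scores_batch(X), axis=1)

    def copy(self) -> "ClassifierModel":
        return ClassifierModel(
            [tp.copy() for tp in self.trees],
            self.margins.copy(), self.d, self.k, self.seed,
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def branch_nonlinearity(z, zleak):
    """Quadratic branch nonlinearity b(z) = (z - zleak)^2 for z > zleak else 0.

    The gate is strict: at z == zleak the branch is inactive.
    Accepts scalars or arrays (broadcast).
    """
    diff = np.asarray(z, dtype=float) - np.asarray(zleak, dtype=float)
    out = np.where(diff > 0, diff * diff, 0.0)
    return out if out.ndim else float(out)


def _tree_output_batch(W: np.ndarray, zleak: np.ndarray, X: np.ndarray) -> np.ndarray:
    Z = X @ W.T  # (P, m) synaptic activations
    return branch_nonlinearity(Z, zleak[None, :]).sum(axis=1)


def tree_output(cm: ConnectionMatrix, zleak: Sequence[float], x: np.ndarray) -> float:
    """Summed branch outputs of one dendritic tree for a binary pattern."""
    x = np.asarray(x, dtype=float)
    zleak = np.asarray(zleak, dtype=float)
    if x.shape != (cm.d,):
        raise ValueError(f"pattern length {x.shape} does not match d={cm.d}")
    if zleak.shape != (cm.m,):
        raise ValueError("zleak length must equal the dendrite count")
    z = cm.W @ x
    return float(branch_nonlinearity(z, zleak).sum())


def class_scores(model: ClassifierModel, x: np.ndarray) -> np.ndarray:
    """Per-class scores o^mu = a_PDT(x) - a_NDT(x)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.d,):
        raise ValueError(f"pattern length {x.shape} does not match d={model.d}")
    o = np.empty(model.n_classes)
    for mu, tp in enumerate(model.trees):
        o[mu] = tree_output(tp.pdt, tp.zleak_pdt, x) - tree_output(
            tp.ndt, tp.zleak_ndt, x
        )
    return o


def wta_decision(o: np.ndarray) -> np.ndarray:
    """One-hot winner-take-all over class scores; ties go to the lowest index."""
    o = np.asarray(o, dtype=float)
    if o.size == 0:
        raise ValueError("empty score vector")
    y = np.zeros(o.shape[0])
    y[int(np.argmax(o))] = 1.0
    return y


def g_margin(alpha, delta: float):
    """Piecewise-linear margin output on [-delta, delta].

    1 for alpha >= delta, 0 for alpha <= -delta, linear ramp 0.5*alpha/delta
    + 0.5 in between.  delta == 0 degenerates to the hard threshold with
    g(0) = 0.5.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    alpha = np.asarray(alpha, dtype=float)
    if delta == 0:
        out = np.where(alpha > 0, 1.0, np.where(alpha < 0, 0.0, 0.5))
    else:
        out = np.clip(0.5 * alpha / delta + 0.5, 0.0, 1.0)
    return out if out.ndim else float(out)


def margin_outputs(model: ClassifierModel, x: np.ndarray, true_class: int) -> np.ndarray:
    """Training-time soft outputs.

    The true class mu and its best competitor nu get margin-softened outputs
    g_margin(+/-(o^mu - o^nu), delta^mu); all other components are the hard-WTA
    value (necessarily 0, since the argmax is mu or nu).
    """
    o = class_scores(model, x)
    mu = int(true_class)
    masked = o.copy()
    masked[mu] = -np.inf
    nu = int(np.argmax(masked))
    alpha = o[mu] - o[nu]
    delta = float(model.margins[mu])
    y = np.zeros(model.n_classes)
    y[mu] = g_margin(alpha, delta)
    y[nu] = g_margin(-alpha, delta)
    return y


def compute_zleak(cm: ConnectionMatrix, X: np.ndarray) -> np.ndarray:
    """Per-branch mean synaptic activation over a pattern set.

    Evaluated once on the tree's initial random connections and then frozen:
    it plays the role of a balancing inhibitory signal.
    """
    cm.validate()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("pattern set must be a non-empty (P, d) matrix")
    if X.shape[1] != cm.d:
        raise ValueError("pattern dimension does not match d")
    return (X @ cm.W.T).mean(axis=0)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def random_connection_matrix(
    m: int, d: int, k: int, rng: np.random.Generator
) -> ConnectionMatrix:
    """m dendrites, each with k contacts drawn uniformly (with replacement)
    from the d input lines, so integer multiplicities > 1 can occur."""
    W = np.zeros((m, d), dtype=np.int64)
    for j in range(m):
        W[j] = np.bincount(rng.integers(0, d, size=k), minlength=d)
    return ConnectionMatrix(W, k)


def init_model(
    n_classes: int,
    d: int,
    m: int | Sequence[int],
    k: int,
    rng: np.random.Generator,
    X: np.ndarray | None = None,
    seed: int | None = None,
) -> ClassifierModel:
    """Random initial classifier; if training patterns ``X`` are given the
    per-branch leak levels are calibrated from them (and stay frozen)."""
    if n_classes < 1:
        raise ValueError("need at least one class")
    ms = [int(m)] * n_classes if np.isscalar(m) else [int(v) for v in m]
    if len(ms) != n_classes:
        raise ValueError("per-class m must have n_classes entries")
    trees = []
    for m_mu in ms:
        pdt = random_connection_matrix(m_mu, d, k, rng)
        ndt = random_connection_matrix(m_mu, d, k, rng)
        if X is not None:
            zl_p = compute_zleak(pdt, X)
            zl_n = compute_zleak(ndt, X)
        else:
            zl_p = np.zeros(m_mu)
            zl_n = np.zeros(m_mu)
        trees.append(TreePair(pdt, ndt, zl_p, zl_n))
    return ClassifierModel(trees, np.zeros(n_classes), d, k, seed=seed)


# ---------------------------------------------------------------------------
# serialization (JSON with nested lists; matrices are small integers)
# ---------------------------------------------------------------------------


def model_to_dict(model: ClassifierModel) -> dict:
    return {
        "format": "dendritic-classifier",
        "version": 1,
        "d": model.d,
        "k": model.k,
        "seed": model.seed,
        "margins": model.margins.tolist(),
        "trees": [
            {
                "pdt": tp.pdt.W.tolist(),
                "ndt": tp.ndt.W.tolist(),
                "zleak_pdt": tp.zleak_pdt.tolist(),
                "zleak_ndt": tp.zleak_ndt.tolist(),
            }
            for tp in model.trees
        ],
    }


def model_from_dict(data: dict) -> ClassifierModel:
    k = int(data["k"])
    trees = [
        TreePair(
            ConnectionMatrix(np.array(t["pdt"]), k),
            ConnectionMatrix(np.array(t["ndt"]), k),
            np.array(t["zleak_pdt"], dtype=float),
            np.array(t["zleak_ndt"], dtype=float),
        )
        for t in data["trees"]
    ]
    return ClassifierModel(
        trees, np.array(data["margins"], dtype=float),
        int(data["d"]), k, seed=data.get("seed"),
    )


def save_model(model: ClassifierModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model)))


def load_model(path: str | Path) -> ClassifierModel:
    return model_from_dict(json.loads(Path(path).read_text()))
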