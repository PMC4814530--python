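"""Correlation-based structural-plasticity learning.

Training never changes analog weights: it rewires.  Each attempt targets one
dendritic tree, scores every active synapse by the correlation

    c_ij = < x_i * b_j(x) * sgn(y_d - y) >        (sign flipped for the NDT)

between its input line, its branch output and the classification error of the
tree's class, then swaps the worst synapse of a random candidate set T
(|T| = n_T) for the best of a random set R (|R| = n_R) of *silent* trial
synapses placed on the same branch.  A swap is kept iff the training error
did not increase.  After ``n_ch`` consecutive attempts without a strict error
decrease a local minimum is declared: the stagnated connection matrix is
checkpointed if it is the best so far, and the last rejected replacement is
forced through to escape.  Training stops on memorization (zero training
error) or after ``n_min`` local minima, returning the best checkpoint.

Margins: the model is first trained with the hard threshold, per-class margins
``delta^mu`` are then calibrated on held-out patterns (the largest score
deficit among that class's misclassifications), and training continues with
the soft margin output.  Whenever the learner revisits the same local minimum
(equal error) five times in a row, all margins decay to 80% of their value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import BinaryPatternSet
from .model import (
    ClassifierModel,
    branch_nonlinearity,
    compute_zleak,
    init_model,
)

__all__ = [
    "LearnParams",
    "TrainHistory",
    "margin_stats",
    "margin_error",
    "hard_error",
    "correlation_map",
    "pick_target",
    "propose_replacement",
    "attempt_swap",
    "set_margins",
    "train",
    "fit",
]


@dataclass
class LearnParams:
    """Knobs of the structural learning loop.

    n_T / n_R are the candidate/replacement set sizes (defaults follow the
    rate-model parameter table), n_ch the stagnation span that declares a
    local minimum, n_min the local-minima budget that ends training.
    """

    n_T: int = 25
    n_R: int = 25
    n_ch: int = 50
    n_min: int = 150
    margin_decay: float = 0.8
    decay_trigger: int = 5

    def __post_init__(self) -> None:
        if self.n_T < 1 or self.n_R < 1:
            raise ValueError("n_T and n_R must be positive")
        if self.n_ch < 1 or self.n_min < 0:
            raise ValueError("n_ch must be >= 1 and n_min >= 0")
        if not (0 < self.margin_decay <= 1):
            raise ValueError("margin decay factor must lie in (0, 1]")


@dataclass
class TrainHistory:
    error: list = field(default_factory=list)        # margin error per iteration
    best_error: list = field(default_factory=list)   # running best
    minima: int = 0
    margin_decays: int = 0
    iterations: int = 0
    events: list = field(default_factory=list)       # (kind, iteration, payload)
    stop_reason: str = ""


# ---------------------------------------------------------------------------
# error metrics and the learning signal
# ---------------------------------------------------------------------------


def margin_stats(o: np.ndarray, labels: np.ndarray, margins: np.ndarray):
    """Per-pattern margin statistics from a (P, N_C) score matrix.

    Returns ``(alpha, nu, satisfied)`` where ``nu`` is the best competing
    class, ``alpha = o[label] - o[nu]`` and ``satisfied`` marks patterns whose
    soft output equals the teacher signal exactly (alpha > 0 and
    alpha >= delta of the pattern's class).
    """
    P = o.shape[0]
    rows = np.arange(P)
    o_lab = o[rows, labels]
    masked = o.copy()
    masked[rows, labels] = -np.inf
    nu = np.argmax(masked, axis=1)
    alpha = o_lab - masked[rows, nu]
    delta = margins[labels]
    satisfied = (alpha > 0) & (alpha >= delta)
    return alpha, nu, satisfied


def margin_error(model: ClassifierModel, X: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of patterns whose margin-thresholded output misses the label."""
    o = model.scores_batch(X)
    _, _, sat = margin_stats(o, labels, model.margins)
    return float(np.mean(~sat))


def hard_error(model: ClassifierModel, X: np.ndarray, labels: np.ndarray) -> float:
    """Plain WTA misclassification rate (the reported error)."""
    return float(np.mean(model.predict(X) != labels))


def _sgn_for_class(mu, labels, nu, satisfied):
    sgn = np.zeros(labels.shape[0])
    sgn[(labels == mu) & ~satisfied] = 1.0
    sgn[(nu == mu) & ~satisfied] = -1.0
    return sgn


def correlation_map(
    model: ClassifierModel,
    patterns: BinaryPatternSet,
    mu: int,
    side: str,
) -> np.ndarray:
    """Synapse-resolved learning signal c_ij for one tree of class ``mu``.

    ``c[j, i]`` averages x_i * b_j(x) * sgn(y_d^mu - y^mu) over the batch,
    with the sign flipped for the inhibitory (NDT) side.  Entries at silent
    (i.e. unconnected) positions score hypothetical trial synapses: a silent
    synapse does not contribute to b_j, so its correlation uses the same
    branch output.
    """
    if side not in ("pdt", "ndt"):
        raise ValueError("side must be 'pdt' or 'ndt'")
    X = np.asarray(patterns.X, dtype=float)
    o = model.scores_batch(X)
    _, nu, sat = margin_stats(o, patterns.labels, model.margins)
    sgn = _sgn_for_class(mu, patterns.labels, nu, sat)
    tp = model.trees[mu]
    cm = tp.pdt if side == "pdt" else tp.ndt
    zleak = tp.zleak_pdt if side == "pdt" else tp.zleak_ndt
    B = branch_nonlinearity(X @ cm.W.T, zleak[None, :])
    sign_factor = 1.0 if side == "pdt" else -1.0
    return sign_factor * (B * sgn[:, None]).T @ X / X.shape[0]


# ---------------------------------------------------------------------------
# replacement selection
# ---------------------------------------------------------------------------


def pick_target(W: np.ndarray, c: np.ndarray, n_T: int, rng: np.random.Generator):
    """Sample n_T active synapse slots (counting multiplicity) without
    replacement and return ``(afferent, dendrite)`` of the lowest-correlation
    one; ties go to the first slot in sampling order."""
    W = np.asarray(W)
    js, is_ = np.nonzero(W)
    reps = W[js, is_]
    total = int(reps.sum())
    if n_T > total:
        raise ValueError(f"n_T={n_T} exceeds the {total} active synapses")
    slot_j = np.repeat(js, reps)
    slot_i = np.repeat(is_, reps)
    sel = rng.choice(total, size=n_T, replace=False)
    vals = c[slot_j[sel], slot_i[sel]]
    pick = int(np.argmin(vals))
    return int(slot_i[sel][pick]), int(slot_j[sel][pick])


def propose_replacement(c_row: np.ndarray, n_R: int, rng: np.random.Generator) -> int:
    """Place n_R silent trial synapses on the target dendrite (candidate
    afferents drawn without replacement from all d lines) and return the one
    with the highest correlation; ties go to the first candidate drawn."""
    d = c_row.shape[0]
    if n_R > d:
        raise ValueError("n_R cannot exceed the number of input lines")
    candidates = rng.choice(d, size=n_R, replace=False)
    return int(candidates[int(np.argmax(c_row[candidates]))])


def attempt_swap(
    model: ClassifierModel,
    patterns: BinaryPatternSet,
    mu: int,
    side: str,
    i_out: int,
    j_T: int,
    i_in: int,
):
    """Apply one replacement on dendrite ``j_T`` (remove a contact of
    ``i_out``, add one of ``i_in``), keep it iff the margin training error did
    not increase, otherwise revert.  Returns ``(accepted, error_after)``."""
    cm = model.trees[mu].pdt if side == "pdt" else model.trees[mu].ndt
    if cm.W[j_T, i_out] < 1:
        raise RuntimeError("target synapse is not connected; swap would break "
                           "the fixed per-dendrite synapse count")
    err0 = margin_error(model, patterns.X, patterns.labels)
    cm.W[j_T, i_out] -= 1
    cm.W[j_T, i_in] += 1
    err1 = margin_error(model, patterns.X, patterns.labels)
    if err1 <= err0:
        return True, err1
    cm.W[j_T, i_in] -= 1
    cm.W[j_T, i_out] += 1
    return False, err0


# ---------------------------------------------------------------------------
# margin calibration
# ---------------------------------------------------------------------------


def set_margins(model: ClassifierModel, patterns: BinaryPatternSet):
    """Calibrate per-class margins on a validation set.

    For every pattern of class mu misclassified (hard WTA) as nu, record the
    score deficit alpha = o^nu - o^mu; delta^mu is the largest deficit, or 0
    for classes with no misclassification.  Margins are set in place; returns
    ``(margins, alphas_by_class)``.
    """
    if patterns.P == 0:
        raise ValueError("empty validation set")
    o = model.scores_batch(patterns.X)
    pred = np.argmax(o, axis=1)
    rows = np.arange(patterns.P)
    deficits = o[rows, pred] - o[rows, patterns.labels]
    alphas = {}
    delta = np.zeros(model.n_classes)
    for mu in range(model.n_classes):
        mask = (patterns.labels == mu) & (pred != mu)
        alphas[mu] = deficits[mask]
        if mask.any():
            delta[mu] = float(deficits[mask].max())
    model.margins = delta
    return delta, alphas


# ---------------------------------------------------------------------------
# the incremental trainer
# ---------------------------------------------------------------------------


class Trainer:
    """Stateful training loop with incrementally maintained activations.

    Caches per tree the branch activations Z = X W^T and branch outputs
    B = b(Z), so a single-synapse swap only touches one matrix column.  The
    model passed in is mutated; ``best_model`` holds the best checkpoint.
    """

    def __init__(
        self,
        model: ClassifierModel,
        patterns: BinaryPatternSet,
        params: LearnParams,
        rng: np.random.Generator,
    ):
        if patterns.d != model.d:
            raise ValueError("pattern dimension does not match the model")
        if patterns.n_classes != model.n_classes:
            raise ValueError("class count does not match the model")
        if params.n_R > model.d:
            raise ValueError("n_R must not exceed d")
        self.model = model
        self.X = np.asarray(patterns.X, dtype=float)
        self.labels = patterns.labels
        self.P = patterns.P
        self.params = params
        self.rng = rng
        self.history = TrainHistory()
        self._Z = [dict() for _ in model.trees]
        self._B = [dict() for _ in model.trees]
        self.o = np.zeros((self.P, model.n_classes))
        for mu in range(model.n_classes):
            self._rebuild_class(mu)
        self._stagnation = 0
        self._pending_reject = None  # last rejected swap, for the forced escape
        self._minima_errors = []
        self._same_minimum_run = 0
        err = self.current_error()
        self.best_error = err
        self.best_model = model.copy()

    # -- caches ------------------------------------------------------------

    def _cm(self, mu, side):
        tp = self.model.trees[mu]
        return tp.pdt if side == "pdt" else tp.ndt

    def _zleak(self, mu, side):
        tp = self.model.trees[mu]
        return tp.zleak_pdt if side == "pdt" else tp.zleak_ndt

    def _rebuild_class(self, mu):
        for side in ("pdt", "ndt"):
            Z = self.X @ self._cm(mu, side).W.T
            self._Z[mu][side] = Z
            self._B[mu][side] = branch_nonlinearity(Z, self._zleak(mu, side)[None, :])
        self.o[:, mu] = self._B[mu]["pdt"].sum(1) - self._B[mu]["ndt"].sum(1)

    def _apply(self, mu, side, j, i_out, i_in):
        cm = self._cm(mu, side)
        if cm.W[j, i_out] < 1:
            raise RuntimeError("swap source not connected")
        cm.W[j, i_out] -= 1
        cm.W[j, i_in] += 1
        Z = self._Z[mu][side]
        Z[:, j] += self.X[:, i_in] - self.X[:, i_out]
        B = self._B[mu][side]
        new_col = branch_nonlinearity(Z[:, j], self._zleak(mu, side)[j])
        sf = 1.0 if side == "pdt" else -1.0
        self.o[:, mu] += sf * (new_col - B[:, j])
        B[:, j] = new_col

    # -- metrics -----------------------------------------------------------

    def stats(self):
        return margin_stats(self.o, self.labels, self.model.margins)

    def current_error(self) -> float:
        _, _, sat = self.stats()
        return float(np.mean(~sat))

    def class_errors(self) -> np.ndarray:
        """Per-class fraction of that class's patterns not yet satisfied."""
        _, _, sat = self.stats()
        out = np.zeros(self.model.n_classes)
        for mu in range(self.model.n_classes):
            mask = self.labels == mu
            if mask.any():
                out[mu] = float(np.mean(~sat[mask]))
        return out

    # -- one replacement attempt --------------------------------------------

    def attempt(self, mu: int, side: str) -> str:
        """One structural-plasticity step on the (mu, side) tree.

        Returns 'memorized', 'minimum', 'accepted' or 'rejected'.
        """
        p = self.params
        _, nu, sat = self.stats()
        err0 = float(np.mean(~sat))
        if err0 == 0.0:
            return "memorized"
        sgn = _sgn_for_class(mu, self.labels, nu, sat)
        B = self._B[mu][side]
        sf = 1.0 if side == "pdt" else -1.0
        c = sf * (B * sgn[:, None]).T @ self.X / self.P
        W = self._cm(mu, side).W
        # candidate set cannot exceed the tree's active synapses (small or
        # freshly initialized trees; trees grow during adaptation)
        n_T = min(p.n_T, int(W.sum()))
        i_out, j_T = pick_target(W, c, n_T, self.rng)
        i_in = propose_replacement(c[j_T], p.n_R, self.rng)

        self._apply(mu, side, j_T, i_out, i_in)
        err1 = self.current_error()
        if err1 < err0:
            self._stagnation = 0
            self._pending_reject = None
            status = "accepted"
            if err1 < self.best_error:
                self.best_error = err1
                self.best_model = self.model.copy()
            if err1 == 0.0:
                return "memorized"
        elif err1 == err0:
            self._stagnation += 1
            self._pending_reject = None
            status = "accepted"
        else:
            self._apply(mu, side, j_T, i_in, i_out)  # revert
            self._stagnation += 1
            self._pending_reject = (mu, side, j_T, i_out, i_in)
            status = "rejected"

        if self._stagnation >= p.n_ch:
            self._declare_minimum(err0 if status == "rejected" else err1)
            return "minimum"
        return status

    def _declare_minimum(self, err: float) -> None:
        """Checkpoint the stagnated state, force the last replacement through
        to escape, and handle the repeated-minimum margin decay."""
        p = self.params
        if err < self.best_error:
            self.best_error = err
            self.best_model = self.model.copy()
        self.history.minima += 1
        self.history.events.append(("minimum", self.history.iterations, err))
        if self._pending_reject is not None:
            self._apply(*self._pending_reject)   # escape even though error rises
            self._pending_reject = None
        self._stagnation = 0
        # repeated-minimum detection -> margin decay
        if self._minima_errors and err == self._minima_errors[-1]:
            self._same_minimum_run += 1
        else:
            self._same_minimum_run = 1
        self._minima_errors.append(err)
        if self._same_minimum_run >= p.decay_trigger:
            if (self.model.margins > 0).any():
                self.model.margins = self.model.margins * p.margin_decay
                self.history.margin_decays += 1
                self.history.events.append(("decay", self.history.iterations,
                                            self.model.margins.copy()))
            self._same_minimum_run = 0

    # -- growth hook (used by the adaptive scheme) ---------------------------

    def add_dendrite(self, mu: int) -> None:
        """Append one fresh random dendrite to both trees of class ``mu``;
        the new branch's leak level comes from its own initial connections."""
        d, k = self.model.d, self.model.k
        tp = self.model.trees[mu]
        for side in ("pdt", "ndt"):
            row = np.bincount(self.rng.integers(0, d, size=k), minlength=d)
            cm = self._cm(mu, side)
            cm.W = np.vstack([cm.W, row[None, :]])
            zl_new = float((self.X @ row).mean())
            if side == "pdt":
                tp.zleak_pdt = np.append(tp.zleak_pdt, zl_new)
            else:
                tp.zleak_ndt = np.append(tp.zleak_ndt, zl_new)
        self._rebuild_class(mu)

    # -- the loop ------------------------------------------------------------

    def run(self, iteration_hook=None) -> ClassifierModel:
        """Iterate until memorization or the local-minima budget is spent.

        Each iteration makes one replacement attempt per dendritic tree
        (classes in fixed order, PDT then NDT).  ``iteration_hook(self)``
        runs after every iteration and may return True to stop early.
        """
        p = self.params
        hist = self.history
        stop = None
        while hist.minima < p.n_min and stop is None:
            hist.iterations += 1
            for mu in range(self.model.n_classes):
                for side in ("pdt", "ndt"):
                    status = self.attempt(mu, side)
                    if status == "memorized":
                        stop = "memorized"
                        break
                    if hist.minima >= p.n_min:
                        stop = "n_min"
                        break
                if stop:
                    break
            err = self.current_error()
            if err < self.best_error:
                self.best_error = err
                self.best_model = self.model.copy()
            hist.error.append(err)
            hist.best_error.append(self.best_error)
            if stop is None and iteration_hook is not None:
                if iteration_hook(self):
                    stop = "hook"
        hist.stop_reason = stop or ("n_min" if p.n_min == 0 else "n_min")
        if stop == "memorized":
            self.best_error = 0.0
            self.best_model = self.model.copy()
        return self.best_model


def train(
    model: ClassifierModel,
    patterns: BinaryPatternSet,
    params: LearnParams | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[ClassifierModel, TrainHistory]:
    """Run the structural learning loop from the given initial model.

    The input model is left untouched; the returned model is the best
    checkpoint encountered (or the memorizing connectivity).
    """
    params = params or LearnParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    trainer = Trainer(model.copy(), patterns, params, rng)
    best = trainer.run()
    return best, trainer.history


def fit(
    patterns: BinaryPatternSet,
    m: int,
    k: int,
    params: LearnParams | None = None,
    seed: int | None = None,
    margin_patterns: BinaryPatternSet | None = None,
    margin_phase: bool = True,
):
    """Full training pipeline: random init (leak levels calibrated on the
    training set), hard-threshold training, margin calibration on
    ``margin_patterns`` (the training set by default), and a second training
    phase under the margin objective.  Returns ``(model, histories)``."""
    params = params or LearnParams()
    rng = np.random.default_rng(seed)
    model = init_model(patterns.n_classes, patterns.d, m, k, rng,
                       X=patterns.X, seed=seed)
    best, hist1 = _train_inplace(model, patterns, params, rng)
    histories = {"hard": hist1}
    if margin_phase:
        delta, _ = set_margins(best, margin_patterns or patterns)
        if (delta > 0).any():
            best, hist2 = _train_inplace(best, patterns, params, rng)
            histories["margin"] = hist2
        best.margins = np.zeros(best.n_classes)  # decisions are hard at test time
    return best, histories


def _train_inplace(model, patterns, params, rng):
    trainer = Trainer(model.copy(), patterns, params, rng)
    return trainer.run(), trainer.history
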