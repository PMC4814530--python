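"""Adaptive dendrite growth: class-specific network sizing during learning.

Instead of fixing the dendrite count m in advance, training starts from a
small tree (m = 5 by default) and appends dendrites — k fresh random
connections as a new row on both the PDT and the NDT — to classes whose
learning has stalled.  A class stalls when its own error has not strictly
decreased for n_ch consecutive iterations.  Two eligibility schemes exist:

* scheme 1: only classes currently among the ``worst_pool`` (default 5)
  highest-error classes may grow;
* scheme 2: any class may grow, but only while its error is the highest of
  all classes — growth strictly follows classification difficulty.

A class whose error has reached zero has memorized its patterns: it neither
stalls nor grows.

Growth is monitored on a held-out validation split (20% of the training
patterns by default): when the validation error has increased at each of the
last three dendrite additions the whole learning run stops and the
connections are frozen.  Otherwise training ends on memorization or the
usual local-minima budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import BinaryPatternSet
from .learning import LearnParams, Trainer, TrainHistory, hard_error
from .model import ClassifierModel, init_model

__all__ = ["GrowthState", "adaptive_train", "split_validation"]


@dataclass
class GrowthState:
    """Audit trail of an adaptive run."""

    scheme: int
    m_per_class: np.ndarray                 # final dendrite counts
    additions: list = field(default_factory=list)
    # each addition: (iteration, class, m_after, train_err, val_err)
    val_errors: list = field(default_factory=list)
    stop_reason: str = ""
    history: TrainHistory | None = None


def split_validation(
    patterns: BinaryPatternSet,
    val_fraction: float,
    rng: np.random.Generator,
):
    """Random held-out split; both halves keep the full class-index space."""
    if not (0 < val_fraction < 1):
        raise ValueError("val_fraction must lie in (0, 1)")
    P = patterns.P
    n_val = max(1, int(round(val_fraction * P)))
    if n_val >= P:
        raise ValueError("validation split would consume the training set")
    perm = rng.permutation(P)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    tr = BinaryPatternSet(patterns.X[tr_idx], patterns.labels[tr_idx],
                          patterns.n_classes)
    val = BinaryPatternSet(patterns.X[val_idx], patterns.labels[val_idx],
                           patterns.n_classes)
    return tr, val


class _GrowthController:
    def __init__(self, trainer, val, scheme, worst_pool):
        self.trainer = trainer
        self.val = val
        self.scheme = scheme
        self.worst_pool = worst_pool
        n_c = trainer.model.n_classes
        self.stall = np.zeros(n_c, dtype=int)
        self.best_class_err = trainer.class_errors()
        self.state = GrowthState(
            scheme=scheme,
            m_per_class=trainer.model.dendrite_counts,
        )
        self.state.val_errors.append(self._val_error())

    def _val_error(self) -> float:
        return hard_error(self.trainer.model, self.val.X, self.val.labels)

    def __call__(self, trainer: Trainer) -> bool:
        """Iteration hook: update stall counters, grow, test the stop rule."""
        errs = trainer.class_errors()
        improved = errs < self.best_class_err
        self.best_class_err = np.minimum(self.best_class_err, errs)
        # a class at zero error has memorized its patterns: it is done, not
        # stuck, so it neither stalls nor grows
        self.stall = np.where(improved | (errs == 0), 0, self.stall + 1)
        stalled = np.flatnonzero(self.stall >= trainer.params.n_ch)
        if stalled.size == 0:
            return False
        if self.scheme == 1:
            pool = min(self.worst_pool, len(errs))
            # classes ranked by current error, worst first
            worst = np.argsort(-errs, kind="stable")[:pool]
            eligible = [mu for mu in stalled if mu in set(worst.tolist())]
        else:
            # a stalled class grows only while its error is the highest of
            # all classes: growth follows classification difficulty
            eligible = [mu for mu in stalled if errs[mu] == errs.max()]
        grew = False
        for mu in eligible:
            trainer.add_dendrite(int(mu))
            self.stall[mu] = 0
            self.best_class_err[mu] = trainer.class_errors()[mu]
            grew = True
            val_err = self._val_error()
            self.state.additions.append(
                (trainer.history.iterations, int(mu),
                 int(trainer.model.trees[mu].m),
                 trainer.current_error(), val_err)
            )
            self.state.val_errors.append(val_err)
            v = self.state.val_errors
            if len(self.state.additions) >= 3 and v[-1] > v[-2] > v[-3] > v[-4]:
                self.state.stop_reason = "validation"
                return True
        if grew:
            self.state.m_per_class = trainer.model.dendrite_counts
        return False


def adaptive_train(
    patterns: BinaryPatternSet,
    k: int,
    init_m: int = 5,
    scheme: int = 2,
    params: LearnParams | None = None,
    val_fraction: float = 0.2,
    worst_pool: int = 5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ClassifierModel, GrowthState]:
    """Structural learning with class-specific dendrite growth.

    Returns the trained model (the connectivity frozen at the validation
    stop, or the best checkpoint when the run ends by memorization or the
    local-minima budget) and the growth audit trail.
    """
    if scheme not in (1, 2):
        raise ValueError("scheme must be 1 or 2")
    params = params or LearnParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    tr, val = split_validation(patterns, val_fraction, rng)
    model = init_model(patterns.n_classes, patterns.d, init_m, k, rng,
                       X=tr.X, seed=seed)
    trainer = Trainer(model, tr, params, rng)
    controller = _GrowthController(trainer, val, scheme, worst_pool)
    best = trainer.run(iteration_hook=controller)
    state = controller.state
    state.history = trainer.history
    state.m_per_class = trainer.model.dendrite_counts
    if not state.stop_reason:
        state.stop_reason = trainer.history.stop_reason
    if state.stop_reason == "validation":
        # paper-faithful: freeze the connections as they are at the stop
        final = trainer.model.copy()
    else:
        final = best
    return final, state
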