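"""Ensembles of dendritic classifiers.

Members are trained independently from different random initial connection
matrices (different seeds) on the same data; at decision time their per-class
intermediate scores o_n^mu(x) are summed class-wise,

    O^mu(x) = sum_n o_n^mu(x),

and a winner-take-all over the combined scores yields the ensemble decision.
The spiking-path analogue sums per-class spike-count differences before the
WTA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BinaryPatternSet
from .learning import LearnParams, fit
from .model import ClassifierModel, wta_decision

__all__ = ["EnsembleModel", "ensemble_scores", "ensemble_decide",
           "ensemble_predict", "train_ensemble"]


@dataclass
class EnsembleModel:
    members: list[ClassifierModel]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty ensemble")
        d0, nc0 = self.members[0].d, self.members[0].n_classes
        for mdl in self.members:
            if mdl.d != d0 or mdl.n_classes != nc0:
                raise ValueError("all members must share d and the class count")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def total_dendrites(self) -> int:
        """M = sum over members of 2 * m^mu summed over classes."""
        return int(sum(2 * tp.m for mdl in self.members for tp in mdl.trees))


def ensemble_scores(ens: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Summed class scores O = sum_n o_n for a batch; (P, N_C)."""
    X = np.atleast_2d(np.asarray(X))
    O = np.zeros((X.shape[0], ens.members[0].n_classes))
    for mdl in ens.members:
        O += mdl.scores_batch(X)
    return O


def ensemble_decide(ens: EnsembleModel, x: np.ndarray) -> np.ndarray:
    """One-hot WTA decision over the summed scores for a single pattern."""
    return wta_decision(ensemble_scores(ens, x)[0])


def ensemble_predict(ens: EnsembleModel, X: np.ndarray) -> np.ndarray:
    return np.argmax(ensemble_scores(ens, X), axis=1)


def train_ensemble(
    patterns: BinaryPatternSet,
    n_members: int,
    m: int,
    k: int,
    params: LearnParams | None = None,
    seed: int = 0,
    margin_phase: bool = True,
) -> EnsembleModel:
    """Train ``n_members`` classifiers that differ only in the RNG seed of
    their initial random connections (seed, seed+1, ...)."""
    members = []
    for n in range(n_members):
        mdl, _ = fit(patterns, m, k, params=params, seed=seed + n,
                     margin_phase=margin_phase)
        members.append(mdl)
    return EnsembleModel(members)
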