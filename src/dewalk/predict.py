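"""Double-ended scoring and ranked candidate output.

One walk is run per node (its stationary distribution is deterministic,
so it is computed once and reused across pairs).  For a pair (d_i, m_j):

    score_d = stationary probability at node m_j of the walk seeded at d_i
    score_m = stationary probability at node d_i of the walk seeded at m_j
    S[i, j] = beta * score_m + (1 - beta) * score_d

with beta = 0.7 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationData, DataError, RankedPrediction, ScoreMatrix
from .network import HeteroNetwork
from .walk import WalkParams, rwr_iterate


@dataclass
class CombineParams:
    """Linear-combination weight beta in [0, 1]; beta weights the
    microbe-seeded walk, 1-beta the disease-seeded walk."""

    beta: float = 0.7

    def __post_init__(self) -> None:
        if not (0 <= self.beta <= 1):
            raise ValueError("beta must be in [0, 1]")


def _seed_matrix(net: HeteroNetwork, assoc: AssociationData) -> np.ndarray:
    """All seed vectors as columns: column k seeds node k plus its known
    association partners, uniformly weighted (sums to 1)."""
    n_d, n_m = assoc.n_diseases, assoc.n_microbes
    P0 = np.eye(n_d + n_m)
    P0[n_d:, :n_d] = assoc.A.T
    P0[:n_d, n_d:] = assoc.A
    return P0 / P0.sum(axis=0)[None, :]


def score_all(
    net: HeteroNetwork,
    assoc: AssociationData,
    walk: WalkParams | None = None,
    comb: CombineParams | None = None,
    allow_nonconverged: bool = False,
) -> ScoreMatrix:
    """Score every disease-microbe pair by the double-ended walk.

    Runs N_d + N_m walks (one per node, batched) and combines the
    counterpart-node probabilities.  Raises on non-convergence unless
    ``allow_nonconverged`` is set.
    """
    walk = walk or WalkParams()
    comb = comb or CombineParams()
    if (
        net.disease_labels != assoc.disease_labels
        or net.microbe_labels != assoc.microbe_labels
    ):
        raise DataError("network and association labels differ")
    P0 = _seed_matrix(net, assoc)
    stat = rwr_iterate(net, P0, walk)
    if not stat.converged and not allow_nonconverged:
        raise DataError(
            f"random walk did not converge in {walk.max_iter} iterations"
        )
    P = stat.p  # column k = stationary distribution of the walk seeded at node k
    n_d = assoc.n_diseases
    score_d = P[n_d:, :n_d].T  # disease-seeded walk read at the microbe node
    score_m = P[:n_d, n_d:]  # microbe-seeded walk read at the disease node
    S = comb.beta * score_m + (1.0 - comb.beta) * score_d
    return ScoreMatrix(list(assoc.disease_labels), list(assoc.microbe_labels), S)


def rank_candidates(
    scores: ScoreMatrix,
    assoc: AssociationData,
    disease: str,
    top_k: int | None = None,
) -> RankedPrediction:
    """Rank all microbes not already associated with ``disease``.

    Sorted by score descending; ties broken by microbe label ascending
    for reproducibility.  ``top_k`` truncates the list.
    """
    i = assoc.disease_index(disease)
    if scores.disease_labels != assoc.disease_labels or (
        scores.microbe_labels != assoc.microbe_labels
    ):
        raise DataError("score matrix labels do not match association data")
    unknown = np.flatnonzero(assoc.A[i, :] == 0.0)
    ordered = sorted(
        ((assoc.microbe_labels[j], float(scores.S[i, j])) for j in unknown),
        key=lambda t: (-t[1], t[0]),
    )
    if top_k is not None:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        ordered = ordered[:top_k]
    return RankedPrediction(
        disease, [(m, s, rank) for rank, (m, s) in enumerate(ordered, start=1)]
    )
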