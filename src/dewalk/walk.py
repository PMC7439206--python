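"""Random walk with restart: seed construction, iteration, closed form.

The walk iterates

    P_{t+1} = (1 - r) A' P_t + r P_0

on the column-normalized heterogeneous adjacency A', from the seed
distribution P_0, until the L1 change drops below ``tol``.  With r > 0
and column sums <= 1 the map is a contraction with factor (1 - r), so
convergence is geometric and the analytic fixed point

    p = r (I - (1 - r) A')^{-1} p0

exists; the closed form serves as an independent oracle for the
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationData, DataError
from .network import HeteroNetwork


@dataclass
class WalkParams:
    """Restart probability r in (0, 1], L1 convergence threshold, and an
    iteration safety cap (generous: convergence is geometric at rate 1-r)."""

    r: float = 0.7
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.r <= 1):
            raise ValueError("restart probability r must be in (0, 1]")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class SeedVector:
    p0: np.ndarray

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        if (self.p0 < 0).any():
            raise DataError("seed vector must be nonnegative")
        if abs(self.p0.sum() - 1.0) > 1e-12:
            raise DataError("seed vector must sum to 1")


@dataclass
class StationaryDistribution:
    p: np.ndarray
    iterations: int
    converged: bool


def build_seed_vector(
    net: HeteroNetwork, query: str, assoc: AssociationData
) -> SeedVector:
    """Uniform seed over the query node and its known association partners.

    A disease seed covers the disease node plus every microbe node it is
    known to associate with (and symmetrically for a microbe query),
    normalized to sum 1.  An isolated query yields the indicator on itself.
    """
    if query not in net.index_map:
        raise KeyError(f"unknown node label: {query!r}")
    n_d = net.n_diseases
    p0 = np.zeros(net.n_nodes)
    p0[net.index_map[query]] = 1.0
    if query in assoc.disease_labels:
        i = assoc.disease_index(query)
        p0[n_d:][assoc.A[i, :] == 1.0] = 1.0
    else:
        j = assoc.microbe_index(query)
        p0[:n_d][assoc.A[:, j] == 1.0] = 1.0
    return SeedVector(p0 / p0.sum())


def _as_norm(net: HeteroNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, HeteroNetwork):
        if net.a_norm is None:
            raise DataError("network not normalized; call column_normalize first")
        return net.a_norm
    return np.asarray(net, dtype=float)


def rwr_iterate(
    net: HeteroNetwork | np.ndarray,
    p0: SeedVector | np.ndarray,
    params: WalkParams | None = None,
) -> StationaryDistribution:
    """Power iteration of the restart walk until the L1 change < tol.

    ``p0`` may be a matrix whose columns are seed distributions; all
    walks then advance together and convergence requires every column's
    L1 change below tol.  A result that hits ``max_iter`` without
    converging is returned flagged, never silently.
    """
    params = params or WalkParams()
    A = _as_norm(net)
    P = p0.p0 if isinstance(p0, SeedVector) else np.asarray(p0, dtype=float)
    P0 = P.copy()
    keep, r = 1.0 - params.r, params.r
    for it in range(1, params.max_iter + 1):
        P_next = keep * (A @ P) + r * P0
        delta = np.abs(P_next - P).sum(axis=0).max()
        P = P_next
        if delta < params.tol:
            return StationaryDistribution(P, it, True)
    return StationaryDistribution(P, params.max_iter, False)


def rwr_closed_form(
    net: HeteroNetwork | np.ndarray,
    p0: SeedVector | np.ndarray,
    r: float = 0.7,
) -> StationaryDistribution:
    """Analytic fixed point p = r (I - (1-r) A')^{-1} p0 (test oracle)."""
    if not (0 < r <= 1):
        raise ValueError("restart probability r must be in (0, 1]")
    A = _as_norm(net)
    P0 = p0.p0 if isinstance(p0, SeedVector) else np.asarray(p0, dtype=float)
    n = A.shape[0]
    p = np.linalg.solve(np.eye(n) - (1.0 - r) * A, r * P0)
    return StationaryDistribution(p, 0, True)
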