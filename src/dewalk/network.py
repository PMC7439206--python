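"""Heterogeneous disease-microbe network assembly and normalization.

Nodes are diseases first (indices 0..N_d-1) then microbes
(N_d..N_d+N_m-1).  The raw adjacency is the block matrix

    [[ SD,  A ],
     [ A^T, KM ]]

with SD/KM similarity blocks and A the binary association block.  The
walk operates on the column-normalized form A'[i,j] = A[i,j] / sum_k A[k,j].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import AssociationData, DataError, SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class HeteroNetwork:
    disease_labels: list[str]
    microbe_labels: list[str]
    a_raw: np.ndarray
    a_norm: np.ndarray | None = None
    index_map: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.disease_labels) + len(self.microbe_labels)
        if self.a_raw.shape != (n, n):
            raise DataError("raw adjacency does not match label count")
        labels = self.node_labels
        if len(set(labels)) != n:
            raise DataError("node labels must be unique across diseases and microbes")
        self.index_map = {lab: k for k, lab in enumerate(labels)}

    @property
    def node_labels(self) -> list[str]:
        return list(self.disease_labels) + list(self.microbe_labels)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_labels)

    @property
    def n_nodes(self) -> int:
        return self.a_raw.shape[0]


def build_heterogeneous_adjacency(
    SD: SimilarityMatrix,
    KM: SimilarityMatrix,
    assoc: AssociationData,
    mode: str = "weighted",
    threshold: float = 0.5,
    drop_self_loops: bool = False,
) -> HeteroNetwork:
    """Assemble the (N_d+N_m)-node block adjacency.

    ``mode='weighted'`` (default) keeps similarity values as edge
    weights; ``mode='binarized'`` thresholds the similarity blocks at
    ``threshold`` (entry = 1 iff value >= threshold).  The association
    block is binary either way.  ``drop_self_loops`` zeroes the diagonal
    (the kernels put 1 there by construction).
    """
    if SD.labels != assoc.disease_labels:
        raise DataError("disease similarity labels do not match association data")
    if KM.labels != assoc.microbe_labels:
        raise DataError("microbe similarity labels do not match association data")
    sd, km = SD.M, KM.M
    if mode == "binarized":
        sd = (sd >= threshold).astype(float)
        km = (km >= threshold).astype(float)
    elif mode != "weighted":
        raise ValueError(f"mode must be 'weighted' or 'binarized', got {mode!r}")
    A = assoc.A
    raw = np.block([[sd, A], [A.T, km]])
    if drop_self_loops:
        np.fill_diagonal(raw, 0.0)
    return HeteroNetwork(list(assoc.disease_labels), list(assoc.microbe_labels), raw)


def column_normalize(net: HeteroNetwork) -> HeteroNetwork:
    """Set ``a_norm`` so every nonzero column sums to 1; zero columns stay
    zero (the restart term keeps the walk bounded regardless) and are logged."""
    if (net.a_raw < 0).any():
        raise DataError("adjacency must be nonnegative for column normalization")
    col_sums = net.a_raw.sum(axis=0)
    zero_cols = col_sums == 0
    if zero_cols.any():
        names = [net.node_labels[k] for k in np.flatnonzero(zero_cols)]
        logger.warning("zero-sum columns left unnormalized: %s", names)
    safe = np.where(zero_cols, 1.0, col_sums)
    net.a_norm = net.a_raw / safe[None, :]
    return net
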