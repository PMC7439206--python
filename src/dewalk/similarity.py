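"""Similarity blocks: GIP kernels, symptom TF-IDF cosine, integration.

The Gaussian interaction profile (GIP) kernel measures how alike two
binary interaction profiles are:

    K(i, j) = exp(-gamma * ||VP_i - VP_j||^2)

where VP_i is the i-th row (disease) or column (microbe) of the
association matrix and the bandwidth is normalized by the mean squared
profile norm,

    gamma = gamma' / ( (1/n) * sum_i ||VP_i||^2 ),

with gamma' = 1 by convention.  Symptom-based disease similarity (SDM)
is the cosine between TF-IDF-weighted symptom vectors; the integrated
disease similarity SD is the elementwise mean of KD and SDM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationData, DataError, SimilarityMatrix, SymptomData

logger = logging.getLogger(__name__)


@dataclass
class KernelParams:
    """GIP kernel bandwidth numerator gamma' (> 0); the effective
    bandwidth divides it by the mean squared profile norm."""

    gamma_prime: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma_prime > 0:
            raise ValueError("gamma_prime must be positive")


def gip_kernel(
    assoc: AssociationData,
    axis: str = "diseases",
    params: KernelParams | None = None,
) -> SimilarityMatrix:
    """GIP kernel over disease rows (``axis='diseases'``, kind KD) or
    microbe columns (``axis='microbes'``, kind KM) of the association matrix.

    Raises
    ------
    DataError
        If every profile along the chosen axis is zero: the bandwidth is
        then undefined (division by zero).
    """
    params = params or KernelParams()
    if axis == "diseases":
        profiles, labels, kind = assoc.A, assoc.disease_labels, "KD"
    elif axis == "microbes":
        profiles, labels, kind = assoc.A.T, assoc.microbe_labels, "KM"
    else:
        raise ValueError(f"axis must be 'diseases' or 'microbes', got {axis!r}")

    sq_norms = np.einsum("ij,ij->i", profiles, profiles)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise DataError(
            f"all {axis} interaction profiles are zero; GIP bandwidth undefined"
        )
    gamma = params.gamma_prime / mean_sq
    # ||x - y||^2 = ||x||^2 + ||y||^2 - 2 x.y ; binary profiles keep this exact
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(sq_dist, 0.0, out=sq_dist)
    M = np.exp(-gamma * sq_dist)
    M = 0.5 * (M + M.T)
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(list(labels), M, kind)


def tfidf_weights(sym: SymptomData, log_base: float | None = None) -> np.ndarray:
    """TF-IDF weighting of the raw symptom x disease counts.

    Each count is multiplied by ``log(N / n_i)`` where N is the number of
    diseases and ``n_i`` the number of diseases with a strictly positive
    count for symptom i.  Symptoms present nowhere get all-zero rows.
    ``log_base`` defaults to e; the downstream cosine is invariant to it.
    """
    N = len(sym.disease_labels)
    if N < 1:
        raise DataError("TF-IDF weighting needs at least one disease")
    n_i = (sym.C > 0).sum(axis=1).astype(float)
    idf = np.zeros_like(n_i)
    present = n_i > 0
    idf[present] = np.log(N / n_i[present])
    if log_base is not None:
        idf /= np.log(log_base)
    return sym.C * idf[:, None]


def cosine_similarity(
    W: np.ndarray, labels: list[str], kind: str = "SDM"
) -> SimilarityMatrix:
    """Pairwise cosine of the (nonnegative) weighted disease column vectors.

    Pairs where either vector is all-zero get similarity 0 off the
    diagonal (the cosine is 0/0 there; zero encodes "no evidence of
    similarity"); the diagonal is always 1.
    """
    W = np.asarray(W, dtype=float)
    norms = np.linalg.norm(W, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    M = (W.T @ W) / np.outer(safe, safe)
    zero = norms == 0
    M[zero, :] = 0.0
    M[:, zero] = 0.0
    M = 0.5 * (M + M.T)
    np.clip(M, 0.0, 1.0, out=M)
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(list(labels), M, kind)


def symptom_similarity(sym: SymptomData, log_base: float | None = None) -> SimilarityMatrix:
    """SDM: cosine of TF-IDF-weighted symptom vectors (convenience wrapper)."""
    if sym.is_degenerate:
        raise DataError("symptom table has no symptoms; SDM undefined")
    return cosine_similarity(tfidf_weights(sym, log_base), sym.disease_labels, "SDM")


def integrate_disease_similarity(
    KD: SimilarityMatrix, SDM: SimilarityMatrix | None = None
) -> SimilarityMatrix:
    """SD = (KD + SDM) / 2 elementwise; falls back to SD = KD when no
    symptom similarity is available (kernel-only configuration)."""
    if SDM is None:
        logger.warning("no symptom similarity given; using SD = KD fallback")
        return SimilarityMatrix(list(KD.labels), KD.M.copy(), "SD")
    if KD.labels != SDM.labels:
        raise DataError("KD and SDM label sets/orderings differ")
    return SimilarityMatrix(list(KD.labels), 0.5 * (KD.M + SDM.M), "SD")
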