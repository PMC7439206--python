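"""Core domain types shared across the pipeline.

The central object is the binary disease x microbe association matrix
``A`` (``AssociationData``): ``A[i, j] = 1`` iff disease ``i`` has a
curated association with microbe ``j``.  Its rows are the disease
interaction profiles and its columns the microbe interaction profiles
used by the Gaussian interaction profile (GIP) kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DataError(ValueError):
    """Raised when an input table or matrix violates its contract."""


def _check_unique(labels: list[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(l for l in labels if l in seen or seen.add(l))  # type: ignore[func-returns-value]
        raise DataError(f"duplicate {what} label: {dup!r}")


@dataclass
class AssociationData:
    """Binary disease x microbe association matrix with axis labels.

    Parameters
    ----------
    disease_labels : list of str
        Unique disease names, in first-appearance order (length N_d).
    microbe_labels : list of str
        Unique microbe names, in first-appearance order (length N_m).
    A : ndarray of shape (N_d, N_m)
        Binary matrix; ``A[i, j] = 1`` iff the pair is a known association.
    evidence : dict, optional
        Pass-through metadata mapping ``(disease, microbe)`` to the list of
        evidence strings seen in the source table.  Never affects ``A``.
    """

    disease_labels: list[str]
    microbe_labels: list[str]
    A: np.ndarray
    evidence: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise DataError("association matrix must be 2-dimensional")
        n_d, n_m = self.A.shape
        if n_d < 1 or n_m < 1:
            raise DataError("association matrix must be nonempty")
        if len(self.disease_labels) != n_d or len(self.microbe_labels) != n_m:
            raise DataError("label lengths do not match matrix shape")
        _check_unique(self.disease_labels, "disease")
        _check_unique(self.microbe_labels, "microbe")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise DataError("association matrix entries must be 0 or 1")

    @property
    def n_diseases(self) -> int:
        return self.A.shape[0]

    @property
    def n_microbes(self) -> int:
        return self.A.shape[1]

    def disease_index(self, label: str) -> int:
        try:
            return self.disease_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown disease: {label!r}") from None

    def microbe_index(self, label: str) -> int:
        try:
            return self.microbe_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown microbe: {label!r}") from None

    def known_pairs(self) -> list[tuple[int, int]]:
        """Index pairs ``(i, j)`` of known associations, row-major order."""
        return [tuple(ij) for ij in np.argwhere(self.A == 1.0)]

    def mask_pairs(self, pairs: list[tuple[int, int]]) -> "AssociationData":
        """Copy with the given known pairs set to 0 (held out)."""
        A = self.A.copy()
        for i, j in pairs:
            A[i, j] = 0.0
        return AssociationData(
            list(self.disease_labels), list(self.microbe_labels), A, dict(self.evidence)
        )


@dataclass
class SymptomData:
    """Nonnegative symptom x disease co-occurrence counts.

    ``C[i, j]`` is the raw co-occurrence count between symptom ``i`` and
    disease ``j`` before TF-IDF weighting.  An empty symptom set
    (0 rows) is permitted but degenerate: the symptom-based similarity
    is undefined and downstream code falls back to the GIP kernel.
    """

    disease_labels: list[str]
    symptom_labels: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2:
            raise DataError("symptom count matrix must be 2-dimensional")
        if self.C.shape != (len(self.symptom_labels), len(self.disease_labels)):
            raise DataError("symptom matrix shape does not match labels")
        _check_unique(self.disease_labels, "disease")
        _check_unique(self.symptom_labels, "symptom")
        if not np.isfinite(self.C).all():
            raise DataError("symptom counts must be finite")
        if (self.C < 0).any():
            raise DataError("symptom counts must be nonnegative")

    @property
    def is_degenerate(self) -> bool:
        """True when there are no symptoms (similarity undefined)."""
        return self.C.shape[0] == 0


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity block with entries in [0, 1].

    ``kind`` tags the block: ``KD``/``KM`` are the GIP kernels over
    disease/microbe interaction profiles, ``SDM`` the symptom TF-IDF
    cosine similarity, ``SD`` the integrated disease similarity.
    """

    labels: list[str]
    M: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        n = len(self.labels)
        if self.M.shape != (n, n):
            raise DataError("similarity matrix must be square and match labels")
        _check_unique(self.labels, "similarity")
        if not np.isfinite(self.M).all():
            raise DataError("similarity entries must be finite")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class ScoreMatrix:
    """Real-valued disease x microbe prediction scores."""

    disease_labels: list[str]
    microbe_labels: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (len(self.disease_labels), len(self.microbe_labels)):
            raise DataError("score matrix shape does not match labels")
        if not np.isfinite(self.S).all():
            raise DataError("scores must be finite")


@dataclass
class RankedPrediction:
    """Ranked candidate microbes for one disease, known pairs excluded.

    ``candidates`` is an ordered list of ``(microbe, score, rank)`` with
    scores nonincreasing; ranks start at 1.
    """

    disease: str
    candidates: list[tuple[str, float, int]]

    def __post_init__(self) -> None:
        scores = [s for _, s, _ in self.candidates]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise DataError("candidate scores must be nonincreasing")
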