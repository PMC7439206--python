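"""Cross-validation harnesses and rank-based ROC/AUC.

Global LOOCV removes one known association at a time, retrains the
similarity kernels and network on the masked matrix (no leakage), and
ranks the held-out pair against every pair with no known evidence of
association.  k-fold CV does the same with random folds of the known
pair set.  The AUC is the Mann-Whitney rank statistic with average
ranks for ties, which equals the trapezoidal area under the tie-grouped
ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import AssociationData, DataError, ScoreMatrix, SymptomData
from .pipeline import NetworkConfig, pipeline_scores
from .predict import CombineParams
from .similarity import KernelParams
from .walk import WalkParams

Scorer = Callable[[AssociationData, SymptomData | None], ScoreMatrix]


@dataclass
class CVConfig:
    """Cross-validation scheme: ``loocv`` or ``kfold`` with ``k`` folds.

    ``recompute_similarity`` (default True) rebuilds kernels, network
    and seeds from the masked training matrix in every round; switching
    it off scores held-out pairs with the full-data model, which leaks
    the held-out entries into the kernels and inflates the AUC.
    """

    scheme: str = "loocv"
    k: int = 5
    rng_seed: int = 0
    recompute_similarity: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in ("loocv", "kfold"):
            raise ValueError("scheme must be 'loocv' or 'kfold'")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("kfold needs k >= 2")


@dataclass
class EvaluationResult:
    """Held-out ranks/quantiles, ROC points and the AUC.

    ``quantiles[t]`` is the fraction of candidate (unknown) pairs scored
    strictly below held-out pair t, counting ties as half; the AUC is
    their mean.  ``ranks`` are the matching 1-based ranks among the
    candidates.  The ROC starts at (0, 0), ends at (1, 1) and its
    trapezoidal area equals ``auc``.
    """

    scheme: str
    auc: float
    quantiles: np.ndarray
    ranks: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    per_fold_aucs: list[float] | None = None
    fold_assignment: list[list[tuple[int, int]]] | None = None

    def roc_table(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_auc(labels: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray) -> EvaluationResult:
    """Rank-based AUC (average ranks for ties) with the matching ROC curve.

    Requires at least one positive and one negative label; equals the
    probability that a random positive outscores a random negative,
    ties counting half.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise DataError("labels and scores must be 1-d arrays of equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("labels must be binary")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC needs at least one positive and one negative")
    ranks = rankdata(s)  # average ranks for ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # tie-grouped ROC: one point per distinct threshold, descending
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    idx = np.r_[boundary, s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[idx]
    fps = (idx + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return EvaluationResult(
        scheme="roc",
        auc=float(auc),
        quantiles=np.array([]),
        ranks=np.array([]),
        fpr=fpr,
        tpr=tpr,
    )


def default_scorer(
    walk: WalkParams | None = None,
    comb: CombineParams | None = None,
    kernel: KernelParams | None = None,
    net_cfg: NetworkConfig | None = None,
) -> Scorer:
    """The full double-ended-walk pipeline as a CV scorer."""

    def _score(train: AssociationData, symptoms: SymptomData | None) -> ScoreMatrix:
        return pipeline_scores(train, symptoms, walk, comb, kernel, net_cfg)

    return _score


def uniform_random_scorer(rng: np.random.Generator) -> Scorer:
    """Null scorer: uniform random scores, ignoring the data (calibration)."""

    def _score(train: AssociationData, symptoms: SymptomData | None) -> ScoreMatrix:
        S = rng.random((train.n_diseases, train.n_microbes))
        return ScoreMatrix(list(train.disease_labels), list(train.microbe_labels), S)

    return _score


def _held_out_stats(
    S: np.ndarray, candidate_mask: np.ndarray, pairs: list[tuple[int, int]]
) -> tuple[list[float], list[float]]:
    """Quantile and rank of each held-out pair among candidate pairs."""
    cand = S[candidate_mask]
    n_cand = cand.size
    qs, rks = [], []
    for i, j in pairs:
        s = S[i, j]
        wins = float((cand < s).sum())
        ties = float((cand == s).sum())
        qs.append((wins + 0.5 * ties) / n_cand)
        rks.append(n_cand - wins - 0.5 * ties + 1.0)
    return qs, rks


def _roc_from_quantiles(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Step ROC of held-out quantiles against the candidate pool.

    A pair with quantile q sits at false-positive fraction 1-q; the
    trapezoidal area of the resulting step curve is mean(q).
    """
    n = q.size
    f_vals, counts = np.unique(1.0 - q, return_counts=True)
    fpr = [0.0]
    tpr = [0.0]
    cum = 0.0
    for f, c in zip(f_vals, counts):
        fpr.extend([f, f])
        tpr.extend([cum, cum + c / n])
        cum += c / n
    fpr.append(1.0)
    tpr.append(1.0)
    return np.asarray(fpr), np.asarray(tpr)


def _run_cv(
    assoc: AssociationData,
    symptoms: SymptomData | None,
    folds: list[list[tuple[int, int]]],
    scorer: Scorer,
    recompute: bool,
    scheme: str,
) -> EvaluationResult:
    candidate_mask = assoc.A == 0.0  # pairs without known evidence, full data
    full_scores: ScoreMatrix | None = None
    if not recompute:
        full_scores = scorer(assoc, symptoms)
    quantiles: list[float] = []
    ranks: list[float] = []
    per_fold: list[float] = []
    for fold in folds:
        if recompute:
            train = assoc.mask_pairs(fold)
            S = scorer(train, symptoms).S
        else:
            S = full_scores.S  # type: ignore[union-attr]
        qs, rks = _held_out_stats(S, candidate_mask, fold)
        quantiles.extend(qs)
        ranks.extend(rks)
        per_fold.append(float(np.mean(qs)))
    q = np.asarray(quantiles)
    fpr, tpr = _roc_from_quantiles(q)
    return EvaluationResult(
        scheme=scheme,
        auc=float(q.mean()),
        quantiles=q,
        ranks=np.asarray(ranks),
        fpr=fpr,
        tpr=tpr,
        per_fold_aucs=per_fold if scheme == "kfold" else None,
        fold_assignment=folds,
    )


def loocv(
    assoc: AssociationData,
    symptoms: SymptomData | None = None,
    walk: WalkParams | None = None,
    comb: CombineParams | None = None,
    cfg: CVConfig | None = None,
    scorer: Scorer | None = None,
    net_cfg: NetworkConfig | None = None,
) -> EvaluationResult:
    """Global LOOCV: each known pair is held out in turn, the model is
    retrained on the masked matrix and the pair is ranked against all
    unknown pairs jointly."""
    cfg = cfg or CVConfig(scheme="loocv")
    pairs = assoc.known_pairs()
    if len(pairs) < 2:
        raise DataError("LOOCV needs at least 2 known associations")
    scorer = scorer or default_scorer(walk, comb, net_cfg=net_cfg)
    folds = [[p] for p in pairs]
    return _run_cv(assoc, symptoms, folds, scorer, cfg.recompute_similarity, "loocv")


def make_folds(
    pairs: list[tuple[int, int]], k: int, rng_seed: int
) -> list[list[tuple[int, int]]]:
    """Random partition of the known-pair list into k near-equal folds."""
    if k > len(pairs):
        raise DataError(f"k={k} exceeds the {len(pairs)} known associations")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(pairs))
    return [[pairs[i] for i in block] for block in np.array_split(perm, k)]


def kfold_cv(
    assoc: AssociationData,
    symptoms: SymptomData | None = None,
    walk: WalkParams | None = None,
    comb: CombineParams | None = None,
    cfg: CVConfig | None = None,
    scorer: Scorer | None = None,
    folds: list[list[tuple[int, int]]] | None = None,
    net_cfg: NetworkConfig | None = None,
) -> EvaluationResult:
    """k-fold CV over known associations; reports per-fold and pooled AUC.

    ``folds`` overrides the random assignment (used by the parameter
    sweep to share folds across grid points)."""
    cfg = cfg or CVConfig(scheme="kfold")
    pairs = assoc.known_pairs()
    if folds is None:
        folds = make_folds(pairs, cfg.k, cfg.rng_seed)
    scorer = scorer or default_scorer(walk, comb, net_cfg=net_cfg)
    return _run_cv(assoc, symptoms, folds, scorer, cfg.recompute_similarity, "kfold")


def parameter_sweep(
    assoc: AssociationData,
    symptoms: SymptomData | None = None,
    r_values: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    beta_values: Sequence[float] = (0.7,),
    cfg: CVConfig | None = None,
    net_cfg: NetworkConfig | None = None,
) -> pd.DataFrame:
    """k-fold AUC on a grid over the restart probability r and the
    combination weight beta, with one shared fold assignment."""
    cfg = cfg or CVConfig(scheme="kfold")
    folds = make_folds(assoc.known_pairs(), cfg.k, cfg.rng_seed)
    rows = []
    for r in r_values:
        for beta in beta_values:
            scorer = default_scorer(
                WalkParams(r=r), CombineParams(beta=beta), net_cfg=net_cfg
            )
            res = kfold_cv(assoc, symptoms, cfg=cfg, scorer=scorer, folds=folds)
            rows.append({"r": r, "beta": beta, "auc": res.auc})
    return pd.DataFrame(rows)
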