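"""Readers and writers for association tables, symptom tables and reports.

All tabular I/O is tab-separated with a header row.  The association
table follows the curated-database convention: one row per evidence
record with columns ``disease``, ``microbe`` and an optional
``evidence`` column; multiple records for the same pair collapse to a
single association.  Labels keep their first-appearance order and are
compared after trimming outer whitespace only (case-sensitive).
"""

from __future__ import annotations

import os
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .datatypes import AssociationData, DataError, RankedPrediction, SymptomData


class ParseError(DataError):
    """Raised for malformed input tables; names the offending line."""


def read_association_table(
    path: str | os.PathLike,
    dialect: dict[str, str] | None = None,
) -> AssociationData:
    """Read a (disease, microbe[, evidence]) pair table into an association matrix.

    Parameters
    ----------
    path:
        TSV file with a header; must contain the disease and microbe columns.
    dialect:
        Optional column mapping, e.g. ``{"disease": "Disease name",
        "microbe": "Organism"}``; values name the columns in the file.

    Duplicate (disease, microbe) pairs collapse to one association; the
    evidence column, when present, is preserved per pair as metadata.
    """
    colmap = {"disease": "disease", "microbe": "microbe", "evidence": "evidence"}
    if dialect:
        colmap.update(dialect)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"empty association file: {path}") from None
    for key in ("disease", "microbe"):
        if colmap[key] not in df.columns:
            raise ParseError(f"missing column {colmap[key]!r} in {path}")
    if len(df) == 0:
        raise ParseError(f"association file has no data rows: {path}")

    has_evidence = colmap["evidence"] in df.columns
    diseases: list[str] = []
    microbes: list[str] = []
    pairs: dict[tuple[str, str], list[str]] = {}
    d_col = df[colmap["disease"]].tolist()
    m_col = df[colmap["microbe"]].tolist()
    e_col = df[colmap["evidence"]].tolist() if has_evidence else None
    for row_idx in range(len(df)):
        line_no = row_idx + 2  # header is line 1
        d = str(d_col[row_idx]).strip()
        m = str(m_col[row_idx]).strip()
        if not d:
            raise ParseError(f"line {line_no}: empty disease field")
        if not m:
            raise ParseError(f"line {line_no}: empty microbe field")
        if d not in diseases:
            diseases.append(d)
        if m not in microbes:
            microbes.append(m)
        ev = pairs.setdefault((d, m), [])
        if e_col is not None:
            e = str(e_col[row_idx]).strip()
            if e:
                ev.append(e)

    A = np.zeros((len(diseases), len(microbes)))
    d_idx = {d: i for i, d in enumerate(diseases)}
    m_idx = {m: j for j, m in enumerate(microbes)}
    for d, m in pairs:
        A[d_idx[d], m_idx[m]] = 1.0
    return AssociationData(diseases, microbes, A, evidence=pairs)


def write_association_table(assoc: AssociationData, path: str | os.PathLike) -> None:
    """Write the known pairs back as a (disease, microbe, evidence) TSV."""
    rows = []
    for i, j in assoc.known_pairs():
        d = assoc.disease_labels[i]
        m = assoc.microbe_labels[j]
        ev = ";".join(assoc.evidence.get((d, m), []))
        rows.append((d, m, ev))
    pd.DataFrame(rows, columns=["disease", "microbe", "evidence"]).to_csv(
        path, sep="\t", index=False
    )


def read_symptom_table(
    path: str | os.PathLike, diseases_in_rows: bool = False
) -> SymptomData:
    """Read a symptom x disease count table (first column = symptom label).

    Set ``diseases_in_rows`` when the file is the transpose (disease rows,
    symptom columns); the result is always oriented symptom x disease.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        C = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"non-numeric symptom count in {path}: {exc}") from None
    if not np.isfinite(C).all():
        raise ParseError(f"non-finite symptom count in {path}")
    if (C < 0).any():
        raise ParseError(f"negative symptom count in {path}")
    row_labels = [str(x).strip() for x in df.index]
    col_labels = [str(x).strip() for x in df.columns]
    if diseases_in_rows:
        return SymptomData(row_labels, col_labels, C.T)
    return SymptomData(col_labels, row_labels, C)


def write_symptom_table(sym: SymptomData, path: str | os.PathLike) -> None:
    pd.DataFrame(sym.C, index=sym.symptom_labels, columns=sym.disease_labels).to_csv(
        path, sep="\t", index_label="symptom"
    )


def write_ranked_predictions(
    pred: RankedPrediction,
    path: str | os.PathLike | TextIO,
    top_k: int = 10,
    header_lines: Iterable[str] = (),
) -> None:
    """Write the top ``top_k`` candidates as a rank/microbe/score TSV.

    ``header_lines`` (e.g. a reproducibility header) are written first,
    each prefixed with ``#``.  Exactly ``min(top_k, n_candidates)`` data
    rows are emitted.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    rows = pred.candidates[:top_k]

    def _emit(fh: TextIO) -> None:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("rank\tmicrobe\tscore\n")
        for microbe, score, rank in rows:
            fh.write(f"{rank}\t{microbe}\t{score:.10g}\n")

    if hasattr(path, "write"):
        _emit(path)  # type: ignore[arg-type]
    else:
        with open(path, "w") as fh:
            _emit(fh)


def write_matrix_tsv(
    M: np.ndarray,
    row_labels: list[str],
    col_labels: list[str],
    path: str | os.PathLike | TextIO,
    index_label: str = "label",
) -> None:
    """Export a labeled matrix (similarity, score, network) as TSV."""
    df = pd.DataFrame(M, index=row_labels, columns=col_labels)
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path: str | os.PathLike) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(x) for x in df.index], [str(x) for x in df.columns]
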