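"""Readers/writers for the tab-delimited formats the pipeline touches.

Expression matrices are TSV: first column ``gene_id``, header row of subject
ids, one gene per row, numeric body. Subject metadata is CSV or TSV with
columns ``subject_id,group,age`` (delimiter sniffed). Values are assumed
already normalized and log2-scaled; raw-array normalization is out of scope.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    AlignmentError,
    ExpressionMatrix,
    FormatError,
    PairedDataset,
    SubjectTable,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_subject_table",
    "write_subject_table",
    "align_paired_dataset",
]

logger = logging.getLogger(__name__)


def read_expression_matrix(path, region_label: str = "") -> ExpressionMatrix:
    """Read a genes x subjects TSV into an :class:`ExpressionMatrix`.

    Row and column order are preserved exactly. Duplicate ids, missing cells
    and non-numeric cells are rejected with the offending coordinate named.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    gene_ids = raw.index.to_numpy(dtype=object)
    subj_ids = raw.columns.to_numpy(dtype=object)
    for ids, kind in ((gene_ids, "gene"), (subj_ids, "subject")):
        dup = pd.Index(ids)[pd.Index(ids).duplicated()]
        if len(dup):
            raise FormatError(f"{path}: duplicate {kind} id {dup[0]!r}")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (raw[col].str.strip() == "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric or missing cell at gene {gene_ids[i]!r}, "
                f"subject {col!r} (row {i + 2}, column {j + 2})"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    return ExpressionMatrix(gene_ids, subj_ids, values, region_label=region_label)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write TSV; floats use shortest round-tripping repr (lossless read-back)."""
    matrix.to_frame().to_csv(path, sep="\t")


def read_subject_table(path) -> SubjectTable:
    """Read subject metadata (``subject_id``, ``group``, ``age``) from CSV/TSV."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep)
    if frame.shape[1] == 1:  # wrong delimiter guess; sniff instead
        frame = pd.read_csv(path, sep=None, engine="python")
    try:
        return SubjectTable(frame)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from e


def write_subject_table(subjects: SubjectTable, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    subjects.table.to_csv(path, sep=sep, index=False)


def align_paired_dataset(
    a: ExpressionMatrix, b: ExpressionMatrix, meta: SubjectTable
) -> PairedDataset:
    """Pair two regional matrices on their shared subjects and genes.

    Both matrices are restricted to the intersection of subject ids and of
    gene ids and reordered identically (region A's order wins). Counts of
    dropped subjects/genes are logged. Aligning an already-aligned pair is a
    no-op.
    """
    shared_subj = [s for s in a.subject_ids if s in set(b.subject_ids)]
    shared_genes = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if len(shared_subj) < 3:
        raise AlignmentError(
            f"only {len(shared_subj)} shared subject(s) between "
            f"{a.region_label!r} ({a.n_subjects}) and {b.region_label!r} "
            f"({b.n_subjects}); need >= 3"
        )
    if len(shared_genes) < 1:
        raise AlignmentError("no shared gene ids between the two matrices")
    known = set(meta.table["subject_id"])
    missing = [s for s in shared_subj if s not in known]
    if missing:
        raise AlignmentError(f"metadata table missing subject(s): {missing[:5]}")
    dropped_subj = (a.n_subjects - len(shared_subj)) + (b.n_subjects - len(shared_subj))
    dropped_genes = (a.n_genes - len(shared_genes)) + (b.n_genes - len(shared_genes))
    if dropped_subj or dropped_genes:
        logger.info(
            "align_paired_dataset: dropped %d subject column(s) and %d gene "
            "row(s) outside the intersection", dropped_subj, dropped_genes,
        )
    a2 = a.subset_subjects(shared_subj).subset_genes(shared_genes)
    b2 = b.subset_subjects(shared_subj).subset_genes(shared_genes)
    return PairedDataset(a2, b2, meta)
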