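"""Core containers for paired-region expression data.

The unit of inference throughout the package is a :class:`PairedDataset`:
two expression matrices measured in distinct tissues (brain regions) of the
*same* subjects, with subject columns aligned so that column ``j`` of region
A and column ``j`` of region B come from one individual. All synchrony
statistics are per-gene correlations computed across that within-subject
pairing, so the containers enforce alignment and completeness up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SubjectTable",
    "PairedDataset",
    "AnalysisConfig",
    "FormatError",
    "ValidationError",
    "AlignmentError",
    "InferenceError",
    "ConfigError",
]


class FormatError(ValueError):
    """A file did not match the expected tabular layout."""


class ValidationError(ValueError):
    """A container invariant was violated."""


class AlignmentError(ValueError):
    """Two matrices could not be paired (insufficient shared ids)."""


class InferenceError(ValueError):
    """An inferential routine was called on an inadequate dataset."""


class ConfigError(ValueError):
    """An invalid configuration object."""


def _check_unique(ids: np.ndarray, kind: str) -> None:
    if len(ids) != len(set(ids)):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise ValidationError(f"duplicate {kind} id: {i!r}")
            seen.add(i)


@dataclass
class ExpressionMatrix:
    """A genes x subjects matrix of log2 expression intensities for one region.

    Parameters
    ----------
    gene_ids : array-like of str
        Row labels (probesets or genes), unique, order preserved.
    subject_ids : array-like of str
        Column labels, unique, order preserved.
    values : ndarray, shape (n_genes, n_subjects)
        Finite log2-scale intensities; missing values are rejected rather
        than imputed, because downstream correlations assume complete
        per-subject pairs.
    region_label : str
        Free-text tissue/region name (e.g. ``"amygdala"``).
    """

    gene_ids: np.ndarray
    subject_ids: np.ndarray
    values: np.ndarray
    region_label: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D genes x subjects array")
        if self.values.shape != (len(self.gene_ids), len(self.subject_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.subject_ids)} subjects"
            )
        if len(self.gene_ids) < 1:
            raise ValidationError("need at least 1 gene")
        if len(self.subject_ids) < 3:
            raise ValidationError("need at least 3 subjects")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.subject_ids, "subject")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"subject {self.subject_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.subject_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, region_label: str = "") -> "ExpressionMatrix":
        return cls(
            gene_ids=frame.index.to_numpy(dtype=object),
            subject_ids=frame.columns.to_numpy(dtype=object),
            values=frame.to_numpy(dtype=float),
            region_label=region_label,
        )

    def subset_subjects(self, subject_ids) -> "ExpressionMatrix":
        """Restrict (and reorder) to the given subject ids."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = np.array([pos[s] for s in subject_ids], dtype=int)
        return replace(
            self,
            subject_ids=np.asarray(list(subject_ids), dtype=object),
            values=self.values[:, idx],
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in gene_ids], dtype=int)
        return replace(
            self,
            gene_ids=np.asarray(list(gene_ids), dtype=object),
            values=self.values[idx, :],
        )


@dataclass
class SubjectTable:
    """Per-subject metadata: diagnosis group and age in years."""

    table: pd.DataFrame  # columns: subject_id, group, age

    REQUIRED = ("subject_id", "group", "age")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"subject table missing column(s): {missing}")
        t = self.table.loc[:, list(self.REQUIRED)].copy()
        t["subject_id"] = t["subject_id"].astype(str)
        t["group"] = t["group"].astype(str)
        t["age"] = pd.to_numeric(t["age"], errors="raise").astype(float)
        if t["subject_id"].duplicated().any():
            dup = t.loc[t["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValidationError(f"duplicate subject id: {dup!r}")
        if (t["age"] < 0).any():
            bad = t.loc[t["age"] < 0].iloc[0]
            raise ValidationError(
                f"negative age {bad['age']} for subject {bad['subject_id']!r}"
            )
        if not np.all(np.isfinite(t["age"].to_numpy())):
            raise ValidationError("non-finite age")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy(dtype=object)

    def ages_for(self, subject_ids) -> np.ndarray:
        """Ages aligned to the given subject order."""
        m = dict(zip(self.table["subject_id"], self.table["age"]))
        try:
            return np.array([m[s] for s in subject_ids], dtype=float)
        except KeyError as e:
            raise ValidationError(f"subject {e.args[0]!r} not in subject table") from e

    def groups_for(self, subject_ids) -> np.ndarray:
        m = dict(zip(self.table["subject_id"], self.table["group"]))
        try:
            return np.array([m[s] for s in subject_ids], dtype=object)
        except KeyError as e:
            raise ValidationError(f"subject {e.args[0]!r} not in subject table") from e

    def subset(self, subject_ids) -> "SubjectTable":
        t = self.table.set_index("subject_id").loc[list(subject_ids)].reset_index()
        return SubjectTable(t)


@dataclass
class PairedDataset:
    """Two subject-aligned expression matrices plus subject metadata.

    ``region_a`` and ``region_b`` must share identical gene order and
    identical subject order; scrambling that subject pairing is what defines
    the permutation null for synchrony.
    """

    region_a: ExpressionMatrix
    region_b: ExpressionMatrix
    subjects: SubjectTable

    def __post_init__(self) -> None:
        a, b = self.region_a, self.region_b
        if not np.array_equal(a.subject_ids, b.subject_ids):
            raise ValidationError("region_a and region_b subject orders differ")
        if not np.array_equal(a.gene_ids, b.gene_ids):
            raise ValidationError("region_a and region_b gene orders differ")
        known = set(self.subjects.table["subject_id"])
        missing = [s for s in a.subject_ids if s not in known]
        if missing:
            raise ValidationError(
                f"subject(s) absent from metadata table: {missing[:5]}"
            )

    @property
    def gene_ids(self) -> np.ndarray:
        return self.region_a.gene_ids

    @property
    def subject_ids(self) -> np.ndarray:
        return self.region_a.subject_ids

    @property
    def n_genes(self) -> int:
        return self.region_a.n_genes

    @property
    def n_subjects(self) -> int:
        return self.region_a.n_subjects

    @property
    def ages(self) -> np.ndarray:
        return self.subjects.ages_for(self.subject_ids)

    def subset_subjects(self, subject_ids) -> "PairedDataset":
        return PairedDataset(
            self.region_a.subset_subjects(subject_ids),
            self.region_b.subset_subjects(subject_ids),
            self.subjects,
        )

    def subset_genes(self, gene_ids) -> "PairedDataset":
        return PairedDataset(
            self.region_a.subset_genes(gene_ids),
            self.region_b.subset_genes(gene_ids),
            self.subjects,
        )


@dataclass
class AnalysisConfig:
    """Knobs shared by the inferential stages.

    Attributes
    ----------
    n_bootstrap : int
        Subject resamples per bootstrap distribution (default 20000; at
        least 100 whenever a p-value is reported from it).
    n_permutations : int
        Subject-linkage scrambles pooled into the permutation null.
    selection_cutoff : float
        |r| threshold for "high synchrony in at least one condition"
        gene selection (default 0.7).
    low_threshold : float
        |r| bound below which a gene counts as unsynchronized when
        classifying gains/losses (default 0.2).
    fdr_q : float
        Benjamini-Hochberg target false discovery rate.
    ci_level : float
        Percentile-bootstrap confidence level.
    rng_seed : int
        Seed for every stochastic stage; identical seeds reproduce results
        bitwise.
    detrend_age : bool
        If True, remove each gene's linear age trend inside every bootstrap
        resample before correlating.
    """

    n_bootstrap: int = 20000
    n_permutations: int = 100
    selection_cutoff: float = 0.7
    low_threshold: float = 0.2
    fdr_q: float = 0.2
    ci_level: float = 0.95
    rng_seed: int = 0
    detrend_age: bool = False

    def __post_init__(self) -> None:
        if self.n_bootstrap < 100:
            raise ConfigError("n_bootstrap must be >= 100 for any reported p-value")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be positive")
        if not (0 < self.selection_cutoff <= 1):
            raise ConfigError("selection_cutoff must be in (0, 1]")
        if not (self.low_threshold < self.selection_cutoff):
            raise ConfigError("low_threshold must be below selection_cutoff")
        if not (0 < self.fdr_q < 1):
            raise ConfigError("fdr_q must be in (0, 1)")
        if not (0 < self.ci_level < 1):
            raise ConfigError("ci_level must be in (0, 1)")
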