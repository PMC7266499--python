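"""Core in-memory containers for the CSF proteomics analysis pipeline.

The central object is the :class:`IntensityMatrix`: a proteins x samples
table of label-free protein-group intensities with explicit missingness
(DIA software reports an intensity only where a protein was confidently
quantified; absent values are informative, typically abundance-dependent).
Per-sample clinical and technical annotations live in :class:`SampleMeta`
records; :class:`StudyBundle` ties a matrix to its metadata and a cohort
partition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "ProteinRecord",
    "IntensityMatrix",
    "SampleMeta",
    "StudyBundle",
    "AnnotationCatalog",
]


class Scale(str, enum.Enum):
    """Scale of the intensity values: raw (linear) or log10-transformed."""

    LINEAR = "linear"
    LOG10 = "log10"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein group: lead accession, optional gene name and isoform tag.

    ``protein_id`` is the primary match key across tables; ``gene_name`` is
    a fallback key for external datasets that index by gene symbol. Two
    protein groups of the same gene (e.g. two PKM isoform groups) are
    distinguished by ``isoform_tag``.
    """

    protein_id: str
    gene_name: str = ""
    isoform_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")


@dataclass
class IntensityMatrix:
    """Proteins x samples intensity grid with explicit missing values.

    ``values`` is a float DataFrame indexed by protein_id with sample IDs as
    columns; missing entries are NaN. On the linear scale all present values
    must be strictly positive. Scale transitions happen only through
    :func:`csfpanel.qc.log10_transform`.
    """

    proteins: list[ProteinRecord]
    values: pd.DataFrame
    scale: Scale = Scale.LINEAR

    def __post_init__(self) -> None:
        ids = [p.protein_id for p in self.proteins]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate protein IDs: {dupes}")
        if list(self.values.index) != ids:
            raise ValueError("values index must match protein record order")
        if self.values.columns.duplicated().any():
            dupes = sorted(set(self.values.columns[self.values.columns.duplicated()]))
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if self.scale is Scale.LINEAR:
            vals = self.values.to_numpy(dtype=float)
            if np.any(vals[~np.isnan(vals)] <= 0):
                raise ValueError("linear-scale intensities must be > 0 where present")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "IntensityMatrix":
        """Column subset preserving protein order; unknown IDs raise KeyError."""
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing}")
        return replace(self, values=self.values.loc[:, sample_ids])

    def subset_proteins(self, protein_ids: Iterable[str]) -> "IntensityMatrix":
        keep = set(protein_ids)
        records = [p for p in self.proteins if p.protein_id in keep]
        unknown = keep - {p.protein_id for p in records}
        if unknown:
            raise KeyError(f"unknown protein IDs: {sorted(unknown)}")
        return replace(
            self,
            proteins=records,
            values=self.values.loc[[p.protein_id for p in records]],
        )


_VALID_SEX = {"male", "female"}


@dataclass
class SampleMeta:
    """Clinical and technical annotations for one CSF sample.

    ELISA concentrations (t-tau, p-tau181, Ab1-42, Ab1-40) are in ng/l; MMSE
    is the 0-30 cognitive score. ``control_override`` forces a non-AD label
    when the clinical chemistry needed by the biochemical classification is
    missing (young emergency-department controls without AD indication).
    """

    sample_id: str
    cohort: str
    group_label: str = ""
    plate_id: str | None = None
    prep_day: str | None = None
    age: float | None = None
    sex: str | None = None
    t_tau: float | None = None
    p_tau181: float | None = None
    ab42: float | None = None
    ab40: float | None = None
    mmse: int | None = None
    control_override: bool = False

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.sex is not None:
            sex = str(self.sex).lower()
            if sex not in _VALID_SEX:
                raise ValueError(
                    f"sample {self.sample_id}: sex must be male/female, got {self.sex!r}"
                )
            self.sex = sex
        for name in ("t_tau", "p_tau181", "ab42", "ab40"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"sample {self.sample_id}: {name} must be >= 0")
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise ValueError(f"sample {self.sample_id}: mmse must be in [0, 30]")


@dataclass
class StudyBundle:
    """An intensity matrix with per-sample metadata and cohort partition."""

    matrix: IntensityMatrix
    metadata: list[SampleMeta]
    cohort_partition: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        meta_ids = [m.sample_id for m in self.metadata]
        if len(set(meta_ids)) != len(meta_ids):
            raise ValueError("duplicate sample IDs in metadata")
        if set(meta_ids) != set(self.matrix.samples):
            raise ValueError("metadata samples must match matrix samples exactly")
        if not self.cohort_partition:
            self.cohort_partition = {}
            for m in self.metadata:
                self.cohort_partition.setdefault(m.cohort, []).append(m.sample_id)
        covered: list[str] = [s for ids in self.cohort_partition.values() for s in ids]
        if len(covered) != len(set(covered)) or set(covered) != set(meta_ids):
            raise ValueError("cohort partition must cover all samples disjointly")

    @property
    def cohorts(self) -> list[str]:
        return list(self.cohort_partition)

    def meta_by_id(self) -> dict[str, SampleMeta]:
        return {m.sample_id: m for m in self.metadata}

    def meta_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame indexed by sample_id (matrix order)."""
        df = pd.DataFrame([vars(m) for m in self.metadata]).set_index("sample_id")
        return df.loc[self.matrix.samples]

    def cohort_matrix(self, cohort: str) -> IntensityMatrix:
        if cohort not in self.cohort_partition:
            raise KeyError(f"unknown cohort {cohort!r}")
        order = [s for s in self.matrix.samples if s in set(self.cohort_partition[cohort])]
        return self.matrix.subset_samples(order)


@dataclass
class AnnotationCatalog:
    """Annotation terms (GO BP/CC, UniProt Keywords, ...) to member sets."""

    terms: dict[str, "AnnotationTerm"] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def filter_by_size(
        self, members_universe: set[str], size_min: int, size_max: int
    ) -> Mapping[str, set[str]]:
        """Terms restricted to a dataset universe, keeping sizes in [min, max]."""
        out: dict[str, set[str]] = {}
        for term in self:
            present = set(term.members) & members_universe
            if size_min <= len(present) <= size_max:
                out[term.term_id] = present
        return out


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    category: str = "other"
    description: str = ""
    members: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id}: member list must be non-empty")
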