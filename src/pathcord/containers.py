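"""Core in-memory containers shared across the pipeline.

An :class:`ExpressionDataset` holds a reporter-by-sample matrix of
log2-scale intensities together with the reporter-to-gene annotation and
the tumor/normal class label of each sample. Gene sets are plain ordered
collections of gene symbols; gene identity is the bare, case-sensitive
symbol string (no alias resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

TUMOR = "tumor"
NORMAL = "normal"
CLASS_LABELS = (TUMOR, NORMAL)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set: identifier, free-text description, member symbols.

    Members are ordered and unique; construction rejects duplicates so that
    dedup policy (keep first occurrence) stays in the I/O layer where the
    warning can name the file line.
    """

    id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("gene set id must be non-empty")
        if not self.members:
            raise ValueError(f"gene set {self.id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.id!r} has duplicate member symbols")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GeneSetCollection:
    """A list of gene sets with unique ids plus a provenance tag."""

    sets: tuple[GeneSet, ...]
    source_tag: str = ""

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene set ids: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sets]

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out.update(s.members)
        return out


@dataclass
class ExpressionDataset:
    """Reporter x sample log2-intensity matrix with class labels.

    ``gene_symbols`` is parallel to ``reporter_ids`` (many reporters may
    annotate to one gene). ``class_labels`` holds ``"tumor"``/``"normal"``
    per sample. Matrices with non-finite entries are rejected: the pipeline
    has no missing-data rule.
    """

    reporter_ids: list[str]
    gene_symbols: list[str]
    values: np.ndarray
    sample_ids: list[str]
    class_labels: list[str]
    platform: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D reporter x sample matrix")
        n_rep, n_smp = self.values.shape
        if len(self.reporter_ids) != n_rep:
            raise ValueError("reporter_ids length does not match matrix rows")
        if len(self.gene_symbols) != n_rep:
            raise ValueError("gene_symbols length does not match matrix rows")
        if len(self.sample_ids) != n_smp:
            raise ValueError("sample_ids length does not match matrix columns")
        if len(self.class_labels) != n_smp:
            raise ValueError("class_labels length does not match matrix columns")
        if len(set(self.reporter_ids)) != n_rep:
            raise ValueError("duplicate reporter ids")
        if len(set(self.sample_ids)) != n_smp:
            raise ValueError("duplicate sample ids")
        bad = set(self.class_labels) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at reporter {self.reporter_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )

    @property
    def n_reporters(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def tumor_mask(self) -> np.ndarray:
        return np.array([c == TUMOR for c in self.class_labels], dtype=bool)

    def require_two_classes(self) -> None:
        mask = self.tumor_mask
        if not mask.any() or mask.all():
            raise ValueError("analysis requires at least one tumor and one normal sample")

    def subset_reporters(self, keep: Sequence[int]) -> "ExpressionDataset":
        keep = list(keep)
        return replace(
            self,
            reporter_ids=[self.reporter_ids[i] for i in keep],
            gene_symbols=[self.gene_symbols[i] for i in keep],
            values=self.values[keep, :] if keep else self.values[:0, :],
        )

    def genes(self) -> set[str]:
        return set(self.gene_symbols)


@dataclass
class ClinicalTable:
    """Per-tumor-sample categorical covariates (MSI status, mutations, stage, ...)."""

    sample_ids: list[str]
    covariates: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids in clinical table")
        for name, col in self.covariates.items():
            if len(col) != n:
                raise ValueError(f"covariate {name!r} length does not match samples")

    def levels(self, covariate: str) -> list[str]:
        seen: list[str] = []
        for v in self.covariates[covariate]:
            if v not in seen:
                seen.append(v)
        return seen
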