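"""Readers and writers for the pipeline's plain-text formats.

* GMT — the Broad/MSigDB tab-separated gene-set convention:
  ``id<TAB>description<TAB>gene1<TAB>gene2...`` (3+ fields per line).
* Expression TSV — first column reporter id, second gene symbol, remaining
  columns samples. A ``#class`` row under the header gives the tumor/normal
  label of each sample; an optional leading ``#platform`` line names the
  platform.
* Clinical TSV — sample id plus one column per covariate.
* qMSP TSV — sample_id, role, target_qty, ref_qty.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np

from .containers import (
    CLASS_LABELS,
    ClinicalTable,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; message carries file coordinates."""


# ---------------------------------------------------------------- GMT

def read_gmt(path: str | Path, source_tag: str = "") -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Duplicate symbols within one set are removed keeping the first
    occurrence, with a logged warning; duplicate set ids are an error.
    """
    sets: list[GeneSet] = []
    seen_ids: set[str] = set()
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            set_id, description, *genes = fields
            if set_id in seen_ids:
                raise ParseError(f"{path}:{lineno}: duplicate gene set id {set_id!r}")
            seen_ids.add(set_id)
            members: list[str] = []
            for g in genes:
                if g in members:
                    logger.warning(
                        "%s:%d: duplicate symbol %r in set %r dropped",
                        path, lineno, g, set_id,
                    )
                else:
                    members.append(g)
            sets.append(GeneSet(set_id, description, tuple(members)))
    return GeneSetCollection(tuple(sets), source_tag=source_tag or str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        for s in collection:
            fh.write("\t".join([s.id, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------- expression TSV

_CLASS_ROW = "#class"
_PLATFORM_ROW = "#platform"


def read_expression(path: str | Path) -> ExpressionDataset:
    """Read an expression TSV; non-numeric cells raise with coordinates."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ParseError(f"{path}: empty file")
    idx = 0
    platform = ""
    if rows[0] and rows[0][0] == _PLATFORM_ROW:
        platform = rows[0][1] if len(rows[0]) > 1 else ""
        idx = 1
    if idx >= len(rows) or len(rows[idx]) < 3:
        raise ParseError(f"{path}: header row must have reporter, gene and sample columns")
    header = rows[idx]
    sample_ids = header[2:]
    idx += 1
    if idx >= len(rows) or rows[idx][0] != _CLASS_ROW:
        raise ParseError(f"{path}: missing '#class' row after the header")
    class_row = rows[idx]
    labels = class_row[2:]
    if len(labels) != len(sample_ids):
        raise ParseError(f"{path}: '#class' row has {len(labels)} labels for "
                         f"{len(sample_ids)} samples")
    for lab in labels:
        if lab not in CLASS_LABELS:
            raise ParseError(f"{path}: unknown class label {lab!r}")
    reporter_ids: list[str] = []
    gene_symbols: list[str] = []
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[idx + 1:], start=idx + 2):
        if not row or (len(row) == 1 and not row[0]):
            continue
        if len(row) != len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
        reporter_ids.append(row[0])
        gene_symbols.append(row[1])
        vals = []
        for col, cell in enumerate(row[2:]):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column "
                    f"{sample_ids[col]!r}"
                ) from None
        data.append(vals)
    values = np.array(data, dtype=float) if data else np.empty((0, len(sample_ids)))
    return ExpressionDataset(
        reporter_ids=reporter_ids,
        gene_symbols=gene_symbols,
        values=values,
        sample_ids=sample_ids,
        class_labels=list(labels),
        platform=platform,
    )


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        if dataset.platform:
            fh.write(f"{_PLATFORM_ROW}\t{dataset.platform}\n")
        fh.write("\t".join(["reporter_id", "gene_symbol", *dataset.sample_ids]) + "\n")
        fh.write("\t".join([_CLASS_ROW, "", *dataset.class_labels]) + "\n")
        for i, rid in enumerate(dataset.reporter_ids):
            row = [rid, dataset.gene_symbols[i]]
            row += [repr(float(v)) for v in dataset.values[i]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------- clinical TSV

def read_clinical(path: str | Path) -> ClinicalTable:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ParseError(f"{path}: empty clinical table")
    header = rows[0]
    if not header or header[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id'")
    names = header[1:]
    sample_ids: list[str] = []
    cols: dict[str, list[str]] = {n: [] for n in names}
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} fields")
        sample_ids.append(row[0])
        for n, v in zip(names, row[1:]):
            cols[n].append(v)
    return ClinicalTable(sample_ids=sample_ids, covariates=cols)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    names = list(table.covariates)
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(["sample_id", *names]) + "\n")
        for i, sid in enumerate(table.sample_ids):
            fh.write("\t".join([sid, *(table.covariates[n][i] for n in names)]) + "\n")
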