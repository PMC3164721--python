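"""Gene and pathway admission filters applied before set-level testing.

Four stages, in fixed order:

1. interquartile-range filter — reporters with IQR strictly below
   ``iqr_min`` (default 0.5 log2 units) are excluded; IQR exactly at the
   threshold is retained;
2. probe-to-gene collapse — for genes measured by several reporters, the
   reporter with the largest IQR represents the gene (ties broken by the
   lexicographically smallest reporter id, for determinism);
3. annotation restriction — genes belonging to no set in the collection
   are dropped;
4. small-set pruning — sets with strictly fewer than ``min_set_size``
   measured member genes (default 10) are dropped, and surviving sets keep
   only their measured members.

IQR uses linear interpolation between order statistics (the default
quantile convention of mainstream numeric stacks), identically in the
filter and the collapse so the two stages agree on "variability".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import AnalysisConfig
from .containers import ExpressionDataset, GeneSet, GeneSetCollection


@dataclass
class FilterReport:
    """Per-stage accounting of what the admission filters removed."""

    n_reporters_in: int = 0
    n_removed_iqr: int = 0
    n_collapsed: int = 0
    n_removed_unannotated: int = 0
    n_genes_out: int = 0
    n_sets_in: int = 0
    n_sets_removed_small: int = 0
    n_sets_out: int = 0

    def check(self) -> None:
        vals = [
            self.n_reporters_in, self.n_removed_iqr, self.n_collapsed,
            self.n_removed_unannotated, self.n_genes_out,
            self.n_sets_in, self.n_sets_removed_small, self.n_sets_out,
        ]
        if any(v < 0 for v in vals):
            raise ValueError("negative count in filter report")
        genes_after_collapse = self.n_reporters_in - self.n_removed_iqr - self.n_collapsed
        if genes_after_collapse - self.n_removed_unannotated != self.n_genes_out:
            raise ValueError("filter report gene counts do not reconcile")
        if self.n_sets_in - self.n_sets_removed_small != self.n_sets_out:
            raise ValueError("filter report set counts do not reconcile")


def compute_iqr(values: np.ndarray) -> float:
    """Q3 - Q1 of a vector of log intensities (linear-interpolation quantiles)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute IQR of an empty vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("IQR input contains non-finite values")
    q1, q3 = np.percentile(values, [25.0, 75.0])
    return float(q3 - q1)


def _row_iqrs(dataset: ExpressionDataset) -> np.ndarray:
    if dataset.n_reporters == 0:
        return np.empty(0)
    q1, q3 = np.percentile(dataset.values, [25.0, 75.0], axis=1)
    return q3 - q1


def filter_low_variability(
    dataset: ExpressionDataset, config: AnalysisConfig
) -> tuple[ExpressionDataset, list[str]]:
    """Drop reporters with IQR strictly below ``config.iqr_min``.

    Returns the filtered dataset and the list of removed reporter ids.
    """
    iqrs = _row_iqrs(dataset)
    keep = [i for i in range(dataset.n_reporters) if iqrs[i] >= config.iqr_min]
    removed = [dataset.reporter_ids[i] for i in range(dataset.n_reporters)
               if iqrs[i] < config.iqr_min]
    return dataset.subset_reporters(keep), removed


def collapse_to_genes(dataset: ExpressionDataset) -> ExpressionDataset:
    """One row per gene: the member reporter with maximal IQR survives."""
    iqrs = _row_iqrs(dataset)
    best: dict[str, int] = {}
    for i, gene in enumerate(dataset.gene_symbols):
        j = best.get(gene)
        if j is None:
            best[gene] = i
        elif iqrs[i] > iqrs[j] or (
            iqrs[i] == iqrs[j] and dataset.reporter_ids[i] < dataset.reporter_ids[j]
        ):
            best[gene] = i
    keep = sorted(best.values())
    return dataset.subset_reporters(keep)


def restrict_to_annotated(
    dataset: ExpressionDataset, collection: GeneSetCollection
) -> ExpressionDataset:
    """Drop rows whose gene symbol appears in no set of the collection."""
    universe = collection.gene_universe()
    keep = [i for i, g in enumerate(dataset.gene_symbols) if g in universe]
    return dataset.subset_reporters(keep)


def prune_small_sets(
    collection: GeneSetCollection, dataset: ExpressionDataset, config: AnalysisConfig
) -> GeneSetCollection:
    """Drop sets with fewer than ``min_set_size`` measured genes; restrict
    surviving sets to their measured members (order preserved)."""
    measured = dataset.genes()
    kept: list[GeneSet] = []
    for s in collection:
        members = tuple(g for g in s.members if g in measured)
        if len(members) >= config.min_set_size:
            kept.append(GeneSet(s.id, s.description, members))
    return GeneSetCollection(tuple(kept), source_tag=collection.source_tag)


def preprocess(
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    config: AnalysisConfig | None = None,
) -> tuple[ExpressionDataset, GeneSetCollection, FilterReport]:
    """Run the full admission pipeline; returns the gene-level dataset, the
    pruned collection, and a :class:`FilterReport` reconciling the counts."""
    config = config or AnalysisConfig()
    report = FilterReport(
        n_reporters_in=dataset.n_reporters, n_sets_in=len(collection)
    )
    if config.collapse_before_filter:
        collapsed = collapse_to_genes(dataset)
        report.n_collapsed = dataset.n_reporters - collapsed.n_reporters
        filtered, removed = filter_low_variability(collapsed, config)
        report.n_removed_iqr = len(removed)
    else:
        filtered0, removed = filter_low_variability(dataset, config)
        report.n_removed_iqr = len(removed)
        filtered = collapse_to_genes(filtered0)
        report.n_collapsed = filtered0.n_reporters - filtered.n_reporters
    annotated = restrict_to_annotated(filtered, collection)
    report.n_removed_unannotated = filtered.n_reporters - annotated.n_reporters
    report.n_genes_out = annotated.n_reporters
    pruned = prune_small_sets(collection, annotated, config)
    report.n_sets_removed_small = len(collection) - len(pruned)
    report.n_sets_out = len(pruned)
    report.check()
    return annotated, pruned, report
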