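"""Two-dataset concordance of enrichment results.

A pathway (or gene) significant at P <= alpha in both independently
analyzed datasets, with the same direction of change, is called
*concordant*; same significance but opposite directions is *opposite*;
significance in exactly one dataset is *single-A*/*single-B*; otherwise
*neither*. Items absent from one platform's measured universe are flagged
unmeasured for it. Under independence of the two cohorts, a null item is
significant in both merely by chance with probability alpha^2 — 1/400 at
alpha = 0.05 — which is the study's argument for not applying a further
multiplicity correction to the intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .enrichment import GeneStat, PathwayResult

CATEGORIES = (
    "concordant-up",
    "concordant-down",
    "opposite",
    "single-A",
    "single-B",
    "neither",
    "unmeasured-A",
    "unmeasured-B",
)


@dataclass
class ConsensusRecord:
    """Concordance classification of one pathway or gene across two datasets."""

    item_id: str
    category: str
    p_a: float | None = None
    p_b: float | None = None
    direction_a: str | None = None
    direction_b: str | None = None
    lfc_a: float | None = None
    lfc_b: float | None = None


@dataclass
class VennSummary:
    """Category counts of a consensus run plus the joint chance risk."""

    counts: dict[str, int]
    alpha: float
    joint_risk: float
    n_items: int = 0


def joint_chance_risk(alpha: float, k_datasets: int = 2) -> float:
    """Probability that a null item is significant in all k independent
    datasets: alpha**k (1/400 for alpha=0.05, k=2)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k_datasets < 1 or int(k_datasets) != k_datasets:
        raise ValueError("k_datasets must be a positive integer")
    # power through the exact decimal value of alpha, so e.g. 0.05**2 comes
    # out as exactly 0.0025 rather than one ulp off
    return float(Fraction(str(alpha)) ** int(k_datasets))


def classify_item(
    p_a: float | None,
    dir_a: str | None,
    p_b: float | None,
    dir_b: str | None,
    alpha: float = 0.05,
) -> str:
    """Apply the concordance rule table to one item.

    ``p_x is None`` means the item was not measured in dataset x.
    Significance is inclusive (p <= alpha). A significant result with
    direction "none" is contradictory input and raises.
    """
    if p_a is None and p_b is None:
        raise ValueError("item measured in neither dataset")
    for p, d, name in ((p_a, dir_a, "A"), (p_b, dir_b, "B")):
        if p is None:
            continue
        if not 0 <= p <= 1:
            raise ValueError(f"p_{name.lower()}={p} outside [0, 1]")
        if d not in ("up", "down", "none"):
            raise ValueError(f"direction_{name.lower()} must be up/down/none")
        if p <= alpha and d == "none":
            raise ValueError(f"dataset {name}: significant p with direction 'none'")
    if p_a is None:
        return "unmeasured-A"
    if p_b is None:
        return "unmeasured-B"
    sig_a = p_a <= alpha
    sig_b = p_b <= alpha
    if sig_a and sig_b:
        if dir_a == dir_b:
            return f"concordant-{dir_a}"
        return "opposite"
    if sig_a:
        return "single-A"
    if sig_b:
        return "single-B"
    return "neither"


def compare_pathways(
    results_a: list[PathwayResult],
    results_b: list[PathwayResult],
    alpha: float = 0.05,
) -> list[ConsensusRecord]:
    """Classify every pathway measured in at least one dataset."""
    by_a = {r.set_id: r for r in results_a}
    by_b = {r.set_id: r for r in results_b}
    records: list[ConsensusRecord] = []
    for set_id in sorted(set(by_a) | set(by_b)):
        a, b = by_a.get(set_id), by_b.get(set_id)
        cat = classify_item(
            a.p if a else None, a.direction if a else None,
            b.p if b else None, b.direction if b else None,
            alpha,
        )
        records.append(ConsensusRecord(
            item_id=set_id, category=cat,
            p_a=a.p if a else None, p_b=b.p if b else None,
            direction_a=a.direction if a else None,
            direction_b=b.direction if b else None,
        ))
    return records


def summarize(records: list[ConsensusRecord], alpha: float = 0.05) -> VennSummary:
    """Category counts for a consensus run; counts sum to the number of
    items measured in at least one dataset."""
    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        counts[r.category] += 1
    return VennSummary(
        counts=counts,
        alpha=alpha,
        joint_risk=joint_chance_risk(alpha, 2),
        n_items=len(records),
    )


def gene_concordance_table(
    gene_stats_a: list[GeneStat],
    gene_stats_b: list[GeneStat],
    gene_set_members: list[str],
    alpha: float = 0.05,
) -> list[ConsensusRecord]:
    """Per-gene concordance records for one pathway's members.

    Mirrors the published per-pathway gene tables: P-value and log fold
    change per dataset, a partition into both/one/neither dataset
    significance, and unmeasured flags for genes absent from a platform.
    Genes measured in neither dataset are omitted.
    """
    by_a = {g.gene: g for g in gene_stats_a}
    by_b = {g.gene: g for g in gene_stats_b}
    records: list[ConsensusRecord] = []
    for gene in gene_set_members:
        a, b = by_a.get(gene), by_b.get(gene)
        if a is None and b is None:
            continue
        cat = classify_item(
            a.p if a else None, a.direction if a else None,
            b.p if b else None, b.direction if b else None,
            alpha,
        )
        records.append(ConsensusRecord(
            item_id=gene, category=cat,
            p_a=a.p if a else None, p_b=b.p if b else None,
            direction_a=a.direction if a else None,
            direction_b=b.direction if b else None,
            lfc_a=a.lfc if a else None, lfc_b=b.lfc if b else None,
        ))
    return records
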