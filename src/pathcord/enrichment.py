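"""Per-gene differential statistics and the set-level enrichment test.

Per gene, a classical two-sided, two-class pooled-variance t-test compares
tumor against normal samples. For each gene set the enrichment score is

    Z = sum(t_g for g in set) / sqrt(n)

where n is the number of measured member genes: positive Z means the set
is coordinately upregulated in tumors. Under independence of genes and an
approximately standard-normal null for each t, Z is approximately standard
normal, which gives the default analytic set P-value. The rigorous
alternative permutes sample class labels, recomputing every per-gene t and
set score per permutation; when the number of distinct label assignments is
small enough the permutation null is enumerated exhaustively and the
P-value is exact.

Known weakness, by construction: the normal reference assumes independent
genes and ignores the heavier-than-normal tails of t (variance
df/(df-2) > 1), so analytic P-values are slightly anticonservative for
small df and correlated sets. The permutation method has neither problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .containers import ExpressionDataset, GeneSetCollection


@dataclass
class GeneStat:
    """Per-gene two-class statistics (tumor minus normal)."""

    gene: str
    t: float
    p: float
    lfc: float
    direction: str  # "up" | "down" | "none"
    zero_variance: bool = False


@dataclass
class PathwayResult:
    """Set-level enrichment result for one dataset."""

    set_id: str
    n_genes: int
    score: float
    p: float
    direction: str  # "up" | "down" | "none"


def _direction(x: float) -> str:
    if x > 0:
        return "up"
    if x < 0:
        return "down"
    return "none"


def two_class_ttest(tumor: np.ndarray, normal: np.ndarray) -> tuple[float, float, bool]:
    """Pooled-variance two-sample t; returns (t, two-sided p, zero_variance).

    Degenerate zero-pooled-variance inputs: equal means give (0, 1), unequal
    means give (+/-inf, 0); both set the zero-variance flag.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    n1, n2 = tumor.size, normal.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    ss = np.sum((tumor - tumor.mean()) ** 2) + np.sum((normal - normal.mean()) ** 2)
    if ss == 0.0:
        diff = tumor.mean() - normal.mean()
        if diff == 0.0:
            return 0.0, 1.0, True
        return math.copysign(math.inf, diff), 0.0, True
    t, p = stats.ttest_ind(tumor, normal, equal_var=True)
    return float(t), float(p), False


def log_fold_change(tumor: np.ndarray, normal: np.ndarray) -> float:
    """Difference of group means on the (already log2) intensity scale."""
    return float(np.mean(tumor) - np.mean(normal))


def enrichment_score(t_values: np.ndarray) -> float:
    """Sum of the set's t-statistics divided by sqrt(set size)."""
    t_values = np.asarray(t_values, dtype=float)
    if t_values.size == 0:
        raise ValueError("enrichment score of an empty set is undefined")
    if not np.all(np.isfinite(t_values)):
        raise ValueError("non-finite t-statistic in set")
    return float(t_values.sum() / math.sqrt(t_values.size))


# ---------------------------------------------------------------- vectorised t

def _t_matrix(values: np.ndarray, tumor_masks: np.ndarray) -> np.ndarray:
    """t-statistics for every gene under every label assignment.

    values: (n_genes, n_samples); tumor_masks: (n_assign, n_samples) boolean
    with a constant row sum. Returns (n_genes, n_assign). Zero-pooled-variance
    cells resolve to 0 (equal means) or +/-inf.
    """
    values = np.asarray(values, dtype=float)
    g = np.asarray(tumor_masks, dtype=float)
    n = values.shape[1]
    n1 = int(g[0].sum())
    n2 = n - n1
    if n1 < 2 or n2 < 2 or n - 2 < 1:
        raise ValueError("degenerate class sizes for the t-test")
    s_tot = values.sum(axis=1, keepdims=True)
    q_tot = (values ** 2).sum(axis=1, keepdims=True)
    s1 = values @ g.T
    q1 = (values ** 2) @ g.T
    m1 = s1 / n1
    m2 = (s_tot - s1) / n2
    ss1 = q1 - n1 * m1 ** 2
    ss2 = (q_tot - q1) - n2 * m2 ** 2
    sp2 = (ss1 + ss2) / (n - 2)
    sp2 = np.maximum(sp2, 0.0)  # guard tiny negative rounding
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t = np.where(denom == 0.0, np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf), t)
    return t


def _null_assignments(
    n_samples: int, n_tumor: int, config: AnalysisConfig
) -> tuple[np.ndarray, bool]:
    """Label assignments for the permutation null.

    Exhaustive enumeration of all C(n, n_tumor) tumor-label placements when
    that count does not exceed ``n_permutations``; otherwise
    ``n_permutations`` seeded random permutations. Returns (masks, exact).
    """
    total = math.comb(n_samples, n_tumor)
    if total <= config.n_permutations:
        masks = np.zeros((total, n_samples), dtype=bool)
        for i, idx in enumerate(combinations(range(n_samples), n_tumor)):
            masks[i, list(idx)] = True
        return masks, True
    rng = np.random.default_rng(config.seed)
    masks = np.zeros((config.n_permutations, n_samples), dtype=bool)
    for i in range(config.n_permutations):
        masks[i, rng.choice(n_samples, size=n_tumor, replace=False)] = True
    return masks, False


#: absolute slack when comparing permutation-null scores to the observed
#: score, so the observed assignment always counts as its own hit despite
#: float rounding between the scalar and vectorised t routines
_TIE_TOL = 1e-9


def set_pvalue(
    score: float,
    t_values: np.ndarray,
    dataset: ExpressionDataset | None,
    gene_set_members: list[str] | None,
    config: AnalysisConfig,
) -> float:
    """Two-sided set P-value for one enrichment score.

    method="normal": standard-normal tail of |score|. method="permutation":
    class labels permuted with per-gene t and score recomputed each time;
    exact when the assignments are enumerable, else Monte Carlo with the
    +1 rule p = (1 + #{|Z*| >= |Z|}) / (n_perm + 1).
    """
    if config.set_pvalue_method == "normal":
        return float(2.0 * stats.norm.sf(abs(score)))
    if dataset is None or gene_set_members is None:
        raise ValueError("permutation method needs the dataset and set members")
    gene_index = {g: i for i, g in enumerate(dataset.gene_symbols)}
    rows = [gene_index[g] for g in gene_set_members if g in gene_index]
    if not rows:
        raise ValueError("no set member measured in the dataset")
    sub = dataset.values[rows, :]
    masks, exact = _null_assignments(
        dataset.n_samples, int(dataset.tumor_mask.sum()), config
    )
    t_null = _t_matrix(sub, masks)
    scores = t_null.sum(axis=0) / math.sqrt(len(rows))
    hits = int(np.sum(np.abs(scores) >= abs(score) - _TIE_TOL))
    if exact:
        return float(hits / scores.size)
    return float((1 + hits) / (masks.shape[0] + 1))


def run_enrichment(
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    config: AnalysisConfig | None = None,
) -> tuple[list[GeneStat], list[PathwayResult]]:
    """Per-gene t-tests and one enrichment result per set, for one dataset.

    Inputs are expected preprocessed (gene-level rows, pruned sets); sets
    are scored on their measured members. Deterministic given config.seed.
    """
    config = config or AnalysisConfig()
    dataset.require_two_classes()
    mask = dataset.tumor_mask
    tumor = dataset.values[:, mask]
    normal = dataset.values[:, ~mask]

    gene_stats: list[GeneStat] = []
    t_by_gene: dict[str, float] = {}
    for i, gene in enumerate(dataset.gene_symbols):
        t, p, zv = two_class_ttest(tumor[i], normal[i])
        lfc = log_fold_change(tumor[i], normal[i])
        gene_stats.append(GeneStat(gene, t, p, lfc, _direction(t), zv))
        t_by_gene[gene] = t

    # permutation null shared across sets: one t matrix, set scores read off it
    null_scores_by_set: dict[str, np.ndarray] = {}
    exact = False
    if config.set_pvalue_method == "permutation":
        masks, exact = _null_assignments(
            dataset.n_samples, int(mask.sum()), config
        )
        t_null = _t_matrix(dataset.values, masks)
        gene_index = {g: i for i, g in enumerate(dataset.gene_symbols)}
        for s in collection:
            rows = [gene_index[g] for g in s.members if g in gene_index]
            if rows:
                null_scores_by_set[s.id] = (
                    t_null[rows, :].sum(axis=0) / math.sqrt(len(rows))
                )

    results: list[PathwayResult] = []
    for s in collection:
        ts = np.array([t_by_gene[g] for g in s.members if g in t_by_gene])
        if ts.size == 0:
            continue
        z = enrichment_score(ts)
        if config.set_pvalue_method == "normal":
            p = float(2.0 * stats.norm.sf(abs(z)))
        else:
            null = null_scores_by_set[s.id]
            hits = int(np.sum(np.abs(null) >= abs(z) - _TIE_TOL))
            p = hits / null.size if exact else (1 + hits) / (null.size + 1)
        results.append(PathwayResult(s.id, int(ts.size), z, p, _direction(z)))
    return gene_stats, results
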