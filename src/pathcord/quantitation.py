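"""Validation-arm quantitation: qRT-PCR normalization, qMSP PMR scoring,
and rank-based association tests.

qRT-PCR quantities are interpolated from a standard curve (least-squares
line of Ct against log10 quantity of a serial dilution), triplicates are
aggregated by their median, and target expression is normalized against
the mean of the endogenous-control medians.

qMSP methylation level is the Percent of Methylated Reference:

    PMR = 100 * (target/ALU)_sample / (target/ALU)_positive control

where the ALU repeat assay normalizes for DNA input and the positive
control is fully methylated DNA. A sample is called methylated when its
PMR strictly exceeds the highest PMR observed in the normal-mucosa panel
(floor 0, so with clean normals the rule reduces to PMR > 0).

Associations between expression and categorical clinicopathological
covariates use the Mann-Whitney-Wilcoxon rank-sum test (two groups; exact
enumeration for small tie-free samples) or the Kruskal-Wallis test (more
than two groups), two-sided, uncorrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from statistics import median

import numpy as np
from scipy import stats

from .containers import ClinicalTable

logger = logging.getLogger(__name__)


@dataclass
class QpcrMeasurement:
    """One assay on one sample: up to 3 standard-curve-interpolated replicate quantities."""

    sample_id: str
    assay: str
    quantities: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.quantities:
            raise ValueError("at least one replicate quantity required")
        if any(q < 0 for q in self.quantities):
            raise ValueError("replicate quantities must be >= 0")

    @property
    def median_quantity(self) -> float:
        return float(median(self.quantities))


@dataclass
class QmspMeasurement:
    """One qMSP record: methylation-specific target and ALU reference quantities."""

    sample_id: str
    role: str  # "sample" | "positive-control" | "normal"
    target_qty: float
    ref_qty: float

    def __post_init__(self) -> None:
        if self.role not in ("sample", "positive-control", "normal"):
            raise ValueError(f"unknown qMSP role {self.role!r}")
        if self.target_qty < 0:
            raise ValueError("target quantity must be >= 0")
        if self.ref_qty <= 0:
            raise ValueError("ALU reference quantity must be > 0 for analyzable records")


@dataclass
class PmrResult:
    sample_id: str
    pmr: float
    methylated: bool


@dataclass
class AssociationResult:
    covariate: str
    test: str  # "MWW" | "Kruskal-Wallis"
    p: float
    group_sizes: tuple[int, ...]


# ---------------------------------------------------------------- qRT-PCR

def standard_curve_quantify(
    ct_values: float | np.ndarray,
    curve_points: list[tuple[float, float]],
) -> float | np.ndarray:
    """Interpolate quantities from Ct values via a standard curve.

    ``curve_points`` are (quantity, Ct) pairs from a serial dilution; the
    least-squares line Ct = a + b*log10(q) is inverted to
    q = 10**((Ct - a)/b). Raises on a flat curve (|b| ~ 0).
    """
    if len(curve_points) < 2:
        raise ValueError("standard curve needs at least 2 points")
    q = np.array([p[0] for p in curve_points], dtype=float)
    ct = np.array([p[1] for p in curve_points], dtype=float)
    if np.any(q <= 0):
        raise ValueError("curve quantities must be > 0")
    logq = np.log10(q)
    if np.unique(logq).size < 2:
        raise ValueError("standard curve needs at least 2 distinct quantities")
    b, a = np.polyfit(logq, ct, 1)
    if abs(b) < 1e-12:
        raise ValueError("flat standard curve: slope indistinguishable from 0")
    ct_values = np.asarray(ct_values, dtype=float)
    out = 10.0 ** ((ct_values - a) / b)
    return float(out) if out.ndim == 0 else out


def normalize_expression(
    target: QpcrMeasurement, controls: list[QpcrMeasurement]
) -> float:
    """Median target quantity divided by the mean of the endogenous-control
    median quantities."""
    if not controls:
        raise ValueError("at least one endogenous control required")
    denom = float(np.mean([c.median_quantity for c in controls]))
    if denom == 0.0:
        raise ValueError("endogenous-control mean quantity is 0")
    return target.median_quantity / denom


# ---------------------------------------------------------------- qMSP / PMR

def pmr(sample: QmspMeasurement, positive_control: QmspMeasurement) -> float:
    """Percent of Methylated Reference of one sample."""
    if positive_control.target_qty <= 0:
        raise ValueError("positive control must have target quantity > 0")
    sample_ratio = sample.target_qty / sample.ref_qty
    control_ratio = positive_control.target_qty / positive_control.ref_qty
    return 100.0 * sample_ratio / control_ratio


def call_methylation(pmr_value: float, normal_panel_pmrs: list[float]) -> bool:
    """Methylated iff the PMR strictly exceeds the normal-panel maximum
    (threshold floored at 0; an empty panel gives threshold 0)."""
    if pmr_value < 0:
        raise ValueError("PMR cannot be negative")
    threshold = max([0.0, *normal_panel_pmrs])
    return pmr_value > threshold


def score_qmsp_panel(measurements: list[QmspMeasurement]) -> list[PmrResult]:
    """PMR and methylation call for every non-control record of a panel.

    The panel must contain exactly one positive-control record; records
    with role "normal" define the calling threshold.
    """
    controls = [m for m in measurements if m.role == "positive-control"]
    if len(controls) != 1:
        raise ValueError(f"expected exactly 1 positive control, found {len(controls)}")
    control = controls[0]
    normal_pmrs = [pmr(m, control) for m in measurements if m.role == "normal"]
    results = []
    for m in measurements:
        if m.role == "positive-control":
            continue
        value = pmr(m, control)
        results.append(PmrResult(m.sample_id, value, call_methylation(value, normal_pmrs)))
    return results


# ---------------------------------------------------------------- rank tests

#: largest per-group size for which the tie-free MWW null is enumerated exactly
_MWW_EXACT_MAX_N = 8


def _mww_exact_p(group1: np.ndarray, group2: np.ndarray) -> float:
    """Exact two-sided MWW P by enumerating all rank-sum placements.

    Two-sided P doubles the smaller one-sided tail of the group-1 rank sum
    and caps at 1.
    """
    pooled = np.concatenate([group1, group2])
    ranks = stats.rankdata(pooled)  # midranks; with ties this is the exact conditional test
    n1 = group1.size
    w_obs = ranks[:n1].sum()
    sums = [sum(c) for c in combinations(ranks, n1)]
    total = len(sums)
    lo = sum(1 for s in sums if s <= w_obs + 1e-9)
    hi = sum(1 for s in sums if s >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi) / total)


def mww_test(group1, group2) -> float:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum P-value.

    Exact enumeration of the rank-sum null when both groups have <= 8
    observations (midranks make this the exact conditional test when ties
    are present); tie-corrected normal approximation for larger groups.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    if g1.size <= _MWW_EXACT_MAX_N and g2.size <= _MWW_EXACT_MAX_N:
        return _mww_exact_p(g1, g2)
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def kruskal_wallis_test(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square (k-1 df) P-value.

    All-identical observations are degenerate: H = 0 and P reported as 1.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def association_screen(
    expression: dict[str, float], clinical: ClinicalTable
) -> list[AssociationResult]:
    """Test one gene's per-sample expression against every covariate.

    Binary covariates go to the MWW test, covariates with more than two
    observed levels to Kruskal-Wallis; covariates with a single observed
    level are skipped with a warning. P-values are two-sided and
    deliberately uncorrected — with many covariates screened, some nominal
    significances are expected by chance.
    """
    results: list[AssociationResult] = []
    for name in clinical.covariates:
        groups: dict[str, list[float]] = {}
        for i, sid in enumerate(clinical.sample_ids):
            if sid not in expression:
                continue
            groups.setdefault(clinical.covariates[name][i], []).append(expression[sid])
        levels = [lv for lv in groups if groups[lv]]
        if len(levels) < 2:
            logger.warning("covariate %r has a single observed level; skipped", name)
            continue
        sizes = tuple(len(groups[lv]) for lv in levels)
        if len(levels) == 2:
            p = mww_test(groups[levels[0]], groups[levels[1]])
            results.append(AssociationResult(name, "MWW", p, sizes))
        else:
            _, p = kruskal_wallis_test([groups[lv] for lv in levels])
            results.append(AssociationResult(name, "Kruskal-Wallis", p, sizes))
    return results
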