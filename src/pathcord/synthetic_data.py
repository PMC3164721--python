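"""Synthetic two-platform study generator.

Emulates the shape of a paired-cohort tumor/normal expression study so the
whole pipeline is testable without any download: two microarray-like
platforms with partially overlapping gene universes, genes measured by
multiple reporters, low-variability genes that the IQR admission filter
should remove, pathway-level expression shifts planted in a known
direction, clinical/mutation labels with optional planted expression
associations, and qMSP quantity panels.

The observation model is deliberately simple: per-gene baseline log2
intensity ~ Normal(8, 1), i.i.d. Gaussian observation noise, a constant
additive shift of ``effect_size`` in tumor samples of planted genes.
There is no inter-gene correlation — which is exactly the independence
assumption of the sum-t/sqrt(n) set statistic, so calibration results on
these data are a best case, not evidence about correlated real cohorts.

All randomness flows from a single master seed through fixed per-component
child streams, so identical designs give byte-identical outputs regardless
of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import ClinicalTable, ExpressionDataset, GeneSet, GeneSetCollection
from .quantitation import QmspMeasurement

# child-stream tags: default_rng([seed, TAG, ...]) per component
_TAG_COLLECTION = 1
_TAG_EXPRESSION = 2
_TAG_CLINICAL = 3
_TAG_QMSP = 4

PLATFORMS = ("A", "B")

#: IQR (log2 units) that rescaled low-variability genes are squeezed to;
#: safely below the default admission threshold of 0.5
_LOWVAR_TARGET_IQR = 0.3

#: covariates emulating a colorectal-cancer clinical table: name ->
#: (levels, sampling probabilities); the first level is the one planted
#: expression effects attach to
CLINICAL_COVARIATES: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "msi": (("MSI", "MSS"), (0.2, 0.8)),
    "kras": (("mut", "wt"), (0.35, 0.65)),
    "braf": (("mut", "wt"), (0.1, 0.9)),
    "tp53": (("mut", "wt"), (0.5, 0.5)),
    "pten": (("mut", "wt"), (0.1, 0.9)),
    "pik3ca": (("mut", "wt"), (0.15, 0.85)),
    "stage": (("IV", "III", "II", "I"), (0.2, 0.35, 0.3, 0.15)),
    "localization": (("right", "left", "rectum"), (0.35, 0.3, 0.35)),
}


class InvalidDesignError(ValueError):
    pass


@dataclass
class SimulationDesign:
    """Parameters of one synthetic two-platform study.

    Default cohort sizes mirror the study layout the pipeline targets:
    platform A with 46 tumors / 4 normals, platform B with 91 tumors /
    6 normals. Effect size and noise are in log2 units.
    """

    n_genes: int = 2000
    n_sets: int = 200
    set_size_range: tuple[int, int] = (10, 30)
    frac_sets_up: float = 0.1
    frac_sets_down: float = 0.1
    effect_size: float = 1.0
    noise_sd: float = 1.0
    platform_overlap: float = 0.9
    multiprobe_frac: float = 0.2
    lowvar_frac: float = 0.1
    samples_a: tuple[int, int] = (46, 4)
    samples_b: tuple[int, int] = (91, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_sets_up", "frac_sets_down", "platform_overlap",
                     "multiprobe_frac", "lowvar_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidDesignError(f"{name}={v} outside [0, 1]")
        if self.frac_sets_up + self.frac_sets_down > 1.0 + 1e-12:
            raise InvalidDesignError("frac_sets_up + frac_sets_down exceeds 1")
        lo, hi = self.set_size_range
        if lo < 1 or hi < lo:
            raise InvalidDesignError(f"bad set_size_range {self.set_size_range}")
        if hi > self.n_genes:
            raise InvalidDesignError("set_size_range.max exceeds n_genes")
        if self.noise_sd < 0:
            raise InvalidDesignError("noise_sd must be >= 0")
        for name in ("samples_a", "samples_b"):
            n_t, n_n = getattr(self, name)
            if n_t < 2 or n_n < 2:
                raise InvalidDesignError(
                    f"{name}: need >= 2 samples per class for the pooled t-test"
                )

    def samples_for(self, platform: str) -> tuple[int, int]:
        if platform == "A":
            return self.samples_a
        if platform == "B":
            return self.samples_b
        raise ValueError(f"unknown platform {platform!r}; expected one of {PLATFORMS}")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study.

    ``set_direction`` labels every generated set up/down/null;
    ``gene_direction`` records the single direction each planted gene
    carries (conflicts between sets are resolved at generation time);
    ``de_genes`` is exactly the union of the members of non-null sets.
    """

    set_direction: dict[str, str]
    de_genes: set[str]
    gene_direction: dict[str, str]
    clinical_effects: dict[str, dict[str, float]] = field(default_factory=dict)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def generate_collection(
    design: SimulationDesign,
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Draw the gene-set collection and its planted-direction truth.

    Set sizes are uniform on ``set_size_range`` and members are sampled
    without replacement per set (genes may belong to several sets). Exactly
    round(frac*n_sets) sets are labeled up resp. down. A gene recruited by
    planted sets of both directions keeps the direction of the first set
    that recruited it and is excluded from later opposite-direction sets.
    """
    rng = np.random.default_rng([design.seed, _TAG_COLLECTION])
    universe = _gene_names(design.n_genes)
    n_up = round(design.frac_sets_up * design.n_sets)
    n_down = round(design.frac_sets_down * design.n_sets)
    directions = ["up"] * n_up + ["down"] * n_down
    directions += ["null"] * (design.n_sets - len(directions))
    rng.shuffle(directions)

    lo, hi = design.set_size_range
    gene_direction: dict[str, str] = {}
    sets: list[GeneSet] = []
    set_direction: dict[str, str] = {}
    for i in range(design.n_sets):
        set_id = f"SET{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(design.n_genes, size=size, replace=False))
        symbols = [universe[j] for j in sorted(members)]
        direction = directions[i]
        if direction != "null":
            kept = []
            for g in symbols:
                prior = gene_direction.get(g)
                if prior is not None and prior != direction:
                    continue  # conflicting recruitment: first set wins
                gene_direction[g] = direction
                kept.append(g)
            symbols = kept
        if not symbols:
            # planted set fully cannibalized by conflicts; keep it null instead
            direction = "null"
            symbols = [universe[j] for j in sorted(members)]
        sets.append(GeneSet(set_id, f"synthetic set {set_id}", tuple(symbols)))
        set_direction[set_id] = direction

    collection = GeneSetCollection(tuple(sets), source_tag="synthetic")
    de_genes: set[str] = set()
    for s in sets:
        if set_direction[s.id] != "null":
            de_genes.update(s.members)
    truth = SyntheticTruth(set_direction, de_genes, gene_direction)
    return collection, truth


def generate_expression(
    design: SimulationDesign, truth: SyntheticTruth, platform: str
) -> ExpressionDataset:
    """Simulate one platform's reporter-by-sample log2 intensity matrix.

    The platform carries a random subset of ``platform_overlap * n_genes``
    universe genes; ``multiprobe_frac`` of those emit 2-3 reporters sharing
    the gene signal with independent noise; ``lowvar_frac`` of them (drawn
    from non-planted genes while any remain) have their sample-wise
    deviations rescaled to an IQR below the admission threshold.
    """
    if platform not in PLATFORMS:
        raise ValueError(f"unknown platform {platform!r}; expected one of {PLATFORMS}")
    unknown = truth.de_genes - set(_gene_names(design.n_genes))
    if unknown:
        raise ValueError(f"truth references genes outside the design universe: "
                         f"{sorted(unknown)[:3]}...")
    p_idx = PLATFORMS.index(platform)
    rng = np.random.default_rng([design.seed, _TAG_EXPRESSION, p_idx])
    universe = _gene_names(design.n_genes)
    n_platform = round(design.platform_overlap * design.n_genes)
    platform_genes = sorted(rng.choice(design.n_genes, size=n_platform, replace=False))
    genes = [universe[j] for j in platform_genes]

    n_multi = round(design.multiprobe_frac * len(genes))
    multi = set(rng.choice(len(genes), size=n_multi, replace=False).tolist())
    n_low = round(design.lowvar_frac * len(genes))
    non_de = [i for i, g in enumerate(genes) if g not in truth.de_genes]
    if n_low <= len(non_de):
        low_pool = non_de
    else:  # not enough untouched genes: spill over into planted ones
        low_pool = list(range(len(genes)))
    lowvar = set(rng.choice(low_pool, size=n_low, replace=False).tolist()) if n_low else set()

    n_tumor, n_normal = design.samples_for(platform)
    n_samples = n_tumor + n_normal
    sample_ids = [f"{platform}_T{i + 1:03d}" for i in range(n_tumor)]
    sample_ids += [f"{platform}_N{i + 1:03d}" for i in range(n_normal)]
    class_labels = ["tumor"] * n_tumor + ["normal"] * n_normal

    reporter_ids: list[str] = []
    gene_symbols: list[str] = []
    rows: list[np.ndarray] = []
    shift_vec = np.zeros(n_samples)
    for i, gene in enumerate(genes):
        baseline = rng.normal(8.0, 1.0)
        shift_vec[:] = 0.0
        d = truth.gene_direction.get(gene)
        if d == "up":
            shift_vec[:n_tumor] = design.effect_size
        elif d == "down":
            shift_vec[:n_tumor] = -design.effect_size
        n_rep = int(rng.integers(2, 4)) if i in multi else 1
        for r in range(n_rep):
            row = baseline + shift_vec + rng.normal(0.0, design.noise_sd, n_samples)
            if i in lowvar:
                q1, q3 = np.percentile(row, [25.0, 75.0])
                iqr = q3 - q1
                if iqr > 0:
                    center = np.median(row)
                    row = center + (row - center) * (_LOWVAR_TARGET_IQR / iqr)
            reporter_ids.append(f"{gene}_r{r + 1}" if n_rep > 1 else f"{gene}_r1")
            gene_symbols.append(gene)
            rows.append(row)

    values = np.vstack(rows) if rows else np.empty((0, n_samples))
    return ExpressionDataset(
        reporter_ids=reporter_ids,
        gene_symbols=gene_symbols,
        values=values,
        sample_ids=sample_ids,
        class_labels=class_labels,
        platform=platform,
    )


def generate_clinical(
    design: SimulationDesign,
    truth: SyntheticTruth,
    dataset: ExpressionDataset,
    clinical_effects: dict[str, dict[str, float]] | None = None,
) -> tuple[ClinicalTable, ExpressionDataset]:
    """Draw per-tumor clinical/mutation labels; plant expression shifts.

    For every covariate named in ``clinical_effects`` (covariate ->
    {gene: shift}), tumor samples carrying the covariate's first level
    (e.g. "MSI", "mut", "IV") get the shift added to the named genes'
    values. Returns the table and a shifted copy of the dataset; the
    effects are recorded into ``truth.clinical_effects``.
    """
    rng = np.random.default_rng([design.seed, _TAG_CLINICAL])
    tumor_ids = [s for s, c in zip(dataset.sample_ids, dataset.class_labels)
                 if c == "tumor"]
    covariates: dict[str, list[str]] = {}
    for name, (levels, probs) in CLINICAL_COVARIATES.items():
        draws = rng.choice(len(levels), size=len(tumor_ids), p=probs)
        covariates[name] = [levels[k] for k in draws]
    table = ClinicalTable(sample_ids=tumor_ids, covariates=covariates)

    clinical_effects = clinical_effects or {}
    values = dataset.values.copy()
    genes_present = set(dataset.gene_symbols)
    col_of = {s: j for j, s in enumerate(dataset.sample_ids)}
    for cov, gene_shifts in clinical_effects.items():
        if cov not in covariates:
            raise ValueError(f"unknown covariate {cov!r}")
        target_level = CLINICAL_COVARIATES[cov][0][0]
        hit_cols = [col_of[sid] for i, sid in enumerate(tumor_ids)
                    if covariates[cov][i] == target_level]
        for gene, shift in gene_shifts.items():
            if gene not in genes_present:
                raise ValueError(f"clinical effect on unknown gene {gene!r}")
            rows = [i for i, g in enumerate(dataset.gene_symbols) if g == gene]
            for r in rows:
                values[r, hit_cols] += shift
    truth.clinical_effects.update(clinical_effects)
    shifted = ExpressionDataset(
        reporter_ids=list(dataset.reporter_ids),
        gene_symbols=list(dataset.gene_symbols),
        values=values,
        sample_ids=list(dataset.sample_ids),
        class_labels=list(dataset.class_labels),
        platform=dataset.platform,
    )
    return table, shifted


def generate_qmsp_panel(
    n_samples: int, n_normals: int, frac_methylated: float, seed: int = 0
) -> list[QmspMeasurement]:
    """Simulate a qMSP panel with exactly one fully methylated positive control.

    round(frac_methylated * n_samples) tumor samples carry a target/ALU
    ratio that is a random positive fraction of the control's ratio (so
    their PMR lands in (0, 100]); the remaining samples and all normals
    have target quantity 0.
    """
    if not 0.0 <= frac_methylated <= 1.0:
        raise ValueError("frac_methylated must be in [0, 1]")
    rng = np.random.default_rng([seed, _TAG_QMSP])
    panel: list[QmspMeasurement] = []
    control_ratio = float(rng.uniform(0.5, 2.0))
    control_ref = float(rng.uniform(50.0, 150.0))
    panel.append(QmspMeasurement(
        "positive_control", "positive-control",
        target_qty=control_ratio * control_ref, ref_qty=control_ref,
    ))
    n_meth = round(frac_methylated * n_samples)
    for i in range(n_samples):
        ref = float(rng.uniform(20.0, 200.0))
        if i < n_meth:
            frac = 1.0 - float(rng.uniform(0.0, 1.0))  # in (0, 1]
            target = frac * control_ratio * ref
        else:
            target = 0.0
        panel.append(QmspMeasurement(f"S{i + 1:03d}", "sample", target, ref))
    for i in range(n_normals):
        ref = float(rng.uniform(20.0, 200.0))
        panel.append(QmspMeasurement(f"N{i + 1:03d}", "normal", 0.0, ref))
    return panel


def generate_two_platform_study(
    design: SimulationDesign,
) -> tuple[GeneSetCollection, SyntheticTruth, ExpressionDataset, ExpressionDataset]:
    """Convenience: collection + truth + both platforms' expression data."""
    collection, truth = generate_collection(design)
    ds_a = generate_expression(design, truth, "A")
    ds_b = generate_expression(design, truth, "B")
    return collection, truth, ds_a, ds_b


# ---------------------------------------------------------------- truth I/O

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Plain-text key-value dump of the ground truth."""
    with open(path, "w") as fh:
        for set_id in sorted(truth.set_direction):
            fh.write(f"set_direction\t{set_id}\t{truth.set_direction[set_id]}\n")
        for gene in sorted(truth.gene_direction):
            fh.write(f"gene_direction\t{gene}\t{truth.gene_direction[gene]}\n")
        for gene in sorted(truth.de_genes):
            fh.write(f"de_gene\t{gene}\n")
        for cov in sorted(truth.clinical_effects):
            for gene, shift in sorted(truth.clinical_effects[cov].items()):
                fh.write(f"clinical_effect\t{cov}\t{gene}\t{shift!r}\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    set_direction: dict[str, str] = {}
    gene_direction: dict[str, str] = {}
    de_genes: set[str] = set()
    clinical_effects: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "set_direction":
                set_direction[fields[1]] = fields[2]
            elif fields[0] == "gene_direction":
                gene_direction[fields[1]] = fields[2]
            elif fields[0] == "de_gene":
                de_genes.add(fields[1])
            elif fields[0] == "clinical_effect":
                clinical_effects.setdefault(fields[1], {})[fields[2]] = float(fields[3])
            else:
                raise ValueError(f"unknown truth record {fields[0]!r}")
    return SyntheticTruth(set_direction, de_genes, gene_direction, clinical_effects)
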