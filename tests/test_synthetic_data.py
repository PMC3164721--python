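import numpy as np
import pytest

from pathcord import (
    AnalysisConfig,
    SimulationDesign,
    generate_clinical,
    generate_collection,
    generate_expression,
    generate_qmsp_panel,
    mww_test,
    preprocess,
    score_qmsp_panel,
    two_class_ttest,
)
from pathcord.geneset_io import write_expression, write_gmt
from pathcord.synthetic_data import InvalidDesignError, read_truth, write_truth


def small_design(**overrides):
    base = dict(
        n_genes=300, n_sets=30, set_size_range=(8, 15),
        frac_sets_up=0.1, frac_sets_down=0.1, effect_size=1.0, noise_sd=1.0,
        platform_overlap=0.9, multiprobe_frac=0.2, lowvar_frac=0.1,
        samples_a=(10, 4), samples_b=(12, 4), seed=42,
    )
    base.update(overrides)
    return SimulationDesign(**base)


# ------------------------------------------------------------------ design

@pytest.mark.parametrize("kwargs", [
    dict(frac_sets_up=0.7, frac_sets_down=0.5),
    dict(platform_overlap=1.2),
    dict(set_size_range=(0, 5)),
    dict(set_size_range=(10, 5)),
    dict(set_size_range=(10, 500)),
    dict(samples_a=(1, 4)),
    dict(noise_sd=-0.1),
])
def test_invalid_designs_rejected(kwargs):
    with pytest.raises(InvalidDesignError):
        small_design(**kwargs)


# ------------------------------------------------------------------ collection

def test_empty_design_gives_empty_collection():
    coll, truth = generate_collection(small_design(n_sets=0))
    assert len(coll) == 0
    assert truth.set_direction == {} and truth.de_genes == set()


def test_direction_fractions_are_exact_counts():
    coll, truth = generate_collection(small_design(n_sets=100, frac_sets_up=0.2,
                                                   frac_sets_down=0.3))
    dirs = list(truth.set_direction.values())
    assert dirs.count("up") == 20
    assert dirs.count("down") == 30
    assert dirs.count("null") == 50
    assert set(truth.set_direction) == set(coll.ids)


def test_set_sizes_within_range():
    coll, truth = generate_collection(small_design(frac_sets_up=0, frac_sets_down=0))
    for s in coll:
        assert 8 <= len(s.members) <= 15


def test_de_genes_equal_union_of_nonnull_members():
    coll, truth = generate_collection(small_design(n_sets=60, frac_sets_up=0.3,
                                                   frac_sets_down=0.3))
    union = set()
    for s in coll:
        if truth.set_direction[s.id] != "null":
            union.update(s.members)
    assert truth.de_genes == union
    assert set(truth.gene_direction) == union


def test_no_gene_carries_conflicting_directions():
    design = small_design(n_genes=60, n_sets=40, set_size_range=(10, 20),
                          frac_sets_up=0.5, frac_sets_down=0.5)
    coll, truth = generate_collection(design)
    for s in coll:
        d = truth.set_direction[s.id]
        if d == "null":
            continue
        for g in s.members:
            assert truth.gene_direction[g] == d


# ------------------------------------------------------------------ expression

def test_same_seed_byte_identical_outputs(tmp_path):
    files = []
    for rep in range(2):
        design = small_design()
        coll, truth = generate_collection(design)
        ds = generate_expression(design, truth, "A")
        table, ds = generate_clinical(design, truth, ds)
        gmt = tmp_path / f"c{rep}.gmt"
        tsv = tmp_path / f"e{rep}.tsv"
        tru = tmp_path / f"t{rep}.txt"
        write_gmt(coll, gmt)
        write_expression(ds, tsv)
        write_truth(truth, tru)
        files.append((gmt.read_bytes(), tsv.read_bytes(), tru.read_bytes()))
    assert files[0] == files[1]


def test_platforms_differ_but_share_universe():
    design = small_design(platform_overlap=0.8)
    coll, truth = generate_collection(design)
    a = generate_expression(design, truth, "A")
    b = generate_expression(design, truth, "B")
    assert a.platform == "A" and b.platform == "B"
    assert a.n_samples == 14 and b.n_samples == 16
    assert len(a.genes()) == round(0.8 * design.n_genes)
    assert a.genes() != b.genes()  # independent subsets
    with pytest.raises(ValueError, match="unknown platform"):
        generate_expression(design, truth, "C")


def test_multiprobe_genes_emit_two_or_three_reporters():
    design = small_design(multiprobe_frac=0.5, lowvar_frac=0.0)
    coll, truth = generate_collection(design)
    ds = generate_expression(design, truth, "A")
    counts = {}
    for g in ds.gene_symbols:
        counts[g] = counts.get(g, 0) + 1
    n_multi = sum(1 for c in counts.values() if c > 1)
    assert n_multi == round(0.5 * len(counts))
    assert all(c in (1, 2, 3) for c in counts.values())


def test_lowvar_one_removes_every_gene():
    design = small_design(lowvar_frac=1.0, frac_sets_up=0.0, frac_sets_down=0.0)
    coll, truth = generate_collection(design)
    ds = generate_expression(design, truth, "A")
    filtered, pruned, report = preprocess(ds, coll, AnalysisConfig())
    assert filtered.n_reporters == 0
    assert report.n_removed_iqr == ds.n_reporters


def test_null_design_ttest_calibration():
    design = small_design(
        n_genes=1000, n_sets=5, effect_size=0.0, frac_sets_up=0.0,
        frac_sets_down=0.0, platform_overlap=1.0, multiprobe_frac=0.0,
        lowvar_frac=0.0, samples_a=(10, 10), seed=2024,
    )
    coll, truth = generate_collection(design)
    ds = generate_expression(design, truth, "A")
    mask = ds.tumor_mask
    ps = np.array([two_class_ttest(ds.values[i][mask], ds.values[i][~mask])[1]
                   for i in range(ds.n_reporters)])
    rate = float(np.mean(ps < 0.05))
    se = np.sqrt(0.05 * 0.95 / ps.size)
    assert abs(rate - 0.05) <= 3 * se


def test_planted_shift_moves_tumor_means():
    design = small_design(effect_size=3.0, noise_sd=0.3, multiprobe_frac=0.0,
                          lowvar_frac=0.0, platform_overlap=1.0)
    coll, truth = generate_collection(design)
    ds = generate_expression(design, truth, "A")
    mask = ds.tumor_mask
    for i, g in enumerate(ds.gene_symbols):
        d = truth.gene_direction.get(g)
        diff = ds.values[i][mask].mean() - ds.values[i][~mask].mean()
        if d == "up":
            assert diff > 1.5
        elif d == "down":
            assert diff < -1.5


# ------------------------------------------------------------------ clinical

def test_clinical_deterministic_and_complete():
    design = small_design(samples_a=(20, 4))
    coll, truth = generate_collection(design)
    ds = generate_expression(design, truth, "A")
    t1, _ = generate_clinical(design, truth, ds)
    t2, _ = generate_clinical(design, truth, ds)
    assert t1.sample_ids == t2.sample_ids and t1.covariates == t2.covariates
    assert len(t1.sample_ids) == 20  # tumors only
    assert set(t1.covariates) == {"msi", "kras", "braf", "tp53", "pten",
                                  "pik3ca", "stage", "localization"}


def test_clinical_effect_on_unknown_gene_rejected():
    design = small_design()
    coll, truth = generate_collection(design)
    ds = generate_expression(design, truth, "A")
    with pytest.raises(ValueError, match="unknown gene"):
        generate_clinical(design, truth, ds, {"msi": {"NOT_A_GENE": 1.0}})
    with pytest.raises(ValueError, match="unknown covariate"):
        generate_clinical(design, truth, ds, {"height": {ds.gene_symbols[0]: 1.0}})


def test_clinical_planted_shift_recovered_with_high_power():
    """A 2-noise-SD subgroup shift among ~70 tumors is nearly always seen by MWW."""
    hits = 0
    trials = 25
    for rep in range(trials):
        design = small_design(n_genes=50, n_sets=5, set_size_range=(5, 8),
                              samples_a=(70, 4), noise_sd=1.0,
                              multiprobe_frac=0.0, lowvar_frac=0.0,
                              frac_sets_up=0.0, frac_sets_down=0.0,
                              platform_overlap=1.0, seed=1000 + rep)
        coll, truth = generate_collection(design)
        ds = generate_expression(design, truth, "A")
        gene = ds.gene_symbols[0]
        table, shifted = generate_clinical(design, truth, ds,
                                           {"tp53": {gene: 2.0}})
        row = shifted.values[0]
        col = dict(zip(shifted.sample_ids, row))
        labels = table.covariates["tp53"]
        g1 = [col[s] for s, l in zip(table.sample_ids, labels) if l == "mut"]
        g2 = [col[s] for s, l in zip(table.sample_ids, labels) if l == "wt"]
        hits += mww_test(g1, g2) < 0.05
    assert hits / trials > 0.9


def test_clinical_no_effects_pvalues_roughly_uniform():
    design = small_design(n_genes=300, n_sets=5, samples_a=(60, 4),
                          effect_size=0.0, frac_sets_up=0.0, frac_sets_down=0.0,
                          multiprobe_frac=0.0, lowvar_frac=0.0,
                          platform_overlap=1.0, seed=77)
    coll, truth = generate_collection(design)
    ds = generate_expression(design, truth, "A")
    table, _ = generate_clinical(design, truth, ds)
    labels = table.covariates["tp53"]
    ps = []
    for i in range(ds.n_reporters):
        col = dict(zip(ds.sample_ids, ds.values[i]))
        g1 = [col[s] for s, l in zip(table.sample_ids, labels) if l == "mut"]
        g2 = [col[s] for s, l in zip(table.sample_ids, labels) if l == "wt"]
        ps.append(mww_test(g1, g2))
    ps = np.array(ps)
    # coarse KS-style check of uniformity at a fixed grid
    for q in (0.05, 0.25, 0.5, 0.75):
        assert abs(np.mean(ps <= q) - q) < 3 * np.sqrt(q * (1 - q) / ps.size) + 0.01


# ------------------------------------------------------------------ qMSP

def test_qmsp_panel_shape_and_determinism():
    p1 = generate_qmsp_panel(10, 4, 0.5, seed=9)
    p2 = generate_qmsp_panel(10, 4, 0.5, seed=9)
    assert p1 == p2
    roles = [m.role for m in p1]
    assert roles.count("positive-control") == 1
    assert roles.count("sample") == 10 and roles.count("normal") == 4


def test_qmsp_frac_zero_and_one():
    panel0 = generate_qmsp_panel(8, 3, 0.0, seed=1)
    res0 = score_qmsp_panel(panel0)
    assert all(r.pmr == 0.0 and not r.methylated for r in res0)
    panel1 = generate_qmsp_panel(8, 3, 1.0, seed=1)
    res1 = score_qmsp_panel(panel1)
    tumor = [r for r in res1 if r.sample_id.startswith("S")]
    assert all(0.0 < r.pmr <= 100.0 and r.methylated for r in tumor)


def test_qmsp_frac_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        generate_qmsp_panel(5, 2, 1.5, seed=0)


# ------------------------------------------------------------------ truth IO

def test_truth_roundtrip(tmp_path):
    design = small_design()
    coll, truth = generate_collection(design)
    ds = generate_expression(design, truth, "A")
    generate_clinical(design, truth, ds, {"msi": {ds.gene_symbols[0]: 1.5}})
    p = tmp_path / "truth.txt"
    write_truth(truth, p)
    back = read_truth(p)
    assert back.set_direction == truth.set_direction
    assert back.de_genes == truth.de_genes
    assert back.gene_direction == truth.gene_direction
    assert back.clinical_effects == truth.clinical_effects
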