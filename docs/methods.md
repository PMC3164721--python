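# Methods

## The set-level test

Each dataset is a reporter × sample matrix of log2 intensities with
tumor/normal class labels. After the admission filters (below), each gene
contributes one pooled-variance two-sample t-statistic t_g (tumor minus
normal, two-sided). A pathway with n measured member genes is scored

    Z = ( Σ_g t_g ) / √n .

If the t_g were i.i.d. standard normal under the null, Z would be standard
normal; the default analytic P-value is the two-sided standard-normal tail
of Z. Two deviations from that idealization matter and are deliberately
documented rather than patched:

* a t-statistic with df degrees of freedom has variance df/(df−2) > 1, so
  the analytic P is slightly anticonservative, noticeably so for small
  cohorts (df = 48 and 95 at the default cohort sizes gives variance
  inflation of ~4% and ~2%);
* genes within a pathway are correlated in real tissue; the score's
  variance then exceeds 1 by the summed pairwise correlations and the
  analytic P can be badly anticonservative. The generator used for testing
  produces independent genes, so calibration results here are a best case
  and say nothing about correlated cohorts.

The rigorous alternative (`set_pvalue_method: permutation`) permutes the
sample class labels, recomputes every per-gene t and every set score per
permutation, and uses the two-sided permutation tail. When the number of
distinct tumor-label placements C(n_samples, n_tumor) is at most
`n_permutations`, all of them are enumerated and the P-value is exact (the
observed labeling counts itself, so P ≥ 1/total); otherwise
`n_permutations` random placements are drawn and the add-one estimate
P = (1 + #hits)/(n_perm + 1) keeps the test valid. Permutation scores are
compared to the observed score with an absolute slack of 1e-9 so the
observed assignment is never lost to float rounding between the scalar and
vectorized t routines. One permutation null (one label-placement matrix) is
shared by all pathways of a dataset, which is the standard economy; it
introduces weak dependence between set P-values but changes no individual
P-value.

Genes belonging to several pathways contribute the same t to each, without
reweighting. No multiple-testing correction is applied to pathway P-values:
the downstream two-dataset intersection already reduces the per-pathway
false-call risk to α² under cross-cohort independence (1/400 at α = 0.05),
and that is the inference the pipeline reports. The α² figure assumes the
cohorts are independent; it is a design argument, not a verified property
of any particular platform pair.

## Admission filters

Fixed order: (1) reporters with IQR strictly below `iqr_min` (default 0.5
log2 units) are removed — IQR exactly at the threshold is retained; (2)
multi-reporter genes are collapsed to the reporter with the largest IQR,
ties broken by the lexicographically smallest reporter id so the pipeline
is deterministic; (3) genes annotated to no pathway are removed; (4)
pathways with fewer than `min_set_size` (default 10) measured genes are
removed and surviving pathways are restricted to their measured members.

"Variability" means IQR throughout — the same measure drives the filter and
the collapse, computed with linear interpolation between order statistics
(the default quantile convention of mainstream numeric stacks). Whether the
IQR filter should run before or after the collapse is genuinely open; the
default is filter-first (a gene survives if any of its reporters does), and
`collapse_before_filter: true` exposes the alternative, which is only
lightly tested. Matrices with non-finite entries are rejected outright:
there is no missing-data rule in this pipeline, and silently imputing one
would change the statistics.

## Concordance classification

Significance is inclusive, p ≤ α. Both datasets significant with the same
direction of Z → `concordant-up`/`concordant-down`; both significant with
opposite directions → `opposite`; exactly one significant → `single-A`/
`single-B`; otherwise `neither`. A pathway or gene absent from one
platform's measured universe is `unmeasured-A`/`unmeasured-B` (it can still
be reported when significant on the other platform); items measured on
neither platform are excluded from summaries entirely. The identical rule
table drives the per-pathway gene concordance tables, which carry each
gene's P-value and log2 fold change per dataset.

Log2 fold change is the difference of group means on the log2 intensity
scale. Platform-specific preprocessing in real studies can put fold changes
on other scales; this definition is the package's fixed convention and is
not calibrated to any particular platform's reporting.

## Validation-arm quantitation

* **Standard curve:** least-squares line Ct = a + b·log10(q) through a
  serial-dilution series; quantities interpolate as q = 10^((Ct−a)/b). A
  slope within 1e-12 of zero is rejected as flat.
* **qRT-PCR normalization:** triplicate quantities are aggregated by their
  median (no further outlier rejection); target expression is the target
  median divided by the mean of the endogenous-control medians.
* **PMR:** 100 × (target/ALU)_sample / (target/ALU)_positive-control, the
  ALU repeat assay normalizing for DNA input. The methylation call is
  strict: PMR must exceed the maximum PMR of the normal panel, floored at
  0. With clean normals (all zero) this reduces to PMR > 0, while normal
  panels with background signal raise the threshold sensibly. PMR is
  invariant to rescaling a sample's target and reference together, and the
  call is monotone in PMR and antitone in the normal-panel maximum.
* **Rank tests:** Mann-Whitney-Wilcoxon for two-level covariates,
  Kruskal-Wallis (tie-corrected H, chi-square reference on k−1 df) for
  more levels; all two-sided. The MWW P-value is computed by exhaustive
  enumeration of the rank-sum null whenever both groups have ≤ 8
  observations — with midranks this remains the exact conditional test
  under ties — doubling the smaller one-sided tail and capping at 1;
  larger groups use the tie-corrected normal approximation with continuity
  correction. Association screens are deliberately uncorrected and say so
  in their output: with ~16 covariates screened, occasional nominal
  significances are expected by chance.

## Synthetic study generator

The generator exists so that every stage — filters, scores, permutation
P-values, concordance, association tests — can be exercised end-to-end
with known ground truth. Its model:

* gene universe of `n_genes` symbols; per gene and platform a baseline
  log2 intensity ~ Normal(8, 1);
* observation = baseline + Normal(0, `noise_sd`); default noise 1.0 log2
  units;
* `n_sets` pathways with sizes uniform on `set_size_range`, members drawn
  without replacement per set (sets overlap); exactly
  round(frac·n_sets) sets planted up resp. down. Every member of a planted
  set is shifted by ±`effect_size` in tumor samples. A gene recruited by
  planted sets of both directions keeps its first direction and is dropped
  from later opposite-direction sets, so no gene ever carries conflicting
  truth;
* each platform measures an independent random `platform_overlap` fraction
  of the universe; `multiprobe_frac` of a platform's genes emit 2–3
  reporters sharing the gene signal with independent noise;
  `lowvar_frac` of them are rescaled around their median to an IQR of 0.3,
  below the default admission threshold — these are drawn from non-planted
  genes while any remain, so planted signal is not silently destroyed;
* clinical tables draw MSI status, five mutation flags, stage and tumor
  localization per tumor sample at realistic colorectal-cancer prevalences;
  planted clinical effects add a chosen shift to named genes in the
  covariate's first level (MSI, mut, stage IV, right-sided);
* qMSP panels give methylated samples a target/ALU ratio that is a random
  positive fraction of the positive control's ratio (PMR in (0, 100]) and
  everything else a target quantity of exactly 0.

Default cohort sizes are 46 tumors/4 normals (platform A) and 91 tumors/6
normals (platform B) — the two-cohort layout this pipeline is designed
around. All randomness derives from one master seed through fixed
per-component child streams (`default_rng([seed, component, ...])`), so
identical designs produce byte-identical files regardless of call order.

What the generator does **not** emulate: inter-gene correlation, batch and
array-position effects, intensity-dependent variance, copy-number-driven
expression, annotation errors. Passing calibration and recovery tests on
these data therefore demonstrates correctness of the implementation under
its stated assumptions, not robustness to real microarray pathology.

## Numerical and degenerate-input choices

* Zero pooled variance in the t-test: equal means → t = 0, p = 1; unequal
  means → t = ±∞, p = 0; both flag `zero_variance`. Sets containing a
  non-finite t cannot be scored and raise.
* Kruskal-Wallis with every observation identical: H = 0, p reported as 1.
* Exact MWW ties on the tail boundary are counted with a 1e-9 slack on the
  rank sums (which are multiples of 0.5, so the slack is exact).
* `joint_chance_risk` computes α^k through the exact decimal value of α so
  that 0.05² is exactly 0.0025 rather than one float ulp off.
* Quantile convention everywhere: numpy's linear interpolation.

## Problem sizes used by the shipped checks

The calibration and recovery checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` run the full pipeline on a 2000-gene universe with
200 (calibration) or 40 (recovery) pathways, 1000 permutations, at the
default 46/4 and 91/6 cohort sizes; the permutation engine is vectorized
over genes and permutations, so each run takes a few seconds. Calibration
tolerances are 3 binomial standard errors around α for per-dataset
rejection and the 99.9% binomial envelope around α² for the null
concordant rate.
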