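# Methods

This note documents the models and procedures implemented in `isopanel`,
the parameters that matter, the design choices made where several
reasonable options existed, and what the synthetic-data generator does and
does not emulate.

## Probe-panel model and identifiability

A gene with isoforms `t_1..t_n` is measured by probes whose target sets
define the incidence matrix `A ∈ {0,1}^{m×n}`. Isoform expressions are
recoverable from probe intensities exactly when `rank(A) = n`. Rank is
computed by fraction-free Gaussian elimination over the rationals, so
small 0/1 matrices never suffer floating-point rank ambiguity; the test
suite cross-checks it against a brute-force minor-expansion oracle.

Rank deficiency is diagnosed at two levels:

- **Indistinguishable groups** — isoforms with *identical* columns of `A`.
  Only the group's expression sum is constrained by data; the group is the
  unambiguous, testable core case of non-identifiability.
- **Partial identifiability** — residual rank deficiency among *distinct*
  columns (linear dependence without duplication). This is flagged at the
  gene level; the minimizer returned for such genes is valid but not
  unique.

Isoforms covered by no probe at all are reported as not-estimable rather
than zero: absence of evidence about an isoform is not evidence of absence.

The `design_max_probe_panel` layout (one probe covering all isoforms,
singleton probes for all but the last) always yields full rank; the last
isoform's expression is the max probe minus the singletons. Row order
follows the input probe list — the arithmetic is order-invariant, so no
canonical ordering is imposed.

## Normalization and deconvolution

**Housekeeping normalization.** Per sample, the geometric mean of the
housekeeping probe counts is computed; the sample is scaled by
(cohort-wide geometric mean of those per-sample geomeans) / (the sample's
geomean). This direction preserves the overall scale of the cohort and is
symmetric in the samples — normalizing to a fixed reference value would
be an equally defensible convention and differs only by a global factor,
which no downstream rank-based statistic can see. Zero housekeeping
counts make the geometric mean undefined and are an error, not a silent
drop. Technical replicates are averaged (arithmetic mean of normalized
counts) *after* normalization and *before* deconvolution; since
deconvolution is linear in `y` whenever the active constraint set is
stable, averaging before or after changes little, and averaging first
reduces the number of NNLS solves.

**Deconvolution.** `deconvolve_gene` minimizes `||y − A x||²` subject to
`x ≥ 0` via the Lawson–Hanson active-set solver (`scipy.optimize.nnls`),
which is deterministic and needs no initialization. Duplicate columns are
collapsed before solving, so the solver always works on distinct columns;
a multi-member group's coefficient is reported as the group sum and its
members as NaN (not-estimable) — an arbitrary within-group split would
fabricate resolution the design does not have. The test suite checks the
solver against an exact support-enumeration oracle (all 2^n − 1 support
sets, feasibility-filtered) on random small designs.

**Transforms.** Gene expression is the sum of the gene's isoform (group)
expressions, computed before the log transform; `log_transform` applies
log2(x+1). The base is configurable and immaterial to every rank-based
statistic downstream; base 2 makes fold-change units read as doublings.

## Proportions and the d statistic

Proportions are computed on the raw (pre-log) scale: `p_ij = x_ij / Σ_j
x_ij`. Genes with zero total expression in a sample are excluded and
counted rather than imputed as uniform — uniform imputation would
systematically shrink the cross-platform difference statistic. The
statistic

    d = (1/n) Σ_i (1/m_i) Σ_j |p^a_ij − p^b_ij|

is a scaled L1 distance: symmetric, zero iff the tables agree, bounded by
1 (each gene's term is at most 2/m_i ≤ 1), and satisfies the triangle
inequality. It is evaluated over the genes present in both tables; when
two designs resolve a gene at different granularity,
`collapse_to_groups` first merges the finer platform's isoforms into the
coarser design's indistinguishable groups so the comparison stays
well-defined.

Comparative-Ct proportions use relative quantity `q_j = E^(−Ct_j)` with
amplification efficiency E = 2.0 per cycle (configurable); proportions
are invariant to any additive shift of a gene's Ct values, which is why
the total-RNA normalization of Ct values is a no-op for this use.
Rank-sum comparisons of d distributions use the exact two-sided
Mann–Whitney distribution for combined n ≤ 20 without ties and the
tie-corrected normal approximation otherwise.

## Concordance battery

- Spearman correlations use average ranks for ties; a constant vector has
  no rank correlation and is reported as missing with a warning rather
  than 0.
- "Overall" correlation is the pooled coefficient over all
  (feature, sample) pairs; the per-sample mean/median is also exposed,
  since pooling can legitimately fall below the per-sample values when
  samples differ by offsets.
- The low-expression subset ranks features by **mean expression across
  samples** per platform (the rule is ambiguous between per-sample and
  mean ranking; mean ranking makes the subset sample-independent), takes
  the bottom `floor(N/3)` on each platform, and intersects.
- Fold-changes are differences of log2(x+1) values for every
  (target-tissue sample, other sample) pair; a raw-ratio variant is
  available behind a flag.
- Differential expression uses per-gene one-way fixed-effects ANOVA
  (`scipy.stats.f_oneway`); tissues with fewer than two samples are
  dropped with a warning. Genes are ranked by ascending p with a
  lexicographic gene-id tie-break so top-k lists are deterministic. A
  gene constant within every group has zero between-group evidence and is
  assigned F = 0, p = 1. No multiple-testing correction enters the
  ranking; a Benjamini–Hochberg q-value column is attached as
  supplementary output.

## Synthetic-data generator

The generator emulates a targeted cancer panel study measured on several
platforms at once. Defaults (all in `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_genes` / `category_weights` | 155; 79:37:18:21 for 2/3/4/5 isoforms | panel size and isoform-count mix; the >4 category is generated with exactly 5 isoforms |
| `allocation` | proportional | largest-remainder category allocation (exact counts); `multinomial` draws instead |
| `n_housekeeping`, `n_spike_in` | 10, 14 | single-isoform housekeeping genes; targetless spike-in control probes |
| `n_samples` / `tissue_weights` | 46; 12:12:11:10:4:2 | cohort size and tissue mix (ovary-heavy cancer cell line panel) |
| `log_mean`, `log_sd` | 4.0, 1.5 (natural log) | per-isoform log-normal baselines; median ≈ 55 counts, range spanning ~3 orders of magnitude |
| `biological_sd` | 0.5 | per isoform × sample multiplicative spread |
| `de_fraction`, `de_effect` | 0.2, 1.0 | fraction of genes with a tissue-specific shift; shift in log2 units |
| `noise_sd` | 0.2 | multiplicative log-normal measurement noise per probe count |
| `sample_scale_sd` | 0.3 | per-sample global scale factor — the nuisance housekeeping normalization removes |
| `n_replicates`, `replicate_sd` | 2, 0.1 | technical replicates and extra per-replicate scale jitter |
| `background` | 0 | additive probe background (no background correction is applied downstream, so the default forward model matches the estimator) |
| `seq_depth` | 10 | Poisson reads per expression unit in the count view |
| `ambiguity` | 0 | fraction of each gene's signal spread uniformly over its isoforms in the count view (gene totals preserved exactly) |
| `array_background`, `array_noise_sd` | 50, 0.1 | additive floor + noise of the array view; the floor compresses the low-expression range after log |
| `ct_offset`, `ct_noise_sd` | 20, 0.2 | Ct = offset − log2(x) + noise |

Housekeeping genes are constant across samples (before measurement
noise); spike-ins carry a fixed level and are excluded from normalization
and deconvolution. A fixed seed makes all outputs byte-identical.

What the generator does **not** emulate: sequence-level effects (GC
content, fragmentation, 3'-bias), cross-hybridization between specific
probes, amplification efficiency differences between primers, batch or
lab effects, and the idiosyncrasies of specific quantification pipelines.
Passing tests therefore demonstrate the estimators' correctness and the
direction of the simulated platform biases, not quantitative agreement
with any real dataset.

Noteworthy identities used in tests: with all noise terms zero the full
pipeline (simulate → normalize → average replicates → deconvolve)
reproduces the ground truth exactly up to one cohort-wide scale factor
(exactly 1 when `sample_scale_sd` = 0), because normalization anchors to
the cohort geometric mean rather than to the truth's absolute scale; and
the within-gene ambiguity mix preserves gene sums exactly, which is what
keeps gene-level concordance flat while isoform-level concordance
degrades.

## Problem sizes

The packaged checks run at desk scale, chosen so the full suite completes
in well under a minute of simulation time: parameter recovery uses 20
simulations of a 150-gene panel with 8 samples each; the concordance
trends use the default 155-gene panel with 12 samples; the ANOVA null
uses 1,000 genes across 3 groups of 5 samples. The oracle comparisons use
500 random 2–4-isoform designs and ~1,000 random proportion tables.

## Known limitations

- Partially identifiable designs (dependent but distinct columns) return
  *a* minimizer with a flag; no minimum-norm or group-merging resolution
  is attempted beyond duplicate columns.
- The housekeeping normalization assumes all housekeeping counts are
  strictly positive; very low-count samples must be handled upstream.
- `proportion_difference` requires matching isoform sets per shared gene
  and deliberately errors otherwise; collapse to shared groups first.
- The d statistic weights every gene equally regardless of expression
  level, so lowly expressed genes with unstable proportions contribute as
  much as well-measured ones; this mirrors the statistic's definition
  rather than a robustness choice.
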