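# Methods

## Model and procedure

Counts k_gj for gene g in sample j are modelled as negative binomial with
mean s_j μ_g(c_j) and dispersion α_g, in the variance parameterization
var = μ + αμ². The two conditions are a wild-type and a mutant group;
log₂ fold changes are mutant versus wild-type. The DE procedure is the
classic exact-test workflow for small replicated designs (no GLM/Wald
framework, no blind dispersion mode, no covariates — deliberate
non-goals):

1. **Size factors.** Median-of-ratios with a geometric-mean
   pseudo-reference, computed over genes with a positive count in every
   sample. Factors are reported unnormalized (so two identical samples get
   factors (1, 1), and a globally doubled sample pair gets (1/√2, √2)).
   If no gene is expressed in all samples the estimator raises rather than
   silently switching reference.
2. **Dispersions.** Raw per-gene method of moments: with v the pooled
   within-condition variance of normalized counts and μ̂ their mean,
   α_raw = (v − μ̂ · mean_j(1/s_j)) / μ̂², which removes the shot-noise term
   of normalization. The trend α(μ) = a₀/μ + a₁ is fitted by least squares
   over genes with α_raw > 0 and μ̂ ≥ 1; final dispersion is
   max(α_raw, fitted, floor) — the conservative maximum-sharing rule.
   The floor is 1e-8.
3. **Exact test.** Conditional on K = K_A + K_B (the per-condition count
   sums), per-condition NB laws are built from the pooled mean
   μ = K/(s_A+s_B): mean_c = s_c μ, var_c = s_c μ + α μ² Σ_{j∈c} s_j².
   p = Σ{P(a, K−a) : P ≤ P_obs} / Σ P, with a 1e-8 relative tie tolerance
   so mathematically symmetric splits are not lost to log-domain rounding.
   K = 0 returns p = 1 by convention; p is floored at the smallest
   positive double and never reported as 0. When the variance excess over
   Poisson is below 1e-6 relative, the Poisson pmf is used: beyond that
   point the NB size parameter exceeds ~1e6 and gammaln cancellation costs
   more accuracy than the overdispersion is worth.
4. **Multiple testing.** BH step-up is the default (delegated to
   statsmodels); Bonferroni is available behind a flag because the source
   material is internally inconsistent about which adjustment produced its
   headline gene list — the conflict is surfaced as an option rather than
   silently resolved.
5. **DE call.** significant ⇔ q < 0.05 and |log₂FC| ≥ log₂ 1.5. The fold
   change uses normalized condition means, with a pseudocount of 1 added
   to both means when either is zero (the zero-handling rule is a package
   choice; nothing upstream defines one).
6. **Display.** Row z-scores use the sample SD (ddof = 1); constant rows
   map to all-zero by convention. Clustering is complete-linkage on
   Euclidean distance via scipy, whose deterministic index-order tie-break
   we document as the package's tie rule.

## Counting rules

Union-exon counting follows htseq-count's union mode: a read (one
contiguous interval; CIGAR, splicing, mates and quality are out of scope)
counts for a gene iff ≥ min_overlap bases (default 1) intersect the
gene's exon union and it does not also qualify for a second gene;
multi-gene overlaps are ambiguous and counted for no gene, so
assigned + no_feature + ambiguous always equals the read total.
Strandedness is off by default; both the mode and strand settings are
declared package defaults, since the upstream protocol they mirror does
not record its own. Coordinates are 0-based half-open internally; GTF is
converted at the I/O boundary only.

## Concordance classification

Membership in the NULL ∪ TG hypothalamus sets defines the shared column;
direction is expressed as an annotation (concordant with NULL, TG-only,
opposite to NULL or like TG, opposite to both). This membership-based
reading is the one under which the published summary table's
per-direction partition arithmetic (shared + other-region + unique =
total) holds, while the prose definition of "shared" as same-direction
corresponds to the concordant_null annotation — both readings are exposed
rather than asserting either. The TG-implied expectation for a
loss-of-function comparison is the opposite of the TG direction
("activated" = down in NULL and up in TG; "repressed" = the reverse);
it is used only for the opposite-both annotation and the
regulation_class field. Genes without a mouse ortholog are classified
unique_rat and reported in a diagnostic list. Reference sets are always
inputs (TSV), never bundled from any publication's supplements.

## Validation scoring

The prediction for a loss-of-function rodent model is the rodent
direction itself; "predicted" requires both statistical significance and
an exact direction match — relative expression magnitude is carried
through but never used for labelling. The five labels are exhaustive and
mutually exclusive over all valid flag combinations (enforced by record
invariants: significance requires detection in both groups and a
direction; non-significant records carry no direction). Percentages are
reported to the nearest integer, matching the convention of the worked
example; exact fractions stay in the machine-readable summary. The
significance criterion for the third-species measurements is an input
flag, not computed here — the upstream assay software owns it.

## Synthetic-data generator

The generator emulates a GEO-style two-genotype bulk RNA-seq design:
4 biological replicates per genotype (8 samples), NB counts, planted
effects, and the downstream reference/ortholog/panel structure. Defaults,
chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_genes | 2000 | desk-scale transcriptome slice |
| n_per_group | 4 | the emulated design's replication |
| de_fraction | 0.1 | moderate DE burden |
| effect sizes | uniform on [log₂1.5, 2.0], sign ~ up_fraction | within the ±2 log₂ envelope of the emulated data and above the 1.5-fold call threshold, so every planted gene is callable |
| up_fraction_rat / up_fraction_null | 0.5 / 0.75 | balanced rat alterations; up-skewed mouse NULL set |
| baseline means | log-uniform, log₁₀ ∈ [0.5, 3.0] | spans low to high expressors so the dispersion trend has leverage |
| dispersion trend (a₀, a₁) | (0.8, 0.05) | typical bulk-tissue mean-dispersion decay with a ~0.05 asymptote |
| category rates (conc/tg/opp/other) | 0.41 / 0.05 / 0.02 / 0.05 | the published grand-total category proportions |
| library size factors | deterministic, e^±0.2 spread, geometric mean 1 | realistic depth variation without an extra RNG stream |

Planted category counts are deterministic (round(rate × n_DE)); the RNG
chooses which genes. The concordant NULL planting is steered toward
up_fraction_null as far as the available rat directions allow (with
concordance_rate = 1 and balanced rat directions the skew saturates at
0.5 — best effort, by construction). Concordant genes also enter the TG
set with the opposite direction, realising the activated/repressed
pattern. Each operation has its own RNG stream seeded from
(seed, crc32(tag)).

What the generator does **not** emulate: GC/length biases, correlated
genes, outlier samples, batch effects, many-to-many orthology, partially
detected panel genes with noisy Cq values, or any sequencing-error/
fragment model (no FASTQ; reads are single intervals). Passing tests
therefore demonstrate correctness of the algorithms under the stated NB
model, not robustness to those real-data artefacts.

## Numerical and design choices

- The exact test enumerates all K+1 splits; at the default mean range the
  per-gene cost is small and 2,000-gene runs complete in seconds.
- Type-I-error calibration is measured with the generator's true
  dispersions and baseline means log-uniform on [10, 1000]: it tests the
  test, not the dispersion estimator, and in that regime the conditional
  law is effectively continuous. At very low totals the conditioned exact
  test is intrinsically conservative (discrete mass at the mode), a known
  property of this test family.
- The end-to-end acceptance run uses 2,000 genes, 4 vs 4, 10% DE — the
  package's chosen desk-scale study condition.
- Degenerate inputs: a gene with identical counts in all replicates has
  α_raw ≤ 0 and is clamped to the floor/trend; an all-zero gene yields
  p = 1 and a pseudocounted fold change of 0; an empty classified set
  yields an all-zero summary with percentages defined as 0.

## Limitations

- The exact test, like its ancestors, loses power relative to GLM-based
  approaches for unbalanced designs and offers no covariate adjustment.
- The least-squares dispersion-trend fit is not robust to heavy-tailed
  raw-dispersion outliers; with maximum sharing this errs conservative.
- Ortholog handling assumes 1:1 mappings; paralog expansions must be
  resolved upstream.
- The summary-table reading (membership-based shared column) is one of
  two defensible interpretations of the published table; the annotation
  layer preserves the other.
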