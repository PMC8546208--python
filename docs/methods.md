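# Methods

This note documents the statistical model behind `adproteo`, the choices made
where the methodology leaves room, and what the synthetic benchmarks do and do
not demonstrate.

## Design and data model

The pipeline targets a case/control brain cohort sampled in four regions
affected during the limbic stage of Alzheimer's disease, in the anatomical
order of spread **HP → CA1 → EC → PRC**.  That order is a single constant
(`trajectory.REGION_ORDER`) used by every cross-region computation.  Three
intensity layers share one matrix contract (features × samples, raw scale
strictly positive, missing = `NaN`, never 0): protein groups, phosphopeptides
(with technical replicates), and paired acetyl channels where `d0` is the
endogenous and `d3` the heavy chemical acetylation of the same peptide.
Covariates (sex, age in years, post-mortem interval in hours) attach to
brains, not samples.

## Pre-processing

All pre-processing is per region, independently.

1. **Technical replicates** are collapsed by the per-feature median over
   present values; a cell missing in every replicate stays missing.
2. **log2 + median normalization**: per-sample median of present values is
   subtracted, so every sample's post-normalization median is exactly 0.
3. **Validity rules** operate on exact count ratios per disease group:
   - qualitative ON/OFF: ≥70% valid in one group and <10% in the other;
   - quantitative: ≥66% in both groups, or on-off-like (<33% vs ≥66%).
   Boundary semantics are literal: "at least" is ≥, "less than" is <, so a
   fraction of exactly 0.70 qualifies and exactly 0.10 disqualifies.
   Comparisons carry a 1e-12 guard because thresholds like 0.66 are not
   exactly representable while count ratios such as 33/50 are the same
   double; the guard makes the mathematically-equal case compare equal.
   With 11 AD brains, "≥66%" means ≥8/11 valid — the integer granularity at
   these group sizes matters for what gets excluded (see *Benchmarks*).
   A feature may satisfy both the ON/OFF and the on-off-like rule; it is
   then reported in both outputs, mirroring how presence/absence and
   quantitative results are tabulated separately.
4. **Imputation** (only features passing the quantitative rule) replaces each
   missing cell of sample *j* by a draw from
   N(μ_j − downshift·σ_j, (width·σ_j)²) with defaults width = 0.3,
   downshift = 1.8, where μ_j, σ_j are that sample's post-normalization
   present-value mean and SD (ddof = 1).  Statistics are per column — a
   deliberate convention match with the software this procedure originates
   from.  Draws come from per-column substreams keyed by the sample id, so
   results do not depend on column order; one global seed reproduces the
   matrix exactly.  Whether imputation precedes or follows the restriction
   to retained features is not fixed by the procedure's description; this
   implementation imputes only retained features, the conventional order.

## Differential analysis

Abundance is regressed on the disease indicator (control = 0, AD = 1) by
OLS; the slope is the AD − control log2 fold change and its two-sided t-test
is algebraically the equal-variance two-sample t-test (the suite checks
agreement with `scipy.stats.ttest_ind` to 1e-10).  Significance =
p < 0.05 AND |log2FC| ≥ 0.7.  **No multiple-testing correction is applied by
default** — the raw-p + fold-change-floor rule is reproduced deliberately; a
`bh_fdr` flag adds BH q-values for reporting without changing the rule.

Covariate screening regresses each feature on each covariate **separately**
(sex 0/1, age, PMI); a slope p < 0.05 flags the feature and removes it from
the retained calls.  Univariate screens are the conservative literal choice
when no joint model is specified; note the cost: under the null, three
independent 5% tests flag ~14% of all features, including true positives.
Balance tests use Fisher's exact test for sex and the Wilcoxon rank-sum test
for age/PMI.

**Exact Wilcoxon.**  For group sizes up to 25 the two-sided p-value comes
from the exact permutation null of the rank-sum statistic, computed by the
shift-algorithm dynamic programme over doubled mid-ranks (so ties are
handled exactly); above that, the normal approximation with tie correction.
The two agree within 0.01 at the switchover.  Complete separation of
{1,2,3} vs {4,5,6} gives 2/20 = 0.1 exactly.

## PTM quantification

**Phosphorylation state** = log2(phosphopeptide) − log2(parent protein),
both post-normalization — a raw-scale ratio.  "Corrected for protein
abundance" is not operationally defined in most descriptions; the log-ratio
is the standard occupancy-free correction and makes a site whose change is
purely protein-driven show a state fold change of ~0 (verified in tests).
The state matrix is computed first, then filtered and imputed like any
layer.  Sites without a quantified parent protein are dropped and counted.

**Acetylation stoichiometry** = Σd0 / (Σd0 + Σd3) per site and sample.
When exactly one channel is missing the ratio is algebraically forced *if*
the absence is real (d3 absent → 1.0, d0 absent → 0.0); since absence may
also be dropout, a `strict_pairs` flag instead requires both channels.  The
permissive default maximizes site coverage.  Group comparison is a
two-sided exact Wilcoxon on the raw ratios (no logit transform, no
imputation), restricted to sites with ≥40% valid ratios in each group.

## Trajectories

Per feature quantified in all four regions: control-median fold changes
(each AD sample's log2 value minus the control median, same feature and
region).  Per-sample fold changes feed a one-way fixed-effects ANOVA across
regions — maximizing degrees of freedom — with Tukey HSD in the
Tukey–Kramer form because AD sample counts can differ by region.  The
vectorized implementation evaluates the studentized-range survival function
through a cached monotone-cubic interpolant (401 knots on q ∈ [0, 20]),
accurate to ~1e-5; the per-feature path uses `scipy.stats.tukey_hsd` exactly
and the two are cross-checked in the tests.

Clustering operates on the 4-dimensional **median** fold-change vectors of
ANOVA-significant features (p < 0.05): medians match the per-region profile
lines of the original figures and make the feature space invariant to
sample counts.  Complete-linkage Euclidean dendrograms are cut by a dynamic
hybrid procedure re-implemented from its published description rather than
ported line-by-line (the reference implementation has many unstated
internals), and validated behaviorally:

1. candidate partitions cut the dendrogram into k = 1…10 branches;
2. a partition is admissible when every pair of branches at or above the
   size floor is separated (complete-linkage distance) by at least θ times
   the larger branch diameter, with θ = 2.0 at deepSplit = 1 (θ ranges
   2.2…1.5 for deepSplit 0…4).  Genuinely separated clusters — centres ≥10×
   the within-cluster SD apart — show ratios ≳2.5, while clumps carved out
   of one homogeneous cloud show ~1.2–1.5, so a homogeneous cloud is never
   split;
3. among admissible partitions the one with the most floor-sized branches
   wins; undersized branches are merged into the nearest retained branch by
   complete-linkage distance.  If nothing reaches the floor
   (minClusterSize = 100 by default) all features form one cluster, with a
   warning.

Shape labels use the four region medians in anatomical order: *increasing*
if non-strictly monotone up with at least one strict increase, *decreasing*
symmetrically, else *other*.

## Enrichment and annotation

Pre-ranked GSEA uses the classic weighted running sum (hit increments
∝ |metric|, normalized; miss decrements 1/(N − N_hits); ES = maximum signed
deviation), weight w = 1.  Ties in the ranking metric break by feature id so
the ES is deterministic.  Significance comes from gene-label permutations —
pre-ranked input has no phenotype labels to permute — with the p-value
computed within the same ES sign, NES = ES / mean(|null ES| of that sign),
and BH FDR across sets.  On tiny instances the permutation p matches
exhaustive subset enumeration (tested).  Annotation intersects per-region
quantified accessions with user-provided lists; kinome detection combines
the protein layer with the phospho layer's parent accessions.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes, at
desk scale, fully determined by one seed (independent substreams per layer).

| parameter | default | rationale |
|---|---|---|
| n_ad_brains / n_control_brains | 11 / 12 | the emulated cohort design |
| regions | HP, CA1, EC, PRC | one sample per brain per region (92 samples) |
| n_proteins / n_phospho / n_acetyl_sites | 2000 / 3000 / 220 | acetyl at the realistic scale of heavy-label experiments; protein/phospho scaled so the full pipeline runs in minutes |
| baseline | N(20, 2²) log2 units | typical label-free dynamic range |
| frac_de / effect_log2fc | 0.05 / 1.5 | clearly detectable spikes at n = 23 |
| region effect multipliers | 1.0, 0.66, 0.5, 0.25 | monotone attenuation HP → PRC, creating trajectory structure |
| sd_noise | 0.5 log2 units | biological + technical residual |
| missing_rate / mnar_strength | 0.10 / 4.0 | see below |
| age_group_shift | +6 y in AD | emulates the age imbalance such cohorts show; set to 0 in recovery benchmarks so covariates are null |
| tech_reps_phospho | 2 | replicate structure of the phospho layer |
| acetyl_noise | 0.1 (log-scale SD) | ~10% multiplicative channel noise |

**Missingness** is logistic in the latent log2 abundance:
P(missing) = expit(a − s·z) with z the standardized abundance and
s = `mnar_strength`.  The intercept *a* is solved numerically (Brent) so the
expected overall missing fraction equals `missing_rate` at every steepness —
steeper MNAR concentrates the same total dropout in low-abundance cells
rather than adding more.  The default s = 4 places missing cells ≈1.8
per-sample SDs below the sample mean, which is self-consistent with the
downshift-1.8 imputation model: the imputation assumes missing values live
exactly where this dropout model puts them.  At s = 0 dropout is uniform at
`missing_rate` (tested against the binomial SE).

Phosphopeptide latents are parent-protein latents plus a site offset
(N(−2, 1)), optional site-level group effects, biological noise and
replicate noise — so phospho-level change can differ from protein-level
change, which is what the state correction must separate.  Acetyl channels
are d0 = occupancy·T·e, d3 = (1 − occupancy)·T·e′ with log-normal e, e′ and
per-group occupancies stored as ground truth; a channel whose true share is
zero is missing, never zero.

What the generator does **not** emulate: peptide-sequence realism, shared
peptides across protein groups, batch/run-order effects, intensity-dependent
variance, and correlated missingness between the layers.  Benchmarks passing
on this generator show the pipeline's rules and statistics behave as
specified under the model's own assumptions; they do not certify performance
on real acquisitions.

## Benchmarks: what recovery the rules allow

With 2000 proteins, 50 spiked at |log2FC| = 1.5, residual SD 0.5 and 10%
MNAR missingness, the pipeline recovers ~65–72% of spiked features as
*retained* calls with a false-discovery proportion of ~5–8% (20-seed
averages; `scripts/acceptance.py` recomputes both).  The sensitivity ceiling
is a property of the workflow itself, not of the estimator:

* the covariate screen discards ~14% of true positives by chance
  (1 − 0.95³ across three univariate tests at α = 0.05);
* abundance-dependent dropout pushes low-baseline features — especially
  down-regulated ones, whose AD samples sink further into the dropout zone —
  into the 33–66% validity dead zone, where the quantitative rule excludes
  them (~15–20% of spikes at these settings);
* weakening the abundance dependence does not help: with near-uniform
  missingness the exclusions shrink, but the 1.8-SD downshifted imputation
  (≈3.7 log2 units below the column mean) lands far from randomly-missing
  mid-abundance values, destroying power on spiked features with imputed
  cells and inflating the false-discovery proportion several-fold.

This trade-off is intrinsic to combining hard validity thresholds,
left-shifted single-imputation and per-covariate exclusion at raw p < 0.05;
the test suite asserts the false-discovery bound and records the measured
sensitivity rather than an aspirational one.

## Numerical choices and degenerate inputs

* Fractions in the filter rules are exact count ratios; thresholds are
  compared with a 1e-12 guard (above).
* A sample with zero present values fails normalization; fewer than two
  present values fails imputation (SD undefined).  Constant covariates and
  constant features are warned about, never flagged.
* A constant ANOVA input (zero between- and within-group variance) reports
  F = 0, p = 1; all-zero GSEA metrics degenerate to the unweighted running
  sum.
* Seeds: every stochastic component takes an explicit integer seed;
  imputation derives per-column streams via CRC32 of the sample id, the
  generator derives per-layer streams from (seed, layer index).

## Limitations

* Regions are analyzed independently; brain-level repeated-measures
  correlation across regions is not modeled (matching the emulated design,
  which treats regions separately).
* One imputation family (downshifted normal); no kNN/MinProb alternatives.
* The tree cut is a documented behavioral variant, not an output-identical
  port of the R reference.
* No acetyl-layer trajectories: with two channels per site the missingness
  burden makes four-region occupancy profiles too sparse to be meaningful.
* The GSEA ranking metric ("which region pair") is a user choice; the CLI
  accepts any pair or a single region.
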