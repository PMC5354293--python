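# Methods

`cohortgwas` re-creates, at workstation scale, the analysis pathway used to
pool genome-wide genotype data that was collected piecemeal across many
nested case–control studies: merge studies by genotyping-platform family,
screen out duplicate samples and platform-artifact markers, impute every
dataset to a common reference panel, and run platform-stratified
association of secondary phenotypes followed by fixed-effects
meta-analysis.  This note records the models, the parameter choices, the
numerical conventions, and what the synthetic data do and do not
demonstrate.

## Synthetic cohorts (`simcohort`)

**Haplotypes.**  A reference panel is built by founder-mosaic copying:
`n_founders` (default 8) founder haplotypes are drawn site-wise from
per-marker allele frequencies ~ Uniform(0.05, 0.95); each panel haplotype
copies one founder at a time and switches to a uniformly chosen founder
between adjacent markers with probability `1 − exp(−r·d)` (`r` the mosaic
switch rate per bp, `d` the gap).  Cohort individuals are in turn mosaics
of panel haplotypes, so genotypes carry block-wise LD without a coalescent
simulation.  Monomorphic and singleton panel columns are redrawn (or
dropped), so the panel mirrors a reference release that excludes such
sites.

Defaults and why:

* mosaic switch rate `1e-5`/bp — LD correlation length ≈ 100 kb (≈ 30
  markers at the default 3 kb spacing), the scale of human array LD.  With
  much longer blocks a handful of causal variants would contaminate a
  large fraction of markers and the null-inflation diagnostics would be
  meaningless.
* marker spacing — exponential gaps, mean 3 kb for imputation-style dense
  panels; 300 kb for genome-wide relatedness panels (10,000 markers then
  span ≈ 3 Gb ≈ 30 Morgans at the 1e-8/bp crossover rate).
* `n_chromosomes` — markers can be split across chromosomes (22 for
  relatedness work); mosaic copying and meiosis restart independently at
  each chromosome boundary.

**Planted truths.**  Duplicates copy a genotype vector (optionally with a
per-genotype discordance rate); full sibs re-run meiosis (Haldane model,
1e-8 crossovers/bp) from two reconstructed parents, half sibs share one
parent; the per-marker transmission patterns are tracked so each planted
pair's *realised* (Z0, Z1, Z2) is stored in the truth ledger.  Artifact
markers are corrupted toward the alternate homozygote with a per-genotype
rate `r`, shifting the study allele frequency by `r(1−p)` per allele — the
mechanism behind real platform-specific spurious SNPs is not publicly
characterised, so this minimal directional-calling-bias model is an
assumption, chosen because it is exactly the kind of between-study
frequency shift the rotating scan is built to catch.  Every plant is recorded in a `TruthLedger`; downstream
recovery tests read only the ledger.

**Traits.**  Quantitative: `y = Σ β_j g_j + study effect + β_age·(age −
mean) + N(0, σ²)`.  Binary: logistic in a genetic score with the intercept
solved by bisection so the population mean equals the target prevalence
(default 0.072, the pooled case fraction of the rare-trait example in the
source study).  Subjects planted in several studies share one draw of age,
trait noise and case status — they are the same person observed twice,
which is precisely what makes retained duplicates inflate association
statistics.

The canned scenarios plant ten causal markers with per-allele effects of
±0.10 trait-SD.  That magnitude is calibrated to the strongest common
BMI-type association (an effect of 0.45 on a trait whose cohort SD is
≈ 4.5 units ⇒ ≈ 0.1 SD per allele): larger planted effects would be
unrealistic and, at desk scale, their LD flanks (≈ 30 markers each out of
50,000) would distort the median chi-square that the inflation
diagnostics rest on — a distortion invisible at the ~10-million-marker
scale the real analyses run at.

**What the simulator does not emulate**: genotyping intensity/clustering
error, sex chromosomes, indels, realistic human demography or allele
frequency spectra, array-specific content bias.  Passing tests therefore
demonstrate the pipeline's *logic* (filters, estimators, inflation
behaviour), not its performance on any particular real array.

## Merging (`harmonize`)

Within a platform family, a marker survives only if present in all
studies, missing in at most 5% of calls per study (strictly greater drops
it), not strand-ambiguous (A/T, C/G), and allele-consistent with the first
study, which defines the reference orientation.  Allele-order swaps are
kept with genotypes recoded `g → 2 − g`; reverse-complement matches are
strand-flipped.  Every input marker lands in exactly one MergeReport
bucket (retained / not-shared / call-rate / ambiguous / allele-mismatch).
The HWE exact test (conditional enumeration with the probability-ordering
two-sided convention, stable two-sided recurrence) is provided as an
operation but not applied during merging — per-study QC is assumed to have
done that upstream.  Monomorphic markers are retained (they carry no
signal and fall to the downstream MAF filter).

## Relatedness (`relatedness`)

Method-of-moments IBD from IBS counts.  With alt frequency `p`, `q = 1−p`:
P(IBS0|IBD0) = 2p²q², P(IBS2|IBD0) = p⁴+q⁴+4p²q², P(IBS2|IBD1) = p²+q²,
and IBD2 pairs are always IBS2.  Then `Z0 = N_IBS0 / Σ P(IBS0|IBD0)`, `Z2`
solves the IBS2 moment equation with `Z1 = 1 − Z0 − Z2` substituted, and
`Z1` is the complement — exactly unbiased given true frequencies
(verified algebraically and by simulation).  Estimates are **not clamped**:
the published duplicate window reaches Z2 = 1.1, which only a raw moment
estimate can attain.  Classification applies the printed closed windows
verbatim (duplicate → full sibling → half sib/avuncular); anything else is
unrelated when Z0 ≥ 0.85 and unclassified otherwise (the source text gives
no unrelated window and no rule for Z2 in the 0.1–0.17 gap; this
convention is ours).

Screening is exhaustive (blocked one-hot matrix products give exact IBS
and expectation sums for every pair) up to 2,000 samples; beyond that a
concordance pre-filter on 512 sampled markers shortlists duplicate
candidates at sampled concordance > 0.95 — a pair with true concordance
0.99 fails that with probability < 1e-10 — and final Z values for
shortlisted pairs always use all markers.

A caveat the tests make explicit: the realised IBD of a true sib pair
varies biologically (SD ≈ 0.06 per Z component for a 30-Morgan genome,
consistent with published realised-relatedness variability), so the
printed sibling window captures a majority but not all true sibs no matter
how many markers are typed.  Detection as *related* (which drives the
retain-but-exclude-from-PCA policy) is essentially complete; duplicate
detection is exact.

Removal policy: expected duplicates (same subject identifiers) lose one
member, chosen by a seeded RNG; unexpected duplicates lose both members
(pairs inside the duplicate window but below 0.999 concordance are treated
the same — an unexplained near-duplicate is dropped); relatives are
retained and recorded.

## Structure (`structure`)

Greedy windowed LD pruning (defaults: window 50 markers, step 5,
r² > 0.2 drops the higher-index marker; the source gives only resulting
SNP counts, so the rule is configuration).  PCA uses EIGENSTRAT
standardization — mean-centred, scaled by √(2p̂(1−p̂)), missing imputed to
the marker mean — with one member of each related pair excluded and
projected back onto the axes afterwards so every sample has covariate
values.  Decomposition: exact LAPACK SVD when the standardized matrix has
≤ 5·10⁶ entries (permutation-stable, used by all tests), randomized SVD
(7 power iterations, fixed seed, deterministic sign convention) at scale.
Outlier handling is flag-and-report at 6 SD on the top components, not
auto-removal.

## Artifact scan (`artifact_scan`)

One rotation per (cohort × primary-outcome) control set: that set becomes
pseudo-cases, all other controls pseudo-controls; primary cases never
enter.  Each rotation fits per-marker logistic regressions of pseudo-case
status on genotype with no covariates (the published QC regressions name
none; configurable upstream).  Because the predictor is 0/1/2, the 2×3
case/control-by-genotype table is sufficient, and IRLS runs on cell counts
— exact and fast enough for 50,000 markers × several rotations in
seconds.  Separation guard: |β| > 15 or 25 iterations marks the marker
non-convergent; such markers are excluded from flags and counted.  Markers
with p < 1e-8 in any rotation are flagged and removed.  Power is strongly
MAF-dependent (the frequency shift of the corruption model is `r(1−p)`):
at alt frequency ≤ 0.15 the planted 10% corruption is flagged essentially
always; near p = 0.5 it is not detectable at genome-wide stringency at
these sample sizes.

## Imputation (`impute`)

Chromosomes are tiled into chunks (default 300 markers, 30-marker flanks);
chunk cores partition the markers and stitching takes each marker from its
core owner, so output is independent of processing order.

Phasing: a greedy sequential pass runs two coupled Li–Stephens forward
recursions, assigning each heterozygous site's alt allele to the haplotype
whose one-step predictive distribution favours it; a fixed number of
leave-one-out refinement sweeps (default 3) then re-assesses every het
site against the posterior computed *without* that site's own emission.
This is deliberately far simpler than a full phasing sampler; an oracle
mode passes the simulator's true phases through so imputation accuracy can
be tested in isolation from phasing error.  Switch error on dense-panel
simulations is under 5%.

Haploid Li–Stephens copying: stay probability `exp(−ρ_eff·d)` per
inter-marker gap plus a uniform switch mass `(1−exp(−ρ_eff·d))/H`, with
`ρ_eff = ρ·4N/H` (ρ = 4e-8/bp, N = 10⁴, H = panel size — the standard
population-scaled switch rate divided among panel haplotypes); emission
1−ε on match, ε = 1e-3 on mismatch, uniform at missing sites.  Scaled
forward-backward posteriors match exhaustive path enumeration to 1e-9.

Dosage = sum of the two haplotype alt posteriors; `p̂ = mean(dosage)/2`;
quality `rsq = Var(dosage) / (2p̂(1−p̂))`, capped into [0, 1], zero at
monomorphic frequency — the standard variance-ratio form of the MACH-style
quality score (the exact internal estimator of that software is not
published to precision).  Genotyped markers pass through as hard calls
with rsq = 1 by convention and are never quality-filtered.  Analysis
filters retain MAF ≥ 0.01 and rsq ≥ 0.3 (boundaries inclusive, matching
the published "excluded <0.3 / <0.01" wording).

## Association and meta-analysis (`assoc_meta`)

Quantitative traits: OLS of the trait on dosage with intercept, study
indicators (one per cohort × primary-outcome stratum, first stratum
alphabetically as reference), age, and the top 4 PCs; genome-wide scans
use Frisch–Waugh–Lovell residualization, which is algebraically identical
to the full OLS fit (checked against a normal-equations oracle at 1e-10).
Binary traits: IRLS logistic with the same covariates minus age, Wald
tests, and the same separation guard as the scan.  p-values are two-sided
normal tails of the Wald z throughout.

Genomic control: λ = median(z²)/0.45494.  Rare-trait stability screen:
expected case minor-allele count `n_cases × MAF` ≥ 10 (per-genotype
convention, which reproduces the published "at least 200 cases at MAF
0.05" gloss; a diploid ×2 convention is available by option).

Meta-analysis: inverse-variance fixed effects (`w = 1/se²`), pooled
`se = (Σw)^{−1/2}`, Cochran's Q with k−1 df for heterogeneity, and a
per-platform direction string.  The effect-size scheme is used (pooled
effects with CIs are what the source reports); the sample-size-weighted
z-score scheme is not implemented.  Replication lookup reports found /
p < 0.05 / direction-concordant flags per known locus, with absent markers
reported rather than raised.

## Problem sizes in the shipped checks

The acceptance runs use one platform of ~6,000 samples × 50,000 markers
(null inflation) and three platforms of ~4,000 samples each over a shared
50,000-marker panel with 5% planted duplicates (meta-analysis inflation,
computed with and without removal); relationship recovery uses 200 planted
pairs at 10,000 genome-wide markers; imputation recovery a 200-haplotype,
500-marker panel with 10% of markers masked; effect-recovery coverage 100
quantitative and 20 binary replicates.  These sizes were chosen as the
smallest at which the published diagnostics are statistically meaningful
(a 50,000-marker median pins λ to ±0.01; 200 pairs resolve a 95%
sensitivity claim).

## Known limitations

* The logistic artifact scan and association use Wald inference; very
  sparse cells (rare alleles in small pseudo-case sets) are guarded but
  not replaced by exact tests.
* Statistical phasing is a fixed-sweep heuristic, not a sampler; its
  switch error (<5% on dense panels) is adequate for the imputation
  accuracy shown but would degrade on sparse panels.
* The founder-mosaic population has no demographic depth: allele
  frequencies are panel-faithful, but rare-variant architecture and
  fine-scale LD are stylized.
* O(n²) exhaustive relatedness screening is capped at 2,000 samples; the
  pre-filter path above that detects duplicates (the removal policy's
  input) but does not enumerate sib pairs cohort-wide.
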