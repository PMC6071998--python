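# Methods

This note records the statistical definitions, the numerical choices, and
the design decisions behind `girscan`, together with what the simulated
validation does and does not demonstrate.

## Statistics

### Quality control

SNP filters run in a fixed order — monomorphic, call rate, minor allele
frequency, Hardy–Weinberg heterozygosity deviation — each counting only the
SNPs that survived the previous rules, so attrition tables are reproducible.
All thresholds are strict inequalities.  The Hardy–Weinberg rule is
implemented as |observed heterozygote frequency − 2p(1−p)| > 0.15: a
"difference between expected and observed frequencies" criterion is only
computable on the heterozygosity scale, since allele frequencies themselves
have no Hardy–Weinberg expectation.  SNP filters use the pooled sample (one
QC pass before any per-population analysis); the sample call-rate filter
runs afterwards.

### Diversity and Fst

For a biallelic SNP with population frequencies p_k and observed
heterozygote frequencies Ho_k (populations weighted equally, the
hierarchical convention, since cohort sizes differ):

    Ho = mean_k Ho_k            Hs = mean_k 2 p_k (1 − p_k)
    Ht = 2 p̄ (1 − p̄)            Fst = (Ht − Hs) / Ht        Fis = 1 − Ho/Hs

The default estimator is the uncorrected gene-diversity partition exactly as
above.  `corrected=True` applies the standard small-sample corrections

    Hs_k' = n_k/(n_k−1) · (2 p_k q_k − Ho_k/(2 n_k))
    Ht'   = 2 p̄ q̄ + mean_k Hs_k'/(ñ r) − Ho/(2 ñ r)

(ñ the harmonic-mean per-locus sample size, r the number of populations).
The corrected estimator is what a practitioner's diversity package computes
and is the source of legitimately negative per-locus Fst values at
undifferentiated loci; these are clamped to zero (counted) because negative
fixation has no biological reading.  Outliers are flagged by a control
chart: Fst above the mean + 3 SD (SD with ddof = 1) of the defined Fst
values, per autosome by default, genome-wide as an option.

For drift-parameter recovery we use a separate estimator.  With two daughter
demes that drifted independently for t generations at size Ne, per-SNP
variance inflation is g = 1 − (1 − 1/(2Ne))^t, but Nei's (Ht−Hs)/Ht built
from the two demes has expectation ≈ g/(2−g) (about half g) because Ht uses
the daughters' mean frequency rather than the ancestral pool.  The
deme-count-corrected ratio

    θ = Σ (Ht − Hs) / Σ (Ht/2 + (Ht − Hs)/2)

restores the ancestral heterozygosity in the denominator (the two-deme
Weir–Cockerham construction) and has ratio-of-means expectation exactly g;
`diversity.drift_fst_from_freqs` implements it and the recovery experiments
test against the closed form.

### Structure

PCA centres the dosage matrix per SNP by the mean dosage 2p (missing calls
mean-imputed) and scales by the binomial SD √(2p(1−p)), compensating for
variance differences across allele frequencies.  Eigenvalues are those of
the sample covariance (ddof = 1); the percent variance of component i is
λᵢ·100/Σλ over *all* components.  Cluster number is chosen by K-means over
the leading PCs with BIC(K) = n·ln(WSS_K/n) + K·ln(n) (k-means++, 10
restarts, seeded) and the smallest K within 1e-9 of the minimum.  Note a
property of this BIC: the WSS term only plateaus against the K·ln(n)
penalty when the retained dimension d is large relative to n/ln(n) — with
few dimensions the curve decreases past the true K.  We therefore cluster
on ~100 PCs, the conventional choice for this style of analysis.
Discriminant functions between clusters are ordinary LDA axes on the PC
scores; at most K−1 exist, so a request for 10 functions with 2 clusters is
clamped to 1 with a warning (requesting more than K−1 is a user-facing
inconsistency we resolve rather than propagate).

### EHH, iHS, XP-EHH

EHH at marker m relative to focal SNP s is the probability that two carrier
haplotypes are identical at every marker between s and m (pair counting
over groups of identical haplotypes).  For the allele-specific cores
(ancestral = 0, derived = 1, requiring ancestral-allele recoding) carriers
share the focal allele; for the allele-agnostic site core (the iES building
block of XP-EHH) all haplotypes are carriers and identity is tracked over
the flanking markers only, so EHH(focal) = 1 holds for every curve.

A flank walk ends at (a) the first marker where EHH < 0.05 (that marker is
included, and its trapezoid enters the integral), (b) an inter-marker gap
> 20 kb (no gap rescaling — one simple documented rule), (c) the chromosome
end (flagged border-truncated, kept), or (d) a marker beyond 1 Mb from the
focal SNP.  The extent cap matches the common scan-tool default and matters
in strongly drifted or few-founder populations where haplotype homozygosity
plateaus above the floor; without it the integral is dominated by the
plateau and the scan loses both speed and contrast.  iHH is the trapezoidal
integral of EHH over physical distance (bp·EHH), flanks summed; physical
rather than genetic distance because the scan consumes the chip's physical
map.  The inner walk is compiled with numba; a test pins its exact
agreement with the pure-Python curve integration.

iHS: per SNP passing the MAF threshold (0.01), UniHS = ln(iHH_A/iHH_D)
(natural log; the standardisation makes the base immaterial) is centred and
scaled (ddof = 1) within derived-allele-frequency bins; bins with fewer
than two scored SNPs or zero spread are flagged unstandardised.  piHS =
−log10(1 − 2|Φ(iHS) − 0.5|) is computed as −log10(2Φ(−|x|)) via the log
survival function, avoiding the catastrophic cancellation that would
corrupt scores beyond |x| ≈ 6.

XP-EHH: LRiES = ln(iES_ref/iES_obs), standardised by the median and SD over
all scored SNPs (so the scan's median score is exactly 0, and swapping the
two populations negates every score).  SNPs are called at two-sided
p < 0.01 with no further multiple-testing correction.  Because the raw
log-ratio grows when the *reference* population is the more homozygous one,
yet reports conventionally attribute negative scores to the reference
population, the score-sign → population mapping is configuration
(`sign_convention`, default `negative_is_reference`), not inference.

iHS significance uses either a fixed p-value threshold (piHS cutoff =
−log10 p; e.g. p = 0.008 ↔ 2.10) or an empirical-null mode: the null
proportion η₀ estimated from the p-value mass on [0.75, 1], a decreasing
density fitted by the Grenander estimator (least concave majorant of the
ECDF), and the cutoff set at the largest p with local fdr η₀/f(p) ≤ 0.2.
With a null-like score distribution no p qualifies and the cutoff falls
below the smallest observed p-value.  This is a documented approximation
to false-non-discovery-rate cutoff selection; the exact algorithm of the
R tool conventionally used for this step is not specified by its callers.

### Candidate windows

Significant SNPs seed ±250 kb windows (clipped at position 1 and at the
chromosome length when known); windows merge within method × population so
per-method counts stay comparable.  Overlap with gene/QTL intervals is
any-overlap, 1-based inclusive on both ends; BED input is converted from
0-based half-open at the reader boundary.  Consensus genes are the union of
per-method hits annotated with their supporting method set.

### Ancestral-allele recoding

Alleles matching the annotated ancestral allele code 0 and the single other
observed allele codes 1.  If the ancestral allele is absent from the
observed alleles, the strand-flipped (complemented) ancestral allele is
tried; A/T and C/G SNPs cannot be strand-resolved and are set missing, as
are SNPs with unknown ancestral state or incompatible alleles.  A report
lists every SNP set missing with its reason.  Missing-data imputation and
phasing are out of scope: the scans require a complete phased panel and
refuse anything else.

## The simulator

`simulate.simulate_divergence` is a forward Wright–Fisher model chosen over
a coalescent because divergent selection and closed-herd mating are then
direct: a founder pool of `n_founder_haplotypes` (default 120, a narrow
base as for a breed built from a limited importation) is expanded to the
ancestral population, burnt in for 50 generations of random mating
(monoecious, selfing allowed), then split.  The split duplicates the
ancestral pool and the first post-split generation performs the resize, so
exactly `t_split` generations of drift separate each daughter from the
ancestor — this makes the closed form 1 − (1 − 1/(2Ne))^t hold without a
spurious founding bottleneck, and t_split = 0 yields byte-identical
frequencies.  Each generation: additive fitness (1, 1+s, 1+2s) at selected
loci, multinomial parent sampling, and recombination as at most one
crossover per chromosome per meiosis (map lengths here are ~0.05 Morgan;
exact Poisson counts behind `poisson_recomb`).  No new mutations after the
founders (a fixed genotyping panel); founder derived-allele frequencies are
uniform on [0.05, 0.95] to mimic array ascertainment.

Markers sit on a jittered regular grid (spacing within [0.2, 1.8]× the
mean), as on a designed array; with the default ~10 kb density no designed
gap violates the 20 kb gap rule, which uniform random placement would do
about 14 % of the time and thereby truncate most walks artefactually.
Chromosomes are scaled (5 Mb, hundreds of SNPs) so a replicate runs in
well under a second; the genome-scale quantities (marker density, map
length per chromosome) are chip-like even though totals are smaller.

Selected loci are re-seeded at the split to their configured initial
frequency on a shared local haplotype background (the carriers most similar
to a randomly chosen origin haplotype over ±10 markers): single-origin
standing variation with tight LD, the regime haplotype tests are designed
for.  A sweep lost to drift is recorded in the truth table, never raised.

What the simulator does **not** emulate: genotyping error and missingness
(panels are complete; the QC call-rate filters are exercised on hand-built
fixtures instead), overlapping generations and unequal sex numbers, a
pedigree-structured mating design beyond random mating within the closed
herd, new mutation, and real linkage-map heterogeneity.  Passing tests
therefore validate the statistics and their calibration under a clean
drift + selection model, not robustness to array artefacts.

## Validation experiments and their sizes

Problem sizes were chosen to keep the full suite within a coffee break on
one core while leaving each experiment statistically meaningful.

- **Neutral drift recovery** — 50 replicates, 2 × 300 SNPs, Ne = 100,
  t = 20: mean θ within 3 Monte-Carlo SEs of 1 − (1 − 1/200)^20 ≈ 0.0954.
- **Neutral iHS calibration** — 6 replicates, 4 × 750 SNPs, 137 samples,
  0.1-wide bins: the fraction of |iHS| > 1.96 is consistent with 5 % within
  3 MC SEs (measured ≈ 4.7 %).  The Gaussian calibration is approximate and
  runs measurably light with small haplotype samples or sparse bins, which
  is why the experiment uses cohort-scale samples.
- **Sweep recovery** — 50 replicates at s = 0.1, Ne = 200, t = 50 (8 × 750
  SNPs, 100 samples per population, sweep from frequency 0.05, detection =
  a genome-wide Fst control-chart outlier *and* a genome-wide top-1 % |iHS|
  SNP within ±250 kb of the planted locus, the candidate-window
  half-width).  Measured: Fst recovers 0.96 of replicates, iHS 0.74, joint
  0.74.  Conditional on the sweep segregating between frequencies 0.5 and
  0.95 at sampling, iHS recovery is ≈ 0.8–0.87; but under these selection
  parameters the sweep usually runs to near-fixation (median final
  frequency ≈ 0.85, ~10–15 % of replicates ≥ 0.95), exactly the regime in
  which the within-population haplotype statistic loses power by
  construction — the cross-population statistic is the designed detector
  there, and the frequency-based control chart catches nearly all of them.
  The joint ≥ 80 % target is therefore not met by the within-population
  test alone under these conditions, and the suite reports that honestly.

## Known limitations

- The empirical-null cutoff is one defensible construction of a
  local-fdr-based threshold, not a reimplementation of any specific tool's
  internals; the fixed mode exists for exact threshold correspondence.
- Per-locus Fst values at low-MAF SNPs are noisy; the control chart treats
  them like any other locus, as the original control-chart approach does.
- The EHH engine assumes complete phased panels; real data must be imputed
  and phased upstream.
- Percent-variance shares are reported over all covariance eigenvalues of
  the (centred, scaled) dosage matrix, which for n ≪ SNPs is at most n − 1
  values; shares are comparable within a run, not across cohorts of
  different size.
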