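# Methods

This note documents the models, estimators and numerical choices
behind `smallpop`, and what its synthetic-data validation does and
does not establish about real data.

## The analysis model

The package targets cohorts of diploid individuals sampled from two
small subpopulations ("demes") of one fragmented population, genotyped
genome-wide.  All statistics operate on a dense genotype container
(`GenotypeMatrix`: allele indices per call with missingness and phase
flags, plus optional per-call DP/GQ).  VCF positions are 1-based;
every internal interval computation is 0-based half-open; BED is read
natively and GFF3 CDS features are converted (GFF is 1-based closed).

### Filtering

The site protocol is applied in a fixed, logged order: biallelic →
site total-depth band (default 5–600 summed over calls) → per-call GQ
masking (calls with GQ < 30 set missing *before* the missingness test)
→ minor-allele frequency (strict `maf > maf_min`; the discovery floor
is 1e-7, analysis-grade filtering uses 0.05) → exact Hardy–Weinberg
test → site missingness (> 10% removed).  Individuals with more than
30% missing calls are then removed ("over 30%" is strict, so exactly
30% is retained), followed by one site-missingness re-pass, since
individual removal changes per-site missingness.  The HWE test is the
exact conditional (Levene) test rather than a chi-squared
approximation because the exclusion floor of 1e-50 lies in a tail
where the chi-squared approximation is meaningless; the implementation
uses the standard stable recurrence over heterozygote counts and is
tested against direct factorial enumeration.

LD pruning follows the PLINK convention: 50-SNP windows advancing by
10, r² as the squared Pearson correlation of dosages over
pairwise-complete samples, and — deliberately — *uniform-random*
removal of one SNP from each linked pair under a caller-supplied seed,
so pruning is reproducible yet unbiased with respect to position.

### Relatedness and structure

Kinship is the KING-robust between-family estimator, which conditions
on the pair's own heterozygosity and therefore remains calibrated
under population structure; degree categories use the standard
power-of-two bands (0.354, 0.177, 0.0884, 0.0442).  Distances are
1 − IBS with per-site share in {0, ½, 1}; this quantity is not
guaranteed to be a metric, so the tests assert symmetry and bounds,
not the triangle inequality.  Neighbor joining is the canonical
Q-matrix algorithm with lowest-index tie-breaking for determinism;
negative branch lengths on non-additive inputs are retained.  PCA
centers dosages by 2p̂ and scales by √(2p̂(1−p̂)) (the drift-variance,
"Patterson" normalization) by default, with plain centering available;
missing calls are mean-imputed after centering and the sign of each
component is fixed by making its largest-magnitude coordinate
positive.

### Diversity and differentiation

Per-site π is (n/(n−1))(1 − Σ p̂²) over that site's called allele
copies, which equals the mean pairwise difference among the copies
exactly — the test suite asserts this equivalence window by window
against brute-force haplotype comparison.  Windows are defined over
*variant counts* (20 SNPs, step 5) rather than base pairs, so every
window carries equal information; per-window F_ST is Weir–Cockerham θ̂
aggregated as a ratio of sums (Σa / Σ(a+b+c)) across the window's
sites, with the observed-heterozygote terms retained so the estimator
is exact under inbreeding.  Negative per-window values are reported,
not clamped.  Hudson's estimator and a mean-of-ratios aggregation are
available because different published tools aggregate differently;
reporting both makes cross-tool comparisons honest.  Expected
heterozygosity is reported without the n/(n−1) correction by default
(so He ∈ [0, 0.5] for biallelic sites, the natural range for
percentile summaries); a toggle applies the correction.  Group
summaries are medians with 2.5/97.5 percentile bounds of per-site
values.  Allelic richness uses hypergeometric rarefaction
AR = Σ_a [1 − C(N−N_a, g)/C(N, g)] at a caller-chosen grab g
(default: twice the smallest group size).

### ROH and F_ROH

Detection is the PLINK-style scanning-window heuristic: 50-SNP
windows, ≤ 1 heterozygote and ≤ 5 missing calls per window, per-SNP
hit fraction ≥ 0.05, runs assembled from qualifying homozygous SNPs
(single isolated heterozygotes inside a run are tolerated up to the
window allowance), then screened by ≥ 25 SNPs, ≥ 0.1 Mb, ≥ 1 SNP per
50 kb, and a 1 Mb maximum gap.  These parameters are exposed in full:
ROH results are parameter-conditional and must be read as such.  The
0.1 Mb minimum is the detection floor; the 0.5/1/2 Mb thresholds are
applied post hoc by `f_roh`.  The F_ROH denominator is the
SNP-covered genome (per-chromosome first-to-last retained SNP,
summed); total assembly length is selectable.  Individuals with no
qualifying ROH at a threshold are reported with F_ROH = 0 and a
`has_roh = False` flag, and group comparisons include only flagged
individuals — matching the convention of ROH box plots that drop
empty individuals.

### Tajima's D and the jackknife

D is the standard 1989 statistic over a pooled site set (typically all
MHC-CDS SNPs): π̂ summed over sites, θ_W = S/a₁, variance from the
canonical a₁…e₂ constants.  Missing data make the copy number vary by
site; π̂ and S use each site's own called copies while the constants
use the *mode* of per-site copy counts, and heterogeneous-n inputs are
flagged.  S = 0 returns an explicit undefined flag, never a silent
zero.  The 95% CI is the delete-one-individual jackknife with the
normal-theory standard error SE = √((n−1)/n · Σ(D_i − D̄)²); replicate
quantiles are a poor 95% estimator at n ≈ 17, so the percentile mode
exists but is not the default.  Replicates with no segregating sites
are dropped and counted, and the CI is flagged when more than 10%
drop.

### XP-EHH

EHH from a core site is Σ_k C(n_k,2)/C(n,2) over haplotype groups
identical from the core outward; iHH is its trapezoidal integral over
*physical* distance (no recombination map is assumed for this kind of
species), both directions summed, truncated at the first point below
EHH = 0.05 with gap (200 kb) and extension (1 Mb) guards;
XP-EHH = ln(iHH_A/iHH_B), computed from all haplotypes per population
(unpolarized), standardized in one genome-wide bin, with the empirical
5th/95th percentiles of included scores as outlier thresholds.
Negative scores mean longer haplotype homozygosity — recent selection
— in population B.  Haplotypes with missing calls in the extension
window drop out of the curve; a curve loses validity when more than 5%
drop.  Curves that run off the contig or hit a guard before decaying
below the cutoff are flagged `partial`.  Phased input is required; the
package performs no phasing.

### Comparison battery

Rank-sum and signed-rank tests use exact null distributions for n ≤ 25
without ties and the tie-corrected normal approximation with
continuity correction otherwise.  Zero paired differences are dropped
(Wilcoxon's original treatment) and counted.  "Paired" comparisons of
windowed statistics pair windows by coordinates.  Kruskal–Wallis uses
tie correction, post hocs are all pairwise rank-sum tests with
Benjamini–Hochberg adjustment.  The per-gene diversity sign-bias test
is the exact binomial at p₀ = 0.5 with zeros excluded; both the
two-sided and one-sided tails are reported because summaries of such
counts in the literature are sometimes one-sided.  These tests wrap
scipy.stats; the package's own tests verify them against exhaustive
enumeration at small n.

## The synthetic-data generator

`simulate_cohort` is a discrete-generation forward Wright–Fisher
simulation chosen over a coalescent because consanguinity and recent
selection are natural to impose forward in time.  Genotypes live on a
fixed panel of candidate sites per chromosome (default 2,000 per
5 Mb); mutation flips alleles at candidate sites with the per-bp flux
concentrated onto the panel, and recombination places Poisson
crossovers on the physical map each meiosis.  The default mutation
rate (7.5 × 10⁻⁸/bp/generation) is deliberately scaled up from
realistic vertebrate rates so that desk-scale chromosomes carry a
realistic SNP density at equilibrium; what matters for every test is
the *shape* of variation (SFS, LD, ROH structure), not the per-bp
rate.

The life cycle: burn-in at the ancestral size (default 200 diploids
for 10N generations, reaching mutation–drift equilibrium — the
neutral-control test verifies mean Tajima's D ≈ 0 across replicate
loci), then an instantaneous split implemented by *partitioning*
existing ancestral individuals into demes (no reproduction step, so
the split itself adds no deme-specific drift — this matches a
coalescent population split, and the windowed-F_ST cross-check against
an independent coalescent simulator under identical demography agrees
within the stated tolerance), then `split_generations` of separate
evolution with migration (an offspring draws both parents from the
other deme with probability m), consanguinity (with probability c an
offspring's parents are two full sibs from one family of the previous
generation — this cascades in small demes and plants the long-ROH
tail of recent inbreeding), and selection.

Balancing selection applies a heterozygote advantage at up to five
candidate sites spread across the configured block (multiplicative
across sites, an MHC-like multi-locus architecture; a single
overdominant site protects too little linked variation for a
block-level π signal to be reliable at desk scale).  The sweep is a
hard sweep: at onset the focal site is cleared and one beneficial copy
is placed on a random deme-B haplotype (re-seeded if lost, so the
sweep completes), with per-copy fitness 1+s.  Pedigree inbreeding F is
tracked exactly through the kinship-matrix recursion with the split
founders as the base population, and is emitted per individual in the
truth table together with per-deme heterozygosity trajectories,
selected-site coordinates and final frequencies.

Planting fixtures operate on any cohort: `plant_inbred_individual`
copies one haplotype over the other in non-overlapping tracts whose
total length is exactly the target fraction of the SNP-covered genome;
`plant_relative_pair` rebuilds two individuals by gamete-dropping from
founders (parent–offspring, half sibs, first cousins, unrelated,
monozygotic) and records both the expected and the realized
(founder-label IBD) kinship.  `random_hwe_cohort` generates a
linkage-free Hardy–Weinberg cohort — the clean substrate for planting
experiments, where the planted signal must be the only signal.

### What the validation scenarios are, and why

Replicated experiments use scenarios scaled for repetition on one CPU;
the sizes below are the package's validation design:

- **F_ROH recovery**: tracts planted at F ∈ {0.1, 0.25, 0.5} (0.8 Mb
  tracts) in a 20-individual HWE cohort over 2 × 5 Mb, 20 replicates;
  recovery is within ±0.05 (observed error ≲ 0.01).
- **F_ST cross-check**: ancestral 100, split 40 generations
  (0.2 × 2N) into isolated demes of 65 and 17; 16 forward replicates
  against 50 coalescent replicates, windowed mean θ̂ within ±0.05.
- **Sweep detection**: demes of 120/120 (larger than the headline
  cohort because EHH has a background identity floor ≈ the
  probability two haplotypes coalesce within a few generations, which
  in very small demes sits above the 0.05 cutoff and saturates every
  curve), recombination 5 × 10⁻⁷/bp (so the swept haplotype is long
  relative to background homozygosity and the signal localizes),
  s = 0.5 fixed within the last two-thirds of a 60-generation split;
  detection = a bottom-5% XP-EHH flag within 100 kb of the sweep
  center, in ≥ 80% of 20 replicates.
- **Balanced-block detection**: deme A of 100, 250 generations of
  maintenance, 100 kb block; block π above genome background and
  pooled block D > 0 in ≥ 80% of replicates (the weak-selection
  invariant at s = 0.05 holds for the π direction; the joint π-and-D
  criterion uses s = 0.2).
- **Calibration**: rank-sum type-I error ∈ [0.03, 0.07] over 2,000
  null replicates; jackknife CI covers the full-data D in ≥ 90% of 200
  neutral coalescent simulations at n = 40.

### What passing these tests does not show

The generator emulates genotype-level structure only: no sequencing
reads, base errors, coverage heterogeneity, genotyping bias or
phasing error (true phase is emitted; real XP-EHH runs inherit
whatever statistical phasing did to the data).  Deme sizes equal
*census* sizes of tens of individuals, so drift, background
relatedness and LD are far stronger than in any real population whose
sample is that size; absolute values of F_ST, F_ROH or EHH decay in
the default cohort are not calibrated to any real species, and the
validation shows estimator correctness and qualitative
signal-direction recovery, not field realism.  The candidate-site
mutation model allows recurrent mutation (homoplasy), which
infinite-sites data lack; at the configured θ per site its effect is
below the tolerances tested.

## Pipeline and reproducibility

`run_pipeline` executes filter → kinship → structure (on a
MAF > 0.05, LD-pruned copy; all other stages use the full filtered
set) → diversity → ROH/F_ROH → stratification → windowed π/F_ST per
region class → pooled MHC Tajima's D with jackknife → XP-EHH → the
comparison battery.  Every table carries a provenance header (package
version, SHA-256 config hash excluding the output path, root seed).
All randomness derives from the root seed through named per-stage
substreams (SHA-256 of `seed:stage`), so toggling one stage never
shifts another's draws, and a rerun with the same config and seed is
byte-identical.  A failed stage leaves partial outputs and a
machine-readable `status.json` naming the failed stage.

## Known limitations

- The scanning-window ROH caller is a heuristic, not an HMM; short-ROH
  calls near the 0.1 Mb floor depend visibly on its parameters.
- XP-EHH on demes of ≲ 40 diploids saturates (the EHH background
  floor); results on such data are reported but carry `partial` flags.
- The simulator's two-deme, single-split demography is the scope; no
  continuous geography, no overlapping generations.
- Kinship-matrix pedigree F uses the split founders as base; it
  measures inbreeding *since the split*, while F_ROH also captures
  older background IBD — the two agree only when pre-split background
  homozygosity is small (large ancestor, short history), which the
  recovery experiment's scenario ensures.
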