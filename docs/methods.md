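# Methods

This note documents the models, estimators and numerical choices
behind each pipeline stage, what the synthetic-data generator does and
does not emulate, and the design decisions taken where more than one
reasonable convention exists.

## Genotype model and conventions

Genotypes are diploid biallelic calls in {0, 1, 2} with an explicit
missing sentinel (−1); 0 is always a valid hom-ref call and never
doubles as "missing". Sites are sorted by (chromosome, position) with
1-based inclusive coordinates internally (the VCF convention); BED
exports convert to 0-based half-open. Optional per-genotype layers
carry read depth, Phred genotype quality (GQ) and (ref, alt) allele
depths. One master seed drives every stochastic stage; per-stage seeds
are derived deterministically from it (CRC-mixed `SeedSequence`), so a
full run is reproducible from a single integer.

## Quality control

Stages run in a fixed order: genotype masking → site filters → HDplot
→ thinning → site missingness → panel-specific MAF and individual
missingness. Threshold conventions follow the wording they implement:
per-genotype cuts are strict (masked when GQ < 30 *or* depth < 6, so a
call at exactly GQ 30 / depth 6 survives), missingness cuts are
inclusive (a site or individual at exactly 20% missing is dropped).

* **Site filters** remove sites with minor-allele count < 3, call rate
  < 70%, zero heterozygotes among called genotypes, or only
  heterozygotes. The latter two are paralog/null-allele pathologies
  rather than frequency filters.
* **HDplot** pools ref reads *a* and alt reads *b* across all
  heterozygous calls at a site and computes D = (a − b)/√(a + b), the
  standard-normal deviation of the pooled allele ratio from ½ under
  binomial(½) sequencing of a true heterozygote. Flagging is
  two-sided (|D| > 5): a collapsed paralog skews the ratio in
  whichever direction its fixed copy points. Sites with no
  heterozygous reads have undefined D and are retained but flagged.
* **Thinning** keeps one SNP per non-overlapping 1-kb bin (positions
  1–1000, 1001–2000, …), choosing the highest call rate, ties to the
  lowest position — deterministic and favouring downstream power.
* **Panels.** The inbreeding panel uses MAF ≥ 0.01 (computed jointly
  across all populations; a per-group option exists) and a strict 10%
  individual-missingness cut, because missingness and strict MAF
  filtering both bias F_ROH downward. The scan panel uses MAF ≥ 0.05
  and 20%, restricted to the scan populations.

A `FilterReport` logs in/removed/out counts per stage and asserts the
arithmetic reconciles.

## Local-ancestry consensus and masking

Three replicate dosage tracks per individual (different random seeds
of an upstream local-ancestry HMM) are discretized by rounding to the
nearest of {0, 1, 2}; values farther than 0.5 from all three integers
are replicate-level no-calls. A site gets a consensus dosage only when
all three replicates agree. Maximal runs of identical consensus
dosage become ancestry windows spanning first-to-last SNP position
(no extension into flanking gaps — conservative, and consistent with
the first-to-last-SNP conventions used elsewhere). Windows spanning
fewer than 1000 bp are discarded as evidence from effectively a single
RAD tag; their genotypes are *not* masked. Genotypes inside windows
containing ≥ 1 nonnative haplotype are set to missing — masking never
rewrites a retained call. Ancestry masking feeds the heterozygosity
and scan panels; ROH detection deliberately runs on the unmasked
inbreeding panel, since introgressed segments are real chromosome and
masking would punch artificial holes in runs.

## Heterozygosity

Per site with n called genotypes and alternate frequency p̂, expected
heterozygosity uses the unbiased gene diversity
h = 2p̂(1−p̂)·2n/(2n−1); `raw=True` gives plain 2p̂q̂. A population's
H_e averages over the *full shared panel* (monomorphic-within-
population sites contribute 0) so that populations are compared on one
denominator; restricting to within-population polymorphic sites would
bias small populations upward.

CIs come from a percentile bootstrap across individuals (100
iterations by default). Plain percentile intervals for gene diversity
are systematically shifted low: resampling with replacement duplicates
individuals, deflating ĥ by roughly a 1/n factor, and in simulation
the plain interval essentially never contains the point estimate. The
default therefore shifts the percentile interval by the estimated
bootstrap bias (bootstrap mean minus point estimate);
`bias_correct=False` restores the plain form. BCa is deliberately not
used.

Observed heterozygosity is reported genome-wide and in non-overlapping
5-Mb windows anchored at position 1 (bins [1, 5 Mb], (5 Mb, 10 Mb], …)
— deterministic and independent of where the first SNP happens to
fall. Group SNP counts (segregating = MAC ≥ 1 in the pooled sample)
support subsampling k populations × 100 replicates with a percentile
CI, to compare groups with unequal population numbers.

## Runs of homozygosity and F_ROH

The detector follows the PLINK `--homozyg` scheme. A 50-SNP window
slides along each chromosome; a window is a *hit* when it has ≤ 1
heterozygous and ≤ 5 missing calls. Each SNP's hit proportion (hits /
windows covering it) must reach 0.05 for run eligibility. Maximal
eligible stretches are split at inter-SNP gaps > 1 Mb and then
segmented greedily left-to-right so each reported run carries ≤ 1
heterozygote in total: when a second het would enter, the run closes
before it and a new run starts at that het. Surviving runs need
≥ 100 SNPs, ≥ 5 Mb span and ≤ 50 kb per SNP. The four explicitly
configured values (window 50, 1 het, 5 missing, 5 Mb) are the
pipeline's standard settings; the remaining four default to the PLINK
v1.9 values they would take there, and all eight live in `ROHParams`.

Run length is end − start (first-to-last SNP), matching the
denominator's convention: detectable autosomal length is the summed
first-to-last-SNP span per chromosome, so numerator and denominator
use the same measure. F_ROH(>L) sums runs strictly longer than L.
"Autosomal" defaults to every chromosome; sex-linked chromosomes can
be excluded by name. The detector is RNG-free, and on small inputs it
is verified segment-for-segment against an exhaustive plain-loop
implementation of the same rules.

The F_ROH analysis is meant to run on one shared SNP panel across all
populations: severely bottlenecked populations are monomorphic
precisely where they are identical by descent, so within-population
SNP sets cannot see their runs.

## Weir–Cockerham F_ST

Per locus, the 1984 variance components a (among populations), b
(among individuals within populations) and c (within individuals) are
computed from diploid genotype counts — the observed heterozygosity
term h̄ enters explicitly, so the heterozygote deficits typical of
small inbred populations are handled as in the original estimator,
not via a haploid allele-count shortcut. The multi-locus estimate is
the ratio of sums Σa / Σ(a+b+c), never a mean of per-locus ratios.
Loci are drawn once, without replacement (default 10,000), and the
same subset serves every pair in a matrix. Negative estimates are
reported as computed (a clamp flag exists), preserving estimator
properties under averaging.

## Covariance-aware genome scan

**Model.** SNP i in population j has observed frequency p̂_ij around
an ancestral frequency π_i, with standardized residuals
r_ij = (p̂_ij − π̂_i)/√(π̂_i(1−π̂_i)). The J×J covariance Ω of these
residuals captures shared drift (population structure). Ω is
moment-estimated: π̂_i is the across-population mean, Ω̂ the across-SNP
covariance of residual vectors, debiased by subtracting each
population's expected binomial sampling contribution
1/(harmonic-mean called allele count) from the diagonal, and projected
to the nearest positive semi-definite matrix if the subtraction
overshoots. Because π̂_i is the per-SNP mean, residuals sum exactly to
zero across populations: Ω̂ has one (near-)null direction, the
inverse is a truncated pseudo-inverse (relative eigenvalue cutoff
10⁻³), and the null XtX distribution is approximately χ² with J − 1
degrees of freedom, inflated by residual binomial noise. This is an
explicit design choice: a deterministic moment fit instead of MCMC,
preserving the inference targets (XtX ranks, POD quantiles, BF
thresholds) at a fraction of the cost.

**XtX and POD calibration.** XtX = r′Ω̂⁻r is a Mahalanobis
differentiation measure — a SNP-specific F_ST analogue corrected for
structure. Because its null distribution depends on J, sample sizes
and the noise level, significance thresholds are *always* re-derived
empirically: a pseudo-observed dataset draws π ~ Beta(â, b̂) (moment
fit to the observed π̂ distribution), population frequencies
π + √(π(1−π))·ε with ε ~ MVN(0, Ω̂) truncated to (0,1), and binomial
allele counts at each population's harmonic-mean sample size; XtX
recomputed on the POD through the identical standardization pipeline
yields the 99th (significant) and 99.99th (stringent) percentile
thresholds. Printed threshold values from any particular dataset are
properties of that dataset, not constants.

**Bayes factors.** For a standardized population covariate z, the
effect model is r = βz + MVN(0, Ω̂ + D), D the diagonal binomial-noise
term at harmonic-mean sample sizes (held constant across SNPs within
a scan — per-SNP sample-size variation is second-order). β has a
uniform prior on [−0.3, 0.3] (width exposed), integrated on a fixed
201-point grid; the log-likelihood is quadratic in β so the grid is
exact to quadrature error. Evidence is reported in decibans
(10·log₁₀ BF), ≥ 20 dB decisive; the posterior-mean β̂ on the grid is
returned. Standardizing z makes the BF invariant to affine trait
rescaling. A secondary Pearson correlation between raw trait values
and population frequencies is reported per SNP as a structure-naive
cross-check. Candidates require both the POD 1% XtX threshold *and*
≥ 20 dB for at least one trait; stringent-XtX-only outliers (99.99th
percentile, no decisive BF) are reported separately.

## Synthetic data

The generator is a forward-in-time diploid Wright–Fisher simulation
with recombination over *founder-labeled* haplotypes: every founding
haplotype carries a unique label and descendants are breakpoint
mosaics of founder segments. True autozygosity is then exact — the
genome fraction where an individual's two haplotypes share a label, in
segments above a cutoff (reported at 0 and at the 5-Mb F_ROH cutoff
for like-for-like recovery tests). Mating is random union of gametes
with selfing allowed, so expected inbreeding follows
F_t = 1/(2N) + (1 − 1/(2N))F_{t−1}, which the simulator reproduces
within Monte-Carlo error on a closed N = 2 line. Crossovers are
Poisson at 10⁻⁸ per bp per generation (1 cM/Mb, no interference);
chromosomes assort freely.

Founder alleles are standing variation: per-site ancestral frequencies
from Beta(0.4, 0.4) clipped to [0.01, 0.99] (a vaguely U-shaped
spectrum), founder haplotypes Bernoulli draws. No mutation occurs
during the simulated epoch, no selection acts, and genotypes have no
error by default — errors, depth and paralog artifacts enter only
through the read-layer stage below.

**Default genome:** 5 chromosomes × 25 Mb, ~20,000 SNPs (≈160
SNPs/Mb — the same order as a dense RADseq panel) — big enough for
many ≥ 5 Mb windows per chromosome, small enough that a full
recovery experiment runs in seconds per seed.

**Presets.** Generation counts for real bottlenecks are unknown
(anywhere from tens to thousands of generations), so the presets fix
qualitative regimes and expose every epoch as a parameter:

| preset | epochs (gens, N), past → present | regime |
|---|---|---|
| `connected` | (20, 1000) | high diversity, F ≈ 0 |
| `recent_bottleneck` | (10, 300), (12, 20), (1, 60) | high background H_e, strong recent inbreeding |
| `historic_bottleneck` | (15, 15), (15, 250) | low H_e, little recent inbreeding |
| `double_bottleneck` | (10, 25), (8, 150), (15, 10), (1, 60) | low H_e and high, variable inbreeding |

Populations are independent by default; an optional shared-epoch
prefix gives groups of populations correlated drift (hierarchical
structure for Ω tests), and a per-offspring migration probability is
available.

**Artifacts.** `inject_nonnative_tracts` replaces exponential-length
haplotype segments (mean 2 Mb, ≥ 100 kb) with draws from a divergent
donor frequency profile until ~5% of an admixed individual's genome is
replaced (admixed individuals stay > 95% native); tracts are recorded
in the truth, and noise-free or noisy replicate dosage tracks can be
emitted for the masking stage. `simulate_read_layers` draws
Poisson(depth) reads, Binomial(depth, ½) het allele splits,
GQ = min(99, 5·depth), and for a chosen fraction of sites merges
reads from a duplicated copy fixed for the reference allele,
re-calling genotypes from merged reads — inflating apparent
heterozygosity and skewing het ratios toward 3:1, the HDplot
signature. `generate_population_traits` builds population covariates
as effect × causal-locus frequency sums plus Gaussian noise, and a
lighter frequency-level generator (`simulate_drift_panel`) produces
independent-drift count panels with an optional causal cline (drift
variance 0.05 on the standardized scale — moderate differentiation —
and a causal amplitude giving frequency–trait r ≈ 0.93) for scan
calibration and power experiments.

**What passing tests do and do not show.** The generator reproduces
the statistical structure the methods assume: clean biallelic calls,
IBD-driven homozygosity, independent-drift or hierarchical frequency
covariance, binomial read sampling. Real RADseq data additionally
carry linked selection, allele dropout, batch effects, reference
bias, genotyping-model error and uncalibrated GQ — none of which are
emulated. Recovery results on synthetic panels therefore validate the
*implementations* and their calibration logic, not robustness to
every field artifact.

## Benchmark problem sizes

The packaged experiments (`rohscan.experiments`, also driven by
`scripts/acceptance.py`) use: F_ROH recovery on `double_bottleneck`
with 50 individuals × 5 seeds at the default genome; scan calibration
and power at J = 10 populations × 20,000 SNPs per seed with 50,000-SNP
PODs (5 and 10 seeds); masking repair on two `recent_bottleneck`
populations × 15 individuals at 6,000 SNPs × 10 seeds; HDplot rates at
60 individuals × 1,250 sites, depth 50, 20% paralogs. These sizes were
chosen so each experiment's Monte-Carlo error is small against the
margins being tested while the whole battery completes in about half a
minute.

## Known limitations

* The scan's Ω is a moment estimate; an MCMC refinement (as in full
  Bayesian implementations) would propagate π uncertainty and handle
  very small J better. With J < ~5 the moment fit is noisy.
* Bayes factors use a constant binomial-noise term per scan
  (harmonic-mean sample sizes); SNPs with extreme missingness get
  slightly mis-scaled evidence.
* The ROH caller's greedy het-budget segmentation is one deterministic
  resolution of an ambiguity the window rules leave open; the
  brute-force oracle pins this exact rule.
* The forward simulator keeps whole populations in memory as segment
  lists; it is built for desk-scale parameters (N up to a few
  thousand, tens of generations), not deep coalescent-scale histories.
* Individual-level trait association is out of scope: traits are
  population-level covariates throughout.
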