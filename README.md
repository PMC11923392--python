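# rohscan

Genomic inbreeding and adaptive-divergence analysis for isolated
populations, built for conservation genomicists weighing *genetic
rescue*: translocating individuals into small, inbred populations
carries a trade-off between relieving inbreeding depression and
disrupting local adaptation (outbreeding depression). Quantifying both
sides needs the same SNP panel analysed two ways — genome-wide
inbreeding coefficients on one hand, trait-associated outlier loci on
the other. `rohscan` implements that full pipeline for diploid
biallelic SNP data (e.g., RADseq panels from stream-dwelling
salmonids), plus a forward simulator with exact identity-by-descent
truth so every stage is verifiable without any external dataset.

## What it computes

**Runs of homozygosity and F_ROH.** A sliding window of 50 SNPs
(≤ 1 heterozygous, ≤ 5 missing calls per window) detects homozygous
runs per individual; runs must span ≥ 5 Mb and ≥ 100 SNPs. The
inbreeding coefficient is

F_ROH(>L) = Σ length(ROH > L) / detectable autosomal length,

where the denominator sums each chromosome's first-to-last-SNP span.
Cutoffs at 5, 10 and 20 Mb separate recent from older inbreeding.

**Expected heterozygosity.** Per population, the unbiased gene
diversity ĥ = 2p̂(1−p̂)·2n/(2n−1) averaged over the shared panel, with
percentile-bootstrap 95% CIs over individuals; observed heterozygosity
genome-wide and in non-overlapping 5-Mb windows.

**Weir–Cockerham F_ST.** Pairwise multi-locus θ from the 1984
among-population / among-individual / within-individual variance
components (a, b, c), computed from diploid genotype counts and
combined as Σa / Σ(a+b+c) over a random 10,000-locus subset.

**Covariance-aware genome scan.** Population allele frequencies are
modelled around a per-SNP ancestral frequency with a J×J covariance Ω
capturing shared drift. Per SNP, XtX = r′Ω⁻r (a covariance-corrected,
SNP-specific F_ST analogue) with significance thresholds taken from
the 99th / 99.99th percentiles of a pseudo-observed dataset (POD)
simulated from the fitted neutral model — never from fixed constants.
Association of SNPs with population-level traits (e.g., maximum fish
length, age-1 length, age-1→2 growth) is scored by Bayes factors in
decibans (10·log₁₀ BF; ≥ 20 dB decisive) for a linear allele-frequency
effect, with Pearson frequency–trait correlations as a secondary,
structure-naive check. Candidate loci must clear both the POD 1% XtX
threshold and 20 dB.

**Quality control.** GQ < 30 / depth < 6 genotype masking, minor
allele count ≥ 3, ≥ 70% site call rate, heterozygote-pathology
removal, the HDplot paralog screen (pooled het read-ratio z-score
D = (a−b)/√(a+b), |D| > 5 flagged), one SNP per kb, and the two panel
branches (MAF ≥ 0.01 + 10% individual missingness for inbreeding;
MAF ≥ 0.05 + 20% for the scan). Replicate local-ancestry dosage
tracks are consensus-discretized, turned into contiguous ancestry
windows (< 1 kb discarded), and genotypes inside nonnative windows
are masked.

**Synthetic data.** A forward Wright–Fisher simulator over
founder-labeled haplotypes gives *exact* autozygosity truth, with four
demographic presets (connected, recent bottleneck, historic
bottleneck, double bottleneck), nonnative-tract injection from a
divergent donor, read-depth/paralog artifact layers, and
trait-driving allele-frequency clines. See `docs/methods.md`.

## Worked example

```python
from rohscan import sim, diversity, fst, roh

scenario = sim.recent_bottleneck(n_pops=2)       # 5 x 25 Mb, ~20k SNPs
gm, truth = sim.simulate_populations(scenario, n_sampled_per_pop=15, seed=42)

for pop in gm.population_labels:
    he, _ = diversity.expected_het(gm, pop)
    lo, hi = diversity.bootstrap_he_ci(gm, pop, seed=42)
    print(f"{pop}: He = {he:.3f} (95% CI {lo:.3f}-{hi:.3f})")

table, segments = roh.inbreeding_table(gm)
print(table.groupby("population")["froh_gt_5mb"].mean().round(3))

theta = fst.wc_fst(gm, "pop1", "pop2", n_loci=10_000, seed=42)
print(f"pairwise Weir-Cockerham theta = {theta:.3f}")
```

prints

```
pop1: He = 0.156 (95% CI 0.147-0.165)
pop2: He = 0.160 (95% CI 0.149-0.168)
pop1    0.230
pop2    0.307
pairwise Weir-Cockerham theta = 0.301
```

Both populations keep moderate background diversity (H_e ≈ 0.16) yet
carry high recent inbreeding (mean F_ROH(>5 Mb) of 0.23–0.31) — the
signature of a strong recent bottleneck on a formerly large
population — and have already drifted far apart (θ ≈ 0.30). The
simulator's truth confirms the inbreeding estimate: mean true
autozygosity in ≥ 5 Mb segments is 0.266 versus a mean F_ROH(>5 Mb)
of 0.269.

The same stages are available as a CLI whose subcommands compose:

```bash
rohscan sim --preset double_bottleneck --n-pops 1 --n-per-pop 20 --out-dir sim/
rohscan qc  --vcf sim/simulated.vcf --popmap sim/popmap.tsv --out-dir qc/
rohscan roh --vcf qc/inbreeding_panel.vcf --popmap sim/popmap.tsv --out-dir roh/
```

plus `mask`, `diversity`, `fst` and `scan` (the latter takes a traits
TSV; a packaged example table for ten isolated trout populations ships
with the package, see `rohscan.load_example_traits()`).

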