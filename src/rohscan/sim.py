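"""Synthetic multi-population SNP panels with known truth.

The generator runs a forward-in-time diploid Wright-Fisher simulation
with recombination over *founder-labeled* haplotypes: every founding
haplotype carries a unique label, and each descendant haplotype is a
mosaic of founder segments.  Autozygosity truth is therefore exact —
an individual is autozygous wherever its two haplotypes carry the same
founder label — which is precisely the identity-by-descent quantity
that runs-of-homozygosity detection tries to recover.  Mating is
random union of gametes (selfing allowed), so pedigree inbreeding
follows the classical recursion F_t = 1/(2N) + (1 - 1/(2N)) F_{t-1}.

Four demographic presets emulate the qualitative histories the
analysis distinguishes: ``connected`` (large stable N, high diversity),
``recent_bottleneck`` (high background diversity, strong recent
inbreeding), ``historic_bottleneck`` (old diversity loss, little
recent inbreeding) and ``double_bottleneck`` (both).  Mutation during
the simulated epoch is not modelled: variation is standing variation
carried by the founders.

On top of the base panel the module injects the artifacts the QC
stages must handle: nonnative ancestry tracts copied from a divergent
donor allele-frequency profile, read-depth/genotype-quality layers
with collapsed-paralog sites, and population-level traits driven by
causal allele-frequency clines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

# one haplotype on one chromosome: (segment start positions, founder labels);
# starts[0] == 1, segment i spans [starts[i], starts[i+1] - 1]
Hap = tuple[np.ndarray, np.ndarray]

DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = tuple(
    (f"chr{i + 1}", 25_000_000) for i in range(5)
)


@dataclass
class DemographyScenario:
    """One population-set demographic history.

    ``epochs`` runs past to present as (generations, N) spans; the
    population is founded by N unrelated individuals at the start of
    the first epoch.  ``shared_epochs`` optionally prefixes a common
    drift phase for every population in a ``groups`` entry, producing
    correlated allele frequencies (hierarchical structure); populations
    not listed in any group evolve independently from their own
    founders.  ``migration_rate`` is the per-offspring probability that
    a parent is drawn from another random population.
    """

    name: str
    n_pops: int
    epochs: list[tuple[int, int]]
    chromosomes: tuple[tuple[str, int], ...] = DEFAULT_CHROMOSOMES
    recomb_rate: float = 1e-8  # crossovers / bp / generation
    target_snps: int = 20_000
    freq_beta: tuple[float, float] = (0.4, 0.4)
    migration_rate: float = 0.0
    shared_epochs: list[tuple[int, int]] | None = None
    groups: list[list[int]] | None = None
    truth_cutoffs: tuple[int, ...] = (0, 5_000_000)

    def __post_init__(self) -> None:
        for gens, n in self.epochs:
            if n < 1:
                raise ValueError("population size must be >= 1 in every epoch")
            if gens < 0:
                raise ValueError("epoch lengths must be >= 0")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def final_n(self) -> int:
        return self.epochs[-1][1]

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------
def connected(n_pops: int = 2, n: int = 1000, gens: int = 20, **kw) -> DemographyScenario:
    """Large stable populations: high diversity, negligible inbreeding."""
    return DemographyScenario("connected", n_pops, [(gens, n)], **kw)


def recent_bottleneck(n_pops: int = 2, **kw) -> DemographyScenario:
    """High background diversity with a strong recent bottleneck."""
    return DemographyScenario(
        "recent_bottleneck", n_pops, [(10, 300), (12, 20), (1, 60)], **kw
    )


def historic_bottleneck(n_pops: int = 2, **kw) -> DemographyScenario:
    """Old diversity-eroding bottleneck followed by recovery: low
    variation, modest recent inbreeding."""
    return DemographyScenario(
        "historic_bottleneck", n_pops, [(15, 15), (15, 250)], **kw
    )


def double_bottleneck(n_pops: int = 1, **kw) -> DemographyScenario:
    """Historic and recent bottlenecks stacked: low diversity and high,
    variable inbreeding — the most severe preset."""
    return DemographyScenario(
        "double_bottleneck", n_pops, [(10, 25), (8, 150), (15, 10), (1, 60)], **kw
    )


PRESETS = {
    "connected": connected,
    "recent_bottleneck": recent_bottleneck,
    "historic_bottleneck": historic_bottleneck,
    "double_bottleneck": double_bottleneck,
}


# ----------------------------------------------------------------------
# truth bookkeeping
# ----------------------------------------------------------------------
@dataclass
class SimTruth:
    """Ground truth carried alongside a simulated panel."""

    # cutoff (bp) -> per-individual autozygous genome fraction
    true_autozygosity: dict[int, np.ndarray] = field(default_factory=dict)
    # individual -> list of (chrom, start, end, ancestry, haplotype)
    tracts: dict[str, list[tuple[str, int, int, str, int]]] = field(
        default_factory=dict
    )
    # list of (site index, {trait: effect})
    causal_loci: list[tuple[int, dict[str, float]]] = field(default_factory=list)
    trait_values: pd.DataFrame | None = None
    # site indices whose read layers were merged with a duplicated locus
    paralog_sites: np.ndarray | None = None

    def tract_fraction(self, individual: str, genome_length: int) -> float:
        """Genome fraction covered by this individual's recorded tracts
        (haplotype-weighted: a one-haplotype tract covers half weight)."""
        tracts = self.tracts.get(individual, [])
        covered = sum((end - start + 1) for _, start, end, _, _ in tracts)
        return covered / (2 * genome_length)


# ----------------------------------------------------------------------
# forward Wright-Fisher machinery
# ----------------------------------------------------------------------
def _founder_individual(label_counter: list[int], n_chrom: int) -> list[tuple[Hap, Hap]]:
    # founders carry one label per haplotype reused across chromosomes;
    # chromosomes assort freely, so within-chromosome IBD logic is unaffected
    l1 = label_counter[0]
    l2 = label_counter[0] + 1
    label_counter[0] += 2
    hap1 = (np.array([1], dtype=np.int64), np.array([l1], dtype=np.int64))
    hap2 = (np.array([1], dtype=np.int64), np.array([l2], dtype=np.int64))
    return [(hap1, hap2)] * n_chrom  # shared tuples; copied on recombination


def _recombine(hap_a: Hap, hap_b: Hap, xos: np.ndarray, first: int, length: int) -> Hap:
    """Gamete from two parental haplotypes with crossovers at ``xos``."""
    haps = (hap_a, hap_b)
    cur = first
    bounds = np.concatenate(([1], xos, [length + 1]))
    starts: list[int] = []
    labels: list[int] = []
    for k in range(bounds.size - 1):
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        s, l = haps[cur]
        i = int(np.searchsorted(s, lo, side="right")) - 1
        while i < s.size and (s[i] < hi):
            seg_start = max(int(s[i]), lo)
            lab = int(l[i])
            if labels and labels[-1] == lab:
                pass  # merge with previous segment
            else:
                starts.append(seg_start)
                labels.append(lab)
            i += 1
        cur ^= 1
    return (
        np.asarray(starts, dtype=np.int64),
        np.asarray(labels, dtype=np.int64),
    )


def _meiosis(
    ind: list[tuple[Hap, Hap]],
    chrom_lengths: list[int],
    rate: float,
    rng: np.random.Generator,
) -> list[Hap]:
    gamete: list[Hap] = []
    for c, length in enumerate(chrom_lengths):
        hap_a, hap_b = ind[c]
        k = rng.poisson(rate * length)
        first = int(rng.integers(2))
        if k == 0:
            gamete.append((hap_a, hap_b)[first])
        else:
            xos = np.unique(rng.integers(2, length + 1, size=k))
            gamete.append(_recombine(hap_a, hap_b, xos, first, length))
    return gamete


def _wf_epochs(
    pop: list[list[tuple[Hap, Hap]]],
    epochs: list[tuple[int, int]],
    chrom_lengths: list[int],
    rate: float,
    rng: np.random.Generator,
) -> list[list[tuple[Hap, Hap]]]:
    for gens, n_next in epochs:
        for _ in range(gens):
            parents = rng.integers(len(pop), size=(n_next, 2))
            pop = [
                [
                    (g1c, g2c)
                    for g1c, g2c in zip(
                        _meiosis(pop[p1], chrom_lengths, rate, rng),
                        _meiosis(pop[p2], chrom_lengths, rate, rng),
                    )
                ]
                for p1, p2 in parents
            ]
        if len(pop) != n_next:  # epoch with 0 generations: resize by drawing
            parents = rng.integers(len(pop), size=(n_next, 2))
            pop = [
                [
                    (g1c, g2c)
                    for g1c, g2c in zip(
                        _meiosis(pop[p1], chrom_lengths, rate, rng),
                        _meiosis(pop[p2], chrom_lengths, rate, rng),
                    )
                ]
                for p1, p2 in parents
            ]
    return pop


def _wf_epochs_multi(
    pops: list[list[list[tuple[Hap, Hap]]]],
    epochs: list[tuple[int, int]],
    chrom_lengths: list[int],
    rate: float,
    migration: float,
    rng: np.random.Generator,
) -> list[list[list[tuple[Hap, Hap]]]]:
    """Joint lock-step evolution of several populations with symmetric
    migration: each parent is foreign with probability ``migration``."""
    n_pops = len(pops)
    for gens, n_next in epochs:
        steps = gens if gens > 0 else (1 if len(pops[0]) != n_next else 0)
        for _ in range(steps):
            new_pops = []
            for j in range(n_pops):
                inds = []
                for _ in range(n_next):
                    gametes = []
                    for _ in range(2):
                        jj = j
                        if n_pops > 1 and rng.random() < migration:
                            jj = int(rng.integers(n_pops - 1))
                            jj = jj if jj < j else jj + 1
                        parent = pops[jj][int(rng.integers(len(pops[jj])))]
                        gametes.append(
                            _meiosis(parent, chrom_lengths, rate, rng)
                        )
                    inds.append(list(zip(gametes[0], gametes[1])))
                new_pops.append(inds)
            pops = new_pops
    return pops


def _autozygous_runs(hap1: Hap, hap2: Hap, length: int) -> list[tuple[int, int]]:
    """Intervals [start, end] where the two haplotypes share a founder label."""
    s1, l1 = hap1
    s2, l2 = hap2
    bounds = np.union1d(s1, s2)
    ends = np.concatenate((bounds[1:] - 1, [length]))
    i1 = np.searchsorted(s1, bounds, side="right") - 1
    i2 = np.searchsorted(s2, bounds, side="right") - 1
    same = l1[i1] == l2[i2]
    runs: list[tuple[int, int]] = []
    for k in range(bounds.size):
        if not same[k]:
            continue
        start, end = int(bounds[k]), int(ends[k])
        if runs and runs[-1][1] + 1 == start:
            runs[-1] = (runs[-1][0], end)
        else:
            runs.append((start, end))
    return runs


def true_autozygosity(
    individual: list[tuple[Hap, Hap]],
    chrom_lengths: list[int],
    cutoff: int,
) -> float:
    """Fraction of the genome in same-founder-label segments >= cutoff."""
    total = 0
    for c, length in enumerate(chrom_lengths):
        hap1, hap2 = individual[c]
        for start, end in _autozygous_runs(hap1, hap2, length):
            run = end - start + 1
            if run >= cutoff:
                total += run
    return total / sum(chrom_lengths)


# ----------------------------------------------------------------------
# panel generation
# ----------------------------------------------------------------------
def _draw_sites(
    scenario: DemographyScenario, rng: np.random.Generator
) -> pd.DataFrame:
    genome = scenario.genome_length
    rows = []
    for name, length in scenario.chromosomes:
        k = int(round(scenario.target_snps * length / genome))
        pos = np.sort(
            rng.choice(np.arange(1, length + 1), size=k, replace=False)
        )
        rows.append(pd.DataFrame({"chrom": name, "pos": pos}))
    sites = pd.concat(rows, ignore_index=True)
    sites["ref"] = "A"
    sites["alt"] = "G"
    return sites


def simulate_populations(
    scenario: DemographyScenario,
    n_sampled_per_pop: int,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate the scenario and sample genotypes plus exact truth.

    Deterministic given ``seed``.  Raises if more individuals are
    requested than the final population size.
    """
    if n_sampled_per_pop > scenario.final_n:
        raise ValueError(
            f"cannot sample {n_sampled_per_pop} from final N={scenario.final_n}"
        )
    rng = np.random.default_rng(seed)
    chrom_lengths = [length for _, length in scenario.chromosomes]
    sites = _draw_sites(scenario, rng)
    label_counter = [0]

    # drift each population (optionally with a shared-group prefix)
    group_of = {}
    if scenario.groups:
        for g, members in enumerate(scenario.groups):
            for m in members:
                group_of[m] = g
    group_states: dict[int, list[list[tuple[Hap, Hap]]]] = {}
    starts: list[list[list[tuple[Hap, Hap]]]] = []
    for j in range(scenario.n_pops):
        g = group_of.get(j)
        if g is not None and scenario.shared_epochs:
            if g not in group_states:
                n0 = scenario.shared_epochs[0][1]
                base = [
                    _founder_individual(label_counter, len(chrom_lengths))
                    for _ in range(n0)
                ]
                group_states[g] = _wf_epochs(
                    base,
                    scenario.shared_epochs,
                    chrom_lengths,
                    scenario.recomb_rate,
                    rng,
                )
            starts.append(list(group_states[g]))
        else:
            n0 = scenario.epochs[0][1]
            starts.append(
                [
                    _founder_individual(label_counter, len(chrom_lengths))
                    for _ in range(n0)
                ]
            )
    if scenario.migration_rate > 0:
        pops = _wf_epochs_multi(
            starts,
            scenario.epochs,
            chrom_lengths,
            scenario.recomb_rate,
            scenario.migration_rate,
            rng,
        )
    else:
        pops = [
            _wf_epochs(
                start,
                scenario.epochs,
                chrom_lengths,
                scenario.recomb_rate,
                rng,
            )
            for start in starts
        ]

    n_founder_haps = label_counter[0]

    # ancestral allele frequencies shared by all founder pools
    a, b = scenario.freq_beta
    p_anc = np.clip(rng.beta(a, b, size=len(sites)), 0.01, 0.99)
    founder_alleles = (
        rng.random((n_founder_haps, len(sites))) < p_anc
    ).astype(np.int8)

    pos_by_chrom = {
        name: sites.loc[sites["chrom"] == name, "pos"].to_numpy()
        for name, _ in scenario.chromosomes
    }
    col_by_chrom = {
        name: np.flatnonzero(sites["chrom"].to_numpy() == name)
        for name, _ in scenario.chromosomes
    }

    individual_ids: list[str] = []
    populations: list[str] = []
    calls = np.empty((scenario.n_pops * n_sampled_per_pop, len(sites)), dtype=np.int8)
    truth = SimTruth()
    auto = {cut: [] for cut in scenario.truth_cutoffs}
    row = 0
    for j, pop in enumerate(pops):
        pick = rng.choice(len(pop), size=n_sampled_per_pop, replace=False)
        for k, idx in enumerate(pick):
            ind = pop[idx]
            ind_id = f"pop{j + 1}_ind{k + 1}"
            individual_ids.append(ind_id)
            populations.append(f"pop{j + 1}")
            for c, (name, length) in enumerate(scenario.chromosomes):
                cols = col_by_chrom[name]
                positions = pos_by_chrom[name]
                g = np.zeros(cols.size, dtype=np.int8)
                for hap in ind[c]:
                    starts, labels = hap
                    seg = np.searchsorted(starts, positions, side="right") - 1
                    g += founder_alleles[labels[seg], cols]
                calls[row, cols] = g
            for cut in scenario.truth_cutoffs:
                auto[cut].append(true_autozygosity(ind, chrom_lengths, cut))
            row += 1
    truth.true_autozygosity = {
        cut: np.asarray(vals) for cut, vals in auto.items()
    }
    gm = GenotypeMatrix(
        individual_ids=individual_ids,
        populations=np.asarray(populations, dtype=object),
        sites=sites,
        calls=calls,
    )
    return gm, truth


# ----------------------------------------------------------------------
# nonnative admixture tracts
# ----------------------------------------------------------------------
def inject_nonnative_tracts(
    gm: GenotypeMatrix,
    truth: SimTruth,
    donor_divergence: float | np.ndarray = 0.8,
    mean_tract_bp: float = 2_000_000,
    fraction_admixed: float = 0.3,
    admixed_genome_fraction: float = 0.05,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Replace haplotype segments of some individuals with donor draws.

    ``donor_divergence`` is either a per-site donor alternate-allele
    frequency array or a scalar offset applied away from the panel's
    own frequency (a divergent congeneric donor).  Each admixed
    individual receives exponential-length tracts (on one random
    haplotype each) until about ``admixed_genome_fraction`` of its
    genome is replaced; the default keeps admixed individuals above
    95% native ancestry.  Tract intervals are recorded in the truth.
    """
    if not 0 <= fraction_admixed <= 1:
        raise ValueError("fraction_admixed must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = gm.copy()
    truth = replace(truth, tracts=dict(truth.tracts))
    if fraction_admixed == 0:
        return out, truth

    p_panel = gm.alt_allele_freq()
    if np.isscalar(donor_divergence):
        shift = float(donor_divergence)
        donor_p = np.where(
            np.nan_to_num(p_panel, nan=0.5) < 0.5,
            np.nan_to_num(p_panel, nan=0.5) + shift,
            np.nan_to_num(p_panel, nan=0.5) - shift,
        )
        donor_p = np.clip(donor_p, 0.01, 0.99)
    else:
        donor_p = np.asarray(donor_divergence, dtype=float)
        if donor_p.shape != (gm.n_sites,):
            raise ValueError("donor frequency array must have one entry per site")

    chroms = [(c, int(gm.sites.loc[gm.sites["chrom"] == c, "pos"].max()))
              for c in gm.chromosomes()]
    # use SNP spans as a proxy for chromosome length when true lengths
    # are unknown; injection only touches genotyped sites anyway
    genome = sum(length for _, length in chroms)
    chrom_all = gm.sites["chrom"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy()

    n_adm = int(round(fraction_admixed * gm.n_individuals))
    admixed = rng.choice(gm.n_individuals, size=n_adm, replace=False)
    for i in admixed:
        ind_id = gm.individual_ids[i]
        tracts = list(truth.tracts.get(ind_id, []))
        occupied: dict[tuple[str, int], list[tuple[int, int]]] = {}
        target = admixed_genome_fraction * 2 * genome
        placed = 0
        tries = 0
        while placed < target and tries < 200:
            tries += 1
            ci = int(rng.choice(len(chroms), p=[l / genome for _, l in chroms]))
            cname, clen = chroms[ci]
            length = max(int(rng.exponential(mean_tract_bp)), 100_000)
            start = int(rng.integers(1, clen + 1))
            end = start + length - 1
            if end > clen:
                warnings.warn("tract clipped at chromosome end", stacklevel=2)
                end = clen
            hap = int(rng.integers(2))
            spans = occupied.setdefault((cname, hap), [])
            if any(s <= end and start <= e for s, e in spans):
                continue
            spans.append((start, end))
            sel = (chrom_all == cname) & (pos_all >= start) & (pos_all <= end)
            cols = np.flatnonzero(sel)
            if cols.size:
                old = out.calls[i, cols]
                remaining = np.where(
                    old == 1, rng.integers(0, 2, size=cols.size), (old == 2)
                ).astype(np.int8)
                donor = (rng.random(cols.size) < donor_p[cols]).astype(np.int8)
                new = remaining + donor
                new[old == MISSING] = MISSING
                out.calls[i, cols] = new
            tracts.append((cname, start, end, "nonnative", hap))
            placed += end - start + 1
        truth.tracts[ind_id] = tracts
    return out, truth


def dosage_tracks_from_truth(
    gm: GenotypeMatrix,
    truth: SimTruth,
    n_replicates: int = 3,
    flip_rate: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Noise-free (or noisy) replicate nonnative-dosage tracks implied by
    the truth tracts, in the tidy TSV schema the masking stage reads."""
    rng = np.random.default_rng(seed)
    chrom_all = gm.sites["chrom"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy()
    frames = []
    for ind in gm.individual_ids:
        dosage = np.zeros(gm.n_sites, dtype=float)
        for cname, start, end, ancestry, _hap in truth.tracts.get(ind, []):
            if ancestry != "nonnative":
                continue
            sel = (chrom_all == cname) & (pos_all >= start) & (pos_all <= end)
            dosage[sel] += 1
        for rep in range(1, n_replicates + 1):
            d = dosage.copy()
            if flip_rate > 0:
                flip = rng.random(gm.n_sites) < flip_rate
                d[flip] = rng.integers(0, 3, size=int(flip.sum()))
            frames.append(
                pd.DataFrame(
                    {
                        "individual": ind,
                        "chrom": chrom_all,
                        "pos": pos_all,
                        "replicate": rep,
                        "dosage_nonnative": d,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# read layers and paralogs
# ----------------------------------------------------------------------
def simulate_read_layers(
    gm: GenotypeMatrix,
    mean_depth: float = 50.0,
    paralog_fraction: float = 0.0,
    seed: int | None = None,
    truth: SimTruth | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Attach depth / GQ / allele-depth layers; optionally collapse a
    fraction of sites with a duplicated paralogous locus.

    Depth is Poisson(mean_depth) per genotype; heterozygote allele
    depths are Binomial(depth, 1/2); GQ is the monotone map
    min(99, 5 * depth).  At paralog sites the reads of a duplicated
    copy fixed for the reference allele are merged in, genotypes are
    re-called from the merged reads, so apparent heterozygosity is
    inflated and het allele ratios skew toward 0.75 ref : 0.25 alt.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    out = gm.copy()
    n_ind, n_sites = out.calls.shape
    depth = rng.poisson(mean_depth, size=(n_ind, n_sites)).astype(np.int32)
    called = out.calls != MISSING
    depth[~called] = 0
    alt_reads = np.zeros((n_ind, n_sites), dtype=np.int32)
    het = out.calls == 1
    alt_reads[het] = rng.binomial(depth[het], 0.5)
    alt_reads[out.calls == 2] = depth[out.calls == 2]
    ref_reads = depth - alt_reads

    paralogs = np.zeros(0, dtype=int)
    if paralog_fraction > 0:
        k = int(round(paralog_fraction * n_sites))
        paralogs = np.sort(rng.choice(n_sites, size=k, replace=False))
        dup = rng.poisson(mean_depth, size=(n_ind, k)).astype(np.int32)
        dup[~called[:, paralogs]] = 0
        ref_reads[:, paralogs] += dup  # duplicated copy fixed for ref
        depth = ref_reads + alt_reads
        # re-call apparent genotypes from merged reads
        block_ref = ref_reads[:, paralogs]
        block_alt = alt_reads[:, paralogs]
        new_calls = np.where(
            block_alt == 0, 0, np.where(block_ref == 0, 2, 1)
        ).astype(np.int8)
        new_calls[~called[:, paralogs]] = MISSING
        out.calls[:, paralogs] = new_calls

    out.depth = depth
    out.gq = np.minimum(99, 5 * depth).astype(np.int16)
    out.allele_depth = np.stack([ref_reads, alt_reads], axis=-1)
    if truth is None:
        truth = SimTruth()
    truth = replace(truth, paralog_sites=paralogs)
    return out, truth


# ----------------------------------------------------------------------
# population traits
# ----------------------------------------------------------------------
def generate_population_traits(
    gm: GenotypeMatrix,
    n_causal: int = 1,
    effect_sizes: float | list[float] = 100.0,
    noise_sd: float = 0.0,
    trait_names: tuple[str, ...] = ("trait",),
    seed: int | None = None,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Population-level traits driven by causal allele-frequency clines.

    Each trait is sum(effect * population alternate-allele frequency at
    its causal loci) plus Gaussian noise.  Causal loci and effects are
    recorded in the truth.
    """
    if n_causal > gm.n_sites:
        raise ValueError("n_causal exceeds site count")
    rng = np.random.default_rng(seed)
    pops = gm.population_labels
    if np.isscalar(effect_sizes):
        effect_sizes = [float(effect_sizes)] * n_causal
    if len(effect_sizes) != n_causal:
        raise ValueError("one effect size per causal locus required")
    causal = (
        np.sort(rng.choice(gm.n_sites, size=n_causal, replace=False))
        if n_causal
        else np.empty(0, dtype=int)
    )
    freqs = np.vstack(
        [gm.alt_allele_freq(gm.pop_indices(p)) for p in pops]
    )  # J x L
    if truth is None:
        truth = SimTruth()
    truth = replace(truth, causal_loci=list(truth.causal_loci))
    values = {}
    for name in trait_names:
        t = np.zeros(len(pops))
        for site, eff in zip(causal, effect_sizes):
            t += eff * np.nan_to_num(freqs[:, site], nan=0.0)
        t += rng.normal(0.0, noise_sd, size=len(pops))
        values[name] = t
    for site, eff in zip(causal, effect_sizes):
        truth.causal_loci.append(
            (int(site), {name: float(eff) for name in trait_names})
        )
    traits = pd.DataFrame(values, index=pd.Index(pops, name="population"))
    truth = replace(truth, trait_values=traits)
    return traits, truth


# ----------------------------------------------------------------------
# frequency-level drift panels for scan experiments
# ----------------------------------------------------------------------
def simulate_drift_panel(
    n_pops: int = 10,
    n_snps: int = 20_000,
    n_alleles: int = 50,
    drift: float = 0.05,
    seed: int | None = None,
    causal_site: int | None = None,
    causal_amplitude: float = 0.55,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int | None]:
    """Independent-drift allele-count panel with an optional causal cline.

    Every SNP draws an ancestral frequency, each population drifts away
    independently with variance ``drift`` on the standardized scale,
    and ``n_alleles`` alleles per population are binomially sampled.
    When ``causal_site`` is set (use -1 for "middle of the panel"), that
    SNP's frequencies follow the returned standardized trait ``z`` with
    amplitude ``causal_amplitude``, producing a frequency-trait
    correlation of about amp / sqrt(amp^2 + drift) (0.93 at defaults).

    Returns ``(alt_counts, total_counts, trait, causal_index)``.
    """
    rng = np.random.default_rng(seed)
    pi = 0.05 + 0.9 * rng.beta(0.8, 0.8, size=n_snps)
    eps = rng.normal(0.0, np.sqrt(drift), size=(n_pops, n_snps))
    z = rng.standard_normal(n_pops)
    z = (z - z.mean()) / z.std()
    idx: int | None = None
    if causal_site is not None:
        idx = n_snps // 2 if causal_site == -1 else causal_site
        pi[idx] = 0.5
        eps[:, idx] = causal_amplitude * z + rng.normal(
            0.0, np.sqrt(drift), size=n_pops
        )
    p = np.clip(pi + np.sqrt(pi * (1 - pi)) * eps, 1e-4, 1 - 1e-4)
    tot = np.full((n_pops, n_snps), n_alleles, dtype=np.int64)
    alt = rng.binomial(tot, p)
    return alt, tot, z, idx
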