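"""End-to-end benchmark experiments on synthetic panels.

Each function simulates data with known truth through the
synthetic-data module, runs the corresponding pipeline stage, and
returns recovery / calibration metrics.  Problem sizes default to
desk scale (a 5 x 25 Mb genome with ~20,000 SNPs, tens of individuals,
a handful of seeds) — large enough for the statistics to stabilise,
small enough to run in minutes.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import ancestry, diversity, fst as fst_mod, qc, roh, scan, sim
from .core import from_calls


def froh_recovery(
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    n_individuals: int = 50,
    cutoff: int = 5_000_000,
) -> dict[str, float]:
    """F_ROH vs true autozygosity on the double-bottleneck preset.

    Pools individuals across seeds and reports the Pearson correlation
    between F_ROH(>5 Mb) and true autozygosity (>=5 Mb segments), the
    mean absolute bias, and the fraction of individuals respecting the
    20/10/5-Mb cutoff monotonicity.
    """
    fr5, fr10, fr20, truth_vals = [], [], [], []
    for seed in seeds:
        scenario = sim.double_bottleneck(n_pops=1)
        gm, truth = sim.simulate_populations(scenario, n_individuals, seed=seed)
        table, _ = roh.inbreeding_table(gm)
        fr5.extend(table["froh_gt_5mb"])
        fr10.extend(table["froh_gt_10mb"])
        fr20.extend(table["froh_gt_20mb"])
        truth_vals.extend(truth.true_autozygosity[cutoff])
    fr5 = np.asarray(fr5)
    fr10 = np.asarray(fr10)
    fr20 = np.asarray(fr20)
    truth_vals = np.asarray(truth_vals)
    mono = np.mean((fr20 <= fr10) & (fr10 <= fr5))
    return {
        "pearson_r": float(np.corrcoef(fr5, truth_vals)[0, 1]),
        "mean_abs_bias": float(np.mean(np.abs(fr5 - truth_vals))),
        "mean_froh": float(fr5.mean()),
        "mean_true_autozygosity": float(truth_vals.mean()),
        "cutoff_monotone_fraction": float(mono),
        "n_individuals": int(fr5.size),
    }


def scan_null_calibration(
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    n_pops: int = 10,
    n_snps: int = 20_000,
    n_pod_snps: int = 50_000,
) -> dict[str, float]:
    """XtX / Bayes-factor calibration on null (no-causal-locus) panels.

    Each seed gets its own panel, fitted model and POD; the exceedance
    of the POD 1% threshold and the >= 20 dB Bayes-factor rate under a
    null trait are pooled across seeds.
    """
    xtx_hits = bf_hits = total = 0
    for seed in seeds:
        alt, tot, z, _ = sim.simulate_drift_panel(
            n_pops=n_pops, n_snps=n_snps, seed=seed
        )
        model = scan.estimate_omega((alt, tot))
        calib = scan.pod_calibrate(model, n_pod_snps, seed=10_000 + seed)
        r, _, _, _ = scan.standardized_residuals(alt, tot)
        x = scan.xtx_stats(r, model)
        db, _ = scan.bayes_factor(r, z, model)
        xtx_hits += int((x >= calib.threshold_1pct).sum())
        bf_hits += int((db >= 20.0).sum())
        total += x.size
    return {
        "xtx_fpr": xtx_hits / total,
        "bf_decisive_rate": bf_hits / total,
        "n_snps": total,
    }


def scan_power(
    seeds: tuple[int, ...] = tuple(range(10)),
    n_pops: int = 10,
    n_snps: int = 20_000,
    n_pod_snps: int = 50_000,
) -> dict[str, float]:
    """Candidate-detection power for one strong causal locus.

    The causal locus follows the trait with a frequency-trait Pearson
    correlation around 0.9; a hit requires the locus to pass both the
    POD 1% XtX threshold and the 20 dB Bayes-factor threshold.
    """
    hits = 0
    freq_rs = []
    for seed in seeds:
        alt, tot, z, idx = sim.simulate_drift_panel(
            n_pops=n_pops, n_snps=n_snps, seed=seed, causal_site=-1
        )
        model = scan.estimate_omega((alt, tot))
        calib = scan.pod_calibrate(model, n_pod_snps, seed=20_000 + seed)
        r, p, _, kept = scan.standardized_residuals(alt, tot)
        x = scan.xtx_stats(r, model)
        db, _ = scan.bayes_factor(r, z, model)
        ci = int(np.flatnonzero(kept == idx)[0])
        freq_rs.append(float(np.corrcoef(p[:, ci], z)[0, 1]))
        hits += int(x[ci] >= calib.threshold_1pct and db[ci] >= 20.0)
    return {
        "power": hits / len(seeds),
        "n_seeds": len(seeds),
        "mean_freq_trait_r": float(np.mean(freq_rs)),
    }


def masking_repair(
    seeds: tuple[int, ...] = tuple(range(10)),
    n_per_pop: int = 15,
    n_snps: int = 6000,
) -> dict[str, float]:
    """Heterozygosity repair by nonnative-ancestry masking.

    Injects ~5% divergent-donor tracts into half the individuals of a
    two-population recent-bottleneck panel, masks with noise-free
    consensus tracks, and counts seeds where the per-population H_e
    error versus the no-admixture truth shrinks after masking.
    """
    improved = 0
    errs_pre, errs_post = [], []
    for seed in seeds:
        scenario = sim.recent_bottleneck(n_pops=2)
        scenario.target_snps = n_snps
        gm0, truth = sim.simulate_populations(scenario, n_per_pop, seed=seed)
        he_truth = {
            p: diversity.expected_het(gm0, p)[0] for p in gm0.population_labels
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm1, truth = sim.inject_nonnative_tracts(
                gm0,
                truth,
                fraction_admixed=0.5,
                admixed_genome_fraction=0.05,
                seed=1000 + seed,
            )
        tracks = sim.dosage_tracks_from_truth(gm1, truth)
        windows = ancestry.consensus_windows_from_tracks(gm1, tracks)
        gm2 = ancestry.mask_nonnative(gm1, windows)
        pre = np.mean(
            [
                abs(diversity.expected_het(gm1, p)[0] - he_truth[p])
                for p in gm0.population_labels
            ]
        )
        post = np.mean(
            [
                abs(diversity.expected_het(gm2, p)[0] - he_truth[p])
                for p in gm0.population_labels
            ]
        )
        errs_pre.append(pre)
        errs_post.append(post)
        improved += int(post < pre)
    return {
        "n_improved": improved,
        "n_seeds": len(seeds),
        "mean_he_error_pre": float(np.mean(errs_pre)),
        "mean_he_error_post": float(np.mean(errs_post)),
    }


def hdplot_rates(
    seed: int = 0,
    n_individuals: int = 60,
    n_sites: int = 1250,
    paralog_fraction: float = 0.2,
    mean_depth: float = 50.0,
    min_hets: int = 20,
    d_max: float = 5.0,
) -> dict[str, float]:
    """HDplot paralog-flagging and clean-site false-flag rates.

    Simulates Hardy-Weinberg genotypes with read layers, collapses a
    fraction of sites with a ref-fixed duplicate, and scores |D| > 5
    flagging restricted (for the paralog rate) to sites with at least
    ``min_hets`` apparent heterozygotes.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.3, 0.7, size=n_sites)
    calls = rng.binomial(2, p, size=(n_individuals, n_sites)).astype(np.int8)
    gm = from_calls(calls)
    gm, truth = sim.simulate_read_layers(
        gm, mean_depth, paralog_fraction, seed=seed + 1
    )
    table = qc.hdplot(gm)
    d = np.abs(table["D"].to_numpy())
    is_par = np.zeros(n_sites, dtype=bool)
    is_par[truth.paralog_sites] = True
    n_het = (gm.calls == 1).sum(axis=0)
    scored = is_par & (n_het >= min_hets)
    return {
        "paralog_flag_rate": float((d[scored] > d_max).mean()),
        "clean_false_flag_rate": float((d[~is_par] > d_max).mean()),
        "n_paralog_scored": int(scored.sum()),
    }


def fst_checks(seed: int = 0, n_null: int = 10_000) -> dict[str, float]:
    """Fixed-difference and panmictic-null F_ST values.

    Two populations fixed for alternate alleles must give theta = 1;
    two samples of 30 from one Hardy-Weinberg pool at ``n_null`` loci
    should give theta near 0.
    """
    a = np.zeros((10, 5), np.int8)
    b = np.full((10, 5), 2, np.int8)
    gm = from_calls(np.vstack([a, b]), populations=["A"] * 10 + ["B"] * 10)
    fixed = fst_mod.wc_fst(gm, "A", "B")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, n_null)
    calls = rng.binomial(2, p, size=(60, n_null)).astype(np.int8)
    gm = from_calls(
        calls,
        positions=np.arange(1, n_null + 1) * 100,
        populations=["A"] * 30 + ["B"] * 30,
    )
    null = fst_mod.wc_fst(gm, "A", "B", n_loci=n_null, seed=seed)
    return {"theta_fixed_difference": float(fixed), "theta_panmictic_null": float(null)}


def preset_diversity(
    seed: int = 0, n_per_pop: int = 15, n_snps: int = 5000
) -> dict[str, float]:
    """Expected heterozygosity and mean true autozygosity per preset,
    at reduced scale (one population each)."""
    out: dict[str, float] = {}
    for name, factory in sim.PRESETS.items():
        scenario = factory(n_pops=1)
        if name == "connected":
            scenario = sim.connected(n_pops=1, n=300, gens=12)
        scenario.target_snps = n_snps
        gm, truth = sim.simulate_populations(scenario, n_per_pop, seed=seed)
        out[f"he_{name}"] = diversity.expected_het(gm, "pop1")[0]
        out[f"auto5mb_{name}"] = float(
            truth.true_autozygosity[5_000_000].mean()
        )
    return out
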