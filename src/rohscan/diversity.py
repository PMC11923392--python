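"""Population diversity summaries.

Expected heterozygosity uses the unbiased gene-diversity estimator
h = 2*p*(1-p) * 2n/(2n-1) per site (n = called genotypes), averaged
over the full shared SNP panel so that populations are compared on one
common denominator; ``raw=True`` switches to plain 2pq.  Confidence
intervals come from a percentile bootstrap over individuals within the
population.  Observed heterozygosity is reported genome-wide and in
non-overlapping 5-Mb windows anchored at position 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


def _site_he(calls: np.ndarray, raw: bool = False) -> np.ndarray:
    """Per-site expected heterozygosity for one population's call block.

    Sites with fewer than 2 called genotypes are NaN (no frequency
    estimate); monomorphic sites contribute 0.
    """
    called = calls != MISSING
    n = called.sum(axis=0).astype(float)
    ac = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ac / (2 * n)
        h = 2 * p * (1 - p)
        if not raw:
            h = h * (2 * n) / (2 * n - 1)
    return np.where(n >= 2, h, np.nan)


def expected_het(
    gm: GenotypeMatrix, population: str, raw: bool = False
) -> tuple[float, np.ndarray]:
    """Mean genome-wide expected heterozygosity of one population.

    Returns (H_e, per-site values); the mean runs over the full shared
    panel, skipping only sites with <2 called genotypes in this
    population.
    """
    idx = gm.pop_indices(population)
    per_site = _site_he(gm.calls[idx], raw=raw)
    return float(np.nanmean(per_site)), per_site


def bootstrap_he_ci(
    gm: GenotypeMatrix,
    population: str,
    n_boot: int = 100,
    seed: int | None = None,
    raw: bool = False,
    bias_correct: bool = True,
) -> tuple[float, float]:
    """Percentile 95% CI for H_e, bootstrapping individuals within the
    population.

    Resampling individuals with replacement duplicates genotypes and
    systematically deflates gene diversity by about a 1/n factor, so
    by default the percentile interval is shifted by the estimated
    bootstrap bias (bootstrap mean minus the point estimate);
    ``bias_correct=False`` gives the plain percentile interval.
    """
    idx = gm.pop_indices(population)
    he, _ = expected_het(gm, population, raw=raw)
    if idx.size < 2:
        warnings.warn(
            f"population {population!r} has <2 individuals; CI degenerate",
            stacklevel=2,
        )
        return he, he
    rng = np.random.default_rng(seed)
    calls = gm.calls[idx]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        rows = rng.integers(0, idx.size, size=idx.size)
        stats[b] = np.nanmean(_site_he(calls[rows], raw=raw))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    if bias_correct:
        bias = stats.mean() - he
        lo, hi = lo - bias, hi - bias
    return float(lo), float(hi)


def diversity_summary(
    gm: GenotypeMatrix,
    n_boot: int = 100,
    seed: int | None = None,
    raw: bool = False,
) -> pd.DataFrame:
    """Per-population H_e with bootstrap CI."""
    rng = np.random.default_rng(seed)
    rows = []
    for pop in gm.population_labels:
        he, _ = expected_het(gm, pop, raw=raw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lo, hi = bootstrap_he_ci(
                gm, pop, n_boot=n_boot, seed=int(rng.integers(2**31)), raw=raw
            )
        rows.append(
            {
                "population": pop,
                "n_individuals": gm.pop_indices(pop).size,
                "he": he,
                "he_ci_lo": lo,
                "he_ci_hi": hi,
            }
        )
    return pd.DataFrame(rows)


def windowed_ho(
    gm: GenotypeMatrix, individual: str, window_bp: int = 5_000_000
) -> pd.DataFrame:
    """Observed heterozygosity of one individual in non-overlapping
    windows anchored at position 1 ([1, window_bp], [window_bp+1, ...]).

    Windows with zero called genotypes have ``ho`` NaN.
    """
    try:
        row = gm.individual_ids.index(individual)
    except ValueError:
        raise KeyError(f"unknown individual: {individual!r}") from None
    calls = gm.calls[row]
    chrom = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    win = (pos - 1) // window_bp
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "window": win,
            "called": calls != MISSING,
            "het": calls == 1,
        }
    )
    grp = df.groupby(["chrom", "window"], sort=False).agg(
        n_called=("called", "sum"), n_het=("het", "sum")
    )
    grp = grp.reset_index()
    grp["start"] = grp["window"] * window_bp + 1
    grp["end"] = (grp["window"] + 1) * window_bp
    with np.errstate(invalid="ignore", divide="ignore"):
        grp["ho"] = np.where(
            grp["n_called"] > 0, grp["n_het"] / grp["n_called"], np.nan
        )
    grp.insert(0, "individual", individual)
    return grp[["individual", "chrom", "start", "end", "n_called", "n_het", "ho"]]


def observed_het(gm: GenotypeMatrix, individual: str) -> float:
    """Genome-wide observed heterozygosity of one individual."""
    row = gm.individual_ids.index(individual)
    calls = gm.calls[row]
    called = calls != MISSING
    if not called.any():
        return float("nan")
    return float((calls == 1).sum() / called.sum())


def group_snp_count(
    gm: GenotypeMatrix,
    populations: list[str],
    subsample_k: int | None = None,
    n_reps: int = 100,
    seed: int | None = None,
) -> dict[str, float]:
    """Count sites segregating (MAC >= 1) within a pooled population group.

    With ``subsample_k`` set, ``n_reps`` random k-population subsets are
    drawn and the mean count with a percentile 95% CI is returned
    (keys ``mean``, ``ci_lo``, ``ci_hi``); otherwise the plain pooled
    count is returned under key ``count``.
    """

    def count(pops: list[str]) -> int:
        rows = np.concatenate([gm.pop_indices(p) for p in pops])
        mac = gm.minor_allele_count(rows)
        return int((mac >= 1).sum())

    if subsample_k is None or subsample_k >= len(populations):
        return {"count": count(populations)}
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    for r in range(n_reps):
        pick = rng.choice(len(populations), size=subsample_k, replace=False)
        reps[r] = count([populations[i] for i in pick])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return {"mean": float(reps.mean()), "ci_lo": float(lo), "ci_hi": float(hi)}
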