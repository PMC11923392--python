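"""Weir & Cockerham (1984) F_ST from genotype counts.

Variance components are computed per locus from diploid genotype
counts — not from a haploid allele-count shortcut — so that
heterozygote deficits in small inbred populations enter through the
observed-heterozygosity term, as in the original estimator.  The
multi-locus theta is the ratio of sums sum(a) / sum(a + b + c) over
loci, never a mean of per-locus ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


def _pair_components(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus variance components (a, b, c) for two populations.

    ``calls_*`` are (individuals x loci) diploid call blocks.  Loci
    where a population has no called genotypes, or where n_c would be
    degenerate, contribute NaN components (excluded from sums).
    """
    r = 2.0
    comp = []
    n_i, p_i, h_i = [], [], []
    for calls in (calls_a, calls_b):
        called = calls != MISSING
        n = called.sum(axis=0).astype(float)  # genotypes
        ac = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = ac / (2 * n)
            h = (calls == 1).sum(axis=0) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    n_tot = n_i.sum(axis=0)
    nbar = n_tot / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_tot

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0

    bad = (n_i < 1).any(axis=0) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def wc_fst(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    n_loci: int | None = 10_000,
    seed: int | None = None,
    loci: np.ndarray | None = None,
    clamp_negative: bool = False,
) -> float:
    """Multi-locus Weir-Cockerham theta between two populations.

    ``n_loci`` loci are sampled without replacement (all loci when the
    panel is smaller or ``n_loci`` is None); an explicit ``loci`` index
    array overrides sampling so the same subset can serve a whole
    pairwise matrix.  Negative estimates are reported as computed
    unless ``clamp_negative``.
    """
    ia = gm.pop_indices(pop_a)
    ib = gm.pop_indices(pop_b)
    if loci is None:
        loci = sample_loci(gm.n_sites, n_loci, seed)
    calls_a = gm.calls[np.ix_(ia, loci)]
    calls_b = gm.calls[np.ix_(ib, loci)]
    if not (calls_a != MISSING).any() or not (calls_b != MISSING).any():
        raise ValueError("a population has no called genotypes at sampled loci")
    a, b, c = _pair_components(calls_a, calls_b)
    denom = np.nansum(a + b + c)
    if denom == 0:
        return float("nan")
    theta = float(np.nansum(a) / denom)
    if clamp_negative:
        theta = max(theta, 0.0)
    return theta


def sample_loci(
    n_sites: int, n_loci: int | None, seed: int | None
) -> np.ndarray:
    """Without-replacement locus subset (all loci if panel is smaller)."""
    if n_loci is None or n_sites <= n_loci:
        return np.arange(n_sites)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_sites, size=n_loci, replace=False))


def pairwise_fst(
    gm: GenotypeMatrix,
    n_loci: int | None = 10_000,
    seed: int | None = None,
    clamp_negative: bool = False,
) -> pd.DataFrame:
    """Symmetric pairwise theta matrix over all populations.

    One random locus subset is drawn under ``seed`` and shared by every
    pair; the diagonal is 0.
    """
    pops = gm.population_labels
    loci = sample_loci(gm.n_sites, n_loci, seed)
    mat = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            theta = wc_fst(
                gm,
                pops[i],
                pops[j],
                loci=loci,
                clamp_negative=clamp_negative,
            )
            mat[i, j] = mat[j, i] = theta
    return pd.DataFrame(mat, index=pops, columns=pops)
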