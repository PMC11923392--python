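"""Runs-of-homozygosity detection and F_ROH inbreeding coefficients.

The detector follows the PLINK ``--homozyg`` sliding-window scheme: a
fixed-size window of consecutive SNPs slides along each chromosome, a
window is a "hit" when it contains at most ``max_het_per_window``
heterozygous and at most ``max_missing_per_window`` missing calls, each
SNP receives the proportion of hit windows among windows covering it,
and maximal stretches of SNPs whose hit proportion reaches
``window_hit_threshold`` become candidate runs.  Candidate runs are
split at inter-SNP gaps above ``max_gap_bp`` and segmented greedily
left-to-right so that each reported run carries at most
``max_het_per_window`` heterozygous calls in total; surviving runs must
satisfy the SNP-count, length and SNP-density floors.

F_ROH is the summed length of runs longer than a cutoff divided by the
detectable autosomal length, i.e. the summed first-to-last-SNP span of
each autosomal chromosome of the (shared) panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

#: default F_ROH length cutoffs (bp)
DEFAULT_CUTOFFS = (5_000_000, 10_000_000, 20_000_000)


@dataclass
class ROHParams:
    """Sliding-window ROH parameters (PLINK ``--homozyg`` conventions).

    Defaults reproduce a 50-SNP window allowing 1 heterozygous and 5
    missing calls per window, a 5-Mb minimum run length, and the
    standard values for the parameters PLINK leaves at its defaults
    (hit threshold 0.05, 100-SNP minimum, 1-Mb maximum gap, 50 kb/SNP
    maximum inverse density).
    """

    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    min_run_bp: int = 5_000_000
    window_hit_threshold: float = 0.05
    min_run_snps: int = 100
    max_gap_bp: int = 1_000_000
    min_density_bp_per_snp: int = 50_000

    def __post_init__(self) -> None:
        for name in (
            "window_snps",
            "min_run_bp",
            "window_hit_threshold",
            "min_run_snps",
            "max_gap_bp",
            "min_density_bp_per_snp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_het_per_window < 0 or self.max_missing_per_window < 0:
            raise ValueError("window tolerances must be >= 0")


@dataclass
class ROHSegment:
    """One homozygous run: first/last SNP positions, 1-based inclusive."""

    individual: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int

    @property
    def length(self) -> int:
        # end - start matches the first-to-last-SNP convention of the
        # detectable-length denominator
        return self.end - self.start


def _eligible_snps(
    het: np.ndarray, miss: np.ndarray, params: ROHParams
) -> np.ndarray:
    """Boolean run-eligibility per SNP from sliding-window hit proportions."""
    n = het.size
    w = params.window_snps
    if n < w:
        return np.zeros(n, dtype=bool)
    het_c = np.concatenate(([0], np.cumsum(het)))
    miss_c = np.concatenate(([0], np.cumsum(miss)))
    # window k covers SNPs k .. k+w-1, k = 0 .. n-w
    het_w = het_c[w:] - het_c[:-w]
    miss_w = miss_c[w:] - miss_c[:-w]
    hit = (het_w <= params.max_het_per_window) & (
        miss_w <= params.max_missing_per_window
    )
    # SNP i is covered by windows max(0, i-w+1) .. min(i, n-w)
    hit_c = np.concatenate(([0], np.cumsum(hit)))
    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n - w)
    n_cov = (hi - lo + 1).astype(float)
    n_hit = hit_c[hi + 1] - hit_c[lo]
    return n_hit / n_cov >= params.window_hit_threshold


def _segment_stretch(
    idx: np.ndarray, het: np.ndarray, params: ROHParams
) -> list[tuple[int, int]]:
    """Greedy left-to-right het-budget segmentation of one eligible stretch.

    When the running heterozygote count would exceed the budget, the
    current run is closed before the offending SNP and a new run starts
    at that SNP (which then carries one heterozygote).
    """
    out: list[tuple[int, int]] = []
    start = 0
    n_het = 0
    for k in range(idx.size):
        if het[idx[k]]:
            n_het += 1
            if n_het > params.max_het_per_window:
                if k - 1 >= start:
                    out.append((start, k - 1))
                if params.max_het_per_window >= 1:
                    start, n_het = k, 1
                else:  # zero-het budget: restart after the het itself
                    start, n_het = k + 1, 0
    if start <= idx.size - 1:
        out.append((start, idx.size - 1))
    return out


def detect_roh(
    gm: GenotypeMatrix, individual: str, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Detect runs of homozygosity for one individual.

    RNG-free and deterministic.  Chromosomes with fewer SNPs than one
    window yield no calls (with a warning).
    """
    params = params or ROHParams()
    try:
        row = gm.individual_ids.index(individual)
    except ValueError:
        raise KeyError(f"unknown individual: {individual!r}") from None
    calls = gm.calls[row]
    chrom_all = gm.sites["chrom"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy()
    segments: list[ROHSegment] = []
    for chrom in gm.chromosomes():
        sel = chrom_all == chrom
        g = calls[sel]
        pos = pos_all[sel]
        if g.size < params.window_snps:
            warnings.warn(
                f"chromosome {chrom} has {g.size} SNPs "
                f"(< window of {params.window_snps}); no ROH calls there",
                stacklevel=2,
            )
            continue
        het = g == 1
        miss = g == MISSING
        eligible = _eligible_snps(het, miss, params)
        if not eligible.any():
            continue
        # maximal runs of consecutive eligible SNPs
        e = np.flatnonzero(eligible)
        breaks = np.flatnonzero(np.diff(e) > 1)
        runs = np.split(e, breaks + 1)
        for run in runs:
            # split at physical gaps above the maximum
            gap_breaks = np.flatnonzero(np.diff(pos[run]) > params.max_gap_bp)
            for piece in np.split(run, gap_breaks + 1):
                for a, b in _segment_stretch(piece, het, params):
                    sub = piece[a : b + 1]
                    n_snps = sub.size
                    length = int(pos[sub[-1]] - pos[sub[0]])
                    if n_snps < params.min_run_snps:
                        continue
                    if length < params.min_run_bp:
                        continue
                    if length / n_snps > params.min_density_bp_per_snp:
                        continue
                    segments.append(
                        ROHSegment(
                            individual=individual,
                            chrom=chrom,
                            start=int(pos[sub[0]]),
                            end=int(pos[sub[-1]]),
                            n_snps=n_snps,
                            n_het=int(het[sub].sum()),
                        )
                    )
    return segments


def detect_roh_all(
    gm: GenotypeMatrix, params: ROHParams | None = None
) -> dict[str, list[ROHSegment]]:
    """ROH segments for every individual in the matrix."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {ind: detect_roh(gm, ind, params) for ind in gm.individual_ids}


def detectable_autosomal_length(
    gm: GenotypeMatrix, exclude_chroms: set[str] | None = None
) -> tuple[dict[str, int], int]:
    """First-to-last SNP span per chromosome and the autosomal total.

    ``exclude_chroms`` removes sex-linked chromosomes from the total;
    by default every chromosome counts as autosomal.
    """
    exclude = exclude_chroms or set()
    chrom = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    spans: dict[str, int] = {}
    for c in gm.chromosomes():
        p = pos[chrom == c]
        span = int(p[-1] - p[0]) if p.size >= 2 else 0
        if p.size < 2:
            warnings.warn(f"chromosome {c} has <2 SNPs; contributes 0", stacklevel=2)
        spans[c] = span
    total = sum(v for c, v in spans.items() if c not in exclude)
    return spans, total


def f_roh(
    segments: list[ROHSegment], detectable_bp: int, min_len: int = 5_000_000
) -> float:
    """F_ROH: summed length of runs strictly longer than ``min_len``
    divided by the detectable autosomal length."""
    if detectable_bp <= 0:
        raise ValueError("detectable_bp must be positive")
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    total = sum(s.length for s in segments if s.length > min_len)
    return total / detectable_bp


def inbreeding_table(
    gm: GenotypeMatrix,
    params: ROHParams | None = None,
    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS,
    exclude_chroms: set[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[ROHSegment]]]:
    """Per-individual F_ROH at each length cutoff, plus the raw segments.

    The returned frame has one row per individual with its population
    and an ``froh_gt_<Mb>mb`` column per cutoff.
    """
    segs = detect_roh_all(gm, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, detectable = detectable_autosomal_length(gm, exclude_chroms)
    rows = []
    for ind in gm.individual_ids:
        row: dict[str, object] = {
            "individual": ind,
            "population": gm.population_of[ind],
        }
        for cut in cutoffs:
            row[f"froh_gt_{cut // 1_000_000}mb"] = f_roh(segs[ind], detectable, cut)
        rows.append(row)
    return pd.DataFrame(rows), segs


def segments_frame(segs: dict[str, list[ROHSegment]]) -> pd.DataFrame:
    """Flatten per-individual segment lists into one tidy frame."""
    rows = [
        {
            "individual": s.individual,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "length": s.length,
            "n_snps": s.n_snps,
            "n_het": s.n_het,
        }
        for lst in segs.values()
        for s in lst
    ]
    cols = ["individual", "chrom", "start", "end", "length", "n_snps", "n_het"]
    return pd.DataFrame(rows, columns=cols)
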