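"""Independent plain-loop reference implementations used as test oracles.

These deliberately avoid the vectorised code paths of the package:
window counts are recomputed by explicit summation and the
variance-component algebra is transcribed directly from the textbook
formulas, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math

MISSING = -1


def brute_force_roh(
    genotypes,
    positions,
    window_snps=50,
    max_het_per_window=1,
    max_missing_per_window=5,
    min_run_bp=5_000_000,
    window_hit_threshold=0.05,
    min_run_snps=100,
    max_gap_bp=1_000_000,
    min_density_bp_per_snp=50_000,
):
    """Exhaustive sliding-window ROH caller for one chromosome.

    Returns (start_pos, end_pos, n_snps, n_het) tuples under the same
    window rules as the pipeline: per-window het/missing tolerances,
    per-SNP hit proportions, eligibility threshold, gap splitting,
    greedy left-to-right het-budget segmentation, and the run-level
    SNP-count / length / density floors.
    """
    g = list(genotypes)
    pos = list(positions)
    n = len(g)
    w = window_snps
    if n < w:
        return []
    hits = []
    for k in range(n - w + 1):
        window = g[k : k + w]
        n_het = sum(1 for x in window if x == 1)
        n_mis = sum(1 for x in window if x == MISSING)
        hits.append(n_het <= max_het_per_window and n_mis <= max_missing_per_window)
    eligible = []
    for i in range(n):
        cov = [hits[k] for k in range(max(0, i - w + 1), min(i, n - w) + 1)]
        eligible.append(sum(cov) / len(cov) >= window_hit_threshold)

    segments = []
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1]:
            j += 1
        # split the eligible stretch at oversized physical gaps
        pieces = []
        cur = [i]
        for k in range(i + 1, j + 1):
            if pos[k] - pos[k - 1] > max_gap_bp:
                pieces.append(cur)
                cur = []
            cur.append(k)
        pieces.append(cur)
        for piece in pieces:
            # greedy left-to-right segmentation under the het budget
            subs = []
            start = 0
            n_het = 0
            for kk in range(len(piece)):
                if g[piece[kk]] == 1:
                    n_het += 1
                    if n_het > max_het_per_window:
                        if kk - 1 >= start:
                            subs.append((start, kk - 1))
                        if max_het_per_window >= 1:
                            start, n_het = kk, 1
                        else:
                            start, n_het = kk + 1, 0
            if start <= len(piece) - 1:
                subs.append((start, len(piece) - 1))
            for a, b in subs:
                sub = piece[a : b + 1]
                n_snps = len(sub)
                length = pos[sub[-1]] - pos[sub[0]]
                if n_snps < min_run_snps:
                    continue
                if length < min_run_bp:
                    continue
                if length / n_snps > min_density_bp_per_snp:
                    continue
                segments.append(
                    (
                        pos[sub[0]],
                        pos[sub[-1]],
                        n_snps,
                        sum(1 for k in sub if g[k] == 1),
                    )
                )
        i = j + 1
    return segments


def textbook_wc_theta(genotypes_a, genotypes_b):
    """Weir-Cockerham multi-locus theta, transcribed loop-by-loop from
    the 1984 variance-component definitions (r = 2 populations)."""
    n_loci = len(genotypes_a[0])
    sum_a = sum_abc = 0.0
    r = 2
    for l in range(n_loci):
        col_a = [row[l] for row in genotypes_a if row[l] != MISSING]
        col_b = [row[l] for row in genotypes_b if row[l] != MISSING]
        if len(col_a) < 1 or len(col_b) < 1:
            continue
        n1, n2 = len(col_a), len(col_b)
        nbar = (n1 + n2) / r
        if nbar <= 1:
            continue
        nc = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
        if nc <= 0:
            continue
        p1 = sum(col_a) / (2 * n1)
        p2 = sum(col_b) / (2 * n2)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        h1 = sum(1 for x in col_a if x == 1) / n1
        h2 = sum(1 for x in col_b if x == 1) / n2
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (nbar / nc) * (
            s2
            - (1 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc
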