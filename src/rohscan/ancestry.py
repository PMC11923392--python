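"""Consensus local-ancestry windows and nonnative-genotype masking.

Input is a per-individual set of replicate local-ancestry dosage
tracks (three replicates of a hidden-Markov local-ancestry run with
different seeds).  Raw dosages are discretized by rounding to the
nearest value in {0, 1, 2}; a replicate value farther than 0.5 from
every integer is a replicate-level no-call.  A site has a consensus
dosage only when all three replicates agree; contiguous runs of the
same consensus dosage become ancestry windows, windows shorter than
1 kb are discarded as unsupported, and genotypes inside windows with
any nonnative dosage are set to missing.

Dosages here count *nonnative* haplotypes (0 = both native, 2 = both
nonnative); the native dosage is 2 minus that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

#: consensus sentinel for "replicates disagree / no call"
NO_CALL: int = -1


@dataclass
class AncestryWindow:
    """Contiguous same-ancestry interval for one individual.

    ``start``/``end`` are the first and last SNP positions of the run,
    1-based inclusive; ``dosage`` counts nonnative haplotypes (0-2).
    """

    individual: str
    chrom: str
    start: int
    end: int
    dosage: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        return {0: "2 native", 1: "1 native + 1 nonnative", 2: "2 nonnative"}[
            self.dosage
        ]


def discretize_dosage(raw: np.ndarray) -> np.ndarray:
    """Round raw dosages to {0, 1, 2}; values farther than 0.5 from all
    three integers become no-calls."""
    raw = np.asarray(raw, dtype=float)
    rounded = np.rint(raw)
    ok = (np.abs(raw - rounded) <= 0.5) & (rounded >= 0) & (rounded <= 2)
    out = np.where(ok, rounded, NO_CALL).astype(np.int8)
    out[np.isnan(raw)] = NO_CALL
    return out


def consensus_dosage(tracks: np.ndarray) -> np.ndarray:
    """Per-site consensus over exactly three replicate dosage tracks.

    ``tracks`` is (3, n_sites), raw or already-discrete.  The consensus
    is the shared discretized dosage when all replicates agree, else
    ``NO_CALL``.
    """
    tracks = np.asarray(tracks, dtype=float)
    if tracks.ndim != 2 or tracks.shape[0] != 3:
        raise ValueError("exactly 3 replicate tracks required")
    disc = discretize_dosage(tracks)
    agree = (disc[0] == disc[1]) & (disc[1] == disc[2]) & (disc[0] != NO_CALL)
    return np.where(agree, disc[0], NO_CALL).astype(np.int8)


def build_windows(
    individual: str,
    chroms: np.ndarray,
    positions: np.ndarray,
    consensus: np.ndarray,
    min_window_bp: int = 1000,
) -> list[AncestryWindow]:
    """Maximal same-consensus runs as windows; runs spanning fewer than
    ``min_window_bp`` base pairs are dropped (strictly-shorter rule)."""
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    consensus = np.asarray(consensus)
    windows: list[AncestryWindow] = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        pos = positions[sel]
        con = consensus[sel]
        n = con.size
        i = 0
        while i < n:
            if con[i] == NO_CALL:
                i += 1
                continue
            j = i
            while j + 1 < n and con[j + 1] == con[i]:
                j += 1
            w = AncestryWindow(
                individual=individual,
                chrom=str(chrom),
                start=int(pos[i]),
                end=int(pos[j]),
                dosage=int(con[i]),
            )
            if w.length >= min_window_bp:
                windows.append(w)
            i = j + 1
    return windows


def consensus_windows_from_tracks(
    gm: GenotypeMatrix,
    tracks: pd.DataFrame,
    min_window_bp: int = 1000,
) -> list[AncestryWindow]:
    """Consensus + window construction for every individual in a tidy
    dosage-track frame.

    ``tracks`` columns: individual, chrom, pos, replicate (1-3), and a
    ``dosage_nonnative`` column (raw dosages accepted).  Sites must
    match the matrix's sites.
    """
    chrom_all = gm.sites["chrom"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy()
    site_key = pd.MultiIndex.from_arrays([chrom_all, pos_all])
    windows: list[AncestryWindow] = []
    for ind, grp in tracks.groupby("individual", sort=False):
        reps = sorted(grp["replicate"].unique())
        if len(reps) != 3:
            raise ValueError(
                f"individual {ind!r} has {len(reps)} replicates (3 required)"
            )
        mat = np.full((3, gm.n_sites), np.nan)
        for k, rep in enumerate(reps):
            sub = grp[grp["replicate"] == rep]
            idx = site_key.get_indexer(
                pd.MultiIndex.from_arrays([sub["chrom"], sub["pos"]])
            )
            if (idx < 0).any():
                raise ValueError(f"dosage track of {ind!r} has unknown sites")
            mat[k, idx] = sub["dosage_nonnative"].to_numpy()
        con = consensus_dosage(mat)
        windows.extend(
            build_windows(str(ind), chrom_all, pos_all, con, min_window_bp)
        )
    return windows


def mask_nonnative(
    gm: GenotypeMatrix, windows: list[AncestryWindow]
) -> GenotypeMatrix:
    """Set genotypes inside each individual's nonnative windows to missing.

    Only windows containing at least one nonnative haplotype (dosage
    >= 1) mask; fully native windows and unassigned regions are left
    untouched.  Values of retained calls are never altered.
    """
    out = gm.copy()
    chrom_all = gm.sites["chrom"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy()
    row_of = {ind: i for i, ind in enumerate(gm.individual_ids)}
    for w in windows:
        if w.dosage < 1:
            continue
        if w.individual not in row_of:
            continue
        sel = (chrom_all == w.chrom) & (pos_all >= w.start) & (pos_all <= w.end)
        out.calls[row_of[w.individual], sel] = MISSING
    return out


def windows_frame(windows: list[AncestryWindow]) -> pd.DataFrame:
    rows = [
        {
            "individual": w.individual,
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "length": w.length,
            "dosage_nonnative": w.dosage,
            "label": w.label,
        }
        for w in windows
    ]
    cols = ["individual", "chrom", "start", "end", "length", "dosage_nonnative", "label"]
    return pd.DataFrame(rows, columns=cols)
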