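"""Core genotype container shared by every pipeline stage.

Genotypes are stored as an individuals x sites matrix of diploid calls
coded 0 (hom-ref), 1 (het), 2 (hom-alt) with ``MISSING`` (-1) as an
explicit sentinel, plus optional per-genotype depth, Phred genotype
quality (GQ) and (ref, alt) allele-depth layers mirroring the VCF
FORMAT fields the pipeline consumes.  Sites are kept in a pandas frame
sorted by (chromosome, position), positions 1-based as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing diploid call; 0 is a valid hom-ref genotype
MISSING: int = -1

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Diploid biallelic SNP genotypes for a multi-population panel.

    Parameters
    ----------
    individual_ids
        Sample labels, one per matrix row.
    populations
        Population label per individual (parallel to ``individual_ids``).
    sites
        Frame with columns ``chrom, pos, ref, alt``; one row per SNP,
        sorted by (chromosome, position), ``pos`` 1-based.
    calls
        ``int8`` array of shape (n_individuals, n_sites) with values in
        {0, 1, 2, MISSING}.
    depth, gq
        Optional per-genotype read depth / genotype quality layers with
        the same shape as ``calls``.
    allele_depth
        Optional ``(n_individuals, n_sites, 2)`` array of (ref, alt)
        read counts.
    """

    individual_ids: list[str]
    populations: np.ndarray
    sites: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None
    allele_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.sites = self.sites.reset_index(drop=True)
        self.validate()

    # ------------------------------------------------------------------
    # shape / bookkeeping
    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def population_of(self) -> dict[str, str]:
        return dict(zip(self.individual_ids, self.populations))

    @property
    def population_labels(self) -> list[str]:
        """Distinct populations in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def pop_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(self.populations == population)
        if idx.size == 0:
            raise KeyError(f"unknown population: {population!r}")
        return idx

    def validate(self) -> None:
        n_ind, n_sites = self.calls.shape
        if n_ind != len(self.individual_ids):
            raise ValueError("calls rows != number of individuals")
        if len(self.populations) != n_ind:
            raise ValueError("populations length != number of individuals")
        if n_sites != len(self.sites):
            raise ValueError("calls columns != number of sites")
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"sites frame lacks columns {missing_cols}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls outside {0,1,2,MISSING}")
        for name in ("depth", "gq"):
            layer = getattr(self, name)
            if layer is not None and layer.shape != self.calls.shape:
                raise ValueError(f"{name} layer shape mismatch")
        if self.allele_depth is not None and self.allele_depth.shape != (
            n_ind,
            n_sites,
            2,
        ):
            raise ValueError("allele_depth layer shape mismatch")
        # sites must be sorted by (chrom, pos); chromosomes grouped
        chrom = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions unsorted on chromosome {c}")
        # chromosome blocks must be contiguous
        change = np.flatnonzero(chrom[1:] != chrom[:-1]) if len(chrom) else []
        if len(np.unique(chrom)) != len(change) + (1 if len(chrom) else 0):
            raise ValueError("sites of one chromosome are not contiguous")

    # ------------------------------------------------------------------
    # subsetting
    # ------------------------------------------------------------------
    def subset(
        self,
        individuals: Sequence[int] | np.ndarray | None = None,
        sites: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given row / site indices."""
        ind = (
            np.arange(self.n_individuals)
            if individuals is None
            else np.asarray(individuals)
        )
        if ind.dtype == bool:
            ind = np.flatnonzero(ind)
        st = np.arange(self.n_sites) if sites is None else np.asarray(sites)
        if st.dtype == bool:
            st = np.flatnonzero(st)

        def cut(layer: np.ndarray | None) -> np.ndarray | None:
            if layer is None:
                return None
            return layer[np.ix_(ind, st)].copy()

        ad = None
        if self.allele_depth is not None:
            ad = self.allele_depth[np.ix_(ind, st)].copy()
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in ind],
            populations=self.populations[ind].copy(),
            sites=self.sites.iloc[st].reset_index(drop=True),
            calls=self.calls[np.ix_(ind, st)].copy(),
            depth=cut(self.depth),
            gq=cut(self.gq),
            allele_depth=ad,
        )

    def copy(self) -> "GenotypeMatrix":
        return self.subset()

    def chromosomes(self) -> list[str]:
        """Chromosome labels in matrix order."""
        chrom = self.sites["chrom"].to_numpy()
        out: list[str] = []
        for c in chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_site_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.sites["chrom"].to_numpy() == chrom)

    # ------------------------------------------------------------------
    # per-site and per-individual summaries
    # ------------------------------------------------------------------
    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    def site_n_called(self, individuals: np.ndarray | None = None) -> np.ndarray:
        calls = self.calls if individuals is None else self.calls[individuals]
        return (calls != MISSING).sum(axis=0)

    def site_call_rate(self) -> np.ndarray:
        return self.site_n_called() / max(self.n_individuals, 1)

    def alt_allele_count(self, individuals: np.ndarray | None = None) -> np.ndarray:
        calls = self.calls if individuals is None else self.calls[individuals]
        return np.where(calls == MISSING, 0, calls).sum(axis=0)

    def alt_allele_freq(self, individuals: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency among called genotypes (NaN if none)."""
        n = self.site_n_called(individuals).astype(float)
        ac = self.alt_allele_count(individuals)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, ac / (2 * n), np.nan)

    def minor_allele_count(self, individuals: np.ndarray | None = None) -> np.ndarray:
        ac = self.alt_allele_count(individuals)
        n = self.site_n_called(individuals)
        return np.minimum(ac, 2 * n - ac)

    def minor_allele_freq(self, individuals: np.ndarray | None = None) -> np.ndarray:
        p = self.alt_allele_freq(individuals)
        return np.where(np.isnan(p), np.nan, np.minimum(p, 1 - p))

    def het_proportion(self) -> np.ndarray:
        """Per-site heterozygote share among called genotypes (NaN if none)."""
        n = self.site_n_called().astype(float)
        het = (self.calls == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, het / n, np.nan)

    def individual_missingness(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.zeros(self.n_individuals)
        return (self.calls == MISSING).sum(axis=1) / self.n_sites

    def site_summaries(self) -> pd.DataFrame:
        """Sites frame augmented with derived per-panel summaries."""
        out = self.sites.copy()
        out["n_called"] = self.site_n_called()
        out["call_rate"] = self.site_call_rate()
        out["mac"] = self.minor_allele_count()
        out["maf"] = self.minor_allele_freq()
        out["het_prop"] = self.het_proportion()
        return out


def population_allele_counts(
    gm: GenotypeMatrix, populations: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-population alternate-allele and called-allele counts.

    Returns ``(alt, tot, pops)`` where ``alt`` and ``tot`` are
    (J populations x L sites) arrays of alternate-allele counts and
    called allele (2 x genotype) counts.
    """
    pops = list(populations) if populations is not None else gm.population_labels
    alt = np.empty((len(pops), gm.n_sites), dtype=np.int64)
    tot = np.empty_like(alt)
    for j, p in enumerate(pops):
        idx = gm.pop_indices(p)
        alt[j] = gm.alt_allele_count(idx)
        tot[j] = 2 * gm.site_n_called(idx)
    return alt, tot, pops


def from_calls(
    calls: np.ndarray,
    positions: Sequence[int] | None = None,
    chrom: str | Sequence[str] = "chr1",
    populations: Sequence[str] | None = None,
    individual_ids: Sequence[str] | None = None,
    **layers: np.ndarray,
) -> GenotypeMatrix:
    """Convenience constructor used heavily in tests and simulations."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    if isinstance(chrom, str):
        chrom_arr = [chrom] * n_sites
    else:
        chrom_arr = list(chrom)
    sites = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
        }
    )
    ids = (
        list(individual_ids)
        if individual_ids is not None
        else [f"ind{i}" for i in range(n_ind)]
    )
    pops = (
        np.asarray(populations, dtype=object)
        if populations is not None
        else np.array(["pop1"] * n_ind, dtype=object)
    )
    return GenotypeMatrix(
        individual_ids=ids, populations=pops, sites=sites, calls=calls, **layers
    )
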