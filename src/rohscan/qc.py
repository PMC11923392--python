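"""Genotype-, site- and individual-level quality control.

Stages, in pipeline order: per-genotype GQ/depth masking, site filters
(minor-allele count, call rate, heterozygote pathologies), the HDplot
paralog screen, one-SNP-per-kb thinning, site missingness, and the
panel-specific MAF and individual-missingness filters.  ``build_panels``
chains them to produce the two analysis panels: a permissive-MAF
inbreeding panel (for ROH) and a stricter-MAF scan panel (for the
genome scan).

Threshold conventions: per-genotype GQ/depth cuts are strict (a call is
masked when GQ < gq_min or depth < depth_min), while missingness cuts
are inclusive (a site or individual is dropped when its missingness is
greater than or equal to the threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


@dataclass
class QCParams:
    gq_min: int = 30
    depth_min: int = 6
    min_mac: int = 3
    min_call_rate: float = 0.70
    hdplot_d_max: float = 5.0
    thin_bin_bp: int = 1000
    max_site_missing: float = 0.20
    inbreeding_maf: float = 0.01
    inbreeding_max_ind_missing: float = 0.10
    scan_maf: float = 0.05
    scan_max_ind_missing: float = 0.20


class FilterReport:
    """Per-stage accounting of sites/individuals/genotypes removed."""

    def __init__(self) -> None:
        self.stages: list[dict[str, object]] = []

    def add(
        self,
        stage: str,
        sites_in: int,
        sites_out: int,
        individuals_in: int,
        individuals_out: int,
        genotypes_masked: int = 0,
    ) -> None:
        self.stages.append(
            {
                "stage": stage,
                "sites_in": sites_in,
                "sites_removed": sites_in - sites_out,
                "sites_out": sites_out,
                "individuals_in": individuals_in,
                "individuals_removed": individuals_in - individuals_out,
                "individuals_out": individuals_out,
                "genotypes_masked": genotypes_masked,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def check(self) -> None:
        for s in self.stages:
            assert s["sites_in"] - s["sites_removed"] == s["sites_out"]
            assert (
                s["individuals_in"] - s["individuals_removed"]
                == s["individuals_out"]
            )


def mask_low_quality_genotypes(
    gm: GenotypeMatrix, gq_min: int = 30, depth_min: int = 6
) -> GenotypeMatrix:
    """Set calls with GQ < gq_min or depth < depth_min to missing.

    If the matrix carries no GQ/depth layers the stage is skipped with
    a warning, matching upstream VCFs that lack those FORMAT fields.
    """
    if gm.gq is None and gm.depth is None:
        warnings.warn("no GQ/depth layers; quality masking skipped", stacklevel=2)
        return gm
    out = gm.copy()
    bad = np.zeros(out.calls.shape, dtype=bool)
    if out.gq is not None:
        bad |= out.gq < gq_min
    if out.depth is not None:
        bad |= out.depth < depth_min
    out.calls[bad] = MISSING
    return out


def filter_sites(
    gm: GenotypeMatrix, min_mac: int = 3, min_call_rate: float = 0.70
) -> GenotypeMatrix:
    """Drop sites failing MAC, call-rate or heterozygote-pathology rules.

    A site is removed when its minor allele is seen fewer than
    ``min_mac`` times, when fewer than ``min_call_rate`` of individuals
    are called, when no heterozygote is observed, or when every called
    genotype is heterozygous (a classic paralog signature).
    """
    mac = gm.minor_allele_count()
    rate = gm.site_call_rate()
    n_called = gm.site_n_called()
    n_het = (gm.calls == 1).sum(axis=0)
    keep = (
        (mac >= min_mac)
        & (rate >= min_call_rate)
        & (n_het > 0)
        & (n_het < n_called)
    )
    return gm.subset(sites=keep)


def hdplot(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site HDplot summaries: heterozygote proportion H and read-ratio
    deviation D.

    Pooling ref reads ``a`` and alt reads ``b`` across all heterozygous
    calls at a site, D = (a - b) / sqrt(a + b), the standard-normal
    deviation of the pooled allele ratio from 1/2.  Sites without
    heterozygous calls (or without reads at them) get D = NaN and are
    flagged ``d_undefined``.
    """
    if gm.allele_depth is None:
        raise ValueError("allele_depth layer required for HDplot")
    het = gm.calls == 1
    ad = gm.allele_depth
    a = np.where(het[..., None], ad, 0)[..., 0].sum(axis=0).astype(float)
    b = np.where(het[..., None], ad, 0)[..., 1].sum(axis=0).astype(float)
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, (a - b) / np.sqrt(tot), np.nan)
    out = pd.DataFrame(
        {
            "chrom": gm.sites["chrom"],
            "pos": gm.sites["pos"],
            "H": gm.het_proportion(),
            "D": d,
            "d_undefined": ~(tot > 0),
        }
    )
    return out


def hdplot_screen(
    gm: GenotypeMatrix, d_max: float = 5.0
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove putative paralogs with |D| > d_max; undefined-D sites are
    retained (flagged in the returned table)."""
    table = hdplot(gm)
    d = table["D"].to_numpy()
    keep = ~(np.abs(d) > d_max)  # NaN compares False -> retained
    table["removed"] = ~keep
    return gm.subset(sites=keep), table


def thin_one_per_kb(gm: GenotypeMatrix, bin_bp: int = 1000) -> GenotypeMatrix:
    """Keep one SNP per non-overlapping 1-kb bin per chromosome.

    Bins cover positions 1..bin_bp, bin_bp+1..2*bin_bp, ...; within a
    bin the SNP with the highest call rate wins, ties going to the
    lowest position, so the choice is deterministic.
    """
    chrom = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    rate = gm.site_call_rate()
    bin_idx = (pos - 1) // bin_bp
    keep: list[int] = []
    df = pd.DataFrame({"chrom": chrom, "bin": bin_idx, "rate": rate})
    for _, grp in df.groupby(["chrom", "bin"], sort=False):
        best = grp.sort_values(["rate"], ascending=False, kind="stable").index[0]
        keep.append(best)
    keep.sort()
    return gm.subset(sites=np.asarray(keep, dtype=int))


def filter_site_missingness(
    gm: GenotypeMatrix, max_missing: float = 0.20
) -> GenotypeMatrix:
    """Drop sites whose missingness is >= max_missing (inclusive)."""
    missing = 1.0 - gm.site_call_rate()
    return gm.subset(sites=missing < max_missing)


def filter_maf(gm: GenotypeMatrix, maf_min: float) -> GenotypeMatrix:
    """Drop sites with minor-allele frequency below ``maf_min``."""
    if maf_min <= 0:
        return gm
    maf = gm.minor_allele_freq()
    keep = ~(maf < maf_min)  # NaN (no calls) handled by missingness stages
    keep &= ~np.isnan(maf)
    return gm.subset(sites=keep)


def filter_individuals(gm: GenotypeMatrix, max_missing: float) -> GenotypeMatrix:
    """Drop individuals with missingness >= max_missing (inclusive)."""
    miss = gm.individual_missingness()
    keep = miss < max_missing
    if not keep.any():
        raise ValueError("individual-missingness filter removed every individual")
    return gm.subset(individuals=keep)


def build_panels(
    gm: GenotypeMatrix,
    params: QCParams | None = None,
    scan_populations: list[str] | None = None,
) -> tuple[GenotypeMatrix, GenotypeMatrix, FilterReport]:
    """Run the shared QC chain, then branch into the two analysis panels.

    Shared chain: GQ/depth masking, site filters, HDplot (when allele
    depths exist), 1-per-kb thinning, site missingness.  The inbreeding
    panel then applies the permissive MAF (default 0.01, computed
    jointly over all populations) and the strict 10% individual
    missingness cut; the scan panel applies MAF 0.05 and the 20%
    individual cut, restricted to ``scan_populations`` when given.
    """
    params = params or QCParams()
    report = FilterReport()

    def log(stage: str, before: GenotypeMatrix, after: GenotypeMatrix, masked=0):
        report.add(
            stage,
            before.n_sites,
            after.n_sites,
            before.n_individuals,
            after.n_individuals,
            masked,
        )

    step = gm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        masked = mask_low_quality_genotypes(step, params.gq_min, params.depth_min)
    n_masked = int(
        ((masked.calls == MISSING) & (step.calls != MISSING)).sum()
    )
    log("gq_depth_mask", step, masked, n_masked)
    step = masked

    after = filter_sites(step, params.min_mac, params.min_call_rate)
    log("site_filters", step, after)
    step = after

    if step.allele_depth is not None:
        after, _ = hdplot_screen(step, params.hdplot_d_max)
        log("hdplot", step, after)
        step = after

    after = thin_one_per_kb(step, params.thin_bin_bp)
    log("thin_1_per_kb", step, after)
    step = after

    after = filter_site_missingness(step, params.max_site_missing)
    log("site_missingness", step, after)
    step = after

    inbreeding = filter_maf(step, params.inbreeding_maf)
    inbreeding = filter_individuals(inbreeding, params.inbreeding_max_ind_missing)
    log("inbreeding_panel", step, inbreeding)

    scan = step
    if scan_populations is not None:
        rows = np.isin(scan.populations, scan_populations)
        scan = scan.subset(individuals=rows)
    scan = filter_maf(scan, params.scan_maf)
    scan = filter_individuals(scan, params.scan_max_ind_missing)
    log("scan_panel", step, scan)

    report.check()
    return inbreeding, scan, report
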