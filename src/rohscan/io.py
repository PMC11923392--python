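"""Readers and writers for the formats the pipeline touches.

VCF 4.2 (GT/GQ/DP/AD) in and out, sample-to-population maps, trait
tables and ancestry-dosage tracks as TSV, ROH segments as BED, and the
per-run output bundle with its JSON manifest.  Internal coordinates
are 1-based inclusive (the VCF convention); BED exports convert to
0-based half-open.
"""

from __future__ import annotations

import datetime
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .ancestry import AncestryWindow
from .core import MISSING, GenotypeMatrix
from .roh import ROHSegment

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# popmap / traits / dosage tables
# ----------------------------------------------------------------------
def read_popmap(path: str | Path) -> dict[str, str]:
    """Two-column sample<TAB>population map, no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"])
    return dict(zip(df["sample"].astype(str), df["population"].astype(str)))


def write_popmap(popmap: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


def read_traits(path: str | Path) -> pd.DataFrame:
    """Population-level trait table: ``population`` column plus one
    numeric column per trait.  All values must be positive."""
    df = pd.read_csv(path, sep="\t").set_index("population")
    if (df <= 0).any().any():
        raise ValueError("trait values must be positive")
    return df


def read_dosage_tracks(path: str | Path) -> pd.DataFrame:
    """Tidy dosage-track TSV: individual, chrom, pos, replicate,
    dosage_nonnative (raw dosages accepted)."""
    df = pd.read_csv(path, sep="\t")
    required = {"individual", "chrom", "pos", "replicate", "dosage_nonnative"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dosage TSV lacks columns: {sorted(missing)}")
    return df


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------
def read_vcf(
    path: str | Path,
    popmap: str | Path | dict[str, str],
    skip_non_biallelic_snps: bool = True,
) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a genotype matrix.

    GQ / DP / AD layers are populated when the FORMAT fields are
    present.  Non-biallelic or non-SNP records are skipped (and
    counted) when ``skip_non_biallelic_snps``, otherwise they raise.
    Every sample must appear in the popmap; an unsorted VCF is a hard
    error.
    """
    if not isinstance(popmap, dict):
        popmap = read_popmap(popmap)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in popmap]
    if unknown:
        raise ValueError(f"samples missing from popmap: {unknown}")

    rows: list[dict] = []
    calls_cols: list[np.ndarray] = []
    gq_cols: list[np.ndarray] = []
    dp_cols: list[np.ndarray] = []
    ad_cols: list[np.ndarray] = []
    have_gq = have_dp = have_ad = False
    n_skipped = 0
    last: tuple[str, int] | None = None
    seen_chroms: list[str] = []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            if skip_non_biallelic_snps:
                n_skipped += 1
                continue
            raise ValueError(
                f"non-biallelic/non-SNP record at {var.CHROM}:{var.POS}"
            )
        if last is not None:
            if var.CHROM == last[0] and var.POS < last[1]:
                raise ValueError(f"unsorted VCF at {var.CHROM}:{var.POS}")
            if var.CHROM != last[0] and var.CHROM in seen_chroms:
                raise ValueError(
                    f"chromosome {var.CHROM} appears in multiple blocks"
                )
        if not seen_chroms or seen_chroms[-1] != var.CHROM:
            seen_chroms.append(var.CHROM)
        last = (var.CHROM, var.POS)
        rows.append(
            {"chrom": var.CHROM, "pos": var.POS, "ref": var.REF, "alt": var.ALT[0]}
        )
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2, 3=missing
        gt[gt == 3] = MISSING
        calls_cols.append(gt)
        gq = var.gt_quals
        if gq is not None:
            have_gq = True
            gq = np.asarray(gq, dtype=float)
            gq_cols.append(np.where(np.isfinite(gq) & (gq >= 0), gq, 0))
        dp = var.gt_depths
        if dp is not None:
            have_dp = True
            dp_cols.append(np.maximum(np.asarray(dp, dtype=np.int32), 0))
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is not None and ad.shape[1] >= 2:
            have_ad = True
            ad_cols.append(np.maximum(ad[:, :2].astype(np.int32), 0))
    if n_skipped:
        log.info("skipped %d non-biallelic/non-SNP records", n_skipped)

    sites = pd.DataFrame(rows)
    calls = (
        np.column_stack(calls_cols)
        if calls_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        individual_ids=samples,
        populations=np.array([popmap[s] for s in samples], dtype=object),
        sites=sites
        if len(sites)
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]),
        calls=calls,
        gq=np.column_stack(gq_cols).astype(np.int16)
        if have_gq and len(gq_cols) == len(rows)
        else None,
        depth=np.column_stack(dp_cols)
        if have_dp and len(dp_cols) == len(rows)
        else None,
        allele_depth=np.stack(ad_cols, axis=1)
        if have_ad and len(ad_cols) == len(rows)
        else None,
    )
    return gm


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with GT and any
    available GQ/DP/AD layers."""
    fmt_fields = ["GT"]
    if gm.gq is not None:
        fmt_fields.append("GQ")
    if gm.depth is not None:
        fmt_fields.append("DP")
    if gm.allele_depth is not None:
        fmt_fields.append("AD")
    chrom_all = gm.sites["chrom"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.gq is not None:
            fh.write(
                '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
            )
        if gm.depth is not None:
            fh.write(
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
            )
        if gm.allele_depth is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
            )
        for c in gm.chromosomes():
            length = int(pos_all[chrom_all == c].max()) if gm.n_sites else 0
            fh.write(f"##contig=<ID={c},length={length + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individual_ids)
            + "\n"
        )
        fmt = ":".join(fmt_fields)
        for s in range(gm.n_sites):
            site = gm.sites.iloc[s]
            cells = []
            for i in range(gm.n_individuals):
                parts = [_GT_STRINGS[int(gm.calls[i, s])]]
                if gm.gq is not None:
                    parts.append(str(int(gm.gq[i, s])))
                if gm.depth is not None:
                    parts.append(str(int(gm.depth[i, s])))
                if gm.allele_depth is not None:
                    parts.append(
                        f"{int(gm.allele_depth[i, s, 0])},{int(gm.allele_depth[i, s, 1])}"
                    )
                cells.append(":".join(parts))
            fh.write(
                f"{site['chrom']}\t{site['pos']}\t.\t{site['ref']}\t{site['alt']}"
                f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


# ----------------------------------------------------------------------
# BED exports (0-based half-open)
# ----------------------------------------------------------------------
def roh_bed(segments: list[ROHSegment]) -> pd.DataFrame:
    """ROH segments as BED rows (chrom, 0-based start, half-open end)."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start - 1,
                "end": s.end,
                "individual": s.individual,
                "n_snps": s.n_snps,
            }
            for s in segments
        ],
        columns=["chrom", "start", "end", "individual", "n_snps"],
    )


def write_roh_bed(segments: list[ROHSegment], path: str | Path) -> None:
    roh_bed(segments).to_csv(path, sep="\t", header=False, index=False)


def windows_bed(windows: list[AncestryWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": w.chrom,
                "start": w.start - 1,
                "end": w.end,
                "individual": w.individual,
                "dosage_nonnative": w.dosage,
            }
            for w in windows
        ],
        columns=["chrom", "start", "end", "individual", "dosage_nonnative"],
    )


# ----------------------------------------------------------------------
# run outputs
# ----------------------------------------------------------------------
def write_outputs(
    results: dict[str, object],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
    overwrite: bool = False,
) -> list[Path]:
    """Write a results bundle plus a JSON run manifest.

    ``results`` maps names to pandas frames (written as ``<name>.tsv``),
    ROH segment lists (``<name>.bed``), genotype matrices
    (``<name>.vcf``) or plain JSON-serializable objects (into the
    manifest).  Existing files raise unless ``overwrite``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict[str, object] = {
        "config": config or {},
        "seed": seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": {},
    }

    def target(name: str, ext: str) -> Path:
        p = out_dir / f"{name}.{ext}"
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists (pass overwrite=True)")
        manifest["outputs"][name] = p.name  # type: ignore[index]
        written.append(p)
        return p

    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(target(name, "tsv"), sep="\t", index=False)
        elif isinstance(obj, GenotypeMatrix):
            write_vcf(obj, target(name, "vcf"))
        elif (
            isinstance(obj, list)
            and obj
            and isinstance(obj[0], ROHSegment)
        ):
            write_roh_bed(obj, target(name, "bed"))
        elif isinstance(obj, list) and not obj:
            # empty segment list still gets an (empty) BED for pipeline
            # composability
            target(name, "bed").write_text("")
        else:
            manifest.setdefault("values", {})[name] = obj  # type: ignore[union-attr]
    mpath = out_dir / "manifest.json"
    if mpath.exists() and not overwrite:
        raise FileExistsError(f"{mpath} exists (pass overwrite=True)")
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(mpath)
    return written
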