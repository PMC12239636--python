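"""Readers and writers for the pipeline's exchange formats.

Conventions: VCF and everything derived from it (marker tables, map TSV)
is 1-based inclusive; BED-style outputs (coverage strata) are 0-based
half-open. GT round-trips bit-exactly through write -> read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from neoxqtl.containers import NA, GeneticMap, GenotypeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sample sheet / phenotypes / map
# ---------------------------------------------------------------------------
def write_sample_sheet(gm: GenotypeMatrix, path: str | Path) -> None:
    cols = ["id", "sex", "generation"] + (
        ["family"] if "family" in gm.individuals.columns else []
    )
    gm.individuals[cols].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"id", "sex", "generation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_map_tsv(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# genetic map; pos_bp is 1-based inclusive (VCF convention)\n")
        gmap.to_frame().to_csv(fh, sep="\t", index=False)


def read_map_tsv(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    return GeneticMap.from_frame(df)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------
def _alt_dosage(gm: GenotypeMatrix) -> np.ndarray:
    """Calls as ALT-allele dosage (the on-disk representation)."""
    calls = gm.calls
    if not gm.polarized:
        return calls
    origin = gm.markers["origin_of_alt"].to_numpy()
    flip = (origin == "UT")[:, None]
    out = np.where((calls != NA) & flip, 2 - calls, calls)
    return out.astype(np.int8)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as uncompressed VCF 4.2 with GT/DP/GQ."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    for chrom, sub in gm.markers.groupby("chrom", sort=False):
        header.contigs.add(str(chrom), length=int(sub["pos_bp"].max()) + 1)
    for iid in gm.individuals["id"]:
        header.add_sample(str(iid))
    dosage = _alt_dosage(gm)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), NA: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in range(gm.n_markers):
            mk = gm.markers.iloc[r]
            rec = vf.new_record(
                contig=str(mk["chrom"]),
                start=int(mk["pos_bp"]) - 1,
                stop=int(mk["pos_bp"]) - 1 + len(mk["ref"]),
                alleles=(str(mk["ref"]), str(mk["alt"])),
                id=str(mk["name"]),
            )
            for c, sample in enumerate(rec.samples.values()):
                sample["GT"] = gt_map[int(dosage[r, c])]
                if gm.dp is not None:
                    sample["DP"] = int(gm.dp[r, c])
                if gm.gq is not None:
                    sample["GQ"] = int(gm.gq[r, c])
            vf.write(rec)


def read_genotype_vcf(
    path: str | Path,
    sample_sheet: pd.DataFrame,
    x_chrom: str = "X",
) -> tuple[GenotypeMatrix, dict]:
    """Read a genotyped VCF into an (unpolarized) GenotypeMatrix.

    All VCF samples must appear in the sheet. Multiallelic records are
    excluded and counted in the returned report dict.
    """
    sheet = sample_sheet.set_index("id")
    report = {"multiallelic_excluded": 0, "records": 0}
    rows = []
    calls_rows = []
    dp_rows = []
    gq_rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        missing = [s for s in samples if s not in sheet.index]
        if missing:
            raise ValueError(f"VCF samples absent from sample sheet: {missing}")
        for line_no, rec in enumerate(vf, start=1):
            report["records"] += 1
            if rec.alts is None or len(rec.alts) != 1:
                report["multiallelic_excluded"] += 1
                continue
            try:
                name = rec.id or f"{rec.chrom}_{rec.pos}"
                rows.append(
                    (name, rec.chrom, rec.pos, rec.ref, rec.alts[0], None)
                )
                call_row = np.empty(len(samples), dtype=np.int8)
                dp_row = np.zeros(len(samples), dtype=np.int32)
                gq_row = np.zeros(len(samples), dtype=np.int32)
                for c, s in enumerate(samples):
                    smp = rec.samples[s]
                    gt = smp.get("GT")
                    if gt is None or any(a is None for a in gt):
                        call_row[c] = NA
                    else:
                        call_row[c] = sum(gt)
                    dp_row[c] = smp.get("DP") or 0
                    gq_row[c] = smp.get("GQ") or 0
                calls_rows.append(call_row)
                dp_rows.append(dp_row)
                gq_rows.append(gq_row)
            except (ValueError, TypeError) as exc:
                raise ValueError(f"malformed VCF record at line ~{line_no}: {exc}") from exc
    markers = pd.DataFrame(
        rows, columns=["name", "chrom", "pos_bp", "ref", "alt", "origin_of_alt"]
    )
    individuals = sheet.loc[samples].reset_index()
    gm = GenotypeMatrix(
        markers=markers,
        individuals=individuals,
        calls=np.array(calls_rows, dtype=np.int8).reshape(len(markers), len(samples)),
        dp=np.array(dp_rows, dtype=np.int32).reshape(len(markers), len(samples)),
        gq=np.array(gq_rows, dtype=np.int32).reshape(len(markers), len(samples)),
        polarized=False,
        x_chrom=x_chrom,
    )
    return gm, report


def write_strata_bed(strata: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# coverage strata; 0-based half-open (BED convention)\n")
        for r in strata.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\t{r.stratum}\t{r.mean_ratio:.4f}\n"
            )


def write_depth_tsv(depth: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-position depth; pos is 1-based\n")
        depth.to_csv(fh, sep="\t", index=False)


def read_depth_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "pos", "depth"}
    if not required <= set(df.columns):
        raise ValueError(f"depth file needs columns {sorted(required)}")
    return df
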