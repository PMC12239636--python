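"""Genotype filter cascade and cross-design X-genotype validation.

The cascade order is fixed: call quality -> parental-informative sites
(with chromosome restriction) -> marker missingness -> individual
missingness -> thinning -> impossible-X flags -> segregation distortion.
Marker missingness is applied before individual missingness; the choice is
arbitrary but stable, and re-running the cascade on its own output is the
identity.

Two X-genotype classes are impossible under the cross design (UT female x
AZ male P0, so the F1 father transmits one intact UT X): heterozygous F2
males (hemizygous X) and F2 females homozygous for two AZ-type X's. Flags
concentrated on a single marker across multiple individuals would require
recurrent double crossovers and mark a bad marker; isolated flags are
treated as bad calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from neoxqtl.containers import AA, AB, BB, NA, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FlagRecord:
    marker_index: int
    marker_name: str
    individual_id: str
    reason: str  # "male_het_X" | "female_AZAZ_X"


@dataclass
class FilterReport:
    """Per-stage record of what was removed."""

    rows: list[tuple[str, str, str]]

    def __init__(self) -> None:
        self.rows = []

    def add(self, stage: str, item: str, reason: str) -> None:
        self.rows.append((stage, item, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["stage", "item", "reason"])


def filter_call_quality(
    gm: GenotypeMatrix,
    gq_min: float = 30,
    dp_min: float = 20,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Mask calls failing GQ > gq_min or DP > dp_min; drop indel/non-SNP sites.

    Thresholds are strict inequalities: a call at exactly GQ 30 or DP 20 is
    removed. Without DP/GQ annotations the call-level filter is skipped with
    a warning.
    """
    out = gm.copy()
    is_snp = (
        out.markers["ref"].str.len().eq(1)
        & out.markers["alt"].str.len().eq(1)
        & ~out.markers["alt"].str.contains(",", regex=False)
    ).to_numpy()
    if report is not None:
        for name in out.markers.loc[~is_snp, "name"]:
            report.add("call_quality", name, "indel_or_multiallelic")
    out = out.take_markers(is_snp)
    if out.gq is None or out.dp is None:
        log.warning("DP/GQ absent; call-quality filter is a no-op")
        return out
    fail = (out.gq <= gq_min) | (out.dp <= dp_min)
    out.calls = np.where(fail, NA, out.calls).astype(np.int8)
    return out


def select_informative_sites(
    gm: GenotypeMatrix,
    p0_az_id: str,
    p0_ut_id: str,
    chromosomes: list[str] | None = None,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Keep sites where the two P0s are homozygous for different alleles.

    Polarizes codes to AZ-allele dosage and restricts to the named
    chromosome-level sequences (defaults to the chromosomes already present).
    """
    ids = list(gm.individuals["id"])
    for pid in (p0_az_id, p0_ut_id):
        if pid not in ids:
            raise ValueError(f"P0 individual {pid!r} not in matrix")
    az_col = ids.index(p0_az_id)
    ut_col = ids.index(p0_ut_id)
    az, ut = gm.calls[:, az_col], gm.calls[:, ut_col]
    hom = np.isin(az, (AA, BB)) & np.isin(ut, (AA, BB))
    informative = hom & (az != ut)
    if chromosomes is not None:
        on_chrom = gm.markers["chrom"].isin(chromosomes).to_numpy()
    else:
        on_chrom = np.ones(gm.n_markers, dtype=bool)
    keep = informative & on_chrom
    if report is not None:
        for name in gm.markers.loc[~informative, "name"]:
            report.add("informative_sites", name, "p0_not_informative")
        for name in gm.markers.loc[informative & ~on_chrom, "name"]:
            report.add("informative_sites", name, "off_named_chromosomes")
    out = gm.take_markers(keep)
    if not gm.polarized:
        # ALT-dosage codes: the AZ parent's call tells us which allele is AZ
        az_is_alt = out.calls[:, az_col] == AA
        flip = ~az_is_alt
        nonmiss = out.calls != NA
        flipped = (2 - out.calls).astype(np.int8)
        out.calls = np.where(nonmiss & flip[:, None], flipped, out.calls).astype(np.int8)
        out.markers = out.markers.assign(
            origin_of_alt=np.where(az_is_alt, "AZ", "UT")
        )
        out.polarized = True
    return out


def filter_missingness(
    gm: GenotypeMatrix,
    marker_missing_max: float = 0.68,
    individual_missing_max: float = 0.99,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Drop markers then individuals exceeding missingness ceilings.

    Both thresholds are inclusive (a marker missing in exactly 68% of
    individuals is removed). P0 individuals are exempt from the individual
    filter so polarization stays possible downstream.
    """
    marker_keep = gm.marker_missingness() < marker_missing_max
    if report is not None:
        for name in gm.markers.loc[~marker_keep, "name"]:
            report.add("marker_missingness", name, "missingness>=max")
    out = gm.take_markers(marker_keep)
    ind_miss = out.individual_missingness()
    is_p0 = (out.individuals["generation"] == "P0").to_numpy()
    ind_keep = (ind_miss < individual_missing_max) | is_p0
    if report is not None:
        for iid in out.individuals.loc[~ind_keep, "id"]:
            report.add("individual_missingness", iid, "missingness>=max")
    out = out.take_individuals(ind_keep)
    if out.n_markers == 0 or out.n_individuals == 0:
        raise ValueError("all data filtered")
    return out


def thin_markers(
    gm: GenotypeMatrix,
    min_gap_bp: int = 100_000,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Keep one marker per ``min_gap_bp``, greedy left-to-right per chromosome.

    The first marker of a chromosome is always kept; a later marker is kept
    iff it is at least ``min_gap_bp`` beyond the last kept one.
    """
    keep = np.zeros(gm.n_markers, dtype=bool)
    for chrom, sub in gm.markers.groupby("chrom", sort=False):
        last = None
        for idx, bp in zip(sub.index, sub["pos_bp"]):
            if last is None or bp - last >= min_gap_bp:
                keep[idx] = True
                last = bp
    if report is not None:
        for name in gm.markers.loc[~keep, "name"]:
            report.add("thinning", name, f"within_{min_gap_bp}bp_of_kept_marker")
    return gm.take_markers(keep)


def flag_impossible_x(gm: GenotypeMatrix) -> list[FlagRecord]:
    """Flag F2 male heterozygous and F2 female AZ/AZ calls on the X.

    Requires a polarized matrix; autosomes are never flagged. Unknown sex
    raises, naming the individual.
    """
    if not gm.polarized:
        raise ValueError("matrix must be polarized before X validation")
    bad_sex = ~gm.individuals["sex"].isin(["M", "F"])
    if bad_sex.any():
        raise ValueError(
            f"unknown sex for individual {gm.individuals.loc[bad_sex, 'id'].iloc[0]!r}"
        )
    flags: list[FlagRecord] = []
    x_rows = np.flatnonzero(gm.marker_is_x())
    f2 = gm.individual_mask(generation="F2")
    male = f2 & (gm.individuals["sex"] == "M").to_numpy()
    female = f2 & (gm.individuals["sex"] == "F").to_numpy()
    for r in x_rows:
        name = gm.markers.at[r, "name"]
        for c in np.flatnonzero(male & (gm.calls[r] == AB)):
            flags.append(FlagRecord(int(r), name, gm.individuals.at[c, "id"], "male_het_X"))
        for c in np.flatnonzero(female & (gm.calls[r] == AA)):
            flags.append(FlagRecord(int(r), name, gm.individuals.at[c, "id"], "female_AZAZ_X"))
    return flags


def resolve_flags(
    gm: GenotypeMatrix,
    flags: list[FlagRecord],
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Drop markers flagged in >= 2 individuals; NA the remaining flags."""
    out = gm.copy()
    by_marker: dict[int, list[FlagRecord]] = {}
    for f in flags:
        by_marker.setdefault(f.marker_index, []).append(f)
    drop = np.zeros(out.n_markers, dtype=bool)
    ids = list(out.individuals["id"])
    for idx, fl in by_marker.items():
        if len(fl) >= 2:
            drop[idx] = True
            if report is not None:
                report.add("x_flags", fl[0].marker_name, "multi_individual_flags")
        else:
            out.calls[idx, ids.index(fl[0].individual_id)] = NA
    return out.take_markers(~drop)


def segregation_distortion_filter(
    gm: GenotypeMatrix,
    alpha: float = 0.01,
    min_calls: int = 10,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Drop autosomal markers departing from 1:2:1 at P < alpha (chi-square, 2 df).

    X markers are exempt: male hemizygosity shows up as homozygous calls and
    legitimately skews the genotype table. Markers with fewer than
    ``min_calls`` F2 genotypes are skipped with a warning.
    """
    f2 = gm.individual_mask(generation="F2")
    keep = np.ones(gm.n_markers, dtype=bool)
    is_x = gm.marker_is_x()
    for r in range(gm.n_markers):
        if is_x[r]:
            continue
        row = gm.calls[r, f2]
        counts = np.array([(row == AA).sum(), (row == AB).sum(), (row == BB).sum()])
        n = counts.sum()
        if n < min_calls:
            log.warning(
                "marker %s: only %d calls, segregation test skipped",
                gm.markers.at[r, "name"], n,
            )
            continue
        expected = n * np.array([0.25, 0.5, 0.25])
        p = stats.chisquare(counts, expected).pvalue
        if p < alpha:
            keep[r] = False
            if report is not None:
                report.add("segregation_distortion", gm.markers.at[r, "name"], f"p={p:.3g}")
    return gm.take_markers(keep)


def run_qc(
    gm: GenotypeMatrix,
    p0_az_id: str,
    p0_ut_id: str,
    gq_min: float = 30,
    dp_min: float = 20,
    marker_missing_max: float = 0.68,
    individual_missing_max: float = 0.99,
    min_gap_bp: int = 100_000,
    distortion_alpha: float = 0.01,
    chromosomes: list[str] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """The full cascade in its fixed order. Returns (filtered matrix, report)."""
    report = FilterReport()
    out = filter_call_quality(gm, gq_min, dp_min, report)
    out = select_informative_sites(out, p0_az_id, p0_ut_id, chromosomes, report)
    out = filter_missingness(out, marker_missing_max, individual_missing_max, report)
    out = thin_markers(out, min_gap_bp, report)
    flags = flag_impossible_x(out)
    out = resolve_flags(out, flags, report)
    out = segregation_distortion_filter(out, distortion_alpha, report=report)
    return out, report
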