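"""Haplotype inference, obligate crossover counts and sex comparisons.

On the X every F2 carries exactly one maternally recombined gamete, so the
parental origin at each marker is read directly: hemizygous males from
their homozygous-looking calls (AA -> AZ, BB -> UT) and females through the
constitutively UT paternal X (AB -> maternal AZ, BB -> maternal UT).
Crossover counts are minimal (obligate): the smallest number of exchanges
consistent with the observed non-missing codes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from neoxqtl.containers import AA, AB, BB, NA, GenotypeMatrix
from neoxqtl.linkmap import maternal_x_origins


def infer_haplotypes(gm: GenotypeMatrix, chrom: str) -> pd.DataFrame:
    """Per-individual origin (X) or genotype (autosome) sequence on ``chrom``.

    Returns a markers x F2-individuals DataFrame: on the X values are
    {"AZ", "UT", NaN}; on autosomes the 3-class genotype labels. Impossible
    X codes (male AB / female AA) raise -- the QC contract guarantees their
    absence.
    """
    sub = gm.subset_chrom(chrom)
    f2 = sub.individual_mask(generation="F2")
    calls = sub.calls[:, f2]
    ids = sub.individuals.loc[f2, "id"].to_numpy()
    if chrom == gm.x_chrom:
        sexes = sub.individuals.loc[f2, "sex"].to_numpy()
        male = sexes == "M"
        bad_m = (calls[:, male] == AB).any()
        bad_f = (calls[:, ~male] == AA).any()
        if bad_m or bad_f:
            raise ValueError("impossible X genotypes present; run QC first")
        origins = maternal_x_origins(calls, sexes)
        data = np.where(origins == 1, "AZ", np.where(origins == 0, "UT", None))
    else:
        labels = {AA: "AA", AB: "AB", BB: "BB"}
        data = np.where(
            calls == NA, None, np.vectorize(lambda c: labels.get(int(c), None))(calls)
        )
    return pd.DataFrame(data, index=sub.markers["name"], columns=ids)


def count_crossovers(seq: np.ndarray, is_x: bool) -> float:
    """Minimal crossover count for one individual's marker sequence.

    X/origin sequences (codes {0, 1, -1}): transitions between consecutive
    non-missing differing origins. Autosomal dosage sequences
    (codes {0, 1, 2, -1}): obligate events are the absolute dosage change
    between consecutive non-missing markers (AA<->BB = 2, hom<->het = 1),
    which equals the exhaustive minimum over phase assignments. All-missing
    sequences return NaN.
    """
    seq = np.asarray(seq)
    obs = seq[seq != NA]
    if len(obs) == 0:
        return float("nan")
    if is_x:
        return float((np.diff(obs) != 0).sum())
    return float(np.abs(np.diff(obs.astype(int))).sum())


def crossover_counts(gm: GenotypeMatrix, chrom: str) -> pd.DataFrame:
    """XOCount table: individual, sex, chrom, count for all F2s."""
    sub = gm.subset_chrom(chrom)
    f2 = sub.individual_mask(generation="F2")
    calls = sub.calls[:, f2]
    sexes = sub.individuals.loc[f2, "sex"].to_numpy()
    ids = sub.individuals.loc[f2, "id"].to_numpy()
    is_x = chrom == gm.x_chrom
    if is_x:
        coded = maternal_x_origins(calls, sexes)
        coded = np.where(coded < 0, NA, coded)
    else:
        coded = calls
    counts = [count_crossovers(coded[:, j], is_x) for j in range(coded.shape[1])]
    return pd.DataFrame(
        {"individual": ids, "sex": sexes, "chrom": chrom, "count": counts}
    )


def compare_sexes(
    counts: pd.DataFrame, chromosomes: list[str], n_tests: int = 12
) -> pd.DataFrame:
    """Per-chromosome two-sided rank-sum test of female vs male counts.

    W is the Mann-Whitney statistic of the female sample (rank-sum
    convention of the female counts minus its minimum); the normal
    approximation with tie correction and continuity correction is used.
    P-values are Bonferroni-adjusted over ``n_tests``.
    """
    rows = []
    for chrom in chromosomes:
        sub = counts[(counts["chrom"] == chrom) & counts["count"].notna()]
        f = sub.loc[sub["sex"] == "F", "count"].to_numpy(dtype=float)
        m = sub.loc[sub["sex"] == "M", "count"].to_numpy(dtype=float)
        if len(f) == 0 or len(m) == 0:
            rows.append((chrom, len(f), np.nan, np.nan, len(m), np.nan, np.nan,
                         np.nan, np.nan, np.nan))
            continue
        res = stats.mannwhitneyu(f, m, alternative="two-sided", method="asymptotic")
        w = float(res.statistic)
        p = float(res.pvalue)
        rows.append(
            (
                chrom,
                len(f),
                float(f.mean()),
                float(f.std(ddof=1) / np.sqrt(len(f))) if len(f) > 1 else np.nan,
                len(m),
                float(m.mean()),
                float(m.std(ddof=1) / np.sqrt(len(m))) if len(m) > 1 else np.nan,
                w,
                p,
                min(1.0, n_tests * p),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "n_f", "mean_f", "se_f", "n_m", "mean_m", "se_m",
            "w_statistic", "p_raw", "p_adjusted",
        ],
    )


def region_restricted_counts(
    gm: GenotypeMatrix,
    chrom: str,
    region: tuple[float, float],
    n_tests: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Crossover counts using only markers inside ``region`` (bp, inclusive).

    Returns (counts table, sex comparison). Useful modes: excluding the
    neo-Y-similar prefix, or restricting to the ancestral-X (>= 48 Mb).
    """
    sub = gm.subset_chrom(chrom)
    pos = sub.markers["pos_bp"].to_numpy()
    inside = (pos >= region[0]) & (pos <= region[1])
    if not inside.any():
        raise ValueError(f"no markers inside region {region} on {chrom}")
    restricted = sub.take_markers(inside)
    restricted.x_chrom = gm.x_chrom
    counts = crossover_counts(restricted, chrom)
    comparison = compare_sexes(counts, [chrom], n_tests=n_tests)
    return counts, comparison


def haplotype_frequency(
    gm: GenotypeMatrix,
    chrom: str,
    region: tuple[float, float],
) -> dict:
    """Origin tally among males without a crossover inside ``region``.

    Returns counts of AZ and UT non-recombinant male X haplotypes in the
    region plus a two-sided binomial p-value against equal transmission.
    """
    counts, _ = region_restricted_counts(gm, chrom, region)
    sub = gm.subset_chrom(chrom)
    pos = sub.markers["pos_bp"].to_numpy()
    inside = (pos >= region[0]) & (pos <= region[1])
    f2 = sub.individual_mask(generation="F2")
    sexes = sub.individuals.loc[f2, "sex"].to_numpy()
    origins = maternal_x_origins(sub.calls[np.ix_(inside, f2)], sexes)
    ids = sub.individuals.loc[f2, "id"].to_numpy()
    nonrec = dict(zip(counts["individual"], counts["count"]))
    az = ut = 0
    for j, ind in enumerate(ids):
        if sexes[j] != "M" or not nonrec.get(ind) == 0:
            continue
        col = origins[:, j]
        col = col[col >= 0]
        if len(col) == 0:
            continue
        if col[0] == 1:
            az += 1
        else:
            ut += 1
    n = az + ut
    p = float(stats.binomtest(az, n, 0.5).pvalue) if n else float("nan")
    return {"AZ": az, "UT": ut, "n": n, "binomial_p": p}
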