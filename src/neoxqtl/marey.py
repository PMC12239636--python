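"""Marey maps: inversion detection, local recombination rate, gene density.

A Marey map pairs each marker's physical position (bp) with its genetic
position (cM). A run of >10 consecutive markers whose bp strictly decreases
while map order advances is called a putative inversion relative to the
reference assembly (the cross may carry a different arrangement, or the
reference a scaffolding error -- the call does not distinguish). Before
estimating local rates, marker bp order is reversed within such runs so the
artifactual negative slopes disappear.

The local recombination rate at each marker is the first derivative of a
locally weighted quadratic regression of cM on Mb (tricube weights,
span 0.7); negative fitted rates are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import median_abs_deviation

from neoxqtl.containers import GeneticMap

log = logging.getLogger(__name__)

MAREY_COLUMNS = ["marker", "chrom", "pos_bp", "pos_cm"]


@dataclass(frozen=True)
class InversionCall:
    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int
    markers: tuple[str, ...]

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class DensityRegression:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_markers_used: int
    excluded: list[str]


def marey_table(gmap: GeneticMap) -> pd.DataFrame:
    """Per-marker (bp, cM) table in map order within chromosome."""
    df = gmap.to_frame().rename(columns={"cm": "pos_cm"})
    df = df.sort_values(["chrom", "pos_cm"], kind="stable").reset_index(drop=True)
    return df[["marker", "chrom", "pos_bp", "pos_cm"]]


def detect_inversions(table: pd.DataFrame, min_run: int = 11) -> list[InversionCall]:
    """Maximal runs of consecutive markers with strictly decreasing bp.

    Runs of at least ``min_run`` markers (i.e. more than ``min_run - 1``
    consecutive decreases) are reported; endpoints are the min and max bp
    among the run's markers. Equal-bp neighbors break a run.
    """
    calls: list[InversionCall] = []
    for chrom, sub in table.groupby("chrom", sort=False):
        bp = sub["pos_bp"].to_numpy()
        names = sub["marker"].to_numpy()
        i = 0
        while i < len(bp) - 1:
            if bp[i + 1] < bp[i]:
                j = i + 1
                while j < len(bp) - 1 and bp[j + 1] < bp[j]:
                    j += 1
                run = slice(i, j + 1)
                n = j - i + 1
                if n >= min_run:
                    calls.append(
                        InversionCall(
                            chrom=str(chrom),
                            start_bp=int(bp[run].min()),
                            end_bp=int(bp[run].max()),
                            n_markers=n,
                            markers=tuple(names[run]),
                        )
                    )
                i = j
            else:
                i += 1
    return calls


def reverse_within_inversions(
    table: pd.DataFrame, calls: list[InversionCall]
) -> pd.DataFrame:
    """Reverse marker bp assignments within each putative inversion.

    Map (cM) order is untouched; only the physical coordinates of the run's
    markers are re-assigned in reversed order. Overlapping calls on one
    chromosome are an error.
    """
    out = table.copy().reset_index(drop=True)
    by_chrom: dict[str, list[InversionCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, cs in by_chrom.items():
        spans = sorted((c.start_bp, c.end_bp) for c in cs)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError(f"overlapping inversion calls on {chrom}")
    name_to_idx = {n: i for i, n in enumerate(out["marker"])}
    for c in calls:
        idx = [name_to_idx[m] for m in c.markers]
        out.loc[idx, "pos_bp"] = out.loc[idx, "pos_bp"].to_numpy()[::-1]
    return out


def _loess_deriv(
    x: np.ndarray, y: np.ndarray, span: float, degree: int
) -> tuple[np.ndarray, np.ndarray]:
    """Tricube-weighted local polynomial fit; returns (fitted, derivative)."""
    n = len(x)
    k = max(int(np.ceil(span * n)), degree + 1)
    fitted = np.empty(n)
    deriv = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.partition(d, min(k - 1, n - 1))[min(k - 1, n - 1)]
        h = max(h, 1e-9)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        use = w > 0
        dx = x[use] - x[i]
        X = np.vander(dx, degree + 1, increasing=True)
        sw = np.sqrt(w[use])
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y[use] * sw, rcond=None)
        fitted[i] = coef[0]
        deriv[i] = coef[1] if len(coef) > 1 else 0.0
    return fitted, deriv


def local_recomb_rate(
    table: pd.DataFrame, span: float = 0.7, degree: int = 2, min_markers: int = 10
) -> pd.DataFrame:
    """Local recombination rate (cM/Mb) at each marker.

    Per chromosome, a locally weighted polynomial regression of cM on Mb;
    the rate is the fit's first derivative at the marker. Chromosomes with
    fewer than ``min_markers`` markers get NaN rates with a warning.
    Negative rates are retained.
    """
    pieces = []
    for chrom, sub in table.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        if len(sub) < min_markers:
            log.warning("chromosome %s has < %d markers; rates set NaN", chrom, min_markers)
            rate = np.full(len(sub), np.nan)
        else:
            x = sub["pos_bp"].to_numpy(dtype=float) / 1e6
            y = sub["pos_cm"].to_numpy(dtype=float)
            _, rate = _loess_deriv(x, y, span, degree)
        pieces.append(sub.assign(rate_cm_per_mb=rate))
    return pd.concat(pieces, ignore_index=True)


def gene_density(
    annotation_path: str,
    window_bp: int = 500_000,
    protein_coding_only: bool = True,
) -> pd.DataFrame:
    """Protein-coding gene counts per half-open window [k*w, (k+1)*w).

    A gene is counted in the window containing its start coordinate.
    Malformed records are skipped and counted. Returns columns
    chrom/window_start/n_genes for every window containing at least one
    gene; absent windows are implicitly zero.
    """
    import gffutils

    db = gffutils.create_db(
        annotation_path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    counts: dict[tuple[str, int], int] = {}
    skipped = 0
    for gene in db.features_of_type("gene"):
        try:
            biotype = (
                gene.attributes.get("gene_biotype")
                or gene.attributes.get("biotype")
                or ["protein_coding"]
            )[0]
            if protein_coding_only and biotype != "protein_coding":
                continue
            w = int(gene.start) // window_bp
            counts[(gene.seqid, w * window_bp)] = counts.get((gene.seqid, w * window_bp), 0) + 1
        except (ValueError, TypeError):
            skipped += 1
    if skipped:
        log.warning("skipped %d malformed annotation records", skipped)
    rows = [(c, s, n) for (c, s), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["chrom", "window_start", "n_genes"])


def rate_density_regression(
    rates: pd.DataFrame,
    densities: pd.DataFrame,
    window_bp: int = 500_000,
    mad_factor: float = 3.0,
    span: float = 0.7,
) -> DensityRegression:
    """OLS of local recombination rate on gene density of the marker's window.

    Outlier exclusion: markers with a negative rate whose absolute residual
    from the chromosome's local (loess) rate trend exceeds
    ``mad_factor`` x MAD are dropped before the regression and reported.
    """
    df = rates.dropna(subset=["rate_cm_per_mb"]).copy()
    df["window_start"] = (df["pos_bp"] // window_bp) * window_bp
    dens = densities.set_index(["chrom", "window_start"])["n_genes"]
    df["density"] = [
        dens.get((c, w), 0) for c, w in zip(df["chrom"], df["window_start"])
    ]

    excluded: list[str] = []
    keep_mask = np.ones(len(df), dtype=bool)
    df = df.reset_index(drop=True)
    for chrom, sub in df.groupby("chrom", sort=False):
        x = sub["pos_bp"].to_numpy(dtype=float) / 1e6
        y = sub["rate_cm_per_mb"].to_numpy(dtype=float)
        if len(sub) < 4:
            continue
        fit, _ = _loess_deriv(x, y, span, 1)
        resid = y - fit
        mad = median_abs_deviation(resid)
        if mad <= 0:
            continue
        bad = (y < 0) & (np.abs(resid) > mad_factor * mad)
        for i, flag in zip(sub.index, bad):
            if flag:
                keep_mask[i] = False
                excluded.append(str(df.at[i, "marker"]))
    used = df[keep_mask]
    if len(used) < 3:
        raise ValueError("fewer than 3 points for the rate-density regression")
    X = sm.add_constant(used["density"].to_numpy(dtype=float))
    model = sm.OLS(used["rate_cm_per_mb"].to_numpy(dtype=float), X).fit()
    return DensityRegression(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n_markers_used=int(len(used)),
        excluded=excluded,
    )
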