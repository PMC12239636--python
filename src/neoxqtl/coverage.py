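"""Male/female windowed sequencing coverage and X stratification.

Males carry one X against a (partially homologous) neo-Y, so the
male/female normalized depth ratio along the X exposes the degree of
neo-X/neo-Y differentiation: ~1 where neo-Y reads still map to the neo-X
(similar), ~0.5 where the male is effectively hemizygous (ancestral X), and
intermediate where degeneration is partial. Depths are normalized per
sample by its mean autosomal windowed depth, so the ratio is invariant to
library-size differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def window_coverage(
    depth: pd.DataFrame,
    window_bp: int = 50_000,
    x_chrom: str = "X",
) -> pd.DataFrame:
    """Mean depth per half-open window [k*w, (k+1)*w), normalized.

    ``depth`` has columns chrom/pos/depth (per-base or per-point records;
    positions are assigned to windows by integer division). Normalization
    divides by the sample's mean autosomal window depth; zero autosomal
    coverage is an error. Window starts are 0-based.
    """
    df = depth.copy()
    df["window_start"] = (df["pos"] // window_bp) * window_bp
    win = (
        df.groupby(["chrom", "window_start"], sort=True)["depth"]
        .mean()
        .reset_index()
        .rename(columns={"depth": "mean_depth"})
    )
    auto = win.loc[win["chrom"] != x_chrom, "mean_depth"]
    if len(auto) == 0 or auto.mean() <= 0:
        raise ValueError("zero autosomal coverage; cannot normalize")
    win["normalized_depth"] = win["mean_depth"] / auto.mean()
    return win


def classify_strata(
    male_windows: pd.DataFrame,
    female_windows: pd.DataFrame,
    chrom: str = "X",
    hemizygous_max: float = 0.6,
    similar_min: float = 0.85,
    min_run: int = 5,
) -> pd.DataFrame:
    """Segment a chromosome into similar / intermediate / hemizygous strata.

    Per-window male/female normalized-depth ratios are thresholded
    (ratio >= similar_min -> "similar", ratio <= hemizygous_max ->
    "hemizygous", else "intermediate"); label runs shorter than ``min_run``
    windows are absorbed into the longer flanking run, and contiguous
    same-label windows merge into segments. Returns columns
    chrom/start_bp/end_bp/stratum/mean_ratio (0-based half-open).
    """
    m = male_windows[male_windows["chrom"] == chrom].set_index("window_start")
    f = female_windows[female_windows["chrom"] == chrom].set_index("window_start")
    common = m.index.intersection(f.index)
    if len(common) == 0:
        raise ValueError("no shared windows between samples")
    if len(common) != len(m.index) or len(common) != len(f.index):
        raise ValueError("mismatched window grids between samples")
    starts = np.sort(common.to_numpy())
    ratio = (
        m.loc[starts, "normalized_depth"].to_numpy()
        / np.maximum(f.loc[starts, "normalized_depth"].to_numpy(), 1e-12)
    )
    labels = np.where(
        ratio >= similar_min, "similar",
        np.where(ratio <= hemizygous_max, "hemizygous", "intermediate"),
    )

    # absorb short runs into the longer neighbor until stable
    def runs(lab: np.ndarray) -> list[tuple[int, int]]:
        out = []
        i = 0
        while i < len(lab):
            j = i
            while j + 1 < len(lab) and lab[j + 1] == lab[i]:
                j += 1
            out.append((i, j))
            i = j + 1
        return out

    changed = True
    while changed:
        changed = False
        rr = runs(labels)
        if len(rr) <= 1:
            break
        for k, (i, j) in enumerate(rr):
            if j - i + 1 < min_run:
                left_len = rr[k - 1][1] - rr[k - 1][0] + 1 if k > 0 else -1
                right_len = rr[k + 1][1] - rr[k + 1][0] + 1 if k < len(rr) - 1 else -1
                if left_len < 0 and right_len < 0:
                    continue
                src = rr[k - 1] if left_len >= right_len else rr[k + 1]
                labels[i : j + 1] = labels[src[0]]
                changed = True
                break

    window_bp = int(np.diff(starts).min()) if len(starts) > 1 else 50_000
    rows = []
    for i, j in runs(labels):
        rows.append(
            (
                chrom,
                int(starts[i]),
                int(starts[j]) + window_bp,
                labels[i],
                float(ratio[i : j + 1].mean()),
            )
        )
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "stratum", "mean_ratio"])
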