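"""Simple static figures: Marey maps, LOD curves, haplotype rasters."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from neoxqtl.containers import ScanResult


def plot_marey(table: pd.DataFrame, path: str, highlight: list | None = None) -> None:
    """One panel per chromosome: physical (Mb) vs genetic (cM) position."""
    chroms = list(dict.fromkeys(table["chrom"]))
    ncol = 4
    nrow = int(np.ceil(len(chroms) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
    for ax, chrom in zip(axes.flat, chroms):
        sub = table[table["chrom"] == chrom]
        ax.plot(sub["pos_bp"] / 1e6, sub["pos_cm"], ".", ms=3, color="firebrick")
        ax.set_title(chrom, fontsize=9)
        ax.set_xlabel("Mb", fontsize=8)
        ax.set_ylabel("cM", fontsize=8)
        for call in highlight or []:
            if call.chrom == chrom:
                ax.axvspan(call.start_bp / 1e6, call.end_bp / 1e6, alpha=0.2)
    for ax in axes.flat[len(chroms):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scan(scan: ScanResult, path: str) -> None:
    """Genome-wide LOD curve with autosomal/X thresholds."""
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0.0
    ticks, labels = [], []
    for chrom, sub in scan.positions.groupby("chrom", sort=False):
        ax.plot(sub["cm"] + offset, sub["lod"], "-", lw=1, color="black")
        ticks.append(offset + sub["cm"].mean())
        labels.append(str(chrom))
        offset += sub["cm"].max() + 5
    if scan.threshold_auto is not None:
        ax.axhline(scan.threshold_auto, ls="--", color="gray")
    if scan.threshold_x is not None:
        ax.axhline(scan.threshold_x, ls="--", color="firebrick")
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=8)
    ax.set_ylabel("LOD")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_haplotype_raster(raster: pd.DataFrame, path: str) -> None:
    """Individuals x markers raster of parental origins on one chromosome."""
    mapping = {"AZ": 1.0, "UT": 0.0}
    mat = raster.T.replace(mapping).astype(float).to_numpy()
    fig, ax = plt.subplots(figsize=(8, max(2, 0.04 * mat.shape[0])))
    ax.imshow(mat, aspect="auto", interpolation="nearest", cmap="coolwarm")
    ax.set_xlabel("marker (map order)")
    ax.set_ylabel("F2 individual")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
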