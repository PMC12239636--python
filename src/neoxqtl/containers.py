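"""Core in-memory containers shared across the pipeline.

Genotype codes count copies of the AZ-origin allele once a matrix is
polarized (``AA`` = two AZ alleles, ``BB`` = two UT alleles). Before
polarization the same integers count ALT alleles relative to the reference.
Hemizygous male X calls are stored as the homozygous-appearing code of the
single inherited haplotype, exactly as a diploid genotype caller emits them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

#: missing call
NA: int = -1
#: homozygous UT/UT (zero AZ alleles) once polarized; hom-ref before
BB: int = 0
#: heterozygous AZ/UT
AB: int = 1
#: homozygous AZ/AZ (or hemizygous AZ male on the X)
AA: int = 2

CODE_LABELS = {AA: "AA", AB: "AB", BB: "BB", NA: "NA"}

MARKER_COLUMNS = ["name", "chrom", "pos_bp", "ref", "alt", "origin_of_alt"]
INDIVIDUAL_COLUMNS = ["id", "sex", "generation"]


@dataclass
class GenotypeMatrix:
    """Markers x individuals genotype matrix.

    Parameters
    ----------
    markers:
        DataFrame with columns ``name, chrom, pos_bp, ref, alt,
        origin_of_alt`` (``origin_of_alt`` in {"AZ", "UT"} or None before
        polarization). Positions are 1-based and strictly increasing within
        a chromosome.
    individuals:
        DataFrame with columns ``id, sex, generation`` (sex in {"M", "F"},
        generation in {"P0", "F1", "F2"}).
    calls:
        int8 array of shape (n_markers, n_individuals) with codes
        {AA, AB, BB, NA}.
    dp, gq:
        optional per-call depth / genotype quality arrays, same shape.
    polarized:
        True once codes count AZ alleles rather than ALT alleles.
    x_chrom:
        label of the X chromosome.
    """

    markers: pd.DataFrame
    individuals: pd.DataFrame
    calls: np.ndarray
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None
    polarized: bool = False
    x_chrom: str = "X"

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.individuals)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.individuals)} individuals"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def validate(self) -> None:
        """Raise if invariants are violated."""
        bad = ~np.isin(self.calls, (AA, AB, BB, NA))
        if bad.any():
            raise ValueError("invalid genotype codes present")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if not self.individuals["sex"].isin(["M", "F"]).all():
            raise ValueError("unknown sex codes")

    # -- masks ----------------------------------------------------------
    def marker_is_x(self) -> np.ndarray:
        return (self.markers["chrom"] == self.x_chrom).to_numpy()

    def individual_mask(self, generation: str | None = None, sex: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_individuals, dtype=bool)
        if generation is not None:
            mask &= (self.individuals["generation"] == generation).to_numpy()
        if sex is not None:
            mask &= (self.individuals["sex"] == sex).to_numpy()
        return mask

    # -- subsetting ------------------------------------------------------
    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            markers=self.markers.iloc[index],
            calls=self.calls[index],
            dp=None if self.dp is None else self.dp[index],
            gq=None if self.gq is None else self.gq[index],
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            individuals=self.individuals.iloc[index],
            calls=self.calls[:, index],
            dp=None if self.dp is None else self.dp[:, index],
            gq=None if self.gq is None else self.gq[:, index],
        )

    def subset_chrom(self, chrom: str) -> "GenotypeMatrix":
        return self.take_markers((self.markers["chrom"] == chrom).to_numpy())

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            markers=self.markers.copy(),
            individuals=self.individuals.copy(),
            calls=self.calls.copy(),
            dp=None if self.dp is None else self.dp.copy(),
            gq=None if self.gq is None else self.gq.copy(),
        )

    # -- summaries -------------------------------------------------------
    def marker_missingness(self) -> np.ndarray:
        return (self.calls == NA).mean(axis=1)

    def individual_missingness(self) -> np.ndarray:
        return (self.calls == NA).mean(axis=0)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))


@dataclass
class LinkageGroup:
    """One ordered linkage group with cM positions (first position 0)."""

    chrom: str
    marker_names: list[str]
    pos_bp: np.ndarray
    cm: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.pos_bp = np.asarray(self.pos_bp, dtype=float)
        self.cm = np.asarray(self.cm, dtype=float)
        if len(self.cm) and abs(self.cm[0]) > 1e-9:
            raise ValueError("cM positions must start at 0")
        if (np.diff(self.cm) < -1e-9).any():
            raise ValueError("cM positions must be non-decreasing")

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1]) if len(self.cm) else 0.0

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)


@dataclass
class GeneticMap:
    """Collection of linkage groups produced by multipoint map estimation."""

    groups: list[LinkageGroup]
    map_function: str = "haldane"
    error_prob: float = 0.001

    @property
    def total_cm(self) -> float:
        return float(sum(g.length_cm for g in self.groups))

    def group(self, chrom: str) -> LinkageGroup:
        for g in self.groups:
            if g.chrom == chrom:
                return g
        raise KeyError(chrom)

    def chromosomes(self) -> list[str]:
        return [g.chrom for g in self.groups]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for name, bp, cm in zip(g.marker_names, g.pos_bp, g.cm):
                rows.append((g.chrom, name, int(bp), float(cm)))
        return pd.DataFrame(rows, columns=["chrom", "marker", "pos_bp", "cm"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, map_function: str = "haldane",
                   error_prob: float = 0.001) -> "GeneticMap":
        groups = []
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("cm", kind="stable")
            cm = sub["cm"].to_numpy(dtype=float)
            groups.append(
                LinkageGroup(
                    chrom=str(chrom),
                    marker_names=list(sub["marker"]),
                    pos_bp=sub["pos_bp"].to_numpy(dtype=float),
                    cm=cm - cm[0],
                )
            )
        return cls(groups=groups, map_function=map_function, error_prob=error_prob)


@dataclass
class ScanResult:
    """Genome-scan output: LOD curve, thresholds, peak and credible interval.

    ``positions`` has columns ``chrom, cm, pos_bp, lod``; grid positions that
    are not markers carry interpolated bp.
    """

    positions: pd.DataFrame
    peak: tuple[str, float, float]  # chrom, cm, lod
    threshold_auto: float | None = None
    threshold_x: float | None = None
    bayes_interval: tuple[str, float, float] | None = None
    effect_table: pd.DataFrame | None = None

    def max_lod(self, chroms: Iterable[str] | None = None) -> float:
        df = self.positions
        if chroms is not None:
            df = df[df["chrom"].isin(list(chroms))]
        return float(df["lod"].max())
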