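"""Simulation of an F2 neo-sex-chromosome intercross.

The cross design being emulated: a P0 cross between a UT female and an AZ
male, whose F1 offspring are intercrossed to produce F2s. Every F1 is
heterozygous AZ/UT along all autosomes. On the X, F1 females carry a
paternal AZ and a maternal UT copy, while F1 males are hemizygous for a
single (maternal, UT) X next to an AZ neo-Y. Consequences that the
simulator reproduces exactly:

* every F2 inherits exactly one maternally recombined X;
* F2 females are AZ/UT or UT/UT on the X, never AZ/AZ;
* F2 males are hemizygous (single-origin) on the X, never heterozygous;
* the X does not cross over in F1 males (only one copy is present).

Meiosis draws a Poisson number of crossovers with mean equal to the map
length in Morgans (no interference, Haldane-consistent), places them
uniformly in genetic coordinates, and converts to bp through the inverse
Marey curve, so suppressed regions receive few crossovers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from neoxqtl.containers import AA, AB, BB, NA, GenotypeMatrix
from neoxqtl.genome import ChromosomeModel, default_genome, default_marker_positions

ORIGIN_UT = 0
ORIGIN_AZ = 1
ORIGIN_LABELS = {ORIGIN_UT: "UT", ORIGIN_AZ: "AZ"}

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# haplotype mosaics
# ---------------------------------------------------------------------------
@dataclass
class HaplotypeMosaic:
    """An inherited chromosome as ordered parental-origin segments.

    Segments are (start_bp, end_bp, origin) with 1-based inclusive
    coordinates tiling [1, length_bp]; adjacent segments differ in origin.
    """

    length_bp: int
    segments: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("mosaic needs at least one segment")
        if self.segments[0][0] != 1 or self.segments[-1][1] != self.length_bp:
            raise ValueError("segments must tile [1, length_bp]")
        for (s1, e1, o1), (s2, e2, o2) in zip(self.segments, self.segments[1:]):
            if s2 != e1 + 1:
                raise ValueError("segments must be contiguous")
            if o1 == o2:
                raise ValueError("adjacent segments must differ in origin")

    @classmethod
    def uniform(cls, length_bp: int, origin: int) -> "HaplotypeMosaic":
        return cls(length_bp, [(1, length_bp, origin)])

    @property
    def crossover_count(self) -> int:
        return len(self.segments) - 1

    @property
    def breakpoints(self) -> np.ndarray:
        """bp positions after which origin switches."""
        return np.array([e for _, e, _ in self.segments[:-1]], dtype=np.int64)

    def origin_at(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos)
        ends = np.array([e for _, e, _ in self.segments])
        origins = np.array([o for _, _, o in self.segments], dtype=np.int8)
        idx = np.searchsorted(ends, pos, side="left")
        return origins[idx]


def _recombine(
    h1: HaplotypeMosaic,
    h2: HaplotypeMosaic,
    xo_bp: np.ndarray,
    start_with: int,
) -> HaplotypeMosaic:
    """Assemble a gamete switching between two parental haplotypes.

    ``xo_bp`` are sorted positions; the template switches after each one.
    Adjacent same-origin stretches are coalesced.
    """
    length = h1.length_bp
    parents = (h1, h2)
    bounds = np.concatenate([[0], xo_bp, [length]]).astype(np.int64)
    raw: list[tuple[int, int, int]] = []
    cur = start_with
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            cur = 1 - cur
            continue
        for s, e, o in parents[cur].segments:
            a, b = max(s, lo + 1), min(e, hi)
            if a <= b:
                raw.append((a, b, o))
        cur = 1 - cur
    merged: list[tuple[int, int, int]] = []
    for seg in raw:
        if merged and merged[-1][2] == seg[2]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(list(seg))  # type: ignore[arg-type]
    return HaplotypeMosaic(length, [tuple(s) for s in merged])


def simulate_meiosis(
    chrom: ChromosomeModel,
    parent_haplotypes: tuple[HaplotypeMosaic, Optional[HaplotypeMosaic]],
    is_f1_male_x: bool,
    rng: np.random.Generator,
) -> HaplotypeMosaic:
    """One gamete from one meiosis.

    An F1 male transmits his single X intact: hemizygosity leaves nothing to
    recombine with, so the first parental haplotype is returned verbatim.
    """
    h1, h2 = parent_haplotypes
    if is_f1_male_x or h2 is None:
        return HaplotypeMosaic(h1.length_bp, list(h1.segments))
    if (np.diff(chrom.marey_cm) < 0).any():
        raise ValueError("non-monotone Marey curve")
    n_xo = rng.poisson(chrom.map_length_cm / 100.0)
    if n_xo == 0:
        start = int(rng.integers(2))
        src = (h1, h2)[start]
        return HaplotypeMosaic(src.length_bp, list(src.segments))
    cm = rng.uniform(0.0, chrom.map_length_cm, size=n_xo)
    bp = np.unique(np.clip(np.asarray(chrom.bp_at(np.sort(cm))).round(), 1, chrom.length_bp - 1)).astype(np.int64)
    start = int(rng.integers(2))
    return _recombine(h1, h2, bp, start)


# ---------------------------------------------------------------------------
# model components
# ---------------------------------------------------------------------------
@dataclass
class QTLModel:
    """X-linked generation-time QTL.

    Class means (days): AZ-hemizygous and UT-hemizygous males, heterozygous
    and UT/UT females. Defaults follow the population estimates the cross
    was built around: 149 d for the AZ haplotype, 76 d for UT, with
    heterozygous females closer to the UT phenotype (partial dominance of
    the short-generation haplotype).
    """

    chrom: str = "X"
    pos_bp: int = 58_300_000
    mean_az_hemi: float = 149.0
    mean_ut_hemi: float = 76.0
    mean_het_female: float = 90.0
    mean_ut_female: float = 76.0
    resid_sd: float = 10.0

    def __post_init__(self) -> None:
        lo, hi = sorted((self.mean_ut_female, self.mean_az_hemi))
        if not (lo <= self.mean_het_female <= hi):
            raise ValueError("mean_het_female must lie between the UT-female and AZ means")


@dataclass
class BodySizeModel:
    """Polygenic pronotum width: many small autosomal effects plus noise.

    Defaults put a ~0.09 mm additive AZ-UT difference on 20 loci, below
    what a QTL scan at this sample size can resolve (a deliberate
    no-detectable-QTL regime).
    """

    n_loci: int = 20
    effect_per_allele: float = 0.00225
    base_female: float = 2.05
    base_male: float = 1.81
    resid_sd: float = 0.05


@dataclass
class ObservationModel:
    """Per-call noise applied to true genotypes."""

    genotype_error_rate: float = 0.001
    missing_rate: float = 0.05
    neoy_contamination_rate: float = 0.10
    depth_mean: float = 40.0
    gq_mean: float = 60.0

    def __post_init__(self) -> None:
        for name in ("genotype_error_rate", "missing_rate", "neoy_contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class ViabilityModel:
    """Survival of F2 males whose maternal X recombined inside ``region``.

    The default region (26.9-49.0 Mb) and zero survival reproduce the
    observed pattern of a crossover-free male interior; set
    ``male_recombinant_survival=1`` for neutral transmission.
    """

    region: tuple[int, int] = (26_900_000, 49_000_000)
    male_recombinant_survival: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.male_recombinant_survival <= 1.0:
            raise ValueError("male_recombinant_survival must be in [0, 1]")


@dataclass
class SimulationConfig:
    genome: list[ChromosomeModel] = field(default_factory=default_genome)
    marker_positions: dict[str, np.ndarray] | None = None
    n_markers: int = 822
    n_f2: int = 181
    n_families: int = 15
    qtl: QTLModel = field(default_factory=QTLModel)
    body_size: BodySizeModel = field(default_factory=BodySizeModel)
    observation: ObservationModel = field(default_factory=ObservationModel)
    viability: ViabilityModel | None = field(default_factory=ViabilityModel)

    def __post_init__(self) -> None:
        if self.n_f2 < 2:
            raise ValueError("n_f2 must be >= 2")

    def x_model(self) -> ChromosomeModel:
        for c in self.genome:
            if c.is_x:
                return c
        raise ValueError("genome has no X chromosome")


@dataclass
class SimTruth:
    """Ground truth: gamete mosaics, QTL model, inversions, seed."""

    seed: int
    qtl: QTLModel
    inversions: dict[str, tuple[int, int]]
    maternal: dict[str, dict[str, HaplotypeMosaic]]  # ind -> chrom -> mosaic
    paternal: dict[str, dict[str, HaplotypeMosaic | None]]
    map_lengths_cm: dict[str, float]

    def to_json(self) -> str:
        def enc(m: HaplotypeMosaic | None):
            if m is None:
                return None
            return [[int(s), int(e), ORIGIN_LABELS[o]] for s, e, o in m.segments]

        payload = {
            "seed": self.seed,
            "qtl": asdict(self.qtl),
            "inversions": {k: list(v) for k, v in self.inversions.items()},
            "map_lengths_cm": self.map_lengths_cm,
            "maternal": {i: {c: enc(m) for c, m in d.items()} for i, d in self.maternal.items()},
            "paternal": {i: {c: enc(m) for c, m in d.items()} for i, d in self.paternal.items()},
        }
        return json.dumps(payload, indent=1)


@dataclass
class SimDataset:
    genotypes: GenotypeMatrix
    truth_genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: SimTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# the cross
# ---------------------------------------------------------------------------
def _marker_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    positions = config.marker_positions
    if positions is None:
        positions = default_marker_positions(config.genome, config.n_markers, rng=rng)
    by_name = {c.name: c for c in config.genome}
    rows = []
    for chrom, pos in positions.items():
        if chrom not in by_name:
            raise ValueError(f"marker positions given for unknown chromosome {chrom}")
        model = by_name[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        out = (pos < 1) | (pos > model.length_bp)
        if out.any():
            raise ValueError(
                f"marker at {chrom}:{pos[out][0]} outside chromosome (1..{model.length_bp})"
            )
        for p in pos:
            rows.append((f"{chrom}_{p}", chrom, int(p)))
    df = pd.DataFrame(rows, columns=["name", "chrom", "pos_bp"])
    n = len(df)
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    df["ref"] = _BASES[ref_i]
    df["alt"] = _BASES[alt_i]
    df["origin_of_alt"] = np.where(rng.random(n) < 0.5, "AZ", "UT")
    return df


def _viability_veto_interval(
    region: tuple[int, int], chrom: ChromosomeModel
) -> tuple[float, float]:
    """True-coordinate interval whose crossovers are visible inside ``region``.

    The region is stated in reference coordinates. When an inversion
    straddles it, reference-adjacent markers inside the region span the
    whole inverted segment in true coordinates, so any breakpoint in the
    closure of the region plus the image of their overlap would surface as
    an apparent crossover between region markers. The veto interval is that
    closure.
    """
    a, b = region
    pts = [float(a), float(b)]
    if chrom.inversion is not None:
        ia, ib = max(a, chrom.inversion[0]), min(b, chrom.inversion[1])
        if ia < ib:
            pts += [float(x) for x in chrom.reference_to_true_bp(np.array([ia, ib]))]
    return min(pts), max(pts)


def _xo_in_region(
    mosaic: HaplotypeMosaic, region: tuple[int, int], chrom: ChromosomeModel
) -> bool:
    lo, hi = _viability_veto_interval(region, chrom)
    bp = mosaic.breakpoints
    return bool(((bp >= lo) & (bp <= hi)).any())


def simulate_cross(config: SimulationConfig, seed: int) -> SimDataset:
    """Run the full P0 -> F1 -> F2 cross and genotype it at the markers.

    Returns the observed genotype matrix (after the observation model), the
    noise-free truth matrix, the F2 phenotype table and complete gamete
    truth. Genotypes of the two P0 individuals are included, as a real
    mapping panel would carry them for polarization.
    """
    x_len = config.x_model().length_bp
    if not 1 <= config.qtl.pos_bp <= x_len:
        raise ValueError(
            f"QTL position {config.qtl.pos_bp} outside X chromosome (1..{x_len})"
        )
    rng = np.random.default_rng(seed)
    markers = _marker_table(config, rng)
    genome = {c.name: c for c in config.genome}
    x_name = config.x_model().name

    # true (cross-arrangement) coordinates of each marker
    true_pos = {
        chrom: genome[chrom].reference_to_true_bp(
            markers.loc[markers["chrom"] == chrom, "pos_bp"].to_numpy()
        )
        for chrom in genome
    }

    n_f2 = config.n_f2
    sexes = np.where(rng.random(n_f2) < 0.5, "M", "F")
    f2_ids = [f"F2_{i + 1:03d}" for i in range(n_f2)]
    families = [f"fam{(i % config.n_families) + 1:02d}" for i in range(n_f2)]

    maternal: dict[str, dict[str, HaplotypeMosaic]] = {}
    paternal: dict[str, dict[str, HaplotypeMosaic | None]] = {}

    # F1 parental haplotypes are population-pure: every F1 autosome pair is
    # (UT, AZ); the F1 female X pair is (AZ paternal, UT maternal); the F1
    # male carries one UT X.
    def f1_female_pair(chrom: ChromosomeModel) -> tuple[HaplotypeMosaic, HaplotypeMosaic]:
        if chrom.is_x:
            return (
                HaplotypeMosaic.uniform(chrom.length_bp, ORIGIN_AZ),
                HaplotypeMosaic.uniform(chrom.length_bp, ORIGIN_UT),
            )
        return (
            HaplotypeMosaic.uniform(chrom.length_bp, ORIGIN_UT),
            HaplotypeMosaic.uniform(chrom.length_bp, ORIGIN_AZ),
        )

    viab = config.viability
    for ind, sex in zip(f2_ids, sexes):
        maternal[ind] = {}
        paternal[ind] = {}
        for chrom in config.genome:
            is_x = chrom.is_x
            while True:
                gam_m = simulate_meiosis(chrom, f1_female_pair(chrom), False, rng)
                if (
                    is_x
                    and sex == "M"
                    and viab is not None
                    and viab.male_recombinant_survival < 1.0
                    and _xo_in_region(gam_m, viab.region, chrom)
                    and rng.random() >= viab.male_recombinant_survival
                ):
                    continue  # rejection sampling of male gametes
                break
            maternal[ind][chrom.name] = gam_m
            if is_x:
                if sex == "F":
                    # F1 father's single X, transmitted without crossover
                    father_x = HaplotypeMosaic.uniform(chrom.length_bp, ORIGIN_UT)
                    paternal[ind][chrom.name] = simulate_meiosis(
                        chrom, (father_x, None), True, rng
                    )
                else:
                    paternal[ind][chrom.name] = None  # neo-Y placeholder
            else:
                paternal[ind][chrom.name] = simulate_meiosis(
                    chrom, f1_female_pair(chrom), False, rng
                )

    # --- truth genotype codes (AZ-allele dosage) ------------------------
    n_ind = n_f2 + 2
    calls = np.full((len(markers), n_ind), NA, dtype=np.int8)
    # column 0: P0 AZ male, column 1: P0 UT female
    is_x_marker = (markers["chrom"] == x_name).to_numpy()
    calls[:, 0] = AA  # AZ male: AZ everywhere (hemizygous AZ on the X)
    calls[:, 1] = BB  # UT female
    for j, ind in enumerate(f2_ids, start=2):
        col = np.empty(len(markers), dtype=np.int8)
        for chrom in config.genome:
            rows = (markers["chrom"] == chrom.name).to_numpy()
            tp = true_pos[chrom.name]
            mat = maternal[ind][chrom.name].origin_at(tp)
            if chrom.is_x:
                if sexes[j - 2] == "M":
                    col[rows] = np.where(mat == ORIGIN_AZ, AA, BB)
                else:
                    col[rows] = np.where(mat == ORIGIN_AZ, AB, BB)
            else:
                pat = paternal[ind][chrom.name].origin_at(tp)
                col[rows] = (mat + pat).astype(np.int8)
        calls[:, j] = col

    individuals = pd.DataFrame(
        {
            "id": ["P0_AZ_male", "P0_UT_female"] + f2_ids,
            "sex": ["M", "F"] + list(sexes),
            "generation": ["P0", "P0"] + ["F2"] * n_f2,
            "family": ["-", "-"] + families,
        }
    )
    truth_gm = GenotypeMatrix(
        markers=markers.copy(),
        individuals=individuals.copy(),
        calls=calls.copy(),
        polarized=True,
        x_chrom=x_name,
    )

    observed = apply_observation_model(truth_gm, config.observation, rng)

    # --- phenotypes ------------------------------------------------------
    x_model = config.x_model()
    qtl_true_bp = float(x_model.reference_to_true_bp(np.array([config.qtl.pos_bp]))[0])
    gen_time = np.empty(n_f2)
    for j, ind in enumerate(f2_ids):
        origin = int(maternal[ind][x_name].origin_at(np.array([qtl_true_bp]))[0])
        if sexes[j] == "M":
            mu = config.qtl.mean_az_hemi if origin == ORIGIN_AZ else config.qtl.mean_ut_hemi
        else:
            mu = config.qtl.mean_het_female if origin == ORIGIN_AZ else config.qtl.mean_ut_female
        gen_time[j] = mu + rng.normal(0.0, config.qtl.resid_sd)

    bs = config.body_size
    auto_rows = np.flatnonzero(~is_x_marker)
    n_loci = min(bs.n_loci, len(auto_rows))
    body_loci = rng.choice(auto_rows, size=n_loci, replace=False)
    dosage = calls[np.ix_(body_loci, np.arange(2, n_ind))].astype(float)
    body = (
        np.where(sexes == "F", bs.base_female, bs.base_male)
        + bs.effect_per_allele * dosage.sum(axis=0)
        + rng.normal(0.0, bs.resid_sd, size=n_f2)
    )

    phenotypes = pd.DataFrame(
        {
            "individual": f2_ids,
            "sex": sexes,
            "family": families,
            "generation_time": np.round(gen_time, 3),
            "body_size": np.round(body, 4),
        }
    )

    truth = SimTruth(
        seed=seed,
        qtl=config.qtl,
        inversions={c.name: c.inversion for c in config.genome if c.inversion is not None},
        maternal=maternal,
        paternal=paternal,
        map_lengths_cm={c.name: c.map_length_cm for c in config.genome},
    )
    return SimDataset(
        genotypes=observed,
        truth_genotypes=truth_gm,
        phenotypes=phenotypes,
        truth=truth,
        config=config,
    )


def apply_observation_model(
    truth: GenotypeMatrix,
    model: ObservationModel,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Corrupt true genotypes per call.

    Order of application: random mis-genotyping, then neo-Y contamination
    of male X calls in the similar region (which overrides to heterozygous),
    then missingness. Hemizygous male X truth enters already encoded as the
    homozygous-looking code of its single origin.
    """
    out = truth.copy()
    calls = out.calls
    shape = calls.shape
    non_missing = calls != NA

    err = (rng.random(shape) < model.genotype_error_rate) & non_missing
    if err.any():
        shift = rng.integers(1, 3, size=int(err.sum()))
        calls[err] = ((calls[err] + shift) % 3).astype(np.int8)

    # neo-Y contamination: male X calls inside the similar region
    x_rows = out.marker_is_x()
    if x_rows.any() and model.neoy_contamination_rate > 0:
        sim_region = _similar_region_of(out)
        if sim_region is not None:
            pos = out.markers["pos_bp"].to_numpy()
            region_rows = x_rows & (pos >= sim_region[0]) & (pos <= sim_region[1])
            male_cols = (out.individuals["sex"] == "M").to_numpy()
            cell = np.outer(region_rows, male_cols) & non_missing
            hit = cell & (rng.random(shape) < model.neoy_contamination_rate)
            calls[hit] = AB

    miss = rng.random(shape) < model.missing_rate
    calls[miss] = NA

    out.dp = rng.poisson(model.depth_mean, size=shape).astype(np.int32)
    out.gq = np.minimum(rng.poisson(model.gq_mean, size=shape), 99).astype(np.int32)
    out.dp[calls == NA] = 0
    return out


_SIMILAR_REGION_DEFAULT = (0, 26_000_000)


def _similar_region_of(gm: GenotypeMatrix) -> tuple[int, int] | None:
    # the matrix itself does not carry the chromosome model; the default
    # similar region matches the default genome and can be overridden by
    # stashing `similar_region` in markers.attrs
    return gm.markers.attrs.get("similar_region", _SIMILAR_REGION_DEFAULT)


# ---------------------------------------------------------------------------
# auxiliary synthetic inputs (annotation, depth)
# ---------------------------------------------------------------------------
def true_marey_table(
    genome: list[ChromosomeModel],
    marker_positions: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Ground-truth Marey table: reference bp vs true genetic position.

    Each marker's genetic position comes from the chromosome's Marey curve
    evaluated at its position in the cross's true arrangement (inversions
    unfolded), while ``pos_bp`` stays in reference coordinates -- exactly
    the configuration an estimated linkage map recovers at infinite sample
    size. Rows are sorted by cM (map order) within chromosome.
    """
    by_name = {c.name: c for c in genome}
    pieces = []
    for chrom, pos in marker_positions.items():
        model = by_name[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        cm = np.asarray(model.cm_at(model.reference_to_true_bp(pos)), dtype=float)
        df = pd.DataFrame(
            {
                "marker": [f"{chrom}_{p}" for p in pos],
                "chrom": chrom,
                "pos_bp": pos,
                "pos_cm": cm,
            }
        ).sort_values("pos_cm", kind="stable")
        df["pos_cm"] -= df["pos_cm"].iloc[0]
        pieces.append(df)
    return pd.concat(pieces, ignore_index=True)


def simulate_annotation(
    genome: list[ChromosomeModel],
    rng: np.random.Generator,
    window_bp: int = 500_000,
    base_rate: float = 2.0,
    slope_rate: float = 6.0,
) -> pd.DataFrame:
    """Synthetic protein-coding gene annotation (GFF3-ready table).

    Gene counts per window are Poisson with intensity increasing in the
    local recombination rate (Marey-curve slope), emulating gene-poor
    pericentromeric regions. Returns columns chrom/start/end/strand/gene_id.
    """
    rows = []
    gid = 0
    for chrom in genome:
        n_win = int(np.ceil(chrom.length_bp / window_bp))
        for w in range(n_win):
            a = w * window_bp
            b = min((w + 1) * window_bp, chrom.length_bp)
            slope = (chrom.cm_at(b) - chrom.cm_at(a)) / ((b - a) / 1e6)  # cM/Mb
            lam = base_rate + slope_rate * min(float(slope), 5.0)
            k = rng.poisson(lam)
            starts = np.sort(rng.integers(a + 1, max(a + 2, b - 2000), size=k))
            for s in starts:
                gid += 1
                rows.append((chrom.name, int(s), int(min(s + 1999, b)), "+", f"gene{gid:05d}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


def write_gff3(annotation: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in annotation.itertuples(index=False):
            attrs = f"ID={r.gene_id};gene_biotype=protein_coding"
            fh.write(
                f"{r.chrom}\tneoxqtl\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


def simulate_depth(
    genome: list[ChromosomeModel],
    sex: str,
    rng: np.random.Generator,
    base_depth: float = 30.0,
    step_bp: int = 10_000,
    noise_cv: float = 0.05,
) -> pd.DataFrame:
    """Per-position sequencing depth for one individual (chrom, pos, depth).

    Males carry half depth over the hemizygous ancestral X (>= 48 Mb),
    three-quarter depth over the intermediate interior (26-48 Mb) and full
    depth over the neo-Y-similar first 26 Mb; females are uniform.
    """
    rows = []
    for chrom in genome:
        pos = np.arange(step_bp // 2, chrom.length_bp, step_bp)
        mult = np.ones(len(pos))
        if chrom.is_x and sex == "M":
            mult = np.where(pos >= 48_000_000, 0.5, np.where(pos >= 26_000_000, 0.75, 1.0))
        depth = np.maximum(0.0, base_depth * mult + rng.normal(0, base_depth * noise_cv, len(pos)))
        rows.append(pd.DataFrame({"chrom": chrom.name, "pos": pos, "depth": np.round(depth, 2)}))
    return pd.concat(rows, ignore_index=True)
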