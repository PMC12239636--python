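"""Chromosome models for simulation: Marey curves, inversions, the X.

A chromosome's recombination landscape is specified as a monotone
piecewise-linear Marey curve G: bp -> cM with G(0) = 0 and
G(length_bp) = total map length. Crossover positions are drawn uniformly in
genetic (cM) coordinates and mapped back to bp through the inverse curve, so
recombination suppression (e.g. a pericentromeric plateau) emerges from the
curve shape itself.

An optional ``inversion`` interval marks a segment whose marker order is
reversed in the reference assembly relative to the arrangement actually
segregating in the cross. An optional ``similar_region`` on the X marks the
interval where neo-Y reads mis-map to the neo-X and produce
heterozygous-looking male calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ChromosomeModel:
    name: str
    length_bp: int
    marey_bp: np.ndarray
    marey_cm: np.ndarray
    is_x: bool = False
    inversion: tuple[int, int] | None = None
    similar_region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.marey_bp = np.asarray(self.marey_bp, dtype=float)
        self.marey_cm = np.asarray(self.marey_cm, dtype=float)
        if self.marey_bp[0] != 0 or self.marey_cm[0] != 0:
            raise ValueError(f"{self.name}: Marey curve must start at (0, 0)")
        if self.marey_bp[-1] != self.length_bp:
            raise ValueError(f"{self.name}: Marey curve must end at length_bp")
        if (np.diff(self.marey_bp) <= 0).any():
            raise ValueError(f"{self.name}: Marey bp knots must increase")
        if (np.diff(self.marey_cm) < 0).any():
            raise ValueError(f"{self.name}: Marey curve must be non-decreasing")
        if self.inversion is not None:
            a, b = self.inversion
            if not (0 <= a < b <= self.length_bp):
                raise ValueError(f"{self.name}: inversion outside chromosome")

    @property
    def map_length_cm(self) -> float:
        return float(self.marey_cm[-1])

    def cm_at(self, bp: np.ndarray | float) -> np.ndarray | float:
        """Genetic position of physical position(s)."""
        return np.interp(bp, self.marey_bp, self.marey_cm)

    def bp_at(self, cm: np.ndarray | float) -> np.ndarray | float:
        """Physical position of genetic position(s) (inverse Marey curve)."""
        return np.interp(cm, self.marey_cm, self.marey_bp)

    def reference_to_true_bp(self, pos: np.ndarray) -> np.ndarray:
        """Map reference coordinates to the cross's true arrangement.

        Positions inside the inversion interval are reflected; everything
        else is unchanged. The transform is an involution.
        """
        pos = np.asarray(pos, dtype=float)
        if self.inversion is None:
            return pos.copy()
        a, b = self.inversion
        out = pos.copy()
        inside = (pos >= a) & (pos <= b)
        out[inside] = a + b - pos[inside]
        return out


def _autosome(name: str, length_mb: float, map_cm: float) -> ChromosomeModel:
    """Acro/telocentric autosome: distal 30% of bp carries 10% of the map."""
    L = int(length_mb * 1e6)
    return ChromosomeModel(
        name=name,
        length_bp=L,
        marey_bp=np.array([0.0, 0.7 * L, L]),
        marey_cm=np.array([0.0, 0.9 * map_cm, map_cm]),
    )


def default_genome(
    with_inversions: bool = True,
    x_map_cm: float = 77.0,
    autosome_map_cm: float = 90.2,
) -> list[ChromosomeModel]:
    """11 autosomes + 1 metacentric X (64.7 Mb), total map 1,069.2 cM.

    The X carries a strongly suppressed 26-48 Mb interior (pericentromeric
    plateau), a neo-Y-similar first 26 Mb, and an 18 Mb segment (40.5-58.5
    Mb) that is inverted in reference coordinates. Autosomes 2 and 3 carry
    smaller reference-discordant inversions (3.7 and 5.5 Mb).
    """
    lengths_mb = [40, 35, 32, 30, 28, 26, 25, 23, 22, 21, 20]
    chroms = [
        _autosome(str(i + 1), mb, autosome_map_cm) for i, mb in enumerate(lengths_mb)
    ]
    if with_inversions:
        chroms[1].inversion = (20_000_000, 23_700_000)
        chroms[2].inversion = (8_000_000, 13_500_000)
    Lx = 64_700_000
    x = ChromosomeModel(
        name="X",
        length_bp=Lx,
        marey_bp=np.array([0.0, 26e6, 48e6, Lx]),
        marey_cm=np.array(
            [0.0, 0.45 * x_map_cm, 0.52 * x_map_cm, x_map_cm]
        ),
        is_x=True,
        similar_region=(0, 26_000_000),
        inversion=(40_500_000, 58_500_000) if with_inversions else None,
    )
    chroms.append(x)
    return chroms


def default_marker_positions(
    genome: list[ChromosomeModel],
    n_markers: int = 822,
    min_gap_bp: int = 100_000,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Marker positions per chromosome, count proportional to bp length.

    Positions are evenly spaced with uniform jitter, then nudged to respect
    ``min_gap_bp``; this emulates a thinned reduced-representation marker
    panel (about one marker per 100 kb after thinning).
    """
    rng = np.random.default_rng(rng)
    total = sum(c.length_bp for c in genome)
    out: dict[str, np.ndarray] = {}
    assigned = 0
    for i, chrom in enumerate(genome):
        if i == len(genome) - 1:
            k = n_markers - assigned
        else:
            k = int(round(n_markers * chrom.length_bp / total))
        assigned += k
        spacing = chrom.length_bp / (k + 1)
        base = spacing * np.arange(1, k + 1)
        jitter = rng.uniform(-0.3, 0.3, size=k) * spacing
        pos = np.sort(np.clip(base + jitter, 1, chrom.length_bp - 1).astype(np.int64))
        # enforce the minimum gap deterministically
        for j in range(1, k):
            if pos[j] - pos[j - 1] < min_gap_bp:
                pos[j] = pos[j - 1] + min_gap_bp
        pos = pos[pos < chrom.length_bp]
        out[chrom.name] = np.unique(pos)
    return out
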