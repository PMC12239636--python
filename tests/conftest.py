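"""Shared fixtures: small simulated crosses reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neoxqtl.containers import GenotypeMatrix
from neoxqtl.genome import default_genome
from neoxqtl.simulate import (
    ObservationModel,
    SimulationConfig,
    simulate_cross,
)


def make_matrix(
    calls: np.ndarray,
    chroms: list[str],
    pos: list[int],
    sexes: list[str],
    generations: list[str] | None = None,
    polarized: bool = True,
    **kwargs,
) -> GenotypeMatrix:
    """Hand-build a GenotypeMatrix for unit tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n_markers, n_ind = calls.shape
    markers = pd.DataFrame(
        {
            "name": [f"{c}_{p}" for c, p in zip(chroms, pos)],
            "chrom": chroms,
            "pos_bp": pos,
            "ref": ["A"] * n_markers,
            "alt": ["T"] * n_markers,
            "origin_of_alt": ["AZ"] * n_markers,
        }
    )
    if generations is None:
        generations = ["F2"] * n_ind
    individuals = pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(n_ind)],
            "sex": sexes,
            "generation": generations,
        }
    )
    return GenotypeMatrix(
        markers=markers,
        individuals=individuals,
        calls=calls,
        polarized=polarized,
        **kwargs,
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free cross, no viability selection, no inversions: n=100, 240 markers."""
    cfg = SimulationConfig(
        genome=default_genome(with_inversions=False),
        n_f2=100,
        n_markers=240,
        observation=ObservationModel(
            genotype_error_rate=0.0, missing_rate=0.0, neoy_contamination_rate=0.0
        ),
        viability=None,
    )
    return simulate_cross(cfg, seed=101)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Study-condition cross (defaults) at reduced size: n=120, 300 markers."""
    cfg = SimulationConfig(genome=default_genome(), n_f2=120, n_markers=300)
    return simulate_cross(cfg, seed=202)
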