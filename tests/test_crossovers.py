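"""Haplotype inference, obligate crossover counting, sex comparisons."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neoxqtl import crossovers
from neoxqtl.containers import AA, AB, BB, NA
from neoxqtl.genome import default_genome
from neoxqtl.simulate import (
    ObservationModel,
    SimulationConfig,
    ViabilityModel,
    simulate_cross,
)

from conftest import make_matrix


def brute_force_min_crossovers(seq: list[int]) -> float:
    """Exhaustive oracle: minimum gamete switches over all phase assignments.

    Each genotype constrains the ordered gamete pair: AA -> (1,1),
    BB -> (0,0), AB -> (1,0) or (0,1); NA is unconstrained and dropped.
    """
    obs = [c for c in seq if c != NA]
    if not obs:
        return float("nan")
    options = {AA: [(1, 1)], BB: [(0, 0)], AB: [(1, 0), (0, 1)]}
    best = np.inf
    for path in itertools.product(*(options[c] for c in obs)):
        n = sum(
            (a[0] != b[0]) + (a[1] != b[1]) for a, b in zip(path, path[1:])
        )
        best = min(best, n)
    return float(best)


class TestCountCrossovers:
    def test_double_recombinant_autosome(self):
        assert crossovers.count_crossovers(np.array([AA, AB, BB]), is_x=False) == 2.0

    def test_missing_inside_run_is_free(self):
        assert crossovers.count_crossovers(np.array([1, NA, 1]), is_x=True) == 0.0

    def test_all_missing_nan(self):
        assert np.isnan(crossovers.count_crossovers(np.array([NA, NA]), is_x=False))

    @pytest.mark.parametrize("length", [2, 3, 4, 5])
    def test_exhaustive_oracle_short_sequences(self, length):
        """Minimal counts equal brute-force enumeration for every sequence."""
        for seq in itertools.product((AA, AB, BB, NA), repeat=length):
            got = crossovers.count_crossovers(np.array(seq, dtype=np.int8), is_x=False)
            want = brute_force_min_crossovers(list(seq))
            assert (np.isnan(got) and np.isnan(want)) or got == want

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(
        st.lists(st.sampled_from([AA, AB, BB]), min_size=2, max_size=12),
        st.data(),
    )
    def test_missingness_never_increases_count(self, seq, data):
        base = crossovers.count_crossovers(np.array(seq, dtype=np.int8), is_x=False)
        mask = data.draw(
            st.lists(st.booleans(), min_size=len(seq), max_size=len(seq))
        )
        masked = np.array(
            [NA if m else c for c, m in zip(seq, mask)], dtype=np.int8
        )
        degraded = crossovers.count_crossovers(masked, is_x=False)
        if not np.isnan(degraded):
            assert degraded <= base


class TestInferHaplotypes:
    def test_male_x_read_directly(self):
        gm = make_matrix(
            np.array([[AA], [AA], [BB], [BB]], dtype=np.int8),
            ["X"] * 4,
            [100, 200, 300, 400],
            ["M"],
        )
        h = crossovers.infer_haplotypes(gm, "X")
        assert list(h.iloc[:, 0]) == ["AZ", "AZ", "UT", "UT"]

    def test_female_x_resolved_through_paternal_ut(self):
        gm = make_matrix(
            np.array([[AB], [BB]], dtype=np.int8), ["X"] * 2, [100, 200], ["F"]
        )
        h = crossovers.infer_haplotypes(gm, "X")
        assert list(h.iloc[:, 0]) == ["AZ", "UT"]

    def test_impossible_codes_raise(self):
        gm = make_matrix(np.array([[AB]], dtype=np.int8), ["X"], [100], ["M"])
        with pytest.raises(ValueError, match="QC"):
            crossovers.infer_haplotypes(gm, "X")

    def test_noise_free_origins_match_truth(self, clean_dataset):
        gm = clean_dataset.genotypes
        h = crossovers.infer_haplotypes(gm, "X")
        x = next(c for c in clean_dataset.config.genome if c.is_x)
        pos = gm.subset_chrom("X").markers["pos_bp"].to_numpy()
        for ind in h.columns[:25]:
            mosaic = clean_dataset.truth.maternal[ind]["X"]
            want = np.where(mosaic.origin_at(pos) == 1, "AZ", "UT")
            assert list(h[ind]) == list(want)

    def test_x_crossover_sum_equals_detectable_truth(self, clean_dataset):
        """Total minimal X crossovers equal truth restricted to marker intervals."""
        gm = clean_dataset.genotypes
        counts = crossovers.crossover_counts(gm, "X")
        pos = gm.subset_chrom("X").markers["pos_bp"].to_numpy()
        total_truth = 0
        for ind in counts["individual"]:
            origins = clean_dataset.truth.maternal[ind]["X"].origin_at(pos)
            total_truth += int((np.diff(origins) != 0).sum())
        assert counts["count"].sum() == total_truth


class TestCompareSexes:
    def test_identical_multisets_p_one(self):
        import pandas as pd

        counts = pd.DataFrame(
            {
                "individual": [f"i{k}" for k in range(6)],
                "sex": ["F"] * 3 + ["M"] * 3,
                "chrom": "1",
                "count": [1.0, 2.0, 0.0, 1.0, 2.0, 0.0],
            }
        )
        row = crossovers.compare_sexes(counts, ["1"]).iloc[0]
        assert row["p_raw"] > 0.99

    def test_w_and_p_against_exact_enumeration(self):
        """W equals the female Mann-Whitney U; p close to the exact permutation p."""
        import pandas as pd

        f, m = [2.0, 2.0, 1.0], [0.0, 1.0, 0.0]
        counts = pd.DataFrame(
            {
                "individual": [f"i{k}" for k in range(6)],
                "sex": ["F"] * 3 + ["M"] * 3,
                "chrom": "1",
                "count": f + m,
            }
        )
        row = crossovers.compare_sexes(counts, ["1"], n_tests=12).iloc[0]
        pooled = np.array(f + m)
        # exact U of the observed female sample
        u_obs = sum((fi > mj) + 0.5 * (fi == mj) for fi in f for mj in m)
        assert row["w_statistic"] == pytest.approx(u_obs)
        # exact two-sided p by enumerating all C(6,3)=20 assignments
        us = []
        for idx in itertools.combinations(range(6), 3):
            ff = pooled[list(idx)]
            mm = pooled[[i for i in range(6) if i not in idx]]
            us.append(sum((a > b) + 0.5 * (a == b) for a in ff for b in mm))
        us = np.array(us)
        dev = np.abs(us - us.mean())
        p_exact = float((dev >= abs(u_obs - us.mean()) - 1e-9).mean())
        # the tie-corrected normal approximation is coarse at n=3+3;
        # require agreement with the exact p only to that accuracy
        assert row["p_raw"] == pytest.approx(p_exact, abs=0.15)
        assert row["p_adjusted"] == pytest.approx(min(1.0, 12 * row["p_raw"]))

    def test_empty_sex_gives_na_row(self):
        import pandas as pd

        counts = pd.DataFrame(
            {"individual": ["i0"], "sex": ["F"], "chrom": "1", "count": [1.0]}
        )
        row = crossovers.compare_sexes(counts, ["1"]).iloc[0]
        assert np.isnan(row["p_raw"])


class TestRegions:
    def test_whole_chromosome_window_equals_unrestricted(self, clean_dataset):
        gm = clean_dataset.genotypes
        full = crossovers.crossover_counts(gm, "X")
        restricted, _ = crossovers.region_restricted_counts(
            gm, "X", (0, 100_000_000)
        )
        assert list(full["count"]) == list(restricted["count"])

    def test_empty_region_raises(self, clean_dataset):
        with pytest.raises(ValueError, match="no markers"):
            crossovers.region_restricted_counts(
                clean_dataset.genotypes, "X", (63_000_000, 63_000_001)
            )

    def test_viability_selection_blocks_male_region_crossovers(self):
        cfg = SimulationConfig(
            genome=default_genome(with_inversions=False),
            n_f2=120,
            n_markers=300,
            observation=ObservationModel(0.0, 0.0, 0.0),
            viability=ViabilityModel(
                region=(26_900_000, 49_000_000), male_recombinant_survival=0.0
            ),
        )
        ds = simulate_cross(cfg, seed=71)
        counts, _ = crossovers.region_restricted_counts(
            ds.genotypes, "X", (26_900_000, 49_000_000)
        )
        assert (counts.loc[counts["sex"] == "M", "count"] == 0).all()


class TestHaplotypeFrequency:
    def test_neutral_transmission_near_equal(self, clean_dataset):
        out = crossovers.haplotype_frequency(
            clean_dataset.genotypes, "X", (26_900_000, 49_000_000)
        )
        n = out["n"]
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= out["AZ"] <= hi
        assert out["AZ"] + out["UT"] == n
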