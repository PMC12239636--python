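"""Filter cascade and cross-design X-genotype validation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neoxqtl import qc
from neoxqtl.containers import AA, AB, BB, NA
from neoxqtl.genome import default_genome
from neoxqtl.simulate import ObservationModel, SimulationConfig, simulate_cross

from conftest import make_matrix


class TestCallQuality:
    def test_boundary_gq_is_strict(self):
        gm = make_matrix([[AA, AB]], ["1"], [100], ["M", "F"])
        gm.gq = np.array([[30, 31]])
        gm.dp = np.array([[50, 50]])
        out = qc.filter_call_quality(gm)
        assert out.calls[0, 0] == NA  # GQ == 30 fails the strict > 30 rule
        assert out.calls[0, 1] == AB

    def test_high_quality_matrix_unchanged(self):
        gm = make_matrix([[AA, AB], [BB, AB]], ["1", "1"], [100, 200], ["M", "F"])
        gm.gq = np.full((2, 2), 99)
        gm.dp = np.full((2, 2), 50)
        out = qc.filter_call_quality(gm)
        assert (out.calls == gm.calls).all()

    def test_indel_sites_dropped(self):
        calls = np.full((10, 2), AB, dtype=np.int8)
        gm = make_matrix(calls, ["1"] * 10, list(range(100, 1100, 100)), ["M", "F"])
        gm.markers.loc[[2, 5, 7], "alt"] = "TTG"  # 3 indel records
        out = qc.filter_call_quality(gm)
        assert out.n_markers == 7


class TestInformativeSites:
    def _matrix(self, p0_calls):
        """Two P0s + two F2s; one marker per supplied P0 call pair."""
        n = len(p0_calls)
        calls = np.array([[a, b, AB, AB] for a, b in p0_calls], dtype=np.int8)
        return make_matrix(
            calls,
            ["1"] * n,
            list(range(100, 100 * (n + 1), 100)),
            ["M", "F", "M", "F"],
            generations=["P0", "P0", "F2", "F2"],
            polarized=False,
        )

    def test_identical_homozygotes_dropped(self):
        gm = self._matrix([(AA, AA)])
        out = qc.select_informative_sites(gm, "i0", "i1")
        assert out.n_markers == 0

    def test_opposite_homozygotes_kept_and_polarized(self):
        gm = self._matrix([(AA, BB), (BB, AA)])
        out = qc.select_informative_sites(gm, "i0", "i1")
        assert out.n_markers == 2
        assert out.polarized
        # after polarization the AZ parent is always AA (two AZ alleles)
        assert (out.calls[:, 0] == AA).all()
        assert (out.calls[:, 1] == BB).all()
        assert list(out.markers["origin_of_alt"]) == ["AZ", "UT"]

    def test_fixture_count_and_chromosome_restriction(self):
        pairs = [(AA, BB)] * 6 + [(AA, AA), (AB, BB), (NA, BB), (BB, BB)] * 3 + [(BB, AA)] * 2
        gm = self._matrix(pairs)
        gm.markers.loc[gm.markers.index[-2:], "chrom"] = "scaffold_99"
        out = qc.select_informative_sites(gm, "i0", "i1", chromosomes=["1"])
        assert out.n_markers == 6

    def test_missing_p0_raises(self):
        gm = self._matrix([(AA, BB)])
        with pytest.raises(ValueError, match="nope"):
            qc.select_informative_sites(gm, "nope", "i1")


class TestMissingness:
    def test_exact_threshold_inclusive(self):
        calls = np.full((1, 100), AB, dtype=np.int8)
        calls[0, :68] = NA  # exactly 68% missing
        gm = make_matrix(calls, ["1"], [100], ["M"] * 100)
        gm2 = make_matrix(np.vstack([calls, np.full((1, 100), AB, np.int8)]),
                          ["1", "1"], [100, 200], ["M"] * 100)
        out = qc.filter_missingness(gm2)
        assert out.n_markers == 1

    def test_complete_matrix_unchanged(self):
        calls = np.full((5, 8), AB, dtype=np.int8)
        gm = make_matrix(calls, ["1"] * 5, list(range(100, 600, 100)), ["M"] * 8)
        out = qc.filter_missingness(gm)
        assert out.n_markers == 5 and out.n_individuals == 8

    def test_all_na_marker_and_individual_removed(self):
        calls = np.full((10, 10), AB, dtype=np.int8)
        calls[3, :] = NA
        calls[:, 6] = NA
        gm = make_matrix(calls, ["1"] * 10, list(range(100, 1100, 100)), ["M"] * 10)
        out = qc.filter_missingness(gm)
        assert (out.n_markers, out.n_individuals) == (9, 9)


class TestThinning:
    def test_greedy_keep_first(self):
        calls = np.full((3, 2), AB, dtype=np.int8)
        gm = make_matrix(calls, ["1"] * 3, [1, 50_000, 120_000], ["M", "F"])
        out = qc.thin_markers(gm, 100_000)
        assert list(out.markers["pos_bp"]) == [1, 120_000]

    def test_single_marker_kept(self):
        gm = make_matrix([[AB]], ["1"], [5], ["M"])
        assert qc.thin_markers(gm).n_markers == 1

    def test_matches_greedy_oracle_on_dense_chromosome(self):
        rng = np.random.default_rng(0)
        pos = np.unique(rng.integers(1, 40_000_000, size=1500))
        calls = np.full((len(pos), 2), AB, dtype=np.int8)
        gm = make_matrix(calls, ["1"] * len(pos), list(pos), ["M", "F"])
        out = qc.thin_markers(gm, 100_000)
        kept, last = [], None  # independent greedy re-implementation
        for p in pos:
            if last is None or p - last >= 100_000:
                kept.append(p)
                last = p
        assert list(out.markers["pos_bp"]) == kept


class TestXFlags:
    def _xmat(self, male_call, female_call):
        calls = np.array([[male_call, female_call]], dtype=np.int8)
        return make_matrix(calls, ["X"], [100], ["M", "F"])

    def test_male_het_flagged(self):
        flags = qc.flag_impossible_x(self._xmat(AB, BB))
        assert len(flags) == 1 and flags[0].reason == "male_het_X"

    def test_male_homozygote_not_flagged(self):
        assert qc.flag_impossible_x(self._xmat(BB, BB)) == []

    def test_female_azaz_flagged(self):
        flags = qc.flag_impossible_x(self._xmat(BB, AA))
        assert len(flags) == 1 and flags[0].reason == "female_AZAZ_X"

    def test_autosomes_never_flagged(self):
        gm = make_matrix([[AB, AA]], ["1"], [100], ["M", "F"])
        assert qc.flag_impossible_x(gm) == []

    def test_unknown_sex_raises(self):
        gm = self._xmat(AB, BB)
        gm.individuals.loc[0, "sex"] = "?"
        with pytest.raises(ValueError, match="i0"):
            qc.flag_impossible_x(gm)

    def test_contamination_flag_count_binomial(self):
        """Flag count matches the binomial expectation from simulation truth."""
        cfg = SimulationConfig(
            genome=default_genome(with_inversions=False),
            n_f2=120,
            n_markers=400,
            observation=ObservationModel(0.0, 0.0, neoy_contamination_rate=0.1),
            viability=None,
        )
        ds = simulate_cross(cfg, seed=12)
        flags = qc.flag_impossible_x(ds.genotypes)
        gm = ds.genotypes
        region = gm.marker_is_x() & (gm.markers["pos_bp"].to_numpy() <= 26_000_000)
        f2m = gm.individual_mask(generation="F2", sex="M")
        n_cells = int(region.sum() * f2m.sum())
        expected = 0.1 * n_cells
        sd = np.sqrt(n_cells * 0.1 * 0.9)
        male_flags = [f for f in flags if f.reason == "male_het_X"]
        assert abs(len(male_flags) - expected) < 3 * sd


class TestResolveFlags:
    def test_multi_individual_marker_dropped(self):
        calls = np.array([[AB, AB, BB]], dtype=np.int8)
        gm = make_matrix(calls, ["X"], [100], ["M", "M", "F"])
        flags = qc.flag_impossible_x(gm)
        assert len(flags) == 2
        out = qc.resolve_flags(gm, flags)
        assert out.n_markers == 0

    def test_single_flag_masked_marker_kept(self):
        calls = np.array([[AB, BB, BB]], dtype=np.int8)
        gm = make_matrix(calls, ["X"], [100], ["M", "M", "F"])
        out = qc.resolve_flags(gm, qc.flag_impossible_x(gm))
        assert out.n_markers == 1
        assert out.calls[0, 0] == NA

    def test_no_flags_identity(self):
        gm = make_matrix([[BB, BB]], ["X"], [100], ["M", "F"])
        out = qc.resolve_flags(gm, [])
        assert (out.calls == gm.calls).all()

    def test_resolution_is_idempotent(self, noisy_dataset):
        gm = noisy_dataset.genotypes
        out = qc.resolve_flags(gm, qc.flag_impossible_x(gm))
        assert qc.flag_impossible_x(out) == []


class TestSegregationDistortion:
    def _marker(self, n_aa, n_ab, n_bb, chrom="1"):
        calls = np.array([[AA] * n_aa + [AB] * n_ab + [BB] * n_bb], dtype=np.int8)
        n = n_aa + n_ab + n_bb
        return make_matrix(calls, [chrom], [100], ["M"] * n)

    def test_perfect_ratio_kept(self):
        out = qc.segregation_distortion_filter(self._marker(25, 50, 25))
        assert out.n_markers == 1

    def test_distorted_marker_dropped(self):
        """Counts (50, 40, 10): chi-square = 34 against (25, 50, 25), P << 0.01."""
        counts = np.array([50, 40, 10])
        expected = np.array([25.0, 50.0, 25.0])
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        assert stats.chi2.sf(chi2, 2) < 0.01
        out = qc.segregation_distortion_filter(self._marker(50, 40, 10))
        assert out.n_markers == 0

    def test_x_markers_exempt(self):
        out = qc.segregation_distortion_filter(self._marker(50, 0, 10, chrom="X"))
        assert out.n_markers == 1


class TestCascade:
    def test_rerun_is_identity(self, noisy_dataset):
        gm = noisy_dataset.genotypes
        once, _ = qc.run_qc(gm, "P0_AZ_male", "P0_UT_female")
        twice, _ = qc.run_qc(once, "P0_AZ_male", "P0_UT_female")
        assert list(once.markers["name"]) == list(twice.markers["name"])
        assert (once.calls == twice.calls).all()

    def test_clean_data_nearly_untouched(self, clean_dataset):
        """Noise-free data: nothing removed except rare chi-square false positives."""
        gm = clean_dataset.genotypes
        out, report = qc.run_qc(gm, "P0_AZ_male", "P0_UT_female")
        df = report.to_frame()
        non_distortion = df[df["stage"] != "segregation_distortion"]
        assert len(non_distortion) == 0
        assert out.n_individuals == gm.n_individuals
        # chi-square at alpha=0.01: allow a generous false-positive margin
        assert len(df) <= np.ceil(0.03 * gm.n_markers)
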