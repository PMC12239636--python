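"""Recombination fractions, ordering, multipoint maps."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoxqtl import linkmap
from neoxqtl.containers import AA, AB, BB, NA
from neoxqtl.genome import ChromosomeModel, default_genome
from neoxqtl.simulate import (
    ObservationModel,
    QTLModel,
    SimulationConfig,
    simulate_cross,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------
@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.floats(min_value=0.0, max_value=0.499))
def test_haldane_round_trip(r):
    assert linkmap.haldane_cm_to_rf(linkmap.haldane_rf_to_cm(r)) == pytest.approx(
        r, abs=1e-12
    )


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.floats(min_value=0.0, max_value=0.49))
def test_kosambi_round_trip(r):
    assert linkmap.kosambi_cm_to_rf(linkmap.kosambi_rf_to_cm(r)) == pytest.approx(
        r, abs=1e-10
    )


# ---------------------------------------------------------------------------
# two-point estimation
# ---------------------------------------------------------------------------
def _brute_force_rf_aa(g1, g2, grid=None):
    """Independent grid-search oracle: enumerate the 16 gamete configurations."""
    if grid is None:
        grid = np.arange(0.0, 0.50005, 1e-4)
    ok = (g1 != NA) & (g2 != NA)
    counts = np.zeros((3, 3))
    np.add.at(counts, (g1[ok], g2[ok]), 1)
    best_r, best_ll = 0.25, -np.inf
    table = np.zeros((len(grid), 3, 3))
    for gi, r in enumerate(grid):
        for m1, m2, p1, p2 in itertools.product((0, 1), repeat=4):
            pm = (1 - r) / 2 if m1 == m2 else r / 2
            pp = (1 - r) / 2 if p1 == p2 else r / 2
            table[gi, m1 + p1, m2 + p2] += pm * pp
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.nansum(counts[None] * np.log(np.maximum(table, 1e-300)), axis=(1, 2))
    return float(grid[np.argmax(ll)])


class TestEstimateRf:
    def test_identical_vectors_rf_zero(self):
        g = np.array([AA, AB, BB, AB, AA, BB, AB, AA, BB, AB], dtype=np.int8)
        sexes = np.array(["M"] * 10)
        est = linkmap.estimate_rf(g, g, sexes, False, False)
        assert est.rf == pytest.approx(0.0, abs=1e-6)
        assert est.lod > 1.0

    def test_independent_markers_rf_half(self):
        rng = np.random.default_rng(0)
        n = 200
        g1 = rng.choice([AA, AB, AB, BB], size=n).astype(np.int8)
        g2 = rng.choice([AA, AB, AB, BB], size=n).astype(np.int8)
        sexes = np.array(["M"] * n)
        est = linkmap.estimate_rf(g1, g2, sexes, False, False)
        se = 0.5 / np.sqrt(2 * n)  # binomial SE on gametes
        assert abs(est.rf - 0.5) < 3 * se
        assert est.lod < 1.0

    def test_too_few_joint_individuals_gives_nan(self):
        g = np.array([AA] * 5 + [NA] * 10, dtype=np.int8)
        sexes = np.array(["M"] * 15)
        est = linkmap.estimate_rf(g, g, sexes, False, False)
        assert np.isnan(est.rf)

    @pytest.mark.parametrize("seed", range(12))
    def test_em_matches_grid_search_oracle(self, seed):
        """EM rf within 1e-3 of brute-force grid maximization (random fixtures)."""
        rng = np.random.default_rng(seed)
        r_true = rng.uniform(0.02, 0.45)
        n = 50
        # simulate linked F2 genotype pairs gamete by gamete
        m1 = rng.integers(0, 2, n)
        p1 = rng.integers(0, 2, n)
        m2 = np.where(rng.random(n) < r_true, 1 - m1, m1)
        p2 = np.where(rng.random(n) < r_true, 1 - p1, p1)
        g1 = (m1 + p1).astype(np.int8)
        g2 = (m2 + p2).astype(np.int8)
        sexes = np.array(["M"] * n)
        est = linkmap.estimate_rf(g1, g2, sexes, False, False)
        oracle = _brute_force_rf_aa(g1, g2)
        assert est.rf == pytest.approx(oracle, abs=1e-3)

    def test_x_pair_uses_maternal_gamete(self):
        # males read directly; females resolve through the UT paternal X
        g1 = np.array([AA, BB, AB, BB], dtype=np.int8)  # M, M, F, F
        g2 = np.array([AA, BB, AB, BB], dtype=np.int8)
        sexes = np.array(["M", "M", "F", "F"])
        est = linkmap.estimate_rf(g1, g2, sexes, True, True, min_joint=4)
        assert est.rf == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------
def _two_chrom_dataset(seed=21, n_f2=150):
    genome = [
        ChromosomeModel("1", 20_000_000, np.array([0.0, 2e7]), np.array([0.0, 80.0])),
        ChromosomeModel("2", 20_000_000, np.array([0.0, 2e7]), np.array([0.0, 80.0])),
        ChromosomeModel(
            "X", 20_000_000, np.array([0.0, 2e7]), np.array([0.0, 60.0]), is_x=True
        ),
    ]
    cfg = SimulationConfig(
        genome=genome,
        marker_positions={
            "1": np.arange(1_000_000, 20_000_000, 1_000_000),
            "2": np.arange(1_000_000, 20_000_000, 1_000_000),
            "X": np.arange(1_000_000, 20_000_000, 1_000_000),
        },
        n_f2=n_f2,
        qtl=QTLModel(pos_bp=10_000_000),
        observation=ObservationModel(0.0, 0.0, 0.0),
        viability=None,
    )
    return simulate_cross(cfg, seed=seed)


class TestOrdering:
    def test_optimal_order_unchanged(self):
        ds = _two_chrom_dataset()
        orders, removed = linkmap.order_and_validate(ds.genotypes, check_cross_linkage=False)
        expected = list(ds.genotypes.markers.loc[
            ds.genotypes.markers["chrom"] == "1", "name"])
        assert orders["1"] == expected
        assert removed == []

    def test_adjacent_swap_recovered(self):
        ds = _two_chrom_dataset(seed=22)
        gm = ds.genotypes.copy()
        rows = np.flatnonzero((gm.markers["chrom"] == "1").to_numpy())
        a, b = rows[8], rows[9]
        # swap the genotype content of two adjacent markers
        gm.calls[[a, b]] = gm.calls[[b, a]]
        orders, _ = linkmap.order_and_validate(gm, check_cross_linkage=False)
        names = list(gm.markers["name"])
        expected = [names[i] for i in rows]
        expected[8], expected[9] = expected[9], expected[8]
        assert orders["1"] == expected

    def test_cross_chromosome_marker_removed(self):
        ds = _two_chrom_dataset(seed=23)
        gm = ds.genotypes.copy()
        rows1 = np.flatnonzero((gm.markers["chrom"] == "1").to_numpy())
        rows2 = np.flatnonzero((gm.markers["chrom"] == "2").to_numpy())
        # plant chromosome-1 genotypes into a marker assigned to chromosome 2
        gm.calls[rows2[5]] = gm.calls[rows1[5]]
        name = gm.markers.at[rows2[5], "name"]
        _, removed = linkmap.order_and_validate(gm)
        assert name in removed


# ---------------------------------------------------------------------------
# multipoint map
# ---------------------------------------------------------------------------
class TestEstimateMap:
    def test_no_error_no_missing_equals_chained_two_point(self):
        """With error_prob=0 and complete data the HMM factorizes."""
        ds = _two_chrom_dataset(seed=24)
        gm = ds.genotypes.subset_chrom("1")
        gm.x_chrom = "X"
        gmap = linkmap.estimate_map(gm, error_prob=0.0)
        sexes = gm.individuals.loc[gm.individual_mask(generation="F2"), "sex"].to_numpy()
        f2 = gm.individual_mask(generation="F2")
        chained = 0.0
        for k in range(gm.n_markers - 1):
            est = linkmap.estimate_rf(
                gm.calls[k, f2], gm.calls[k + 1, f2], sexes, False, False
            )
            chained += float(linkmap.haldane_rf_to_cm(est.rf))
        assert gmap.total_cm == pytest.approx(chained, rel=1e-3, abs=0.05)

    def test_zero_recombinants_zero_length(self):
        calls = np.tile(np.array([[AA], [AA], [AA]], dtype=np.int8), (1, 30))
        gm = make_matrix(calls, ["1"] * 3, [100, 200, 300], ["M"] * 30)
        gmap = linkmap.estimate_map(gm, error_prob=0.0)
        assert gmap.total_cm == pytest.approx(0.0, abs=1e-6)

    def test_three_marker_em_matches_joint_grid_oracle(self):
        """Adjacent rf within 1e-3 of brute-force joint likelihood maximization."""
        rng = np.random.default_rng(31)
        n = 30
        r1_true, r2_true = 0.15, 0.3
        m = np.empty((3, n), dtype=int)
        p = np.empty((3, n), dtype=int)
        m[0] = rng.integers(0, 2, n)
        p[0] = rng.integers(0, 2, n)
        for k, r in ((1, r1_true), (2, r2_true)):
            m[k] = np.where(rng.random(n) < r, 1 - m[k - 1], m[k - 1])
            p[k] = np.where(rng.random(n) < r, 1 - p[k - 1], p[k - 1])
        calls = (m + p).astype(np.int8)
        gm = make_matrix(calls, ["1"] * 3, [100, 200, 300], ["M"] * n)
        gmap = linkmap.estimate_map(gm, error_prob=0.001)
        cm_to_rf = linkmap.haldane_cm_to_rf
        cm = gmap.groups[0].cm
        r_est = (cm_to_rf(cm[1] - cm[0]), cm_to_rf(cm[2] - cm[1]))

        e = 0.001

        def loglik(r1, r2):
            # independent enumeration over 4^3 hidden gamete-pair paths
            total = 0.0
            states = list(itertools.product((0, 1), repeat=2))
            for i in range(n):
                li = 0.0
                for s1 in states:
                    for s2 in states:
                        for s3 in states:
                            pr = 0.25
                            for (a, b), r in (((s1, s2), r1), ((s2, s3), r2)):
                                pr *= ((1 - r) if a[0] == b[0] else r) * (
                                    (1 - r) if a[1] == b[1] else r
                                )
                            for k, s in enumerate((s1, s2, s3)):
                                obs = calls[k, i]
                                pr *= (1 - e) if obs == sum(s) else e / 2
                            li += pr
                total += np.log(li)
            return total

        # two-stage grid around the EM estimate
        coarse = np.arange(0.02, 0.48, 0.01)
        ll = np.array([[loglik(r1, r2) for r2 in coarse] for r1 in coarse])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        fine1 = np.arange(max(coarse[i] - 0.012, 0.001), coarse[i] + 0.012, 5e-4)
        fine2 = np.arange(max(coarse[j] - 0.012, 0.001), coarse[j] + 0.012, 5e-4)
        llf = np.array([[loglik(r1, r2) for r2 in fine2] for r1 in fine1])
        i2, j2 = np.unravel_index(np.argmax(llf), llf.shape)
        assert r_est[0] == pytest.approx(fine1[i2], abs=1e-3)
        assert r_est[1] == pytest.approx(fine2[j2], abs=1e-3)

    def test_em_loglik_nondecreasing(self):
        ds = _two_chrom_dataset(seed=25)
        gm = ds.genotypes.subset_chrom("1")
        f2 = gm.individual_mask(generation="F2")
        sexes = gm.individuals.loc[f2, "sex"].to_numpy()
        calls = gm.calls[:, f2]
        r0 = linkmap._initial_rf(calls, sexes, False)
        _, _, _, trace = linkmap._fit_chromosome(calls, sexes, False, 0.001, r0)
        assert (np.diff(trace) > -1e-6).all()

    def test_error_model_recovers_true_length(self):
        """With error_prob set to the true noise rate, length is recovered ~10%."""
        genome = [
            ChromosomeModel("1", 30_000_000, np.array([0.0, 3e7]), np.array([0.0, 100.0])),
            ChromosomeModel("X", 10_000_000, np.array([0.0, 1e7]),
                            np.array([0.0, 40.0]), is_x=True),
        ]
        cfg = SimulationConfig(
            genome=genome,
            marker_positions={
                "1": np.arange(500_000, 30_000_000, 500_000),
                "X": np.arange(1_000_000, 10_000_000, 1_000_000),
            },
            n_f2=250,
            qtl=QTLModel(pos_bp=5_000_000),
            observation=ObservationModel(0.01, 0.0, 0.0),
            viability=None,
        )
        ds = simulate_cross(cfg, seed=33)
        chrom1 = genome[0]
        pos = ds.genotypes.markers.loc[ds.genotypes.markers["chrom"] == "1", "pos_bp"]
        true_span = float(chrom1.cm_at(pos.max()) - chrom1.cm_at(pos.min()))
        sub = ds.genotypes.subset_chrom("1")
        sub.x_chrom = "X"
        with_model = linkmap.estimate_map(sub, error_prob=0.01)
        naive = linkmap.estimate_map(sub, error_prob=1e-8)
        est = with_model.groups[0].length_cm
        assert abs(est - true_span) / true_span < 0.10
        # ignoring the noise inflates the map
        assert naive.groups[0].length_cm > est


class TestSexSpecificMaps:
    def test_small_sex_raises(self):
        calls = np.full((2, 12), AB, dtype=np.int8)
        gm = make_matrix(calls, ["1"] * 2, [100, 200], ["M"] * 11 + ["F"])
        with pytest.raises(ValueError, match="sex F"):
            linkmap.sex_specific_maps(gm)

    def test_no_sex_difference_without_selection(self, clean_dataset):
        male, female = linkmap.sex_specific_maps(clean_dataset.genotypes)
        mx = male.group("X").length_cm
        fx = female.group("X").length_cm
        # same maternal process for both sexes: lengths agree within
        # Poisson sampling noise of the crossover counts
        n = 50  # ~individuals per sex
        se_cm = 100 * np.sqrt(2 * 0.77 / n)
        assert abs(mx - fx) < 3 * se_cm
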