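"""Local-adaptation statistics against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import MiniSnapshot, two_deme_snapshot
from landla.la_stats import (
    additive_variance_per_deme,
    allele_age_summary,
    cumulative_maladaptation,
    effect_class_sums,
    home_away_la,
    la_rel,
    local_heterogeneity,
    pool_low_high,
    snp_contributions,
    wc_fst,
)


class TestHomeAwayLA:
    def test_two_deme_hand_value(self):
        # perfectly adapted residents, optima 0 and 1, V_s = 1:
        # home fitness 1, away fitness exp(-1/2), LA = 1 - exp(-0.5)
        snap = two_deme_snapshot(n_per_deme=4, v_s=1.0)
        res = home_away_la(snap)
        expected = 1.0 - np.exp(-0.5)
        assert res.per_deme_la == pytest.approx([expected, expected])
        assert res.mean_la == pytest.approx(expected)

    def test_uniform_optima_give_zero(self):
        snap = two_deme_snapshot()
        snap.optima[:] = 0.5
        res = home_away_la(snap)
        assert res.mean_la == pytest.approx(0.0)
        assert np.isnan(res.cv_la)  # CV undefined at non-positive mean LA

    def test_mean_equals_mean_of_per_deme(self, evolved_snapshot):
        res = home_away_la(evolved_snapshot)
        assert res.mean_la == pytest.approx(float(res.per_deme_la.mean()))
        assert res.cv_la == pytest.approx(
            float(res.per_deme_la.std(ddof=1) / res.per_deme_la.mean())
        )

    def test_random_deme_relabelling_has_zero_expectation(self, evolved_snapshot):
        snap = evolved_snapshot
        rng = np.random.default_rng(12)
        base = home_away_la(snap)
        vals = []
        deme0 = snap.deme.copy()
        try:
            for _ in range(200):
                snap.deme = rng.permutation(deme0)
                vals.append(home_away_la(snap).mean_la)
        finally:
            snap.deme = deme0
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 4 * se
        assert base.mean_la > np.mean(vals) + 4 * se  # true labels beat shuffled


class TestLaRel:
    def test_zero_effect_allele_contributes_exactly_zero(self):
        snap = two_deme_snapshot(n_per_deme=6)
        # add a second polymorphism with no phenotypic effect
        extra = np.zeros((snap.geno.shape[0], 1), dtype=np.uint8)
        extra[::3] = 1
        snap.geno = np.hstack([snap.geno, extra])
        snap.eff = np.vstack([snap.eff, [[0.0]]])
        snap.pos = np.array([1.0, 2.0])
        snap.origin = np.zeros(2, dtype=np.int64)
        assert la_rel(snap, 1, rng=0) == 0.0

    def test_globally_fixed_allele_contributes_exactly_zero(self):
        snap = two_deme_snapshot(n_per_deme=6)
        fixed = np.ones((snap.geno.shape[0], 1), dtype=np.uint8)
        snap.geno = np.hstack([snap.geno, fixed])
        snap.eff = np.vstack([snap.eff, [[0.7]]])
        snap.pos = np.array([1.0, 2.0])
        snap.origin = np.zeros(2, dtype=np.int64)
        assert la_rel(snap, 1, rng=0) == 0.0

    def test_single_causal_mutation_explains_all_la(self):
        # the only polymorphism perfectly separates the two optima; shuffling
        # it equalizes its frequency across demes in expectation, so the
        # residual mean LA tends to 0 and LA_rel to 1
        snap = two_deme_snapshot(n_per_deme=20, v_s=1.0)
        val = la_rel(snap, 0, n_shuffles=400, rng=1)
        assert val == pytest.approx(1.0, abs=0.05)

    def test_undefined_at_zero_baseline(self):
        snap = two_deme_snapshot()
        snap.optima[:] = 0.5
        with pytest.raises(ValueError, match="undefined"):
            la_rel(snap, 0, rng=0)

    def test_contribution_table_reproducible(self, evolved_snapshot):
        t1 = snp_contributions(evolved_snapshot, seed=7)
        t2 = snp_contributions(evolved_snapshot, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) == evolved_snapshot.n_mut


class TestCumulativeMaladaptation:
    def test_no_negative_rows(self):
        assert cumulative_maladaptation([0.2, 0.0, 0.5]) == 0.0

    def test_arithmetic(self):
        assert cumulative_maladaptation([-0.01, -0.02, 0.5]) == pytest.approx(0.03)

    def test_accepts_contribution_frame(self):
        df = pd.DataFrame({"la_rel": [-0.1, 0.4, -0.2]})
        assert cumulative_maladaptation(df) == pytest.approx(0.3)


class TestEffectClasses:
    def test_partition_is_exact(self):
        rng = np.random.default_rng(5)
        la = rng.normal(0, 0.2, 500)
        sums = effect_class_sums(la)
        total = la[la > 0].sum()
        assert sums["large"] + sums["intermediate"] + sums["small"] == pytest.approx(
            total, rel=1e-12
        )
        assert (
            sums["proportion_large"]
            + sums["proportion_intermediate"]
            + sums["proportion_small"]
        ) == pytest.approx(1.0)


class TestAdditiveVariance:
    def test_single_snp_half_frequency(self):
        snap = two_deme_snapshot(n_per_deme=4)
        # construct one deme at p = 0.5 for a gamma = 1 mutation
        geno = np.zeros((8, 1), dtype=np.uint8)
        geno[::2] = 1
        mini = MiniSnapshot([0.0], np.zeros(4, dtype=int), geno, [[1.0]])
        va = additive_variance_per_deme(mini)
        assert va.ravel()[0] == pytest.approx(0.5)

    def test_monomorphic_deme_has_zero_va(self):
        geno = np.ones((8, 1), dtype=np.uint8)
        mini = MiniSnapshot([0.0], np.zeros(4, dtype=int), geno, [[1.0]])
        assert additive_variance_per_deme(mini).ravel()[0] == 0.0

    def test_matches_hardy_weinberg_resampling(self):
        # V_A formula equals the variance of breeding values when genotypes
        # are resampled under Hardy-Weinberg at the deme's frequencies
        rng = np.random.default_rng(8)
        p = np.array([0.3, 0.7, 0.12])
        gamma = np.array([0.5, -1.2, 2.0])
        expected = float(np.sum(2 * p * (1 - p) * gamma**2))
        genotypes = rng.binomial(2, p, size=(200_000, 3))
        breeding = genotypes @ gamma
        assert breeding.var() == pytest.approx(expected, rel=0.02)

    def test_on_evolved_snapshot_nonnegative(self, evolved_snapshot):
        va = additive_variance_per_deme(evolved_snapshot)
        assert va.shape == (7, 7)
        assert (va >= 0).all()


class TestLocalHeterogeneity:
    def test_uniform_neighbourhood_zero(self):
        grid = np.full((5, 5), 0.5)
        assert local_heterogeneity(grid, (2, 2)) == 0.0

    def test_hand_value(self):
        grid = np.full((3, 3), 0.5)
        grid[2, 1] = 1.5
        assert local_heterogeneity(grid, (1, 1)) == pytest.approx(0.25)

    def test_edge_and_corner_rejected(self):
        grid = np.zeros((4, 4))
        for deme in [(0, 0), (0, 2), (3, 3), (1, 0)]:
            with pytest.raises(ValueError, match="interior"):
                local_heterogeneity(grid, deme)


def oracle_wc_fst(counts, sizes):
    """Independent variance-components computation (per-locus loops)."""
    counts = np.asarray(counts, dtype=float)
    sizes = np.broadcast_to(np.asarray(sizes, dtype=float), (counts.shape[0],))
    r = counts.shape[0]
    num_sum, den_sum = 0.0, 0.0
    for l in range(counts.shape[1]):
        p = counts[:, l] / sizes
        sum_n = sizes.sum()
        nc = (sum_n - (sizes**2).sum() / sum_n) / (r - 1)
        pbar = (sizes * p).sum() / sum_n
        msp = (sizes * (p - pbar) ** 2).sum() / (r - 1)
        msg = (sizes * p * (1 - p)).sum() / (sum_n - r)
        num_sum += msp - msg
        den_sum += msp + (nc - 1) * msg
    return num_sum / den_sum


class TestWcFst:
    def test_alternate_fixation_gives_one(self):
        counts = np.array([[40], [0]])
        assert wc_fst(counts, 40) == pytest.approx(1.0)

    def test_identical_frequencies_nonpositive(self):
        counts = np.array([[20], [20], [20]])
        assert wc_fst(counts, 40) <= 0.0

    def test_two_deme_textbook_case(self):
        counts = np.array([[10], [40]])  # p = 0.2 and 0.8, n = 50 alleles
        assert wc_fst(counts, 50) == pytest.approx(oracle_wc_fst(counts, 50), abs=1e-12)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            sizes = rng.integers(20, 80, size=6)
            p = rng.uniform(0.05, 0.95, size=(6, 10))
            counts = rng.binomial(sizes[:, None], p)
            assert wc_fst(counts, sizes) == pytest.approx(
                oracle_wc_fst(counts, sizes), abs=1e-12
            )

    def test_all_monomorphic_errors(self):
        counts = np.array([[40, 0], [40, 0]])
        with pytest.raises(ValueError, match="monomorphic"):
            wc_fst(counts, 40)

    def test_single_deme_errors(self):
        with pytest.raises(ValueError):
            wc_fst(np.array([[5]]), 10)


class TestAlleleAge:
    def test_equal_ages(self):
        assert allele_age_summary(([7.0, 7.0], [0.1, 2.0])) == 7.0
        assert allele_age_summary(
            ([7.0, 7.0], [0.1, 2.0]), weighted=True
        ) == pytest.approx(7.0)

    def test_equal_weights_match_unweighted(self):
        args = ([10.0, 1000.0], [1.0, -1.0])
        assert allele_age_summary(args) == pytest.approx(505.0)
        assert allele_age_summary(args, weighted=True) == pytest.approx(505.0)

    def test_weighting_pulls_toward_large_effects(self):
        val = allele_age_summary(([10.0, 1000.0], [0.1, 3.0]), weighted=True)
        assert val > 505.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            allele_age_summary(([], []))


class TestPooling:
    def test_low_high_split(self):
        tables = [pd.DataFrame({"la_rel": [float(i)]}) for i in range(6)]
        morans = [0.9, 0.1, 0.5, 0.05, 0.8, 0.3]
        low, high = pool_low_high(tables, morans, 2)
        assert sorted(low["la_rel"]) == [1.0, 3.0]
        assert sorted(high["la_rel"]) == [0.0, 4.0]

    def test_invalid_pool_size(self):
        with pytest.raises(ValueError):
            pool_low_high([pd.DataFrame()] * 3, [0.1, 0.2, 0.3], 2)
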