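"""Data preparation: imputation, dominant coding, the risk-allele filter,
D'/LD pruning, hypertension derivation and the stratified split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_genotypes, make_trait
from ibi.preprocess import (
    derive_htn,
    dominant_code,
    dprime,
    impute_mode,
    ld_prune,
    risk_ratio_filter,
    stratified_split,
)


class TestImputeMode:
    def test_mode_one(self):
        g = impute_mode(make_genotypes([[1], [1], [0], [-1]]))
        assert list(g.values[:, 0]) == [1, 1, 0, 1]

    def test_mode_zero(self):
        g = impute_mode(make_genotypes([[0], [0], [1], [-1], [-1]]))
        assert list(g.values[:, 0]) == [0, 0, 1, 0, 0]

    def test_no_missing_is_identity(self):
        src = make_genotypes([[0, 1], [1, 0]])
        assert np.array_equal(impute_mode(src).values, src.values)

    def test_all_missing_column_names_the_snp(self):
        with pytest.raises(ValueError, match="snp1"):
            impute_mode(make_genotypes([[0, -1], [1, -1]]))


class TestDominantCode:
    def test_one_or_two_copies_becomes_one(self):
        assert list(dominant_code(np.array([0, 1, 2]))) == [0, 1, 1]

    def test_constant_columns(self):
        assert (dominant_code(np.zeros((4, 2), dtype=int)) == 0).all()
        assert (dominant_code(np.full((4, 2), 2)) == 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dominant_code(np.array([0, 3]))


class TestRiskRatioFilter:
    def _geno_with_rates(self, carrier_cases, carrier_total, non_cases, non_total):
        col = [1] * carrier_total + [0] * non_total
        htn = [1] * carrier_cases + [0] * (carrier_total - carrier_cases)
        htn += [1] * non_cases + [0] * (non_total - non_cases)
        return make_genotypes(np.array(col)[:, None]), make_trait(htn)

    def test_rr_four_is_retained(self):
        g, t = self._geno_with_rates(8, 10, 2, 10)
        assert risk_ratio_filter(g, t).n_snps == 1

    def test_protective_snp_removed(self):
        g, t = self._geno_with_rates(1, 10, 5, 10)
        assert risk_ratio_filter(g, t).n_snps == 0

    def test_boundary_rr_one_is_kept(self):
        g, t = self._geno_with_rates(3, 10, 3, 10)
        assert risk_ratio_filter(g, t).n_snps == 1

    def test_zero_denominator_counts_as_risk(self):
        g, t = self._geno_with_rates(4, 10, 0, 10)
        assert risk_ratio_filter(g, t).n_snps == 1

    def test_constant_trait_rejected(self):
        g, _ = self._geno_with_rates(4, 10, 0, 10)
        with pytest.raises(ValueError):
            risk_ratio_filter(g, make_trait([1] * 20))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        g = make_genotypes(rng.integers(0, 2, (80, 12)))
        t = make_trait(rng.integers(0, 2, 80))
        once = risk_ratio_filter(g, t)
        twice = risk_ratio_filter(once, t)
        assert np.array_equal(once.values, twice.values)


class TestDprime:
    def test_identical_columns_are_in_complete_ld(self):
        v = np.array([1, 0, 1, 1, 0, 0])
        assert dprime(v, v) == pytest.approx(1.0)

    def test_complement_is_complete_repulsion(self):
        v = np.array([1, 0, 1, 1, 0, 0])
        assert dprime(v, 1 - v) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(12)
        a = (rng.random(100_000) < 0.4).astype(int)
        b = (rng.random(100_000) < 0.3).astype(int)
        assert dprime(a, b) < 0.02

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 200)
        b = rng.integers(0, 2, 200)
        assert dprime(a, b) == pytest.approx(dprime(b, a))

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            dprime(np.ones(5), np.array([0, 1, 0, 1, 0]))


class TestLdPrune:
    def test_identical_pair_drops_lower_maf(self):
        v = np.array([1, 0, 1, 0, 1, 1, 0, 0])
        g = make_genotypes(
            np.column_stack([v, v]), pos=[1000, 2000], maf=[0.3, 0.2]
        )
        pruned = ld_prune(g, threshold=0.2, window_bp=500_000)
        assert list(pruned.snps["rsid"]) == ["snp0"]

    def test_no_high_ld_pairs_is_identity(self):
        rng = np.random.default_rng(8)
        g = make_genotypes(rng.integers(0, 2, (5000, 6)))
        pruned = ld_prune(g, threshold=0.2, window_bp=500_000)
        # independent columns at n=5000 stay below the threshold
        assert pruned.n_snps == 6

    def test_chain_keeps_the_flanks(self):
        # A ~ B and B ~ C in high LD, A ~ C not: greedy scan removes exactly B
        rng = np.random.default_rng(21)
        a = rng.integers(0, 2, 8000)
        noise1 = rng.random(8000) < 0.32
        b = np.where(noise1, 1 - a, a)
        noise2 = rng.random(8000) < 0.32
        c = np.where(noise2, 1 - b, b)
        g = make_genotypes(
            np.column_stack([a, b, c]), pos=[1000, 2000, 3000], maf=[0.3, 0.3, 0.3]
        )
        d_ab = dprime(a, b)
        d_bc = dprime(b, c)
        d_ac = dprime(a, c)
        assert d_ab > 0.2 and d_bc > 0.2 and d_ac <= 0.2
        pruned = ld_prune(g, threshold=0.2, window_bp=500_000)
        assert list(pruned.snps["rsid"]) == ["snp0", "snp2"]

    def test_outside_window_not_compared(self):
        v = np.array([1, 0, 1, 0, 1, 1, 0, 0])
        g = make_genotypes(np.column_stack([v, v]), pos=[0, 600_000])
        assert ld_prune(g, threshold=0.2, window_bp=500_000).n_snps == 2

    def test_idempotent_and_no_residual_high_ld(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 2, (3000, 4))
        # duplicate some columns with noise to force pruning
        extra = np.where(rng.random((3000, 4)) < 0.05, 1 - base, base)
        values = np.concatenate([base, extra], axis=1)
        g = make_genotypes(values, pos=np.arange(8) * 1000,
                           maf=np.linspace(0.1, 0.45, 8))
        pruned = ld_prune(g, threshold=0.2, window_bp=500_000)
        again = ld_prune(pruned, threshold=0.2, window_bp=500_000)
        assert np.array_equal(pruned.values, again.values)
        for i in range(pruned.n_snps):
            for j in range(i + 1, pruned.n_snps):
                assert dprime(pruned.values[:, i], pruned.values[:, j]) <= 0.2

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            ld_prune(make_genotypes([[0], [1]]), threshold=1.5)


class TestDeriveHtn:
    @pytest.mark.parametrize(
        "sbp, dbp, meds, expected",
        [
            (142, 80, 0, 1),   # SBP at/over 140
            (139, 89, 0, 0),   # both below threshold, unmedicated
            (120, 70, 1, 1),   # medication alone defines hypertension
            (130, 85, 1, 1),   # +10/+5 pushes adjusted SBP to 140
            (100, 90, 0, 1),   # DBP at threshold
        ],
    )
    def test_threshold_rules(self, sbp, dbp, meds, expected):
        _, _, htn = derive_htn([sbp], [dbp], [meds])
        assert htn[0] == expected

    def test_medication_adjustment_values(self):
        adj_sbp, adj_dbp, _ = derive_htn([120], [70], [1])
        assert adj_sbp[0] == 130 and adj_dbp[0] == 75

    def test_missing_bp_without_meds_rejected(self):
        with pytest.raises(ValueError):
            derive_htn([np.nan], [80], [0])

    def test_missing_bp_with_meds_is_hypertensive(self):
        _, _, htn = derive_htn([np.nan], [np.nan], [1])
        assert htn[0] == 1

    @given(
        sbp=st.floats(80, 200),
        dbp=st.floats(40, 130),
        bump=st.floats(0, 40),
        meds=st.integers(0, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_blood_pressure(self, sbp, dbp, bump, meds):
        _, _, low = derive_htn([sbp], [dbp], [meds])
        _, _, high = derive_htn([sbp + bump], [dbp + bump], [meds])
        assert high[0] >= low[0]


class TestStratifiedSplit:
    def test_exact_stratification(self):
        t = make_trait([1] * 100 + [0] * 100)
        res = stratified_split(t.subjects, t, 0.8, seed=0)
        train_idx = np.isin(t.subjects, res.train)
        assert train_idx.sum() == 160
        assert t.htn[train_idx].sum() == 80

    def test_deterministic_under_seed(self):
        t = make_trait([1] * 30 + [0] * 70)
        a = stratified_split(t.subjects, t, 0.8, seed=5)
        b = stratified_split(t.subjects, t, 0.8, seed=5)
        assert np.array_equal(a.train, b.train)
        c = stratified_split(t.subjects, t, 0.8, seed=6)
        assert not np.array_equal(a.train, c.train)

    def test_floor_rounding_per_stratum(self):
        t = make_trait([1] * 930 + [0] * 70)
        res = stratified_split(t.subjects, t, 0.8, seed=1)
        train_idx = np.isin(t.subjects, res.train)
        assert t.htn[train_idx].sum() == 744  # floor(0.8 * 930)

    def test_partition_is_disjoint_and_complete(self):
        t = make_trait([1] * 13 + [0] * 17)
        res = stratified_split(t.subjects, t, 0.7, seed=2)
        assert len(set(res.train) & set(res.test)) == 0
        assert len(res.train) + len(res.test) == 30

    def test_tiny_stratum_rejected(self):
        t = make_trait([1] + [0] * 9)
        with pytest.raises(ValueError):
            stratified_split(t.subjects, t, 0.8, seed=0)
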