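"""The individualized scoring algorithm: population scores, the partitioned
score and its brute-force oracle, and per-patient posteriors."""

import math

import numpy as np
import pytest

from conftest import make_genotypes, make_trait, one_parent_oracle, restricted_oracle
from ibi import core
from ibi.bdeu import BdeuParams


class TestScoreGlobal:
    def test_single_snp_has_full_posterior(self):
        g = make_genotypes([[1], [0], [1], [0]])
        t = make_trait([1, 0, 1, 0])
        table = core.score_global(g, t)
        assert table["gpp"].iloc[0] == pytest.approx(1.0)

    def test_identical_columns_share_posterior(self):
        v = [[1, 1], [1, 1], [0, 0], [0, 0]]
        table = core.score_global(make_genotypes(v), make_trait([1, 0, 1, 0]))
        assert table["gpp"].to_numpy() == pytest.approx([0.5, 0.5])

    def test_worked_four_subject_example(self):
        # V tracks T exactly; U is uninformative
        g = make_genotypes([[1, 1], [1, 0], [0, 1], [0, 0]])
        t = make_trait([1, 1, 0, 0])
        table = core.score_global(g, t)
        assert table["m_s"].iloc[0] == pytest.approx(
            2 * math.log(0.3125 / 0.75), abs=1e-10
        )
        assert table["m_s"].iloc[0] > table["m_s"].iloc[1]
        assert table["gpp"].iloc[0] > table["gpp"].iloc[1]

    def test_gpp_sums_to_one_and_preserves_ranking(self):
        rng = np.random.default_rng(0)
        g = make_genotypes(rng.integers(0, 2, (60, 15)))
        t = make_trait(rng.integers(0, 2, 60))
        table = core.score_global(g, t)
        assert table["gpp"].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.array_equal(
            np.argsort(-table["gpp"].to_numpy(), kind="stable"),
            np.argsort(-table["m_s"].to_numpy(), kind="stable"),
        )

    def test_constant_trait_rejected(self):
        g = make_genotypes([[1], [0]])
        with pytest.raises(ValueError):
            core.score_global(g, make_trait([1, 1]))


def brute_force_partitioned(values: np.ndarray, trait: np.ndarray, ess: float = 1.0):
    """Independent exhaustive scorer for small panels: per-SNP restricted
    scores via the gamma-ratio product oracle, with a full loop over r."""
    n, m = values.shape
    m_s1 = np.empty(m)
    m_r0 = np.empty(m)
    r_best = np.empty(m, dtype=int)
    for s in range(m):
        carriers = values[:, s] == 1
        m_s1[s] = restricted_oracle(values[:, s], trait, carriers, ess)
        best, best_r = -np.inf, -1
        for r in range(m):
            score = restricted_oracle(values[:, r], trait, ~carriers, ess)
            if score > best + 1e-12:
                best, best_r = score, r
        m_r0[s], r_best[s] = best, best_r
    return m_s1, m_r0, m_s1 + m_r0, r_best


class TestScorePartitioned:
    def test_matches_brute_force_oracle_on_small_panels(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = rng.integers(4, 9)
            m = rng.integers(2, 5)
            values = rng.integers(0, 2, (n, m))
            trait = rng.integers(0, 2, n)
            if trait.min() == trait.max():
                continue
            g = make_genotypes(values)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # empty-subpopulation notices
                table = core.score_partitioned(g, make_trait(trait))
            m_s1, m_r0, m_sr, _ = brute_force_partitioned(values, trait)
            np.testing.assert_allclose(table["m_s1"], m_s1, atol=1e-10)
            np.testing.assert_allclose(table["m_r0"], m_r0, atol=1e-10)
            np.testing.assert_allclose(table["m_sr"], m_sr, atol=1e-10)

    def test_partition_identity_and_dominance(self):
        rng = np.random.default_rng(23)
        g = make_genotypes(rng.integers(0, 2, (200, 50)))
        t = make_trait(rng.integers(0, 2, 200))
        table = core.score_partitioned(g, t)
        # M_s = M_s^1 + M_s^0 via the independent oracle
        for s in range(0, 50, 7):
            assert table["m_s"].iloc[s] == pytest.approx(
                one_parent_oracle(g.values[:, s], t.htn), abs=1e-10
            )
        assert (table["m_sr"] >= table["m_s"] - 1e-10).all()

    def test_perfect_predictor_tops_the_ranking(self):
        # T equals V_a exactly: on D^{Va=0} every subject is a control
        values = np.array(
            [[1, 1, 0], [1, 0, 1], [1, 1, 0], [0, 0, 1], [0, 1, 0], [0, 0, 1]]
        )
        trait = values[:, 0].copy()
        table = core.score_partitioned(make_genotypes(values), make_trait(trait))
        assert table["rank_msr"].iloc[0] == 1
        assert table["m_sr"].iloc[0] == table["m_sr"].max()

    def test_argmax_tie_breaks_to_smallest_index(self):
        # two identical candidate estimators: r must pick the first
        v = np.array([[1, 0, 0], [1, 1, 1], [0, 1, 1], [0, 0, 0], [0, 1, 1], [1, 0, 0]])
        t = make_trait([1, 1, 0, 0, 1, 0])
        table = core.score_partitioned(make_genotypes(v), t)
        s = 0
        assert v[:, 1].tolist() == v[:, 2].tolist()
        assert table["r_index"].iloc[s] != 2 or table["m_r0"].iloc[s] == pytest.approx(
            restricted_oracle(v[:, 1], t.htn, v[:, s] == 0)
        )

    def test_block_size_does_not_change_results(self):
        rng = np.random.default_rng(2)
        g = make_genotypes(rng.integers(0, 2, (100, 30)))
        t = make_trait(rng.integers(0, 2, 100))
        a = core.score_partitioned(g, t, block=7)
        b = core.score_partitioned(g, t, block=1024)
        np.testing.assert_array_equal(a["m_sr"], b["m_sr"])
        np.testing.assert_array_equal(a["r_index"], b["r_index"])


class TestPatientPosteriors:
    def _table(self, m_sr):
        import pandas as pd

        return pd.DataFrame({"m_sr": np.asarray(m_sr, dtype=float)})

    def test_single_candidate_gets_probability_one(self):
        e = core.patient_posteriors(self._table([-5.0, -1.0]), [0, 1])
        assert e.posteriors == pytest.approx([1.0])
        assert e.top1 == 1

    def test_equal_scores_split_evenly(self):
        e = core.patient_posteriors(self._table([-3.0, -3.0]), [1, 1])
        assert e.posteriors == pytest.approx([0.5, 0.5])
        assert e.top1 == 0  # tie -> smaller index

    def test_softmax_arithmetic(self):
        e = core.patient_posteriors(self._table([-10.0, -12.0]), [1, 1])
        expected = 1.0 / (1.0 + math.exp(-2.0))
        assert e.posteriors == pytest.approx([expected, 1 - expected], abs=1e-4)
        assert e.posteriors[0] == pytest.approx(0.8808, abs=1e-4)

    def test_extreme_log_marginals_stay_normalized(self):
        e = core.patient_posteriors(self._table([-2500.0, -2510.0, -2499.0]), [1, 1, 1])
        assert e.posteriors.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            core.patient_posteriors(self._table([-1.0]), [0])


class TestAssignmentsAndCoverage:
    def test_disjoint_candidate_sets_can_differ(self):
        import pandas as pd

        table = pd.DataFrame({"m_sr": [-1.0, -2.0, -3.0]})
        e1 = core.patient_posteriors(table, [1, 0, 0], "p1")
        e2 = core.patient_posteriors(table, [0, 0, 1], "p2")
        top = core.assign_top1([e1, e2])
        assert top == {"p1": 0, "p2": 2}

    def test_coverage_curve_cumulative_counts(self):
        assignments = {f"p{i}": snp for i, snp in enumerate([0] * 5 + [1] * 3 + [2] * 2)}
        curve = core.coverage_curve(assignments, snp_order=[0, 1, 2])
        assert list(curve["cumulative"]) == [5, 8, 10]

    def test_coverage_curve_orders_by_method_rank(self):
        assignments = {"p0": 2, "p1": 2, "p2": 0}
        curve = core.coverage_curve(assignments, snp_order=[2, 1, 0])
        assert list(curve["snp"]) == [2, 0]
        assert list(curve["cumulative"]) == [2, 3]

    def test_threshold_coverage_monotone_in_tau(self):
        import pandas as pd

        table = pd.DataFrame({"m_sr": [-1.0, -1.5, -4.0]})
        rng = np.random.default_rng(4)
        explanations = [
            core.patient_posteriors(table, row)
            for row in rng.integers(0, 2, (40, 3))
            if row.any()
        ]
        taus = [0.05, 0.2, 0.5, 0.9]
        covs = [core.coverage_at_threshold(explanations, tau) for tau in taus]
        assert all(a >= b for a, b in zip(covs, covs[1:]))

    def test_equal_score_candidates_never_reach_total_posterior(self):
        import pandas as pd

        table = pd.DataFrame({"m_sr": [-2.0, -2.0]})
        e = core.patient_posteriors(table, [1, 1])
        assert core.coverage_at_threshold([e], 0.99) == 0.0
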