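import numpy as np
import pytest
from scipy.stats import chisquare

from dietshift import (
    CountMatrix,
    NullConfig,
    empirical_p,
    null_distribution,
    null_replicate,
    paired_permutation_test,
    probit_ses,
    redistribute_quantities,
    sample_incidence,
)


@pytest.fixture()
def counts_2x3():
    return CountMatrix(["a", "b", "c"], ["x", "y"],
                       np.array([[10, 0], [0, 5], [2, 7]]))


class TestNullConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="n_perm"):
            NullConfig(n_perm=0)
        with pytest.raises(ValueError, match="variant"):
            NullConfig(variant="bogus")


class TestSampleIncidence:
    def test_two_survey_sampler_is_uniform_on_enumerable_case(self):
        # feasible set for [[1,0],[0,1]] is exactly two matrices
        cm = CountMatrix(["a", "b"], ["x", "y"], np.array([[3, 0], [0, 4]]))
        rng = np.random.default_rng(11)
        hits = sum(
            sample_incidence(cm, rng)[0, 0] for _ in range(10_000)
        )
        assert abs(hits - 5000) <= 150
        stat, p = chisquare([hits, 10_000 - hits])
        assert p > 0.001

    def test_no_freedom_when_all_taxa_shared(self):
        cm = CountMatrix(["a", "b"], ["x", "y"], np.array([[3, 1], [2, 4]]))
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert sample_incidence(cm, rng).all()

    @pytest.mark.parametrize("n_surveys", [2, 4])
    def test_margins_always_preserved(self, n_surveys):
        rng = np.random.default_rng(5)
        for _ in range(50):
            counts = rng.integers(0, 6, size=(6, n_surveys))
            counts[0] += 1  # avoid empty columns/rows
            cm = CountMatrix([f"t{i}" for i in range(6)],
                             [f"s{j}" for j in range(n_surveys)],
                             counts, allow_zero_rows=True)
            inc = sample_incidence(cm, rng)
            obs = cm.counts > 0
            assert np.array_equal(inc.sum(axis=0), obs.sum(axis=0))
            assert np.array_equal(inc.sum(axis=1), obs.sum(axis=1))


class TestRedistributeQuantities:
    def test_shuffle_samp_conserves_value_multiset(self, counts_2x3):
        rng = np.random.default_rng(3)
        inc = sample_incidence(counts_2x3, rng)
        rep = redistribute_quantities(counts_2x3, inc, "shuffle_samp", rng)
        assert sorted(rep.counts[rep.counts > 0]) == [2, 5, 7, 10]

    def test_shuffle_both_draws_all_compositions(self):
        cm = CountMatrix(["a", "b"], ["x"], np.array([[1], [3]]))
        inc = cm.counts > 0
        rng = np.random.default_rng(4)
        seen = set()
        for _ in range(200):
            rep = redistribute_quantities(cm, inc, "shuffle_both", rng)
            assert rep.counts.sum() == 4
            assert (rep.counts[inc] >= 1).all()
            seen.add(tuple(rep.counts[:, 0]))
        assert seen == {(1, 3), (2, 2), (3, 1)}

    def test_occupied_cell_mismatch_rejected(self, counts_2x3):
        bad = np.ones_like(counts_2x3.counts, dtype=bool)
        with pytest.raises(ValueError, match="mismatch"):
            redistribute_quantities(counts_2x3, bad, "shuffle_samp",
                                    np.random.default_rng(0))


class TestNullReplicate:
    @pytest.mark.parametrize("variant", ["shuffle_samp", "shuffle_both", "multinomial"])
    def test_conserved_quantities(self, variant, counts_2x3):
        rng = np.random.default_rng(9)
        cfg = NullConfig(n_perm=1, variant=variant)
        obs_zero_per_survey = (counts_2x3.counts == 0).sum(axis=0)
        for _ in range(200):
            rep = null_replicate(counts_2x3, cfg, rng)
            assert rep.counts.sum() == counts_2x3.counts.sum()
            assert (rep.counts > 0).sum() == (counts_2x3.counts > 0).sum()
            assert np.array_equal(
                (rep.counts == 0).sum(axis=0), obs_zero_per_survey
            )

    def test_multinomial_conserves_survey_totals(self, counts_2x3):
        rng = np.random.default_rng(2)
        cfg = NullConfig(n_perm=1, variant="multinomial")
        for _ in range(100):
            rep = null_replicate(counts_2x3, cfg, rng)
            assert np.array_equal(rep.column_totals(), counts_2x3.column_totals())

    def test_shuffle_samp_lets_survey_totals_migrate(self, counts_2x3):
        # values can land in either survey, so column totals vary while
        # the grand total stays fixed
        rng = np.random.default_rng(6)
        cfg = NullConfig(n_perm=1, variant="shuffle_samp")
        totals = {
            tuple(null_replicate(counts_2x3, cfg, rng).column_totals())
            for _ in range(200)
        }
        assert len(totals) > 1


class TestNullDistribution:
    def test_deterministic_for_fixed_seed(self, counts_2x3):
        cfg = NullConfig(n_perm=50, seed=123)
        stat = lambda cm: float(cm.counts[:, 0].sum())
        a = null_distribution(counts_2x3, stat, cfg)
        b = null_distribution(counts_2x3, stat, cfg)
        assert np.array_equal(a, b)

    def test_constant_statistic_gives_zero_variance(self, counts_2x3):
        cfg = NullConfig(n_perm=30, seed=1)
        null = null_distribution(counts_2x3, lambda cm: 7.0, cfg)
        assert null.var() == 0.0

    def test_statistic_failure_reports_replicate(self, counts_2x3):
        cfg = NullConfig(n_perm=5, seed=1)

        def bad(cm):
            raise ZeroDivisionError("boom")

        with pytest.raises(RuntimeError, match="replicate"):
            null_distribution(counts_2x3, bad, cfg)


class TestEmpiricalP:
    def test_two_sided_exhaustive_count(self):
        assert empirical_p(4.0, np.array([1.0, 2.0, 3.0, 4.0]), "two_sided") == 0.6

    def test_left_tail_minimum(self):
        null = np.arange(1, 100, dtype=float)
        assert empirical_p(0.0, null, "left") == 1 / 100

    def test_right_tail_mirrors_left(self):
        null = np.arange(10, dtype=float)
        assert empirical_p(100.0, null, "right") == 1 / 11
        assert empirical_p(-100.0, null, "right") == 1.0

    def test_monotone_in_extremity(self):
        rng = np.random.default_rng(8)
        null = rng.normal(size=999)
        ps = [empirical_p(t, null, "two_sided") for t in np.linspace(0, 4, 30)]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_bounds(self):
        null = np.zeros(9)
        for alt in ("left", "right", "two_sided"):
            p = empirical_p(0.0, null, alt)
            assert 1 / 10 <= p <= 1.0


class TestProbitSes:
    @pytest.mark.parametrize(
        "p,direction,expected",
        [
            (0.0459, -1, -1.996),
            (0.7683, +1, 0.295),
            (0.0001, -1, -3.891),
            (0.0259, +1, 2.228),
            (0.0186, -1, -2.3535),  # direct quantile evaluation
            (1.0, +1, 0.0),
        ],
    )
    def test_signed_probit_values(self, p, direction, expected):
        assert probit_ses(p, direction) == pytest.approx(expected, abs=5e-4)

    def test_two_sigma_at_five_percent(self):
        assert abs(probit_ses(0.05, 1)) == pytest.approx(1.960, abs=5e-4)

    def test_strictly_decreasing_in_p(self):
        ps = np.linspace(0.001, 1.0, 200)
        ses = [probit_ses(p, +1) for p in ps]
        assert all(b < a for a, b in zip(ses, ses[1:]))

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.0001])
    def test_rejects_out_of_range(self, p):
        with pytest.raises(ValueError):
            probit_ses(p, 1)


class TestPairedPermutationTest:
    def test_constant_statistic_is_null(self, counts_2x3):
        cfg = NullConfig(n_perm=99, seed=5)
        res = paired_permutation_test(counts_2x3, lambda cm: 1.0, cfg,
                                      "two_sided", "const")
        assert res.p == 1.0
        assert res.ses == 0.0
        assert not res.significant

    def test_ses_sign_follows_observed_minus_null_mean(self, counts_2x3):
        cfg = NullConfig(n_perm=199, seed=5, variant="multinomial")
        stat = lambda cm: float(cm.counts[0, 0])
        res = paired_permutation_test(counts_2x3, stat, cfg, "two_sided", "c00")
        if res.observed != res.null_mean:
            assert np.sign(res.ses) == np.sign(res.observed - res.null_mean)
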