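import numpy as np
import pandas as pd
import pytest
from scipy import stats

import prsrank as pr
from prsrank.composition import CLASSES, SIGNS
from prsrank.errors import ValidationError

from .util import make_geno, make_table


def _decomposition(counts, contribs):
    return pr.ScoreDecomposition(
        pd.DataFrame(counts, index=list(SIGNS), columns=list(CLASSES)),
        pd.DataFrame(contribs, index=list(SIGNS), columns=list(CLASSES)),
    )


class TestDecompose:
    def test_four_snp_toy(self):
        t = make_table([0.1, 0.2, -0.1, -0.3])
        dec = pr.decompose(np.array([2, 1, 1, 0]), t)
        assert dec.counts.loc["positive"].tolist() == [1, 1, 0]
        assert dec.counts.loc["negative"].tolist() == [0, 1, 1]
        assert dec.contributions.loc["positive", "hom_effect"] == pytest.approx(0.2)
        assert dec.contributions.loc["positive", "het"] == pytest.approx(0.2)
        assert dec.contributions.loc["negative", "hom_effect"] == 0.0
        assert dec.contributions.loc["negative", "het"] == pytest.approx(-0.1)
        assert dec.total == pytest.approx(0.3)

    def test_all_zero_dosage(self):
        t = make_table([0.1, -0.2, 0.3])
        dec = pr.decompose(np.zeros(3), t)
        assert dec.counts["hom_noneffect"].sum() == 3
        assert dec.total == 0.0

    def test_zero_beta_snps_counted_separately(self):
        t = make_table([0.1, 0.0, -0.2])
        dec = pr.decompose(np.array([1, 2, 1]), t)
        assert dec.n_zero_beta == 1
        assert dec.counts.to_numpy().sum() == 2

    def test_cell_counts_sum_to_panel(self, small_cohort, rng):
        _, table, geno, _, _ = small_cohort
        i = rng.integers(geno.n_individuals)
        dec = pr.decompose(geno.dosage[i], table)
        assert dec.counts.to_numpy().sum() + dec.n_zero_beta == geno.n_snps

    def test_conservation_against_compute_scores(self, small_cohort):
        _, table, geno, _, focal = small_cohort
        dec = pr.decompose(geno.row(focal), table)
        score = pr.compute_scores(geno, table).loc[focal]
        assert dec.total == pytest.approx(score, rel=1e-9)


class TestExcessHomozygotes:
    def test_reference_counts(self):
        dec = _decomposition([[465, 621, 347], [267, 634, 510]], np.zeros((2, 3)))
        assert pr.excess_homozygotes(dec) == 198

    def test_symmetric_is_zero(self):
        dec = _decomposition([[10, 5, 3], [10, 2, 8]], np.zeros((2, 3)))
        assert pr.excess_homozygotes(dec) == 0

    def test_toy_subtraction(self):
        dec = _decomposition([[10, 0, 0], [3, 0, 0]], np.zeros((2, 3)))
        assert pr.excess_homozygotes(dec) == 7

    def test_antisymmetric_under_beta_sign_swap(self, rng):
        betas = rng.normal(0, 0.05, 40)
        d = rng.integers(0, 3, 40)
        a = pr.excess_homozygotes(pr.decompose(d, make_table(betas)))
        # flipping every beta sign AND the dosage orientation mirrors the cells
        b = pr.excess_homozygotes(pr.decompose(d, make_table(-betas)))
        assert pr.decompose(d, make_table(betas)).counts.loc["positive", "hom_effect"] == \
            pr.decompose(d, make_table(-betas)).counts.loc["negative", "hom_effect"]
        assert a == -b


class TestGofTest:
    def test_perfect_fit(self):
        r = pr.gof_test([10, 20, 30], [1 / 6, 2 / 6, 3 / 6])
        assert r.chi2 == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_two_cell_statistic_and_monte_carlo_p(self, rng):
        r = pr.gof_test([10, 0], [0.5, 0.5])
        assert r.chi2 == pytest.approx(10.0)
        assert r.df == 1
        # Monte-Carlo multinomial null for the p-value (asymptotics are
        # approximate at n=10, so compare within a factor of 2)
        draws = rng.multinomial(10, [0.5, 0.5], size=100_000)
        chi2_null = ((draws - 5.0) ** 2 / 5.0).sum(axis=1)
        p_mc = (chi2_null >= 10.0 - 1e-9).mean()
        assert 0.5 * p_mc <= r.p <= 2.0 * p_mc

    def test_six_cell_hand_chi2(self):
        obs = [10, 20, 30, 15, 15, 10]
        prop = np.full(6, 1 / 6)
        expected = np.full(6, 100 / 6)
        hand = float(((np.array(obs) - expected) ** 2 / expected).sum())
        r = pr.gof_test(obs, prop)
        assert r.chi2 == pytest.approx(hand)
        assert r.df == 5
        assert r.expected_counts.sum() == pytest.approx(100)

    def test_p_uniform_under_true_null(self, rng):
        prop = np.array([0.1, 0.15, 0.2, 0.25, 0.2, 0.1])
        ps = []
        for _ in range(2000):
            obs = rng.multinomial(600, prop)
            ps.append(pr.gof_test(obs, prop).p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 1e-3

    def test_renormalizes_with_warning(self):
        with pytest.warns(UserWarning, match="renormalizing"):
            r = pr.gof_test([5, 5], [0.4, 0.4])
        assert r.expected_counts.tolist() == [5.0, 5.0]

    def test_zero_expected_with_observed_rejected(self):
        with pytest.raises(ValidationError):
            pr.gof_test([5, 5], [1.0, 0.0])


class TestPearsonCorrelation:
    @staticmethod
    def _pheno(ids, heights):
        return pr.PhenotypeTable(pd.DataFrame({"individual_id": ids, "height_cm": heights}))

    def test_perfect_linearity(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        res = pr.pearson_correlation(x, self._pheno(list("abcd"), 2 * x.values + 160))
        assert res["r"] == pytest.approx(1.0)

    def test_five_point_hand_computation(self):
        x = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        y = np.array([160.0, 164, 161, 170, 168])
        res = pr.pearson_correlation(x, self._pheno(list("abcde"), y))
        xv = x.values
        hand = ((xv - xv.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((xv - xv.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res["r"] == pytest.approx(hand, rel=1e-12)
        assert res["n"] == 5

    def test_null_distribution_small_r(self, rng):
        n = 407
        rs, ps = [], []
        for _ in range(20):
            x = pd.Series(rng.normal(0, 1, n), index=[f"i{k}" for k in range(n)])
            y = 170 + rng.normal(0, 6, n)
            res = pr.pearson_correlation(x, self._pheno(list(x.index), y))
            rs.append(res["r"])
            ps.append(res["p"])
        assert max(abs(r) for r in rs) < 0.2
        assert 0.2 < np.mean(ps) < 0.8

    def test_id_intersection_and_min_pairs(self):
        x = pd.Series([1.0, 2], index=["a", "b"])
        with pytest.raises(ValidationError):
            pr.pearson_correlation(x, self._pheno(["a", "b"], [170.0, 171]))

    def test_zero_variance_rejected(self):
        x = pd.Series([1.0, 1, 1], index=list("abc"))
        with pytest.raises(ValidationError):
            pr.pearson_correlation(x, self._pheno(list("abc"), [170.0, 171, 172]))


class TestAverageDecomposition:
    def test_matches_per_individual_mean(self, rng):
        betas = rng.normal(0, 0.05, 15)
        D = rng.integers(0, 3, (30, 15))
        t = make_table(betas)
        g = make_geno(D)
        avg = pr.average_decomposition(g, t)
        manual = np.mean(
            [pr.decompose(D[i], t).contributions.to_numpy() for i in range(30)], axis=0
        )
        np.testing.assert_allclose(avg.contributions.to_numpy(), manual, rtol=1e-9)
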