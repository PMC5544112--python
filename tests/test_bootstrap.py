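"""Cohort simulation, marginal GWAS, bootstrap SEs, pre-test, selection."""

import numpy as np
import pytest

from haprap import (
    HaplotypeTable,
    LDModelSpec,
    make_haplotype_frequencies,
    marginal_gwas,
    pretest,
    run_haprap,
    simhaprap_se,
    simulate_cohort,
    simulate_phenotype,
    snp_effect_operator,
    stepwise_select,
    three_snp_model,
)
from haprap.errors import EmptyRegionError, HaprapError

from conftest import make_snps, quantitative_stats, random_haplotype_table


@pytest.fixture(scope="module")
def two_snp_table():
    spec = LDModelSpec(mafs=(0.3, 0.5), r2_targets={(0, 1): 0.0})
    return make_haplotype_frequencies(spec)


class TestSimulateCohort:
    def test_empty_cohort_rejected(self, two_snp_table):
        with pytest.raises(EmptyRegionError):
            simulate_cohort(two_snp_table, 0, seed=1)

    def test_dosage_means_match_frequencies(self, two_snp_table):
        n = 50_000
        dos = simulate_cohort(two_snp_table, n, seed=2)
        p = two_snp_table.freqs
        se = np.sqrt(p * (1 - p) / (2 * n))
        np.testing.assert_array_less(
            np.abs(dos.mean(axis=0) / 2 - p), 3 * se + 1e-12
        )

    def test_determinism(self, two_snp_table):
        a = simulate_cohort(two_snp_table, 100, seed=9)
        b = simulate_cohort(two_snp_table, 100, seed=9)
        np.testing.assert_array_equal(a, b)


class TestSimulatePhenotype:
    def test_null_quantitative_matches_phenotype_sd(self, two_snp_table):
        n = 100_000
        dos = simulate_cohort(two_snp_table, n, seed=3)
        stats = quantitative_stats(two_snp_table, np.zeros(2), phenotype_sd=1.7)
        y = simulate_phenotype(dos, np.zeros(2), stats, seed=4)
        assert y.std() == pytest.approx(1.7, rel=0.02)

    def test_null_binary_case_rate(self, two_snp_table):
        from haprap.sumstats import MarginalStats

        n = 50_000
        dos = simulate_cohort(two_snp_table, n, seed=5)
        stats = MarginalStats(
            snp=["snp1", "snp2"], a1=["A", "A"], a2=["G", "G"],
            freq=two_snp_table.freqs, beta=[0.0, 0.0], se=[0.1, 0.1],
            p=[1, 1], n=[n, n], trait_type="binary", case_proportion=0.3,
        )
        y = simulate_phenotype(dos, np.zeros(2), stats, seed=6)
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(y.mean() - 0.3) < 3 * se

    def test_variance_decomposition(self, two_snp_table):
        n = 100_000
        V = np.array([0.4, 0.2])
        dos = simulate_cohort(two_snp_table, n, seed=7)
        stats = quantitative_stats(two_snp_table, V, phenotype_sd=1.0)
        y = simulate_phenotype(dos, V, stats, seed=8)
        assert y.var() == pytest.approx(1.0, rel=0.02)

    def test_inconsistent_inputs_floor_warns(self, two_snp_table):
        dos = simulate_cohort(two_snp_table, 1000, seed=9)
        V = np.array([5.0, 5.0])  # genetic variance >> stated total
        stats = quantitative_stats(two_snp_table, V, phenotype_sd=1.0)
        with pytest.warns(RuntimeWarning, match="floor"):
            simulate_phenotype(dos, V, stats, seed=10)


class TestMarginalGwas:
    def test_perfect_fit(self, two_snp_table):
        dos = simulate_cohort(two_snp_table, 500, seed=11)
        stats = marginal_gwas(dos, dos[:, 0].copy())
        assert stats.beta[0] == pytest.approx(1.0, abs=1e-12)
        assert stats.se[0] < 1e-12

    def test_closed_form_matches_statsmodels(self, two_snp_table):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        dos = simulate_cohort(two_snp_table, 300, seed=12)
        y = dos[:, 0] * 0.3 + rng.standard_normal(300)
        stats = marginal_gwas(dos, y)
        for j in range(2):
            X = sm.add_constant(dos[:, j])
            res = sm.OLS(y, X).fit()
            assert stats.beta[j] == pytest.approx(res.params[1], abs=1e-10)
            assert stats.se[j] == pytest.approx(res.bse[1], abs=1e-10)
            assert stats.p[j] == pytest.approx(res.pvalues[1], rel=1e-8)

    def test_type_one_error_calibration(self, two_snp_table):
        # independent null SNPs: rejection rate at alpha=0.05 near 0.05
        rng = np.random.default_rng(13)
        n, reps = 400, 1000
        hits = 0
        for r in range(reps):
            dos = simulate_cohort(two_snp_table, n, seed=1000 + r)
            y = rng.standard_normal(n)
            stats = marginal_gwas(dos, y)
            hits += int(stats.p[0] < 0.05)
        assert 0.035 <= hits / reps <= 0.065

    def test_binary_logistic_recovers_log_odds(self, two_snp_table):
        from scipy.special import expit

        rng = np.random.default_rng(14)
        n = 20_000
        dos = simulate_cohort(two_snp_table, n, seed=14)
        logit_p = -1.0 + 0.5 * dos[:, 0]
        y = (rng.random(n) < expit(logit_p)).astype(float)
        stats = marginal_gwas(dos, y, trait_type="binary")
        assert stats.trait_type == "binary"
        assert stats.beta[0] == pytest.approx(0.5, abs=3 * stats.se[0])
        assert stats.fit_ok.all()


class TestSimhaprapSE:
    def test_single_snp_matches_analytic_ols_se(self):
        p, n = 0.3, 10_000
        table = HaplotypeTable(M=[[0], [1]], F=[1 - p, p], snps=make_snps(1))
        stats = quantitative_stats(
            table, np.array([0.05]), n_total=n, phenotype_sd=1.0
        )
        boot = simhaprap_se(table, np.array([0.05]), stats, reps=500, seed=21)
        analytic = 1.0 / np.sqrt(n * 2 * p * (1 - p))
        assert boot.se[0] == pytest.approx(analytic, rel=0.15)

    def test_reps_below_two_rejected(self, two_snp_table):
        stats = quantitative_stats(two_snp_table, np.zeros(2))
        with pytest.raises(HaprapError):
            simhaprap_se(two_snp_table, np.zeros(2), stats, reps=1, seed=1)

    def test_sqrt_n_scaling(self):
        p = 0.4
        table = HaplotypeTable(M=[[0], [1]], F=[1 - p, p], snps=make_snps(1))
        ses = []
        for n in (5_000, 10_000):
            stats = quantitative_stats(
                table, np.array([0.03]), n_total=n, phenotype_sd=1.0
            )
            boot = simhaprap_se(table, np.array([0.03]), stats, reps=500, seed=3)
            ses.append(boot.se[0])
        assert ses[0] / ses[1] == pytest.approx(np.sqrt(2), rel=0.10)

    def test_bit_for_bit_determinism(self, two_snp_table):
        stats = quantitative_stats(
            two_snp_table, np.array([0.1, 0.0]), n_total=2000
        )
        a = simhaprap_se(two_snp_table, np.array([0.1, 0.0]), stats, reps=50, seed=5)
        b = simhaprap_se(two_snp_table, np.array([0.1, 0.0]), stats, reps=50, seed=5)
        np.testing.assert_array_equal(a.se, b.se)


class TestPretest:
    def test_single_significant_snp_retained(self):
        table = HaplotypeTable(M=[[0], [1]], F=[0.5, 0.5], snps=make_snps(1))
        stats = quantitative_stats(table, np.array([0.5]), se=0.01)
        assert pretest(table, stats, threshold=5e-8) == ["snp1"]

    def test_null_snp_removed_first(self, two_snp_table):
        # two independent SNPs; the null one has joint effect ~0 -> highest p
        A = snp_effect_operator(two_snp_table)
        O = A @ np.array([0.5, 0.0])
        stats = quantitative_stats(two_snp_table, O, se=0.01)
        retained = pretest(two_snp_table, stats, threshold=1e-4)
        assert retained == ["snp1"]

    def test_three_snp_model_bystander_eliminated(self):
        # noiseless marginals at tight SEs: the bystander is the only null
        table = make_haplotype_frequencies(three_snp_model())
        A = snp_effect_operator(table)
        O = A @ np.array([1.0, 0.0, 0.3])
        stats = quantitative_stats(table, O, se=0.005, n_total=100_000)
        retained = pretest(table, stats, threshold=5e-8)
        assert retained == ["snp1", "snp3"]


class TestStepwiseSelect:
    def test_vacuous_threshold_keeps_everything(self, two_snp_table):
        A = snp_effect_operator(two_snp_table)
        O = A @ np.array([0.3, 0.1])
        stats = quantitative_stats(two_snp_table, O, se=0.01, n_total=5_000)
        trace = stepwise_select(
            two_snp_table, stats, p_threshold=1.0, reps=50, seed=2
        )
        assert trace.steps == []
        assert trace.final_snps == ["snp1", "snp2"]

    def test_three_snp_model_selects_both_signals(self):
        # simulated meta-analysis: bystander out, lead and secondary stay
        table = make_haplotype_frequencies(three_snp_model())
        n = 100_000
        dos = simulate_cohort(table, n, seed=31)
        rng = np.random.default_rng(32)
        y = dos @ np.array([1.0, 0.0, 0.3]) + rng.standard_normal(n)
        stats = marginal_gwas(dos, y, snps=table.snps)
        trace = stepwise_select(table, stats, p_threshold=5e-8, reps=200, seed=33)
        assert sorted(trace.final_snps) == ["snp1", "snp3"]
        assert [s.snp for s in trace.steps] == ["snp2"]
        assert (trace.p_joint <= 5e-8).all()

    def test_all_null_gives_empty_model(self, two_snp_table):
        rng = np.random.default_rng(34)
        n = 2_000
        dos = simulate_cohort(two_snp_table, n, seed=34)
        y = rng.standard_normal(n)
        stats = marginal_gwas(dos, y, snps=two_snp_table.snps)
        trace = stepwise_select(
            two_snp_table, stats, p_threshold=5e-8, reps=50, seed=35
        )
        assert trace.final_snps == []
        assert len(trace.steps) == 2

    def test_elimination_monotone_and_bounded(self):
        table = make_haplotype_frequencies(three_snp_model())
        A = snp_effect_operator(table)
        O = A @ np.array([0.05, 0.0, 0.01])
        stats = quantitative_stats(table, O, se=0.02, n_total=3_000)
        trace = stepwise_select(table, stats, p_threshold=1e-3, reps=50, seed=36)
        sizes = [len(s.remaining) for s in trace.steps]
        assert sizes == sorted(sizes, reverse=True)
        assert len(trace.steps) <= table.n_snps


class TestPretestConservatism:
    def test_pretest_never_keeps_what_bootstrap_rejects(self):
        """Marginal SEs are never larger than bootstrap joint SEs, so a SNP
        passing the pre-test can still be dropped later — but a SNP the
        pre-test would drop must also fail the bootstrap t-test."""
        rng = np.random.default_rng(40)
        threshold = 1e-3
        from scipy import stats as sps

        for _ in range(10):
            table = random_haplotype_table(rng, max_snps=3, max_condition=20)
            J = table.n_snps
            n = 20_000
            V_true = rng.standard_normal(J) * 0.05
            dos = simulate_cohort(table, n, seed=int(rng.integers(2**31 - 1)))
            y = dos @ V_true + rng.standard_normal(n)
            mstats = marginal_gwas(dos, y, snps=table.snps)
            fit = run_haprap(table, mstats.beta, seed=1)
            boot = simhaprap_se(table, fit.V, mstats, reps=100, seed=2)
            p_pre = 2 * sps.norm.sf(np.abs(fit.V) / mstats.se)
            df = max(n - J - 1, 1)
            p_boot = 2 * sps.t.sf(np.abs(fit.V) / boot.se, df=df)
            dropped_by_pretest = p_pre > threshold
            assert (p_boot[dropped_by_pretest] > threshold).all()
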