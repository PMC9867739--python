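"""The beta-binomial likelihood engine: log-pmf against quadrature and
scipy oracles, parameter recovery, LRT calibration, and the peak-level
multiplicity scheme."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from rcc_regulome import allelic_imbalance as ai
from rcc_regulome.synthetic_data import simulate_betabin


def quadrature_loglik(k, n, pi, rho):
    """Independent oracle: integrate Binomial(n, t) over Beta(alpha, beta)."""
    ab = (1 - rho) / rho
    a, b = pi * ab, (1 - pi) * ab
    val, _ = integrate.quad(
        lambda t: stats.binom.pmf(k, n, t) * stats.beta.pdf(t, a, b),
        0, 1, epsabs=1e-14, limit=200,
    )
    return np.log(val)


class TestBetabinLoglik:
    def test_binomial_limit_closed_form(self):
        # rho = 0: log C(10,5) + 10 log(0.5) = log 0.24609...
        got = ai.betabin_loglik(5, 10, pi=0.5, rho=0.0)
        assert got == pytest.approx(np.log(252 * 0.5**10), abs=1e-12)

    def test_empty_observation_zero(self):
        assert ai.betabin_loglik(0, 0, pi=0.3, rho=0.1) == pytest.approx(0.0)

    def test_matches_quadrature_oracle_on_grid(self):
        errs = []
        for pi in (0.1, 0.3, 0.5, 0.7, 0.9):
            for rho in (0.01, 0.05, 0.1, 0.19):
                for k, n in ((0, 10), (3, 10), (5, 10), (9, 10), (17, 40)):
                    errs.append(
                        abs(ai.betabin_loglik(k, n, pi=pi, rho=rho)
                            - quadrature_loglik(k, n, pi, rho))
                    )
        assert max(errs) < 1e-8
        assert len(errs) == 100

    def test_matches_scipy_betabinom(self):
        for pi, rho in ((0.3, 0.1), (0.7, 0.05)):
            ab = (1 - rho) / rho
            expected = stats.betabinom.logpmf(4, 12, pi * ab, (1 - pi) * ab)
            assert ai.betabin_loglik(4, 12, pi=pi, rho=rho) == pytest.approx(expected, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ai.betabin_loglik(3, 10, pi=1.5, rho=0.1)
        with pytest.raises(ValueError):
            ai.betabin_loglik(3, 10, pi=0.5, rho=1.0)
        with pytest.raises(ValueError):
            ai.betabin_loglik(11, 10, pi=0.5, rho=0.1)

    def test_model_dataclass_validation(self):
        with pytest.raises(ValueError):
            ai.BetaBinModel(pi=0.0, rho=0.1)
        with pytest.raises(ValueError):
            ai.BetaBinModel(pi=0.5, rho=-0.1)
        m = ai.BetaBinModel(pi=0.5, rho=0.0)
        assert ai.betabin_loglik(1, 2, m) == pytest.approx(np.log(0.5))


class TestFitPi:
    def test_binomial_mle(self):
        assert ai.fit_pi([9], [10], 0.0) == pytest.approx(0.9, abs=1e-4)

    def test_symmetry_gives_half(self):
        assert ai.fit_pi([7, 3], [10, 10], 0.05) == pytest.approx(0.5, abs=1e-4)

    def test_recovery_simulation(self):
        rng = np.random.default_rng(21)
        depth = np.full(50, 30)
        k = simulate_betabin(30, 0.7, 0.05, 50, rng)
        assert 0.65 <= ai.fit_pi(k, depth, 0.05) <= 0.75

    def test_zero_reads_error(self):
        with pytest.raises(ValueError):
            ai.fit_pi([0], [0], 0.0)

    def test_median_recovery_error_across_pi_grid(self):
        rng = np.random.default_rng(99)
        for pi_true in (0.5, 0.6, 0.7, 0.9):
            errors = []
            for _ in range(20):
                depth = np.full(20, 30)
                k = simulate_betabin(30, pi_true, 0.05, 20, rng)
                errors.append(abs(ai.fit_pi(k, depth, 0.05) - pi_true))
            assert np.median(errors) <= 0.03


class TestEstimateRho:
    def _counts(self, k, n, stratum=1):
        return pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(len(k))],
             "hap1_reads": k, "hap2_reads": np.asarray(n) - np.asarray(k),
             "cn_stratum": stratum}
        )

    def test_recovers_planted_rho(self):
        rng = np.random.default_rng(5)
        k = simulate_betabin(20, 0.5, 0.05, 500, rng)
        rho = ai.estimate_rho(self._counts(k, np.full(500, 20)))
        assert 0.03 <= rho["global"] <= 0.07

    def test_binomial_data_near_zero(self):
        rng = np.random.default_rng(6)
        k = rng.binomial(20, 0.5, size=500)
        rho = ai.estimate_rho(self._counts(k, np.full(500, 20)))
        assert rho["global"] <= 0.01

    def test_cap_at_max_rho(self):
        rng = np.random.default_rng(7)
        k = simulate_betabin(20, 0.5, 0.5, 500, rng)
        rho = ai.estimate_rho(self._counts(k, np.full(500, 20)))
        assert rho["global"] == pytest.approx(0.2, abs=1e-3)

    def test_min_reads_filter_and_empty_error(self):
        df = self._counts([1, 1], [2, 2])  # both below min_reads=5
        with pytest.raises(ValueError):
            ai.estimate_rho(df)

    def test_sparse_stratum_inherits_global(self):
        rng = np.random.default_rng(8)
        k = simulate_betabin(20, 0.5, 0.05, 100, rng)
        df = self._counts(k, np.full(100, 20), stratum=3)
        df.loc[:4, "cn_stratum"] = 9  # only 5 SNPs in stratum 9 (< min_snps)
        rho = ai.estimate_rho(df)
        assert rho[9] == rho["global"]


class TestImbalanceLrt:
    def test_hand_computed_binomial_lrt(self):
        # 9/10 hap1, rho 0: LRT = 2[9 ln(0.9/0.5) + ln(0.1/0.5)] = 7.36
        pi_hat, lrt, p = ai.test_imbalance([9], [10], 0.0)
        expected = 2 * (9 * np.log(0.9 / 0.5) + np.log(0.1 / 0.5))
        assert lrt == pytest.approx(expected, abs=1e-3)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-3)
        assert p == pytest.approx(0.0067, abs=5e-4)

    def test_null_at_mle_zero(self):
        _, lrt, p = ai.test_imbalance([5], [10], 0.0)
        assert lrt == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0)

    def test_grid_search_oracle(self):
        k, n, rho = np.array([14, 9]), np.array([20, 15]), 0.02
        grid = np.linspace(0.005, 0.995, 2000)
        lls = [np.sum(ai.betabin_loglik(k, n, pi=g, rho=rho)) for g in grid]
        ll0 = np.sum(ai.betabin_loglik(k, n, pi=0.5, rho=rho))
        expected_lrt = 2 * (max(lls) - ll0)
        _, lrt, _ = ai.test_imbalance(k, n, rho)
        assert lrt == pytest.approx(expected_lrt, abs=1e-4)

    def test_differential_identical_groups_null(self):
        pi1, pi2, lrt, p = ai.test_differential_imbalance(
            [40], [100], 0.01, [40], [100], 0.01
        )
        assert lrt == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_differential_detects_group_shift(self):
        _, _, _, p = ai.test_differential_imbalance([80], [100], 0.01, [50], [100], 0.01)
        assert p < 0.01

    def test_differential_zero_reads_error(self):
        with pytest.raises(ValueError):
            ai.test_differential_imbalance([0], [0], 0.0, [5], [10], 0.0)

    def test_lrt_nonnegative_random(self, rng):
        for _ in range(50):
            n = rng.integers(1, 40, size=5)
            k = rng.binomial(n, 0.5)
            _, lrt, _ = ai.test_imbalance(k, n, 0.05)
            assert lrt >= 0


class TestPeakLevel:
    def _snp_frame(self, rows):
        return pd.DataFrame(rows, columns=["peak_id", "snp_id", "pi_hat", "lrt",
                                           "pvalue", "n_individuals", "total_reads"])

    def test_bonferroni_best_snp(self):
        df = self._snp_frame([
            ("pk1", "a", 0.7, 5, 0.01, 3, 100),
            ("pk1", "b", 0.6, 1, 0.5, 3, 100),
            ("pk1", "c", 0.55, 0, 0.9, 3, 100),
            ("pk2", "d", 0.8, 9, 0.004, 3, 100),
        ])
        res = ai.peak_level_significance(df)
        assert res.loc["pk1", "bonferroni_p"] == pytest.approx(0.03)
        assert res.loc["pk1", "best_snp_id"] == "a"
        assert res.loc["pk2", "bonferroni_p"] == pytest.approx(0.004)  # single SNP

    def test_bh_arithmetic_across_peaks(self, rng):
        rows = [(f"pk{i}", f"s{i}", 0.7, 20, 1e-4, 3, 100) for i in range(100)]
        rows += [(f"null{i}", f"n{i}", 0.5, 0, float(p), 3, 100)
                 for i, p in enumerate(rng.uniform(0.05, 1, size=900))]
        res = ai.peak_level_significance(self._snp_frame(rows))
        strong = res.loc[[f"pk{i}" for i in range(100)]]
        assert (strong["q_value"] < 0.05).all()
        # BH oracle for the best peak: q >= m/n * p
        assert res["q_value"].min() >= 1e-4

    def test_classification_rules(self):
        idx = ["p1", "p2", "p3"]
        g1 = pd.DataFrame({"imbalanced": [True, True, False]}, index=idx)
        g2 = pd.DataFrame({"imbalanced": [False, True, False]}, index=idx)
        diff = pd.DataFrame({"diff_padj": [0.001, 0.8, 0.9]}, index=idx)
        labels = ai.classify_group_specific(g1, g2, diff)
        assert labels["p1"] == "ccRCC-specific"
        assert labels["p2"] == "shared"
        assert labels["p3"] == "none"


class TestSnpAssignment:
    def test_assign_and_drop_outside(self):
        from rcc_regulome.core_genomics import GenomicInterval, Peak, PeakSet

        universe = PeakSet([Peak(GenomicInterval("chr1", 100, 200))])
        df = pd.DataFrame({
            "snp_id": ["a", "b"], "chrom": ["chr1", "chr1"], "pos": [150, 250],
            "individual": ["i", "i"], "hap1_reads": [3, 3], "hap2_reads": [2, 2],
        })
        out = ai.assign_snps_to_peaks(df, universe)
        assert out["snp_id"].tolist() == ["a"]
        assert out["peak_id"].iloc[0] == "chr1:100-200"


class TestPlantedRecovery:
    def test_planted_ai_peaks_recalled(self, bundle, ai_output):
        from rcc_regulome.pipeline import ai_recovery

        rec = ai_recovery(bundle, ai_output)
        assert rec["recall"] >= 0.9
        assert rec["false_positive_rate_balanced"] <= 0.05

    def test_group_specific_labels_match_truth(self, bundle, ai_output):
        from rcc_regulome.pipeline import map_planted_peaks_to_universe

        mapping = map_planted_peaks_to_universe(bundle, ai_output["universe"])
        truth = bundle.truth.ai_peak_classes
        labels = ai_output["labels"]
        for cls in ("ccRCC-specific", "pRCC-specific"):
            planted = truth.index[truth == cls]
            regions = mapping.reindex(planted).dropna()
            hit = (labels.reindex(regions.values) == cls).mean()
            assert hit >= 0.6  # three-condition rule is conservative
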