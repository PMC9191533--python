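import numpy as np
import pytest

import mirtarget as mt
from mirtarget import regression as reg
from helpers import make_paired, ols_oracle


class TestFitPairGaussian:
    def test_matches_closed_form_ols(self, rng):
        x = rng.uniform(0.0, 1.0, 30)
        y = np.clip(3.0 - 2.0 * x + rng.normal(0, 0.01, 30), 0, None)
        data = make_paired(x, y)
        fit = mt.fit_pair(data, "gene", ["mir"], family="gaussian")
        b0, b1 = ols_oracle(x, y)
        assert fit.beta[0] == pytest.approx(b0, abs=1e-8)
        assert fit.beta[1] == pytest.approx(b1, abs=1e-8)
        assert fit.converged and not fit.degenerate

    def test_constant_response_gives_zero_slope(self):
        data = make_paired(np.arange(1.0, 11.0), np.full(10, 5.0))
        fit = mt.fit_pair(data, "gene", ["mir"], family="gaussian")
        assert fit.beta[1] == 0.0
        assert fit.r2 == 0.0
        assert fit.pvalues[1] == 1.0

    def test_constant_predictor_flagged_degenerate(self):
        data = make_paired(np.full(10, 4.0), np.arange(1.0, 11.0))
        fit = mt.fit_pair(data, "gene", ["mir"], family="gaussian")
        assert fit.degenerate
        assert fit.pvalues[1] == 1.0
        assert fit.aic == np.inf

    def test_gaussian_aic_closed_form(self, rng):
        # AIC = n ln(RSS/n) + 2k + n ln(2 pi) + n with k = 3 (b0, b1, sigma)
        for _ in range(20):
            n = int(rng.integers(8, 30))
            x = rng.uniform(0, 5, n)
            y = np.clip(rng.uniform(1, 10) + rng.normal(0, 1, n), 0, None)
            data = make_paired(x, y)
            fit = mt.fit_pair(data, "gene", ["mir"], family="gaussian")
            b0, b1 = ols_oracle(x, y)
            rss = np.sum((y - b0 - b1 * x) ** 2)
            expected = n * np.log(rss / n) + 2 * 3 + n * np.log(2 * np.pi) + n
            assert fit.aic == pytest.approx(expected, abs=1e-6)

    def test_scaling_covariance(self, rng):
        x = rng.uniform(1, 9, 40)
        y = np.clip(20 - 1.5 * x + rng.normal(0, 0.5, 40), 0, None)
        c = 250.0
        base = mt.fit_pair(make_paired(x, y), "gene", ["mir"], family="gaussian")
        scaled = mt.fit_pair(make_paired(x * c, y), "gene", ["mir"],
                             family="gaussian", scale=1.0 / c)
        assert scaled.beta[1] == pytest.approx(base.beta[1], abs=1e-8)

    def test_interaction_recovers_planted_effect(self):
        planted = [mt.TruthRecord("mir_0001", "gene_0001", "beta3", 1.5,
                                  mirna_id2="mir_0002")]
        data, _ = mt.simulate_paired_counts(
            100, 2, 1, planted, family="gaussian",
            noise=mt.NoiseParams(sigma=0.1), seed=42)
        fit = mt.fit_pair(data, "gene_0001", ["mir_0001", "mir_0002"],
                          family="gaussian", formula="interaction")
        assert fit.beta[3] == pytest.approx(1.5, abs=0.1)

    def test_multivariate_needs_two_predictors(self, rng):
        data = make_paired(rng.uniform(1, 9, 20), rng.uniform(1, 9, 20))
        with pytest.raises(ValueError, match="exactly 2"):
            mt.fit_pair(data, "gene", ["mir"], formula="multivariate")

    def test_too_few_samples_errors(self):
        data = make_paired(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        with pytest.raises(reg.FitError, match="samples"):
            mt.fit_pair(data, "gene", ["mir"], family="gaussian")


class TestCountFamilies:
    def test_non_integer_response_rejected(self, rng):
        data = make_paired(rng.uniform(1, 9, 20), rng.uniform(1, 9, 20) + 0.5)
        with pytest.raises(reg.FitError, match="gaussian"):
            mt.fit_pair(data, "gene", ["mir"], family="poisson")

    def test_round_counts_escape_hatch(self, rng):
        x = rng.uniform(0, 2, 40)
        y = rng.poisson(5.0, 40) + 0.4  # deliberately non-integer
        fit = mt.fit_pair(make_paired(x, y), "gene", ["mir"],
                          family="poisson", round_counts=True)
        assert fit.converged

    def test_poisson_recovers_log_linear_slope(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 50, 200)
        y = rng.poisson(np.exp(2.0 - 0.04 * x)).astype(float)
        fit = mt.fit_pair(make_paired(x, y, unit="counts"), "gene", ["mir"],
                          family="poisson")
        assert fit.beta[1] == pytest.approx(-0.04, abs=0.01)

    def test_zero_inflated_fit_counts_parameters(self):
        data, _ = mt.simulate_paired_counts(
            120, 1, 1, [mt.TruthRecord("mir_0001", "gene_0001", "beta1", -0.03)],
            family="zero_inflated_poisson", seed=11)
        fit = mt.fit_pair(data, "gene_0001", ["mir_0001"],
                          family="zero_inflated_poisson")
        assert fit.n_params == 3  # b0, b1, inflation constant
        assert fit.aic == pytest.approx(2 * 3 - 2 * fit.loglik, abs=1e-9)


class TestSelectModel:
    def test_explicit_family_bypasses_selection(self, planted_gaussian_dataset):
        data, _ = planted_gaussian_dataset
        fit = mt.fit_pair(data, "gene_0001", ["mir_0001"], family="gaussian")
        assert fit.family == "gaussian"

    def test_gaussian_data_selects_gaussian(self, planted_gaussian_dataset):
        data, _ = planted_gaussian_dataset
        fit = mt.select_model(data, "gene_0001", ["mir_0001"])
        assert fit.family == "gaussian"

    def test_poisson_counts_select_count_family(self):
        data, _ = mt.simulate_paired_counts(
            100, 1, 1, [mt.TruthRecord("mir_0001", "gene_0001", "beta1", -0.05)],
            family="poisson", seed=21)
        fit = mt.select_model(data, "gene_0001", ["mir_0001"])
        assert fit.family in ("poisson", "negative_binomial")

    def test_selected_aic_is_minimum_over_families(self):
        data, _ = mt.simulate_paired_counts(
            80, 1, 1, [mt.TruthRecord("mir_0001", "gene_0001", "beta1", -0.04)],
            family="negative_binomial", seed=31)
        best = mt.select_model(data, "gene_0001", ["mir_0001"])
        for family in reg.FAMILY_ORDER:
            try:
                fit = mt.fit_pair(data, "gene_0001", ["mir_0001"], family=family)
            except reg.FitError:
                continue
            if fit.converged:
                assert best.aic <= fit.aic + 1e-9


class TestBHAdjustment:
    @staticmethod
    def bh_oracle(p):
        # brute-force: adj_i = min_{j: p_j >= p_i by rank} p_(j) * n / j, capped at 1
        p = np.asarray(p, float)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        adj_sorted = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            running = min(running, p[order[rank - 1]] * n / rank)
            adj_sorted[rank - 1] = running
        out = np.empty(n)
        out[order] = adj_sorted
        return out

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            p = rng.uniform(0, 1, int(rng.integers(1, 101)))
            np.testing.assert_allclose(mt.bh_adjust(p), self.bh_oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 60)
        assert (mt.bh_adjust(p) >= p - 1e-15).all()

    def test_nan_passthrough(self):
        out = mt.bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(out[1]) and not np.isnan(out[0])


@pytest.fixture(scope="module")
def planted_batch():
    planted = [mt.TruthRecord(f"mir_{i:04d}", f"gene_{i:04d}", "beta1", -2.0)
               for i in range(1, 6)]
    data, truth = mt.simulate_paired_counts(
        50, 20, 20, planted, family="gaussian",
        noise=mt.NoiseParams(sigma=0.1), seed=77)
    pairs = [(f"mir_{i:04d}", f"gene_{i:04d}") for i in range(1, 21)]
    return data, truth, pairs


class TestRunPart1:
    def test_negative_direction_recovers_planted(self, planted_batch):
        data, truth, pairs = planted_batch
        report = mt.run_part1(data, pairs, family="gaussian",
                              alpha=0.05, direction="negative")
        sig = report.table[report.table["significant"]]
        found = set(zip(sig["mirna_id1"], sig["mrna_id"]))
        assert found == {(t.mirna_id, t.mrna_id) for t in truth}

    def test_positive_direction_finds_nothing(self, planted_batch):
        data, _, pairs = planted_batch
        report = mt.run_part1(data, pairs, family="gaussian",
                              alpha=0.05, direction="positive")
        assert report.summary["n_significant"] == 0

    def test_co_prediction_count_and_percentage(self, planted_batch):
        data, truth, pairs = planted_batch
        # predictions cover 2 of the 5 planted (significant) pairs
        pred = mt.simulate_prediction_table(truth[:2], decoy_count=0, seed=1)
        report = mt.run_part1(data, pairs, family="gaussian",
                              alpha=0.05, direction="negative", predictions=pred)
        assert report.summary["n_significant"] == 5
        assert report.summary["n_co_predicted"] == 2
        assert report.summary["pct_co_predicted"] == 40.0

    def test_rows_sorted_by_adjusted_p(self, planted_batch):
        data, _, pairs = planted_batch
        report = mt.run_part1(data, pairs, family="gaussian")
        padj = report.table["p_adj"].to_numpy()
        padj = padj[~np.isnan(padj)]
        assert (np.diff(padj) >= -1e-15).all()

    def test_global_null_calibration(self):
        # correctly specified null: gaussian responses with a true slope of 0,
        # so the t-based p-values are exactly uniform
        null_planted = [mt.TruthRecord(f"mir_{i:04d}", f"gene_{i:04d}", "beta1", 0.0)
                        for i in range(1, 501)]
        data, _ = mt.simulate_paired_counts(
            50, 500, 500, null_planted, family="gaussian",
            noise=mt.NoiseParams(sigma=1.0), seed=99)
        pairs = [(f"mir_{i:04d}", f"gene_{i:04d}") for i in range(1, 501)]
        report = mt.run_part1(data, pairs, family="gaussian", alpha=0.05)
        raw = report.table["p_raw"].to_numpy()
        frac = np.mean(raw < 0.05)
        assert 0.03 <= frac <= 0.07
        assert report.summary["n_significant"] <= 2

    def test_interaction_pairs_use_three_tuples(self):
        planted = [mt.TruthRecord("mir_0001", "gene_0001", "beta3", 1.5,
                                  mirna_id2="mir_0002")]
        data, _ = mt.simulate_paired_counts(
            100, 4, 4, planted, family="gaussian",
            noise=mt.NoiseParams(sigma=0.1), seed=13)
        pairs = [("mir_0001", "mir_0002", "gene_0001"),
                 ("mir_0003", "mir_0004", "gene_0002")]
        report = mt.run_part1(data, pairs, formula="interaction", family="gaussian")
        sig = report.table[report.table["significant"]]
        assert list(zip(sig["mirna_id1"], sig["mirna_id2"], sig["mrna_id"])) == [
            ("mir_0001", "mir_0002", "gene_0001")]

    def test_lrt_pvalue_close_to_wald_on_strong_effect(self, planted_batch):
        data, _, _ = planted_batch
        wald = mt.fit_pair(data, "gene_0001", ["mir_0001"], family="gaussian")
        lrt = mt.fit_pair(data, "gene_0001", ["mir_0001"], family="gaussian",
                          pvalue_method="lrt")
        assert lrt.pvalues[1] < 1e-10 and wald.pvalues[1] < 1e-10
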