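import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hzmhc.comparative import (
    aggregate_transects,
    apply_lambda,
    lrt,
    pair_correlation_matrix,
    pgls_fit,
)

BALANCED = "((A:1,B:1):1,(C:1,D:1):1);"
SIX_TIP = "(((A:2,B:2):3,(C:4,D:4):1):5,(E:8,F:8):2);"


class TestPairCorrelation:
    def test_hand_computed_four_taxon_case(self):
        # MRCA(A,B) and MRCA(C,D) are 2 apart; max tip distance 4
        corr = pair_correlation_matrix(BALANCED, [("A", "B"), ("C", "D")])
        assert corr.matrix[0, 1] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(corr.matrix), 1.0)

    def test_identical_mrca_gives_unit_correlation(self):
        corr = pair_correlation_matrix(BALANCED, [("A", "B"), ("A", "B")])
        assert corr.matrix[0, 1] == pytest.approx(1.0)

    def test_most_distant_mrcas_give_zero(self):
        # with zero-length tip branches the MRCA nodes sit at the two ends
        # of the longest tip-to-tip path: d = d_max, correlation 0
        star_ends = "((A:0,B:0):10,(C:0,D:0):10);"
        corr = pair_correlation_matrix(star_ends, [("A", "B"), ("C", "D")], repair_psd=False)
        assert corr.matrix[0, 1] == pytest.approx(0.0)

    def test_missing_species_error(self):
        with pytest.raises(ValueError, match="missing"):
            pair_correlation_matrix(BALANCED, [("A", "Z")])

    def test_tip_order_permutation_invariant(self):
        reordered = "((D:1,C:1):1,(B:1,A:1):1);"
        pairs = [("A", "B"), ("C", "D"), ("A", "C")]
        c1 = pair_correlation_matrix(BALANCED, pairs)
        c2 = pair_correlation_matrix(reordered, pairs)
        np.testing.assert_allclose(c1.matrix, c2.matrix)


class TestApplyLambda:
    def corr(self):
        return pair_correlation_matrix(SIX_TIP, [("A", "B"), ("C", "D"), ("E", "F")])

    def test_lambda_zero_gives_identity(self):
        out = apply_lambda(self.corr(), 0.0)
        np.testing.assert_allclose(out.matrix, np.eye(3))

    def test_lambda_one_is_identity_transform(self):
        c = self.corr()
        np.testing.assert_allclose(apply_lambda(c, 1.0).matrix, c.matrix)

    def test_lambda_half_halves_off_diagonals(self):
        c = self.corr()
        out = apply_lambda(c, 0.5)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(out.matrix[off], 0.5 * c.matrix[off])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_lambda(self.corr(), 1.5)


def example_data(seed=0):
    rng = np.random.default_rng(seed)
    pairs = [("A", "B"), ("C", "D"), ("E", "F")]
    return (
        pd.DataFrame(
            {
                "pair": pairs * 2,
                "mhc_class": ["I"] * 3 + ["II"] * 3,
                "response": rng.normal(0.5, 1.0, 6),
                "variance": rng.uniform(0.5, 2.0, 6),
                "time": [2.0, 4.0, 8.0] * 2,
            }
        ),
        pair_correlation_matrix(SIX_TIP, pairs),
    )


class TestPGLS:
    def test_lambda_zero_equals_weighted_least_squares(self):
        data, corr = example_data()
        fit = pgls_fit(data, corr, ["class"], weights="inverse_variance", lam=0.0)
        X = np.column_stack([np.ones(6), (data.mhc_class == "II").astype(float)])
        W = np.diag(1.0 / data.variance)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ data.response)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_identity_structure_unit_weights_equals_ols(self):
        data, corr = example_data(1)
        fit = pgls_fit(data, corr, ["class"], weights=None, lam=0.0)
        X = np.column_stack([np.ones(6), (data.mhc_class == "II").astype(float)])
        beta = np.linalg.lstsq(X, data.response.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_intercept_only_identity_gives_sample_mean(self):
        data, corr = example_data(2)
        one_class = data.assign(mhc_class="I")
        fit = pgls_fit(one_class, corr, [], weights=None, lam=0.0)
        assert fit.params["intercept"] == pytest.approx(one_class.response.mean())

    def test_class_effect_and_lambda_recovered_in_simulation(self):
        # response with a known class effect under phylogenetic correlation;
        # eight pairs give lambda enough leverage to be identified on average
        newick = "(" + ",".join(f"(T{2*i}:1,T{2*i+1}:1):{i+1}" for i in range(8)) + ");"
        pairs = [(f"T{2*i}", f"T{2*i+1}") for i in range(8)]
        corr = pair_correlation_matrix(newick, pairs)
        rng = np.random.default_rng(3)
        results = {}
        for true_lam in (0.0, 1.0):
            C = apply_lambda(corr, true_lam).matrix
            L = np.linalg.cholesky(C + 1e-10 * np.eye(8))
            effects, lambdas = [], []
            for _ in range(100):
                eps = np.concatenate([L @ rng.normal(0, 1, 8), L @ rng.normal(0, 1, 8)])
                data = pd.DataFrame(
                    {
                        "pair": pairs * 2,
                        "mhc_class": ["I"] * 8 + ["II"] * 8,
                        "response": 1.0 + 2.0 * np.r_[np.zeros(8), np.ones(8)] + eps,
                    }
                )
                fit = pgls_fit(data, corr, ["class"], weights=None, lam="ml")
                effects.append(fit.params["class[II]"])
                lambdas.append(fit.lambda_)
            results[true_lam] = (np.asarray(effects), np.asarray(lambdas))
        for true_lam, (effects, _) in results.items():
            sem = effects.std(ddof=1) / np.sqrt(len(effects))
            assert np.mean(effects) == pytest.approx(2.0, abs=4 * sem)
        # lambda estimates respond to the generating structure
        assert results[1.0][1].mean() > results[0.0][1].mean() + 0.1


class TestLRT:
    def test_identical_models_give_p_one(self):
        data, corr = example_data(4)
        fit = pgls_fit(data, corr, ["class"], weights=None, lam=0.0)
        assert lrt(fit, fit) == 1.0

    def test_chi2_quantile_anchor(self):
        # 2*deltaLL = 3.84 on 1 df sits at p ~ 0.05
        data, corr = example_data(5)
        red = pgls_fit(data, corr, ["class"], weights=None, lam=0.0)
        full = pgls_fit(data, corr, ["class", "time"], weights=None, lam=0.0)
        expected = stats.chi2.sf(2 * (full.log_likelihood - red.log_likelihood), 1)
        assert lrt(full, red) == pytest.approx(expected)
        assert stats.chi2.sf(2 * 1.92, 1) == pytest.approx(0.0500, abs=5e-4)

    def test_non_nested_rejected(self):
        data, corr = example_data(6)
        f1 = pgls_fit(data, corr, ["class"], weights=None, lam=0.0)
        f2 = pgls_fit(data, corr, ["time"], weights=None, lam=0.0)
        with pytest.raises(ValueError, match="nested"):
            lrt(f2, f1)

    def test_fit_pathology_detected(self):
        data, corr = example_data(7)
        full = pgls_fit(data, corr, ["class", "time"], weights=None, lam=0.0)
        red = pgls_fit(data, corr, ["class"], weights=None, lam=0.0)
        bad_full = type(full)(
            params=red.params, bse=red.bse, pvalues=red.pvalues, lambda_=0.0,
            log_likelihood=red.log_likelihood - 1.0, sigma2=red.sigma2,
            n_obs=red.n_obs, n_params=red.n_params + 1, weights_used=False,
            terms=full.terms,
        )
        with pytest.raises(ValueError, match="pathology"):
            lrt(bad_full, red)


class TestAggregation:
    def test_single_transect_unchanged(self):
        df = pd.DataFrame(
            {"pair": [("A", "B")], "mhc_class": ["I"], "response": [1.5], "variance": [0.3]}
        )
        out = aggregate_transects(df)
        assert out.loc[0, "response"] == 1.5 and out.loc[0, "variance"] == 0.3

    def test_two_transects_average_estimates_and_variances(self):
        df = pd.DataFrame(
            {
                "pair": [("A", "B")] * 2,
                "mhc_class": ["I"] * 2,
                "response": [1.0, 3.0],
                "variance": [0.5, 1.5],
            }
        )
        out = aggregate_transects(df)
        assert out.loc[0, "response"] == pytest.approx(2.0)
        assert out.loc[0, "variance"] == pytest.approx(1.0)

    def test_idempotent_on_identical_replicates(self):
        df = pd.DataFrame(
            {
                "pair": [("A", "B")] * 3,
                "mhc_class": ["I"] * 3,
                "response": [2.0] * 3,
                "variance": [0.7] * 3,
            }
        )
        out = aggregate_transects(df)
        assert out.loc[0, "response"] == 2.0 and out.loc[0, "variance"] == pytest.approx(0.7)
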