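"""Design matrix construction and maximum simulated likelihood estimation."""

import numpy as np
import pandas as pd
import pytest

from mmchoice import (
    ChoiceDataset,
    EstimationSettings,
    TrueModel,
    build_design_matrix,
    estimate,
    halton_normal_draws,
    simulate_choices,
    simulate_profiles,
    simulated_loglik,
)
from conftest import simulate_small


class TestDesignMatrix:
    def test_23_columns_for_default_catalog(self, sim_dataset, catalog):
        data, _ = sim_dataset
        m = build_design_matrix(data, catalog)
        assert m.n_columns == 23
        assert len(m.labels) == 23

    def test_reference_row_is_all_zero(self, catalog):
        df = pd.DataFrame(
            {
                "respondent_id": [1, 1],
                "task_id": [1, 1],
                "block_id": [1, 1],
                "alternative": ["A", "B"],
                "chosen": [1, 0],
                "optout": [0, 0],
                "is_stability_repeat": [0, 0],
                "is_dominance_test": [0, 0],
            }
        )
        for a in catalog:
            df[a.name] = [a.reference_index, a.n_levels - 1]
        data = ChoiceDataset(df, [a.name for a in catalog], [])
        m = build_design_matrix(data, catalog)
        assert np.all(m.values[0] == 0.0)
        assert m.values[1].sum() > 0

    def test_row_permutation_equivariance(self, sim_dataset, catalog):
        data, _ = sim_dataset
        m = build_design_matrix(data, catalog)
        perm = np.random.default_rng(0).permutation(len(data.df))
        shuffled = ChoiceDataset(
            data.df.iloc[perm].reset_index(drop=True),
            data.attribute_names,
            data.covariate_names,
        )
        m2 = build_design_matrix(shuffled, catalog)
        assert np.array_equal(m2.values, m.values[perm])

    def test_invalid_level_names_offending_row(self, catalog):
        df = pd.DataFrame(
            {
                "respondent_id": [1, 1],
                "task_id": [1, 1],
                "block_id": [1, 1],
                "alternative": ["A", "B"],
                "chosen": [1, 0],
                "optout": [0, 0],
                "is_stability_repeat": [0, 0],
                "is_dominance_test": [0, 0],
            }
        )
        for a in catalog:
            df[a.name] = [0, 0]
        df.loc[1, "orr"] = 99
        data = ChoiceDataset(df, [a.name for a in catalog], [])
        with pytest.raises(ValueError, match="row 1.*orr"):
            build_design_matrix(data, catalog)


class TestSimulatedLoglik:
    def test_sigma_zero_equals_closed_form(self, small_design, small_catalog, small_truth):
        data = simulate_small(small_design, small_truth, 80, seed=21)
        m = build_design_matrix(data, small_catalog)
        draws = halton_normal_draws(data.n_respondents, 32, seed=1)
        rng = np.random.default_rng(2)
        beta = rng.normal(scale=0.5, size=m.n_columns)
        theta = np.concatenate([beta, [0.0]])
        got = simulated_loglik(theta, m, data, draws)
        # independent closed form: sum of log-sigmoid over choice rows
        df = data.df.sort_values(["respondent_id", "task_id", "alternative"]).reset_index(drop=True)
        X = build_design_matrix(
            ChoiceDataset(df, data.attribute_names, data.covariate_names), small_catalog
        ).values
        cA = df["chosen"].to_numpy()[0::2]
        d = np.where(cA[:, None] == 1, X[0::2] - X[1::2], X[1::2] - X[0::2])
        expected = float(np.sum(-np.log1p(np.exp(-d @ beta))))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_sigma_zero_matches_statsmodels_logit(self, small_design, small_catalog, small_truth):
        """Cross-check against statsmodels: two-alternative conditional logit
        equals a binary logit on differenced covariates."""
        import statsmodels.api as sm

        data = simulate_small(small_design, small_truth, 80, seed=22)
        m = build_design_matrix(data, small_catalog)
        df = data.df.sort_values(["respondent_id", "task_id", "alternative"]).reset_index(drop=True)
        X = build_design_matrix(
            ChoiceDataset(df, data.attribute_names, data.covariate_names), small_catalog
        ).values
        dAB = X[0::2] - X[1::2]
        yA = df["chosen"].to_numpy()[0::2]
        beta = np.array([0.3, -0.2, 0.5, 0.25])
        sm_ll = float(sm.Logit(yA, dAB).loglike(beta))
        draws = halton_normal_draws(data.n_respondents, 16, seed=3)
        got = simulated_loglik(np.concatenate([beta, [0.0]]), m, data, draws)
        assert got == pytest.approx(sm_ll, abs=1e-10)

    def test_null_equals_n_log_half(self, small_design, small_catalog, small_truth):
        data = simulate_small(small_design, small_truth, 40, seed=23)
        m = build_design_matrix(data, small_catalog)
        draws = halton_normal_draws(data.n_respondents, 8, seed=1)
        got = simulated_loglik(np.zeros(m.n_columns + 1), m, data, draws)
        assert got == pytest.approx(data.n_choice_rows * np.log(0.5), abs=1e-12)

    def test_draw_count_convergence(self, small_design, small_catalog, small_truth):
        data = simulate_small(small_design, small_truth, 200, seed=24)
        m = build_design_matrix(data, small_catalog)
        theta = np.concatenate([small_truth.to_vector(small_catalog), [0.6]])
        ll1 = simulated_loglik(theta, m, data, halton_normal_draws(data.n_respondents, 500, seed=1))
        ll2 = simulated_loglik(theta, m, data, halton_normal_draws(data.n_respondents, 1000, seed=1))
        assert abs(ll2 - ll1) / data.n_respondents < 1e-3

    def test_rejects_nonfinite_parameters(self, small_design, small_catalog, small_truth):
        data = simulate_small(small_design, small_truth, 10, seed=25)
        m = build_design_matrix(data, small_catalog)
        draws = halton_normal_draws(data.n_respondents, 4, seed=1)
        bad = np.full(m.n_columns + 1, np.nan)
        with pytest.raises(ValueError, match="finite"):
            simulated_loglik(bad, m, data, draws)


class TestEstimate:
    def test_optimum_at_least_null(self, small_design, small_catalog, small_truth, fast_settings):
        data = simulate_small(small_design, small_truth, 150, seed=26)
        fit = estimate(data, small_catalog, fast_settings)
        m = build_design_matrix(data, small_catalog)
        draws = halton_normal_draws(
            data.n_respondents, fast_settings.n_draws, seed=fast_settings.seed
        )
        ll_null = simulated_loglik(np.zeros(m.n_columns + 1), m, data, draws)
        assert fit.log_likelihood >= ll_null

    def test_respondent_permutation_invariance(self, small_design, small_catalog, small_truth, fast_settings):
        data = simulate_small(small_design, small_truth, 100, seed=27)
        fit1 = estimate(data, small_catalog, fast_settings)
        rng = np.random.default_rng(3)
        ids = data.df["respondent_id"].unique()
        relabel = dict(zip(ids, rng.permutation(ids)))
        df2 = data.df.copy()
        df2["respondent_id"] = df2["respondent_id"].map(relabel)
        data2 = ChoiceDataset(df2, data.attribute_names, data.covariate_names)
        fit2 = estimate(data2, small_catalog, fast_settings)
        # same respondents, same draws pool up to respondent relabeling
        assert np.allclose(
            fit1.estimates.drop("sigma"), fit2.estimates.drop("sigma"), atol=5e-3
        )

    def test_alternative_relabeling_leaves_partworths(self, small_design, small_catalog, small_truth, fast_settings):
        data = simulate_small(small_design, small_truth, 150, seed=28)
        fit1 = estimate(data, small_catalog, fast_settings)
        df2 = data.df.copy()
        df2["alternative"] = df2["alternative"].map({"A": "B", "B": "A"})
        data2 = ChoiceDataset(df2, data.attribute_names, data.covariate_names)
        fit2 = estimate(data2, small_catalog, fast_settings)
        assert np.allclose(
            fit1.estimates.drop("sigma"), fit2.estimates.drop("sigma"), atol=1e-4
        )
        assert fit1.estimates["sigma"] == pytest.approx(fit2.estimates["sigma"], abs=1e-3)

    def test_numeric_label_shift_changes_nothing(self, small_design, small_catalog, small_truth, fast_settings):
        """The model sees level indicators only, so shifting all numeric
        level values leaves the design matrix and fit untouched."""
        from mmchoice import AttributeSpec

        data = simulate_small(small_design, small_truth, 60, seed=29)
        shifted = [
            AttributeSpec(
                a.name, a.label, a.kind, a.levels, a.reference_index,
                tuple(v + 100.0 for v in a.numeric_values),
            )
            for a in small_catalog
        ]
        m1 = build_design_matrix(data, small_catalog)
        m2 = build_design_matrix(data, shifted)
        assert np.array_equal(m1.values, m2.values)

    def test_sigma_reported_absolute(self, small_design, small_catalog, small_truth, fast_settings):
        data = simulate_small(small_design, small_truth, 100, seed=30)
        fit = estimate(data, small_catalog, fast_settings)
        assert fit.estimates["sigma"] >= 0
        cov = fit.covariance.to_numpy()
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > -1e-10

    def test_validity_tasks_excluded_by_default(self, sim_dataset, catalog, fast_settings):
        data, _ = sim_dataset
        fit = estimate(data, catalog, fast_settings)
        # 12 experimental tasks per respondent enter the likelihood
        assert fit.n_choices == 12 * data.n_respondents

    def test_sigma_zero_not_spuriously_detected(self, small_catalog):
        """Data generated without an error component: the likelihood-ratio
        statistic for the error component stays below the 97.7th percentile
        of its boundary null (a 50:50 mixture of 0 and chi-square-1, so the
        Wald z on sigma itself is not normal here) in at least 90% of
        replicates of 500 respondents x 12 tasks."""
        from mmchoice import generate_design

        design12 = generate_design(small_catalog, 12, 1, seed=3, n_sweeps=10)
        truth = TrueModel(
            part_worths={"orr": {1: 0.5, 2: 1.0}, "os": {1: 0.7}, "crs": {0: -0.6}},
            sigma=0.0,
        )
        hits = 0
        n_reps = 20
        for rep in range(1, n_reps + 1):
            data = simulate_small(design12, truth, 500, seed=600 + rep)
            full = estimate(data, small_catalog, EstimationSettings(n_draws=64, seed=rep))
            null = estimate(
                data, small_catalog, EstimationSettings(n_draws=64, seed=rep, fix_sigma=True)
            )
            lr = 2.0 * (full.log_likelihood - null.log_likelihood)
            assert lr > -1e-6  # nesting
            hits += int(lr < 3.84)
        assert hits / n_reps >= 0.90

    def test_json_round_trip(self, small_design, small_catalog, small_truth, fast_settings, tmp_path):
        data = simulate_small(small_design, small_truth, 60, seed=31)
        fit = estimate(data, small_catalog, fast_settings)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        from mmchoice import ECLFit

        again = ECLFit.from_json(path)
        assert np.allclose(again.estimates, fit.estimates)
        assert np.allclose(again.covariance, fit.covariance)
        assert again.labels == fit.labels
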