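"""Association models: standardized OLS, delta-R2, logistic, contrasts, mixed."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from expofactor.association import (cluster_random_intercept_model, delta_r2,
                                    group_contrast, logistic_model,
                                    standardized_linear_model)


class TestStandardizedLinearModel:
    def test_perfect_fit(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"x": rng.standard_normal(200)})
        res = standardized_linear_model(x["x"] * 3.0 + 2.0, x)
        assert float(res.beta["x"]) == pytest.approx(1.0, abs=1e-10)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_null_model_r2_near_zero(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((1000, 7)),
                         columns=[f"f{i}" for i in range(7)])
        y = rng.standard_normal(1000)
        res = standardized_linear_model(y, X)
        assert res.adj_r2 == pytest.approx(0.0, abs=0.02)

    def test_planted_standardized_beta_recovered(self):
        rng = np.random.default_rng(2)
        n = 10000
        g = rng.standard_normal(n)
        y = 0.285 * g + np.sqrt(1 - 0.285**2) * rng.standard_normal(n)
        res = standardized_linear_model(y, pd.DataFrame({"g": g}))
        assert float(res.beta["g"]) == pytest.approx(0.285, abs=0.02)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="x2"):
            standardized_linear_model(rng.standard_normal(100), X)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_standardization_invariance_under_rescaling(self, scale):
        rng = np.random.default_rng(4)
        n = 300
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = 0.5 * x - 0.3 * z + rng.standard_normal(n)
        ref = standardized_linear_model(y, pd.DataFrame({"x": x, "z": z}))
        scaled = standardized_linear_model(y, pd.DataFrame({"x": x * scale,
                                                            "z": z}))
        assert float(scaled.beta["x"]) == pytest.approx(float(ref.beta["x"]),
                                                        abs=1e-10)


class TestDeltaR2:
    def test_pure_noise_predictors_add_nothing(self):
        rng = np.random.default_rng(5)
        n = 2000
        c = pd.DataFrame({"c": rng.standard_normal(n)})
        y = 0.4 * c["c"] + rng.standard_normal(n)
        noise = pd.DataFrame(rng.standard_normal((n, 3)),
                             columns=["n1", "n2", "n3"])
        res = delta_r2(y, c, noise)
        assert res.delta == pytest.approx(0.0, abs=0.02)

    def test_additivity_by_construction(self):
        rng = np.random.default_rng(6)
        n = 1000
        c = pd.DataFrame({"c": rng.standard_normal(n)})
        p = pd.DataFrame({"p": rng.standard_normal(n)})
        y = 0.3 * c["c"] + 0.5 * p["p"] + rng.standard_normal(n)
        res = delta_r2(y, c, p)
        assert res.adj_r2_base + res.delta == pytest.approx(res.adj_r2_full,
                                                            abs=1e-12)

    def test_empty_base_equals_full_model_r2(self):
        rng = np.random.default_rng(7)
        n = 500
        p = pd.DataFrame({"p": rng.standard_normal(n)})
        y = 0.6 * p["p"] + rng.standard_normal(n)
        res = delta_r2(y, pd.DataFrame(index=p.index), p)
        assert res.adj_r2_base == 0.0
        assert res.delta == pytest.approx(res.adj_r2_full, abs=1e-12)

    def test_overlapping_predictors_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="already in base"):
            delta_r2([1.0, 2, 3, 4], df, df)


class TestLogistic:
    def test_two_by_two_closed_form_odds_ratio(self):
        # counts [[20,10],[10,20]] -> OR = (20*20)/(10*10) = 4
        y = np.repeat([0, 0, 1, 1], [20, 10, 10, 20])
        x = np.repeat([0, 1, 0, 1], [20, 10, 10, 20])
        res = logistic_model(y, pd.DataFrame({"x": x.astype(float)}))
        assert float(res.odds_ratio["x"]) == pytest.approx(4.0, abs=1e-6)

    def test_null_predictor_ci_contains_one(self):
        rng = np.random.default_rng(8)
        n = 5000
        y = rng.integers(0, 2, n)
        x = pd.DataFrame({"x": rng.standard_normal(n)})
        res = logistic_model(y, x)
        assert float(res.ci_low["x"]) < 1.0 < float(res.ci_high["x"])

    def test_planted_odds_ratio_recovered(self):
        rng = np.random.default_rng(9)
        n = 10000
        g = rng.standard_normal(n)
        from scipy.special import expit

        p = expit(-1.6 + np.log(1.4) * g)
        y = (rng.random(n) < p).astype(int)
        res = logistic_model(y, pd.DataFrame({"g": g}))
        assert 1.3 <= float(res.odds_ratio["g"]) <= 1.5

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            logistic_model(np.zeros(50),
                           pd.DataFrame({"x": np.random.default_rng(0)
                                         .standard_normal(50)}))

    def test_separation_detected(self):
        x = np.concatenate([np.full(30, -2.0), np.full(30, 2.0)])
        y = (x > 0).astype(int)
        with pytest.raises((ValueError, np.linalg.LinAlgError, Exception)):
            logistic_model(y, pd.DataFrame({"x": x}))


class TestGroupContrast:
    def test_identical_groups_null_result(self):
        x = np.tile([1.0, 2.0, 3.0, 4.0], 10)
        grp = np.repeat([0, 1], 20)
        res = group_contrast(np.concatenate([x[:20], x[:20]]), grp)
        assert res.cohens_d == pytest.approx(0.0, abs=1e-12)
        assert res.p_adjusted == 1.0

    def test_unit_separation_gives_d_of_one(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal(20000) + 1.0
        b = rng.standard_normal(20000)
        res = group_contrast(np.concatenate([b, a]),
                             np.repeat([0, 1], 20000))
        assert res.cohens_d == pytest.approx(1.0, abs=0.03)

    def test_planted_large_contrast_recovered(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal(2000) + 1.40
        b = rng.standard_normal(2000)
        res = group_contrast(np.concatenate([b, a]), np.repeat([0, 1], 2000))
        assert res.cohens_d == pytest.approx(1.40, abs=0.08)

    def test_bonferroni_adjustment_caps_at_one(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(100)
        res = group_contrast(x, np.repeat([0, 1], 50), m_comparisons=7)
        assert res.p_adjusted == min(1.0, 7 * res.p_raw)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two levels"):
            group_contrast(np.arange(10.0), np.zeros(10))


class TestMixedModel:
    def test_zero_cluster_variance_collapses_to_ols(self):
        rng = np.random.default_rng(13)
        n = 800
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        site = np.repeat(np.arange(4), n // 4)
        family = np.arange(n) // 2
        X = pd.DataFrame({"x": x})
        res = cluster_random_intercept_model(y, X, site, family)
        ols = standardized_linear_model(y, X)
        # raw-scale coefficient ~ standardized here because sd(x)~sd(y-ish)~1
        assert res.var_site == pytest.approx(0.0, abs=0.05)
        assert res.var_family == pytest.approx(0.0, abs=0.10)
        assert float(res.fixed_effects["x"]) == pytest.approx(0.5, abs=0.1)

    def test_planted_family_variance_recovered(self):
        rng = np.random.default_rng(14)
        n_fam = 2000
        fam_effect = rng.normal(scale=np.sqrt(0.2), size=n_fam)
        family = np.repeat(np.arange(n_fam), 2)
        site = family % 5
        x = rng.standard_normal(2 * n_fam)
        y = 0.4 * x + fam_effect[family] + rng.normal(scale=np.sqrt(0.8),
                                                      size=2 * n_fam)
        res = cluster_random_intercept_model(y, pd.DataFrame({"x": x}),
                                             site, family)
        assert res.var_family == pytest.approx(0.2, abs=0.05)

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(15)
        n = 400
        x = rng.standard_normal(n)
        y = 0.3 * x + rng.standard_normal(n)
        site = np.repeat(np.arange(4), n // 4)
        family = np.arange(n) // 2
        X = pd.DataFrame({"x": x})
        r1 = cluster_random_intercept_model(y, X, site, family)
        r2 = cluster_random_intercept_model(y, X, site, family)
        assert float(r1.fixed_effects["x"]) == float(r2.fixed_effects["x"])
        assert r1.var_family == r2.var_family
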