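"""Conditional-logit likelihood, estimation, sandwich covariance, model comparison."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from fact8d import (
    DIMENSIONS,
    FitError,
    LevelGroup,
    ModelSpec,
    TruePreferences,
    WeightVector,
    build_regressors,
    fit,
    generate_design,
    loglik,
    lr_test,
    simulate_choices,
    simulate_respondents,
)
from fact8d.clogit import FitResult, information_criteria, pair_dataset
from fact8d.datasets import published_parameter_map


def one_alt_frame(levels: dict[str, int], duration: float) -> pd.DataFrame:
    row = {d: 1 for d in DIMENSIONS} | levels
    row["duration"] = duration
    return pd.DataFrame([row])


class TestRegressors:
    def test_reference_state_uses_only_duration(self, full_spec):
        X, names = build_regressors(one_alt_frame({}, 5), full_spec)
        assert names[0] == "duration"
        assert X[0, 0] == 5
        assert (X[0, 1:] == 0).all()

    def test_level_dummy_is_scaled_by_duration(self, full_spec):
        X, names = build_regressors(one_alt_frame({"pain": 5}, 10), full_spec)
        assert X[0, names.index("pain:L5")] == 10
        assert X[0, 0] == 10

    def test_merged_levels_share_a_column(self):
        groups = {d: [LevelGroup((l,)) for l in (2, 3, 4, 5)] for d in DIMENSIONS}
        groups["work"] = (LevelGroup((2,)), LevelGroup((3, 4)), LevelGroup((5,)))
        spec = ModelSpec(groups)
        col = spec.parameter_names.index("work:L3-4")
        X3, _ = build_regressors(one_alt_frame({"work": 3}, 5), spec)
        X4, _ = build_regressors(one_alt_frame({"work": 4}, 5), spec)
        assert X3[0, col] == 5 and X4[0, col] == 5

    def test_reference_merged_levels_contribute_nothing(self):
        groups = {d: tuple(LevelGroup((l,)) for l in (2, 3, 4, 5)) for d in DIMENSIONS}
        groups["pain"] = (LevelGroup((2,), to_reference=True),
                          LevelGroup((3,)), LevelGroup((4,)), LevelGroup((5,)))
        spec = ModelSpec(groups)
        X, names = build_regressors(one_alt_frame({"pain": 2}, 5), spec)
        assert "pain:L2" not in names
        assert (X[0, 1:] == 0).all()


@pytest.fixture(scope="module")
def tiny():
    """One respondent answering one 16-set block."""
    design = generate_design(1, seed=201)
    profiles = pd.DataFrame({"respondent": [1]})
    prefs = TruePreferences.from_published("model3")
    return simulate_choices(design, prefs, profiles, seed=203,
                            partial_completion_rate=0.0)


class TestLogLikelihood:
    def test_zero_parameters_give_m_log_half(self, tiny, full_spec):
        ll, _ = loglik(np.zeros(full_spec.n_parameters), tiny, full_spec)
        assert ll == pytest.approx(16 * np.log(0.5), abs=1e-12)

    def test_gradient_matches_central_differences(self, sim, full_spec):
        rng = np.random.default_rng(7)
        params = rng.normal(scale=0.05, size=full_spec.n_parameters)
        ch = sim["choices"]
        _, grad = loglik(params, ch, full_spec)
        h = 1e-6
        for j in rng.choice(full_spec.n_parameters, size=8, replace=False):
            e = np.zeros_like(params)
            e[j] = h
            lp, _ = loglik(params + e, ch, full_spec)
            lm, _ = loglik(params - e, ch, full_spec)
            fd = (lp - lm) / (2 * h)
            assert grad[j] == pytest.approx(fd, abs=1e-4 * max(1, abs(fd)))

    def test_doubling_weights_doubles_ll_and_gradient(self, sim, full_spec):
        ch = sim["choices"]
        resp = sim["profiles"]["respondent"].to_numpy()
        w1 = WeightVector(respondent=resp, weights=np.ones(len(resp)))
        w2 = WeightVector(respondent=resp, weights=2 * np.ones(len(resp)))
        params = np.full(full_spec.n_parameters, 0.01)
        ll1, g1 = loglik(params, ch, full_spec, w1)
        ll2, g2 = loglik(params, ch, full_spec, w2)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)
        np.testing.assert_allclose(g2, 2 * g1, rtol=1e-12)

    def test_ll_ignores_attributes_shared_by_both_alternatives(self, full_spec):
        """Only within-pair differences matter: when two alternatives share a
        duration, changing a tied dimension to another tied level leaves the
        likelihood unchanged (the shared duration-scaled dummy cancels)."""
        design = generate_design(8, seed=210, require_duration_differs=False)
        profiles = pd.DataFrame({"respondent": np.arange(120)})
        prefs = TruePreferences.from_published("model3")
        ch = simulate_choices(design, prefs, profiles, seed=211,
                              partial_completion_rate=0.0, randomize_ab=False)
        params = np.full(full_spec.n_parameters, 0.02)
        ll0, _ = loglik(params, ch, full_spec)
        ch = ch.sort_values(["respondent", "set", "alt"]).reset_index(drop=True)
        a, b = ch.iloc[0::2], ch.iloc[1::2]
        shared = ((a["worry"].to_numpy() == b["worry"].to_numpy())
                  & (a["duration"].to_numpy() == b["duration"].to_numpy()))
        assert shared.any()
        idx_a, idx_b = a.index[shared], b.index[shared]
        ch.loc[idx_a, "worry"] = 1 + (ch.loc[idx_a, "worry"] % 5)
        ch.loc[idx_b, "worry"] = ch.loc[idx_a, "worry"].to_numpy()
        ll1, _ = loglik(params, ch, full_spec)
        assert ll1 == pytest.approx(ll0, abs=1e-9)


class TestFit:
    def test_matches_statsmodels_logit_on_differences(self, sim, full_spec):
        """Independent oracle: paired clogit = binary logit on differenced X."""
        result = fit(sim["choices"], full_spec)
        data = pair_dataset(sim["choices"], full_spec)
        oracle = sm.Logit(data.y, data.dx).fit(disp=0, method="newton", tol=1e-10)
        np.testing.assert_allclose(result.params, oracle.params, atol=1e-5)
        assert result.loglik == pytest.approx(oracle.llf, abs=1e-6)

    def test_cluster_sandwich_matches_statsmodels(self, sim, full_spec):
        result = fit(sim["choices"], full_spec)
        data = pair_dataset(sim["choices"], full_spec)
        oracle = sm.Logit(data.y, data.dx).fit(
            disp=0, cov_type="cluster",
            cov_kwds={"groups": data.clusters, "use_correction": False})
        np.testing.assert_allclose(result.cov, np.asarray(oracle.cov_params()),
                                   rtol=5e-4, atol=1e-9)

    def test_singleton_clusters_reduce_to_hc0(self, sim, full_spec):
        # keep one (varying) set per respondent -> every cluster has one
        # observation while the pooled sets still identify all parameters
        ch = sim["choices"]
        keep = ch["set"] == (ch["respondent"] % 16)
        ch = ch[keep]
        result = fit(ch, full_spec)
        data = pair_dataset(ch, full_spec)
        assert data.n_clusters == len(data.y)
        oracle = sm.Logit(data.y, data.dx).fit(disp=0, cov_type="HC0")
        np.testing.assert_allclose(result.cov, np.asarray(oracle.cov_params()),
                                   rtol=5e-4, atol=1e-9)

    def test_unweighted_equals_unit_weighted_bit_for_bit(self, sim, full_spec):
        resp = sim["profiles"]["respondent"].to_numpy()
        unit = WeightVector(respondent=resp, weights=np.ones(len(resp)))
        a = fit(sim["choices"], full_spec)
        b = fit(sim["choices"], full_spec, unit)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.params, b.params)

    def test_estimates_invariant_to_ab_relabeling(self, sim, full_spec):
        ch = sim["choices"].copy()
        flipped = ch.copy()
        flipped["alt"] = flipped["alt"].map({"A": "B", "B": "A"})
        a = fit(ch, full_spec)
        b = fit(flipped, full_spec)
        np.testing.assert_allclose(a.params, b.params, atol=1e-8)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)

    def test_recovery_within_three_robust_ses(self, sim, full_spec):
        result = fit(sim["choices"], full_spec)
        truth = published_parameter_map("model3")
        z = [(result.coefficients()[k] - truth[k]) / se
             for k, se in zip(result.names, result.se)]
        assert max(abs(v) for v in z) < 3

    def test_consistency_error_shrinks_with_n(self, margins):
        prefs = TruePreferences.from_published("model3")
        truth_vec = np.array(list(published_parameter_map("model3").values()))
        rmse = []
        for i, n in enumerate([200, 800, 3200]):
            design = generate_design(12, seed=300 + i)
            profiles = simulate_respondents(margins, n, seed=310 + i)
            ch = simulate_choices(design, prefs, profiles, seed=320 + i,
                                  partial_completion_rate=0.0)
            res = fit(ch)
            rmse.append(float(np.sqrt(np.mean((res.params - truth_vec) ** 2))))
        assert rmse[0] > rmse[1] > rmse[2]

    def test_degenerate_dataset_rejected(self, tiny, full_spec):
        ch = tiny.copy()
        ch["chosen"] = np.where(ch["alt"] == "A", 1, 0)
        with pytest.raises(FitError, match="degenerate"):
            fit(ch, full_spec)

    def test_underidentified_design_reports_singular_hessian(self, margins):
        # one 16-set block cannot identify 33 parameters
        design = generate_design(1, seed=400)
        profiles = simulate_respondents(margins, 200, seed=401)
        prefs = TruePreferences.from_published("model3")
        ch = simulate_choices(design, prefs, profiles, seed=402)
        with pytest.raises(FitError, match="[Ss]ingular"):
            fit(ch)


class TestInformationCriteria:
    def test_identities_hold_on_fits(self, sim, full_spec):
        r = fit(sim["choices"], full_spec)
        assert r.aic == pytest.approx(2 * r.n_parameters - 2 * r.loglik)
        assert r.bic == pytest.approx(r.n_parameters * np.log(r.n_obs) - 2 * r.loglik)
        assert r.n_obs == len(sim["choices"]) // 2

    def test_published_unweighted_ll_reproduces_published_aic(self):
        aic, _ = information_criteria(-15009.31, 33, n_obs=25000)
        assert aic == pytest.approx(30084.62, abs=0.005)


def stub_fit(ll: float, k: int, fingerprint: str = "f") -> FitResult:
    spec = ModelSpec.full()
    return FitResult(spec=spec, params=np.zeros(spec.n_parameters),
                     names=spec.parameter_names,
                     cov=np.eye(spec.n_parameters), loglik=ll, n_parameters=k,
                     n_obs=100, n_clusters=10, aic=np.nan, bic=np.nan,
                     converged=True, n_iter=1, grad_norm=0.0, weighted=False,
                     fingerprint=fingerprint)


class TestLikelihoodRatio:
    def test_identical_fits_give_zero_statistic(self, sim, full_spec):
        r = fit(sim["choices"], full_spec)
        nested = dataclasses.replace(r, n_parameters=r.n_parameters - 1)
        stat, df, p = lr_test(nested, r)
        assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_chi_square_survival_value(self):
        stat, df, p = lr_test(stub_fit(-100.0, 31), stub_fit(-98.0, 33))
        assert stat == pytest.approx(4.0)
        assert df == 2
        assert p == pytest.approx(0.1353, abs=5e-5)

    def test_mismatched_data_fingerprints_rejected(self):
        with pytest.raises(ValueError, match="different datasets"):
            lr_test(stub_fit(-100.0, 31, "x"), stub_fit(-98.0, 33, "y"))

    def test_nested_must_be_smaller(self):
        with pytest.raises(ValueError, match="fewer parameters"):
            lr_test(stub_fit(-100.0, 33), stub_fit(-98.0, 33))
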