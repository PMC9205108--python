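"""Violation detection, monotonicity constraining, and MRS anchoring."""

import numpy as np
import pytest

from fact8d import (
    DIMENSIONS,
    FitError,
    ModelSpec,
    compare_fits,
    constrain,
    derive_value_set,
    detect_violations,
    fit,
    pits,
    score_state,
)
from fact8d.clogit import FitResult
from fact8d.cohort import TruePreferences, simulate_choices, simulate_respondents
from fact8d.datasets import published_model_spec, published_parameter_map
from fact8d.descriptive import WORST_STATE, enumerate_utilities
from fact8d.design import generate_design


def fit_from_params(param_map: dict[str, float], spec: ModelSpec) -> FitResult:
    """Wrap a plain coefficient table as a FitResult for derivation tests."""
    params = np.array([param_map[name] for name in spec.parameter_names])
    k = spec.n_parameters
    return FitResult(spec=spec, params=params, names=spec.parameter_names,
                     cov=np.zeros((k, k)), loglik=np.nan, n_parameters=k,
                     n_obs=0, n_clusters=0, aic=np.nan, bic=np.nan,
                     converged=True, n_iter=0, grad_norm=0.0, weighted=True,
                     fingerprint="published")


class TestDetection:
    def test_published_raked_model_violations(self, full_spec):
        """The published unconstrained raked fit shows the known inconsistencies."""
        coefs = published_parameter_map("model2")
        found = {(v.dimension, v.kind, v.levels) for v in
                 detect_violations(coefs, full_spec)}
        assert ("sleep", "positive", (2,)) in found       # +0.024
        assert ("sleep", "positive", (3,)) in found       # +0.036
        assert ("support", "reversed", (3,)) in found     # +0.009 vs -0.034
        assert ("worry", "reversed", (3,)) in found       # -0.021 vs -0.046
        assert ("pain", "positive", (2,)) in found        # +0.014

    def test_monotone_profile_is_clean(self, full_spec):
        coefs = {"duration": 0.3}
        for d in DIMENSIONS:
            for i, l in enumerate((2, 3, 4, 5)):
                coefs[f"{d}:L{l}"] = -0.02 * (i + 1)
        assert detect_violations(coefs, full_spec) == []

    def test_reversed_adjacent_pair_flagged_once(self, full_spec):
        coefs = {"duration": 0.3}
        for d in DIMENSIONS:
            for i, l in enumerate((2, 3, 4, 5)):
                coefs[f"{d}:L{l}"] = -0.02 * (i + 1)
        coefs["nausea:L4"] = -0.05
        coefs["nausea:L5"] = -0.03
        records = detect_violations(coefs, full_spec)
        assert len(records) == 1
        r = records[0]
        assert (r.dimension, r.kind, r.levels, r.milder_levels) == (
            "nausea", "reversed", (5,), (4,))

    def test_ordering_mildest_first_canonical_dimensions(self, full_spec):
        records = detect_violations(published_parameter_map("model2"), full_spec)
        dims = [r.dimension for r in records]
        assert dims == sorted(dims, key=DIMENSIONS.index)


class TestConstrain:
    def test_published_merge_pattern_has_23_parameters(self):
        assert published_model_spec().n_parameters == 23
        assert ModelSpec.full().n_parameters == 33

    def test_forced_published_pattern_on_simulated_data(self, sim):
        spec, result, history = constrain(
            sim["choices"], forced_spec=published_model_spec())
        assert result.n_parameters == 23
        assert spec is published_model_spec() or spec.parameter_names == \
            published_model_spec().parameter_names

    def test_loop_removes_all_violations(self, sim):
        spec, result, history = constrain(sim["choices"])
        assert detect_violations(result) == []
        assert result.n_parameters <= 33

    def test_idempotent_once_consistent(self, sim):
        spec, result, _ = constrain(sim["choices"])
        spec2, result2, history2 = constrain(sim["choices"], spec)
        assert spec2.parameter_names == spec.parameter_names
        assert history2 == []
        assert result2.loglik == pytest.approx(result.loglik, abs=1e-9)

    def test_constrained_ll_never_exceeds_unconstrained(self, sim, full_spec):
        unconstrained = fit(sim["choices"], full_spec)
        _, constrained, _ = constrain(sim["choices"], full_spec)
        assert constrained.loglik <= unconstrained.loglik + 1e-9
        assert constrained.n_parameters <= unconstrained.n_parameters


class TestDerivation:
    def test_published_constrained_coefficients_reproduce_published_decrements(self):
        spec = published_model_spec()
        result = fit_from_params(published_parameter_map("model3", spec), spec)
        vs = derive_value_set(result)
        # rows of the published table consistent with -beta/alpha at 3 dp
        assert vs.decrement("nausea", 5) == pytest.approx(0.298, abs=5e-4)
        assert vs.decrement("fatigue", 5) == pytest.approx(0.164, abs=5e-4)
        assert vs.decrement("sleep", 4) == pytest.approx(0.077, abs=5e-4)
        assert vs.decrement("sleep", 5) == vs.decrement("sleep", 4)
        assert vs.decrement("pain", 2) == 0.0                  # merged to reference
        assert vs.monotone

    def test_zero_betas_give_unit_utilities(self, full_spec):
        coefs = {name: 0.0 for name in full_spec.parameter_names}
        coefs["duration"] = 0.3
        vs = derive_value_set(fit_from_params(coefs, full_spec))
        assert pits(vs) == 1.0

    def test_nonpositive_alpha_rejected(self, full_spec):
        coefs = {name: -0.01 for name in full_spec.parameter_names}
        coefs["duration"] = -0.1
        with pytest.raises(FitError, match="alpha"):
            derive_value_set(fit_from_params(coefs, full_spec))

    def test_non_monotone_fit_rejected(self, full_spec):
        coefs = {name: -0.01 for name in full_spec.parameter_names}
        coefs["duration"] = 0.3
        coefs["pain:L2"] = 0.05
        with pytest.raises(FitError, match="non-monotone"):
            derive_value_set(fit_from_params(coefs, full_spec))

    def test_anchoring_identity_end_to_end(self, sim):
        """Worst-state utility equals PITS; all state utilities lie in [PITS, 1]."""
        _, result, _ = constrain(sim["choices"])
        vs = derive_value_set(result)
        assert score_state(WORST_STATE, vs) == pytest.approx(pits(vs), abs=1e-12)
        u = enumerate_utilities(vs)
        assert u.min() == pytest.approx(pits(vs)) and u.max() == 1.0


class TestComparison:
    def test_identical_fits_have_zero_differences(self, sim, full_spec):
        r = fit(sim["choices"], full_spec)
        cmp = compare_fits(r, r)
        assert cmp.max_abs_difference == 0.0
        assert cmp.all_signs_agree

    def test_spec_mismatch_rejected(self, sim, full_spec):
        r1 = fit(sim["choices"], full_spec)
        _, r3, _ = constrain(sim["choices"], forced_spec=published_model_spec())
        with pytest.raises(ValueError, match="different spec"):
            compare_fits(r1, r3)

    def test_two_seeds_agree_in_sign_on_well_identified_effects(self, sim, margins):
        prefs = TruePreferences.from_published("model3")
        design = generate_design(12, seed=501)
        profiles = simulate_respondents(margins, 400, seed=502)
        other = simulate_choices(design, prefs, profiles, seed=503,
                                 partial_completion_rate=0.0)
        ra = fit(sim["choices"])
        rb = fit(other)
        cmp = compare_fits(ra, rb)
        truth = published_parameter_map("model3")
        strong = [n for n, v in truth.items() if abs(v) >= 0.05]
        sign_a = np.sign([ra.coefficients()[n] for n in strong])
        sign_b = np.sign([rb.coefficients()[n] for n in strong])
        np.testing.assert_array_equal(sign_a, sign_b)
        assert cmp.max_abs_difference > 0
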