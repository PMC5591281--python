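"""Closed-form choice probabilities against algebra and a Monte-Carlo oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from facecue import (
    Condition,
    ModelParams,
    Stimulus,
    effective_form,
    response_probability,
    simulate_decision_mc,
)

MODELS = ("OPT", "BEST", "AVG", "OPT_IB")


def phi_quad(z: float) -> float:
    """Standard normal CDF by numerical integration of the density
    (independent of scipy.special.ndtr used by the implementation)."""
    val, _ = quad(lambda t: np.exp(-t * t / 2.0) / np.sqrt(2.0 * np.pi), -12.0, z)
    return val


@pytest.mark.parametrize(
    "s_f, c, expected",
    [(0.5, 0.0, 0.5), (0.6, 0.35, 0.6), (0.0, 0.35, 0.21), (1.0, 0.0, 1.0)],
)
def test_effective_form(s_f, c, expected):
    assert effective_form(s_f, c) == pytest.approx(expected, abs=1e-12)


def test_opt_combined_matches_integration_oracle():
    """sigma_m = sigma_f = 0.2, s_m = 0.8, s_f = 0.6, b = 0.5, old off:
    the fused z-score is (25*0.3 + 25*0.1)/sqrt(50) = sqrt(2)."""
    params = ModelParams(0.2, 0.2, 0.2, 0.5, 0.0)
    stim = Stimulus(Condition.COMB, 0.8, 0.6, 0.0)
    p = response_probability("OPT", stim, params)
    assert p == pytest.approx(phi_quad(np.sqrt(2.0)), abs=1e-9)
    assert p == pytest.approx(0.9213504, abs=1e-6)


def test_best_combined_uses_better_cue():
    """Form is the better cue (0.17 < 0.28); z = (0.67-0.5)/0.17 = 1."""
    params = ModelParams(0.28, 0.17, 0.17, 0.5, 0.0)
    stim = Stimulus(Condition.COMB_PLUS, 0.52, 0.67, 0.0)
    p = response_probability("BEST", stim, params)
    assert p == pytest.approx(phi_quad(1.0), abs=1e-9)
    assert p == pytest.approx(0.8413447, abs=1e-6)


def test_best_tie_resolves_to_form():
    params = ModelParams(0.2, 0.2, 0.2, 0.5, 0.0)
    stim = Stimulus(Condition.COMB_PLUS, 0.5 - 0.075, 0.5 + 0.075, 0.0)
    p = response_probability("BEST", stim, params)
    assert p == pytest.approx(phi_quad(0.075 / 0.2), abs=1e-9)


def test_avg_symmetry_at_boundary():
    params = ModelParams(0.3, 0.15, 0.2, 0.5, 0.0)
    stim = Stimulus(Condition.COMB_PLUS, 0.4, 0.6, 0.0)
    assert response_probability("AVG", stim, params) == pytest.approx(0.5, abs=1e-12)


@pytest.mark.parametrize("model", MODELS)
@pytest.mark.parametrize("condition", list(Condition))
def test_full_lapse_means_guessing(model, condition, median_params):
    stim = Stimulus(condition, 0.9, 0.9, 0.0)
    params = ModelParams(
        median_params.sigma_m, median_params.sigma_f, median_params.sigma_f_old,
        median_params.b, 1.0,
    )
    assert response_probability(model, stim, params) == pytest.approx(0.5, abs=1e-12)


@pytest.mark.parametrize("model", MODELS)
def test_boundary_stimulus_is_ambiguous(model):
    stim = Stimulus(Condition.COMB, 0.51, 0.51, 0.0)
    params = ModelParams(0.3, 0.2, 0.25, 0.51, 0.1)
    assert response_probability(model, stim, params) == pytest.approx(0.5, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    s_m=st.floats(0, 1), s_f=st.floats(0, 1),
    sigma=st.floats(0.05, 1.0), b=st.floats(-0.2, 1.2),
    lam=st.floats(0, 0.9),
)
def test_opt_equals_avg_when_equal_precisions_old_off(s_m, s_f, sigma, b, lam):
    """With sigma_m = sigma_f and old off, reliability weighting degenerates
    to the unweighted average: the two rules are algebraically identical."""
    params = ModelParams(sigma, sigma, 2 * sigma, b, lam)
    stim = Stimulus(Condition.COMB_PLUS, s_m, s_f, 0.0)
    assert response_probability("OPT", stim, params) == pytest.approx(
        response_probability("AVG", stim, params), abs=1e-12
    )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    model=st.sampled_from(MODELS),
    condition=st.sampled_from([c.value for c in Condition]),
    s_m=st.floats(0, 0.98), s_f=st.floats(0, 0.98),
    c=st.sampled_from([0.0, 0.35]),
    lam=st.floats(0, 0.98),
)
def test_monotone_in_both_cues_and_lapse_bounded(model, condition, s_m, s_f, c, lam):
    params = ModelParams(0.3, 0.18, 0.25, 0.45, lam)
    stim = Stimulus(condition, s_m, s_f, c)
    p0 = response_probability(model, stim, params)
    assert params.lapse / 2 - 1e-12 <= p0 <= 1 - params.lapse / 2 + 1e-12
    eps = 0.02
    up_m = Stimulus(condition, min(s_m + eps, 1.0), s_f, c)
    up_f = Stimulus(condition, s_m, min(s_f + eps, 1.0), c)
    assert response_probability(model, up_m, params) >= p0 - 1e-12
    assert response_probability(model, up_f, params) >= p0 - 1e-12


def test_opt_single_cue_limits(median_params):
    """Vanishing precision of one cue collapses the fusion rule onto the
    other cue's single-cue curve."""
    p = median_params
    stim = Stimulus(Condition.COMB, 0.7, 0.7, 0.0)
    wide_form = ModelParams(p.sigma_m, 1e6, 1e6, p.b, p.lapse)
    motion_only = response_probability(
        "OPT", Stimulus(Condition.MOTION, 0.7, 0.5, 0.0), p
    )
    assert response_probability("OPT", stim, wide_form) == pytest.approx(motion_only, abs=1e-6)
    wide_motion = ModelParams(1e6, p.sigma_f, p.sigma_f_old, p.b, p.lapse)
    form_only = response_probability("OPT", Stimulus(Condition.FORM, 0.5, 0.7, 0.0), p)
    assert response_probability("OPT", stim, wide_motion) == pytest.approx(form_only, abs=1e-6)


def test_old_on_form_single_cue_slope(median_params):
    """Old-on FORM trials: OPT/BEST/AVG invert the compression, giving slope
    (1-c)/sigma_f_old; the incorrect-beliefs variant uses the raw form mean."""
    stim = Stimulus(Condition.FORM, 0.5, 0.9, 0.35)
    p = median_params
    z_inverted = (1 - 0.35) * (0.9 - p.b) / p.sigma_f_old
    z_raw = (0.6 * 0.35 + 0.65 * 0.9 - p.b) / p.sigma_f_old
    lam = p.lapse
    for model in ("OPT", "BEST", "AVG"):
        assert response_probability(model, stim, p) == pytest.approx(
            lam / 2 + (1 - lam) * phi_quad(z_inverted), abs=1e-9
        )
    assert response_probability("OPT_IB", stim, p) == pytest.approx(
        lam / 2 + (1 - lam) * phi_quad(z_raw), abs=1e-9
    )


@pytest.mark.parametrize("model", MODELS)
@pytest.mark.parametrize("c", [0.0, 0.35])
def test_mc_oracle_agrees_with_closed_form(model, c, median_params):
    """The raw decision-rule simulator is the independent oracle for the
    closed forms (spot check; the full grid runs in the acceptance suite)."""
    stim = Stimulus(Condition.COMB_MINUS, 0.575, 0.425, c)
    est = simulate_decision_mc(model, stim, median_params, n_samples=50_000, seed=7)
    p = response_probability(model, stim, median_params)
    assert abs(est.p_hat - p) <= 3 * est.se + 1e-12


def test_mc_full_lapse_is_chance(median_params):
    params = ModelParams(0.28, 0.17, 0.24, 0.51, 1.0)
    stim = Stimulus(Condition.COMB, 0.9, 0.9, 0.0)
    est = simulate_decision_mc("OPT", stim, params, n_samples=50_000, seed=8)
    assert abs(est.p_hat - 0.5) <= 3 * est.se


def test_mc_infinite_precision_is_step():
    params = ModelParams(1e-4, 1e-4, 1e-4, 0.5, 0.0)
    hi = Stimulus(Condition.COMB, 0.6, 0.6, 0.0)
    lo = Stimulus(Condition.COMB, 0.4, 0.4, 0.0)
    assert simulate_decision_mc("OPT", hi, params, 1000, seed=9).p_hat == 1.0
    assert simulate_decision_mc("OPT", lo, params, 1000, seed=9).p_hat == 0.0


def test_invalid_inputs_raise(median_params):
    stim = Stimulus(Condition.COMB, 0.5, 0.5, 0.0)
    with pytest.raises(ValueError):
        response_probability("OPT", stim, ModelParams(-0.1, 0.2, 0.2, 0.5, 0.0))
    with pytest.raises(ValueError):
        response_probability("NOT_A_MODEL", stim, median_params)
    with pytest.raises(ValueError):
        response_probability("OPT", stim, median_params, single_cue_rule="bogus")
    with pytest.raises(ValueError):
        simulate_decision_mc("OPT", stim, median_params, n_samples=10)
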