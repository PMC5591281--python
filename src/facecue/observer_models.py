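"""Observer models of 2AFC identity choice from facial form and motion.

Generative model
----------------
On each trial the observer draws conditionally independent noisy measurements

    x_m ~ N(s_m, sigma_m^2)
    x_f ~ N(0.6 c + (1 - c) s_f, sigma_f(c)^2)

where ``c`` is the old level (0 or 0.35), 0.6 is the form position of the
aged average face, and the form noise SD may differ between old-off
(``sigma_f``) and old-on (``sigma_f_old``) trials.  With precisions
J = 1/sigma^2, the four decision rules for reporting "Susan" are

* ``OPT``    — reliability-weighted fusion with correct inversion of the
  old compression:
  [J_m x_m + (1-c) J_f (x_f - 0.6c)] / [J_m + (1-c)^2 J_f] > b
* ``BEST``   — use only the cue with the smaller SD: x_m > b or x_f > b
* ``AVG``    — unweighted average: (x_m + x_f)/2 > b
* ``OPT_IB`` — optimal fusion but with the incorrect belief that old faces
  are pure aged versions of each identity, i.e. the old compression is not
  inverted: (J_m x_m + J_f x_f) / (J_m + J_f) > b

Each rule yields a closed-form choice probability through the standard
normal CDF, mixed with a symmetric lapse: p = λ/2 + (1-λ) Φ(z).  A
Monte-Carlo simulator of the raw decision rules serves as an independent
oracle for the closed forms.

In single-cue blocks the observer is explicitly cued which feature to use;
by default all models then base their decision on the instructed cue only
(``single_cue_rule="relevant_cue_only"``), with the full fusion rule
available for sensitivity analysis.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import ndtr

from .design import OLD_AVERAGE_FORM, Condition, Stimulus

__all__ = [
    "ModelId",
    "ModelParams",
    "PAPER_MEDIAN_PARAMS",
    "effective_form",
    "response_probability",
    "response_probabilities",
    "simulate_decision_mc",
]


class ModelId(str, enum.Enum):
    OPT = "OPT"          # reliability-weighted optimal fusion
    BEST = "BEST"        # best (most reliable) single cue
    AVG = "AVG"          # unweighted simple average
    OPT_IB = "OPT_IB"    # optimal fusion with incorrect beliefs about old faces


@dataclass(frozen=True)
class ModelParams:
    """Per-subject observer parameters.

    sigma_m      motion measurement noise SD (morph units, > 0)
    sigma_f      form noise SD, old off (> 0)
    sigma_f_old  form noise SD, old on (> 0)
    b            category boundary on the morph axis
    lapse        probability of a stimulus-independent random guess, in [0, 1]
    """

    sigma_m: float
    sigma_f: float
    sigma_f_old: float
    b: float
    lapse: float

    def validate(self) -> None:
        for name in ("sigma_m", "sigma_f", "sigma_f_old"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name}={getattr(self, name)} must be > 0")
        if not (0.0 <= self.lapse <= 1.0):
            raise ValueError(f"lapse={self.lapse} must lie in [0,1]")
        if not math.isfinite(self.b):
            raise ValueError("b must be finite")

    def sigma_f_for(self, c):
        """Condition-appropriate form SD: sigma_f_old on old-on trials."""
        return np.where(np.asarray(c) > 0, self.sigma_f_old, self.sigma_f)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(d[k]) for k in ("sigma_m", "sigma_f", "sigma_f_old", "b", "lapse")})

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls.from_dict(json.loads(text))


#: Group-median maximum-likelihood estimates from the joint fit of the
#: optimal model to the 22 human subjects.
PAPER_MEDIAN_PARAMS = ModelParams(
    sigma_m=0.28, sigma_f=0.17, sigma_f_old=0.24, b=0.51, lapse=0.04
)


def effective_form(s_f, c):
    """Physical form position after the old morph: 0.6 c + (1 - c) s_f."""
    return OLD_AVERAGE_FORM * np.asarray(c) + (1.0 - np.asarray(c)) * np.asarray(s_f)


def _combined_z(model: ModelId, s_m, s_f, c, p: ModelParams):
    """Standardized decision variable for combined-cue trials."""
    sf_c = p.sigma_f_for(c)
    if model is ModelId.OPT:
        j_m = 1.0 / p.sigma_m**2
        j_f = (1.0 - c) ** 2 / sf_c**2
        return (j_m * (s_m - p.b) + j_f * (s_f - p.b)) / np.sqrt(j_m + j_f)
    if model is ModelId.AVG:
        return (s_m + effective_form(s_f, c) - 2.0 * p.b) / np.sqrt(p.sigma_m**2 + sf_c**2)
    if model is ModelId.BEST:
        # tie sigma_m == sigma_f(c) resolves to form (measure zero under fitting)
        motion_better = p.sigma_m < sf_c
        return np.where(
            motion_better,
            (s_m - p.b) / p.sigma_m,
            (effective_form(s_f, c) - p.b) / sf_c,
        )
    if model is ModelId.OPT_IB:
        j_m = 1.0 / p.sigma_m**2
        j_f = 1.0 / sf_c**2
        return (j_m * (s_m - p.b) + j_f * (effective_form(s_f, c) - p.b)) / np.sqrt(j_m + j_f)
    raise ValueError(f"unknown model: {model!r}")


def _single_cue_z(model: ModelId, condition, s_m, s_f, c, p: ModelParams):
    """Decision variable when only the instructed cue is used.

    FORM: OPT/BEST/AVG invert the old compression of the generative model,
    giving slope (1-c)/sigma_f(c); OPT_IB compares the raw form measurement
    to the boundary.  MOTION is unaffected by the old manipulation.
    """
    sf_c = p.sigma_f_for(c)
    is_motion = np.asarray(condition) == Condition.MOTION.value
    if model is ModelId.OPT_IB:
        z_form = (effective_form(s_f, c) - p.b) / sf_c
    else:
        z_form = (1.0 - c) * (s_f - p.b) / sf_c
    return np.where(is_motion, (s_m - p.b) / p.sigma_m, z_form)


def response_probabilities(
    model: ModelId | str,
    condition,
    s_m,
    s_f,
    c,
    params: ModelParams,
    single_cue_rule: str = "relevant_cue_only",
) -> np.ndarray:
    """Vectorized Pr(respond "Susan") for arrays of stimuli.

    Parameters are broadcast over the stimulus arrays.  ``single_cue_rule``
    is ``"relevant_cue_only"`` (default) or ``"full_rule"``; combined-cue
    trials always use the model's fusion rule.
    """
    model = ModelId(model)
    params.validate()
    if single_cue_rule not in ("relevant_cue_only", "full_rule"):
        raise ValueError(f"unknown single_cue_rule: {single_cue_rule!r}")
    condition = np.asarray(condition)
    s_m = np.asarray(s_m, dtype=float)
    s_f = np.asarray(s_f, dtype=float)
    c = np.asarray(c, dtype=float)

    z = _combined_z(model, s_m, s_f, c, params)
    if single_cue_rule == "relevant_cue_only":
        single = np.isin(condition, ("FORM", "MOTION"))
        if np.any(single):
            z = np.where(single, _single_cue_z(model, condition, s_m, s_f, c, params), z)
    lam = params.lapse
    return lam / 2.0 + (1.0 - lam) * ndtr(z)


def response_probability(
    model: ModelId | str,
    stim: Stimulus,
    params: ModelParams,
    single_cue_rule: str = "relevant_cue_only",
) -> float:
    """Closed-form Pr(respond "Susan") for one stimulus; lies in [λ/2, 1-λ/2]."""
    p = response_probabilities(
        model,
        np.asarray(Condition(stim.condition).value),
        stim.s_m,
        stim.s_f,
        stim.c,
        params,
        single_cue_rule,
    )
    return float(p)


@dataclass(frozen=True)
class MCEstimate:
    """Monte-Carlo choice-probability estimate with binomial standard error."""

    p_hat: float
    se: float
    n_samples: int


def simulate_decision_mc(
    model: ModelId | str,
    stim: Stimulus,
    params: ModelParams,
    n_samples: int = 100_000,
    seed: int = 0,
    single_cue_rule: str = "relevant_cue_only",
) -> MCEstimate:
    """Brute-force oracle: simulate raw measurements and apply the decision rule.

    Draws ``n_samples`` measurement pairs, applies the model's decision rule
    on the measurements (not the closed form), mixes in the lapse process,
    and returns the "Susan" fraction with its binomial standard error.
    """
    model = ModelId(model)
    params.validate()
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    cond = Condition(stim.condition)
    c = float(stim.c)
    sf_c = float(params.sigma_f_for(c))
    rng = np.random.default_rng(seed)

    x_m = rng.normal(stim.s_m, params.sigma_m, n_samples)
    x_f = rng.normal(effective_form(stim.s_f, c), sf_c, n_samples)

    single = single_cue_rule == "relevant_cue_only" and cond in (
        Condition.FORM,
        Condition.MOTION,
    )
    if single:
        if cond is Condition.MOTION:
            susan = x_m > params.b
        elif model is ModelId.OPT_IB:
            susan = x_f > params.b
        else:
            # invert the old compression of the form measurement before
            # comparing to the boundary
            susan = (x_f - OLD_AVERAGE_FORM * c) / (1.0 - c) > params.b
    elif model is ModelId.OPT:
        j_m = 1.0 / params.sigma_m**2
        j_f = 1.0 / sf_c**2
        est = (j_m * x_m + (1.0 - c) * j_f * (x_f - OLD_AVERAGE_FORM * c)) / (
            j_m + (1.0 - c) ** 2 * j_f
        )
        susan = est > params.b
    elif model is ModelId.BEST:
        susan = (x_m > params.b) if params.sigma_m < sf_c else (x_f > params.b)
    elif model is ModelId.AVG:
        susan = (x_m + x_f) / 2.0 > params.b
    else:  # OPT_IB
        j_m = 1.0 / params.sigma_m**2
        j_f = 1.0 / sf_c**2
        susan = (j_m * x_m + j_f * x_f) / (j_m + j_f) > params.b

    lapse_mask = rng.random(n_samples) < params.lapse
    guesses = rng.random(n_samples) < 0.5
    susan = np.where(lapse_mask, guesses, susan)

    p_hat = float(np.mean(susan))
    se = math.sqrt(max(p_hat * (1.0 - p_hat), 1e-12) / n_samples)
    return MCEstimate(p_hat=p_hat, se=se, n_samples=n_samples)
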