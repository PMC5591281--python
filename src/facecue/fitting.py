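"""Per-subject maximum-likelihood fitting of the observer models.

Two fit variants mirror the study's analyses:

* ``joint`` — all five parameters (sigma_m, sigma_f, sigma_f_old, b, lapse)
  are fitted to all conditions (single-cue and combined) at once;
* ``predictive`` — all five parameters are fitted to single-cue trials only,
  then the combined-cue log likelihood is evaluated at those parameters
  without refitting.  The overall log likelihood remains the sum of the
  single-cue and combined-cue parts.

Optimization is bounded L-BFGS-B with multiple random restarts; restart
start points are drawn uniformly within bounds (log-uniformly for the noise
SDs).  Bounds: sigma in [0.01, 2] morph units, b in [-0.5, 1.5], lapse in
[0, 0.5].  Choice probabilities are clipped away from 0/1 by a 1e-9 floor
before taking logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import SINGLE_CUE_CONDITIONS
from .observer_models import ModelId, ModelParams, response_probabilities

__all__ = [
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "FitResult",
    "negative_log_likelihood",
    "fit_mle",
    "fit_population",
]

PARAM_NAMES = ("sigma_m", "sigma_f", "sigma_f_old", "b", "lapse")
PARAM_BOUNDS = {
    "sigma_m": (0.01, 2.0),
    "sigma_f": (0.01, 2.0),
    "sigma_f_old": (0.01, 2.0),
    "b": (-0.5, 1.5),
    "lapse": (0.0, 0.5),
}
_LOG_UNIFORM = {"sigma_m", "sigma_f", "sigma_f_old"}
_PROB_FLOOR = 1e-9


@dataclass
class RestartRecord:
    start: ModelParams
    converged_params: ModelParams
    loglik: float
    converged: bool


@dataclass
class FitResult:
    """Outcome of one (subject, model, variant) fit.

    ``loglik`` is the total maximized log likelihood and always equals
    ``loglik_single + loglik_combined``; ``params`` belongs to the best
    restart.
    """

    model: ModelId
    variant: str
    params: ModelParams
    loglik: float
    loglik_single: float
    loglik_combined: float
    restarts: list[RestartRecord] = field(default_factory=list)

    def to_row(self, subject=None) -> dict:
        row = {"subject": subject, "model": self.model.value, "variant": self.variant}
        row.update(self.params.to_dict())
        row.update(
            loglik=self.loglik,
            loglik_single=self.loglik_single,
            loglik_combined=self.loglik_combined,
        )
        return row


def _loglik_arrays(model, params_vec, condition, s_m, s_f, c, resp, single_cue_rule):
    params = ModelParams(*params_vec)
    p = response_probabilities(model, condition, s_m, s_f, c, params, single_cue_rule)
    p = np.clip(p, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    return float(np.sum(np.where(resp == 1, np.log(p), np.log1p(-p))))


def negative_log_likelihood(
    model: ModelId | str,
    params: ModelParams,
    data: pd.DataFrame,
    single_cue_rule: str = "relevant_cue_only",
) -> float:
    """Bernoulli negative log likelihood of a response table under a model."""
    if len(data) == 0:
        raise ValueError("data is empty")
    params.validate()
    return -_loglik_arrays(
        ModelId(model),
        (params.sigma_m, params.sigma_f, params.sigma_f_old, params.b, params.lapse),
        data["condition"].to_numpy(),
        data["s_m"].to_numpy(),
        data["s_f"].to_numpy(),
        data["c"].to_numpy(),
        data["response"].to_numpy(),
        single_cue_rule,
    )


def _draw_start(rng: np.random.Generator) -> np.ndarray:
    vals = []
    for name in PARAM_NAMES:
        lo, hi = PARAM_BOUNDS[name]
        if name in _LOG_UNIFORM:
            vals.append(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            vals.append(rng.uniform(lo, hi))
    return np.asarray(vals)


def fit_mle(
    model: ModelId | str,
    data: pd.DataFrame,
    n_restarts: int = 10,
    seed: int = 0,
    variant: str = "joint",
    single_cue_rule: str = "relevant_cue_only",
    extra_starts: list[ModelParams] | None = None,
) -> FitResult:
    """Fit one subject's responses by multi-restart bounded MLE.

    ``extra_starts`` appends user-supplied start points (e.g. the true
    generating parameters) to the random restarts.  Deterministic given
    (data, seed).
    """
    model = ModelId(model)
    if variant not in ("joint", "predictive"):
        raise ValueError(f"unknown variant: {variant!r}")
    if len(data) == 0:
        raise ValueError("data is empty")

    single_mask = data["condition"].isin(SINGLE_CUE_CONDITIONS).to_numpy()
    if variant == "predictive":
        if not single_mask.any():
            raise ValueError("predictive variant requires single-cue trials")
        if single_mask.all():
            raise ValueError("predictive variant requires combined-cue trials to evaluate")
        fit_data = data.loc[single_mask]
    else:
        fit_data = data

    cols = ("condition", "s_m", "s_f", "c", "response")
    arrays = tuple(fit_data[k].to_numpy() for k in cols)

    def nll(vec: np.ndarray) -> float:
        return -_loglik_arrays(model, vec, *arrays, single_cue_rule)

    bounds = [PARAM_BOUNDS[name] for name in PARAM_NAMES]
    rng = np.random.default_rng(seed)
    starts = [_draw_start(rng) for _ in range(n_restarts)]
    for p0 in extra_starts or []:
        starts.append(np.asarray([getattr(p0, name) for name in PARAM_NAMES]))

    restarts: list[RestartRecord] = []
    for x0 in starts:
        # ftol is relative in L-BFGS-B; 1e-9 gives ~1e-6 absolute at typical NLLs
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-9})
        restarts.append(
            RestartRecord(
                start=ModelParams(*x0),
                converged_params=ModelParams(*res.x),
                loglik=-float(res.fun),
                converged=bool(res.success),
            )
        )
    if not any(np.isfinite(r.loglik) for r in restarts):
        raise RuntimeError(f"all {len(restarts)} restarts failed: {restarts}")

    best = max(restarts, key=lambda r: r.loglik)
    params = best.converged_params

    ll_single = (
        -negative_log_likelihood(model, params, data.loc[single_mask], single_cue_rule)
        if single_mask.any()
        else 0.0
    )
    ll_combined = (
        -negative_log_likelihood(model, params, data.loc[~single_mask], single_cue_rule)
        if (~single_mask).any()
        else 0.0
    )
    return FitResult(
        model=model,
        variant=variant,
        params=params,
        loglik=ll_single + ll_combined,
        loglik_single=ll_single,
        loglik_combined=ll_combined,
        restarts=restarts,
    )


def fit_population(
    models,
    responses: pd.DataFrame,
    n_restarts: int = 10,
    seed: int = 0,
    variant: str = "joint",
    single_cue_rule: str = "relevant_cue_only",
) -> tuple[pd.DataFrame, dict]:
    """Fit every subject under every model.

    Returns a tidy table (one row per subject x model) and the nested
    ``{subject: {model: FitResult}}`` mapping.  Per-(subject, model) seeds
    are derived from ``seed`` so fits are independent and reproducible.
    """
    models = [ModelId(m) for m in models]
    rows, results = [], {}
    for subject, sub_data in responses.groupby("subject"):
        results[subject] = {}
        for k, model in enumerate(models):
            fit_seed = np.random.SeedSequence([seed, int(subject), k]).generate_state(1)[0]
            fr = fit_mle(
                model,
                sub_data,
                n_restarts=n_restarts,
                seed=int(fit_seed),
                variant=variant,
                single_cue_rule=single_cue_rule,
            )
            results[subject][model] = fr
            rows.append(fr.to_row(subject=subject))
    return pd.DataFrame(rows), results
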