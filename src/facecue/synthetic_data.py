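"""Synthetic subject populations and trial-level binary responses.

Stands in for the behavioral dataset of the original study: 22 observers
categorizing dynamic faces as "Laura" (0) or "Susan" (1) over the full
condition grid.  Subjects are drawn around the group-median observer
parameters with a location-preserving heterogeneity model:

* noise SDs get a multiplicative log-normal spread (the median of each SD
  is exactly the population location);
* the boundary b and lapse rate get additive Gaussian spread, clipped to
  [0, 1] and [0, 0.5] respectively.

Default spreads are back-solved from the across-subject IQRs of the fitted
parameters, so a default population reproduces realistic between-subject
variability.  Responses are independent Bernoulli draws with the generating
model's closed-form choice probability; everything is deterministic given
the population seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignSpec, build_design
from .observer_models import (
    PAPER_MEDIAN_PARAMS,
    ModelId,
    ModelParams,
    response_probabilities,
)

__all__ = [
    "PopulationSpec",
    "paper_like_population",
    "sample_subject_params",
    "assign_models",
    "simulate_responses",
    "simulate_population",
    "write_response_table",
    "read_response_table",
]

RESPONSE_COLUMNS = ["subject", "trial", "condition", "s_m", "s_f", "c", "response"]


@dataclass(frozen=True)
class PopulationSpec:
    """Synthetic population definition.

    ``generating_model`` may be a single ModelId (all subjects), a mapping
    of ModelId -> mixture weight, or an explicit per-subject sequence.
    ``sigma_spread`` is the SD of the log-normal multiplier on the noise
    SDs; ``b_spread``/``lapse_spread`` are additive Gaussian SDs.
    """

    n_subjects: int = 22
    generating_model: ModelId | Mapping | Sequence = ModelId.OPT
    param_location: ModelParams = PAPER_MEDIAN_PARAMS
    sigma_spread: float = 0.33
    b_spread: float = 0.07
    lapse_spread: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("sigma_spread", "b_spread", "lapse_spread"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if isinstance(self.generating_model, Mapping):
            total = float(sum(self.generating_model.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture weights sum to {total}, expected 1")


def paper_like_population(seed: int = 0, **overrides) -> PopulationSpec:
    """Preset mirroring the per-subject posterior counts of the human study:
    15 optimal, 3 best-cue and 4 simple-average subjects out of 22."""
    assignment = [ModelId.OPT] * 15 + [ModelId.BEST] * 3 + [ModelId.AVG] * 4
    return PopulationSpec(
        n_subjects=22, generating_model=tuple(assignment), seed=seed, **overrides
    )


def _subject_rng(seed: int, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, subject_index, stream])


def sample_subject_params(spec: PopulationSpec, subject_index: int) -> ModelParams:
    """Draw one subject's true parameters; deterministic given (seed, index)."""
    spec.validate()
    rng = _subject_rng(spec.seed, subject_index, 0)
    loc = spec.param_location
    z = rng.standard_normal(5)
    return ModelParams(
        sigma_m=loc.sigma_m * np.exp(spec.sigma_spread * z[0]),
        sigma_f=loc.sigma_f * np.exp(spec.sigma_spread * z[1]),
        sigma_f_old=loc.sigma_f_old * np.exp(spec.sigma_spread * z[2]),
        b=float(np.clip(loc.b + spec.b_spread * z[3], 0.0, 1.0)),
        lapse=float(np.clip(loc.lapse + spec.lapse_spread * z[4], 0.0, 0.5)),
    )


def assign_models(spec: PopulationSpec) -> list[ModelId]:
    """Generating model per subject (deterministic given spec.seed)."""
    spec.validate()
    gm = spec.generating_model
    if isinstance(gm, (ModelId, str)):
        return [ModelId(gm)] * spec.n_subjects
    if isinstance(gm, Mapping):
        models = [ModelId(m) for m in gm]
        weights = np.asarray([gm[m] for m in gm], dtype=float)
        rng = np.random.default_rng([spec.seed, 997])
        draws = rng.choice(len(models), size=spec.n_subjects, p=weights)
        return [models[i] for i in draws]
    assignment = [ModelId(m) for m in gm]
    if len(assignment) != spec.n_subjects:
        raise ValueError(
            f"per-subject assignment has length {len(assignment)}, expected {spec.n_subjects}"
        )
    return assignment


def simulate_responses(
    model: ModelId | str,
    params: ModelParams,
    trials: pd.DataFrame,
    seed: int = 0,
    subject: int = 0,
    single_cue_rule: str = "relevant_cue_only",
) -> pd.DataFrame:
    """Simulate one subject's binary responses over a trial table.

    Each response is an independent Bernoulli draw with the model's
    closed-form "Susan" probability for that trial.
    """
    p = response_probabilities(
        model,
        trials["condition"].to_numpy(),
        trials["s_m"].to_numpy(),
        trials["s_f"].to_numpy(),
        trials["c"].to_numpy(),
        params,
        single_cue_rule,
    )
    rng = np.random.default_rng([seed, subject, 1])
    out = trials[["trial", "condition", "s_m", "s_f", "c"]].copy()
    out.insert(0, "subject", subject)
    out["response"] = (rng.random(len(out)) < p).astype(int)
    return out


def simulate_population(
    spec: PopulationSpec,
    design: DesignSpec | pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full synthetic dataset.

    Returns ``(responses, truth)``: a long-format response table over all
    subjects and a ground-truth sidecar (generating model and true
    parameters per subject, plus the seed) for recovery scoring.
    """
    spec.validate()
    if design is None:
        design = DesignSpec()
    if isinstance(design, DesignSpec):
        trials = build_design(design, seed=spec.seed)
    else:
        trials = design
    models = assign_models(spec)
    frames, truth_subjects = [], []
    for i in range(spec.n_subjects):
        params = sample_subject_params(spec, i)
        frames.append(
            simulate_responses(models[i], params, trials, seed=spec.seed, subject=i)
        )
        truth_subjects.append(
            {"subject": i, "model": models[i].value, "params": params.to_dict()}
        )
    responses = pd.concat(frames, ignore_index=True)
    truth = {"seed": spec.seed, "subjects": truth_subjects}
    return responses, truth


def write_response_table(responses: pd.DataFrame, path, truth: dict | None = None) -> None:
    """CSV with header subject,trial,condition,s_m,s_f,c,response; optional
    ground-truth JSON sidecar at ``<path>.truth.json``."""
    responses[RESPONSE_COLUMNS].to_csv(path, index=False)
    if truth is not None:
        with open(f"{path}.truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)


def read_response_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(RESPONSE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    return table
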