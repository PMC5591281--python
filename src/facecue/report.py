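"""Psychometric summaries: mean percentage of "Susan" reports per condition,
old level and morph level, with between-subject standard errors, plus
model-fit overlays on the same axes.

The x-axis for a trial is the varied cue's morph level: ``s_f`` in FORM
blocks, ``s_m`` in MOTION blocks, the common level in the congruent
combined condition, and — selectable via ``axis_rule`` — the mean of
``(s_m, s_f)`` (default), the form level, or the motion level in the
incongruent conditions.  MOTION trials are pooled over old levels when the
design marks them poolable (motion reliability is unaffected by the old
manipulation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import Condition
from .fitting import FitResult
from .observer_models import response_probabilities

__all__ = ["stimulus_axis", "psychometric_summary", "overlay_model_fit"]

CURVE_COLUMNS = ["condition", "old", "level", "mean_pct", "sem", "n"]


def stimulus_axis(data: pd.DataFrame, axis_rule: str = "mean") -> np.ndarray:
    """Morph-level axis value for each trial row."""
    if axis_rule not in ("mean", "form", "motion"):
        raise ValueError(f"unknown axis_rule: {axis_rule!r}")
    cond = data["condition"].to_numpy()
    s_m = data["s_m"].to_numpy(dtype=float)
    s_f = data["s_f"].to_numpy(dtype=float)
    if axis_rule == "form":
        incong = s_f
    elif axis_rule == "motion":
        incong = s_m
    else:
        incong = (s_m + s_f) / 2.0
    axis = np.where(cond == Condition.FORM.value, s_f, incong)
    axis = np.where(cond == Condition.MOTION.value, s_m, axis)
    axis = np.where(cond == Condition.COMB.value, s_m, axis)
    return np.round(axis, 10)


def _prepare(data: pd.DataFrame, axis_rule: str, pool_motion_old: bool) -> pd.DataFrame:
    d = data.copy()
    d["level"] = stimulus_axis(d, axis_rule)
    d["old"] = (d["c"] > 0).astype(int)
    if pool_motion_old:
        d.loc[d["condition"] == Condition.MOTION.value, "old"] = 0
    return d


def psychometric_summary(
    data: pd.DataFrame,
    axis_rule: str = "mean",
    pool_motion_old: bool = True,
    value_col: str = "response",
) -> pd.DataFrame:
    """Across-subject psychometric curves.

    For every condition x old x level cell: first the per-subject mean
    "Susan" rate, then the across-subject mean (in percent) and s.e.m.
    With a single subject the s.e.m. is 0 by convention and the frame's
    ``attrs["single_subject"]`` flag is set.  Cells missing for some
    subjects are listed in ``attrs["missing_cells"]``, never imputed.
    """
    if data["subject"].nunique() < 1 or len(data) == 0:
        raise ValueError("need at least one subject with trials")
    d = _prepare(data, axis_rule, pool_motion_old)

    per_subject = (
        d.groupby(["condition", "old", "level", "subject"], sort=True)[value_col]
        .mean()
        .reset_index()
    )
    n_subjects = d["subject"].nunique()

    rows = []
    missing = []
    for (cond, old, level), grp in per_subject.groupby(
        ["condition", "old", "level"], sort=True
    ):
        vals = grp[value_col].to_numpy(dtype=float) * 100.0
        n = len(vals)
        if n < n_subjects:
            missing.append((cond, int(old), float(level), n))
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "condition": cond,
                "old": int(old),
                "level": float(level),
                "mean_pct": float(np.mean(vals)),
                "sem": sem,
                "n": n,
            }
        )
    curves = pd.DataFrame(rows, columns=CURVE_COLUMNS)
    curves.attrs["single_subject"] = n_subjects == 1
    curves.attrs["missing_cells"] = missing
    return curves


def overlay_model_fit(
    data: pd.DataFrame,
    fits: dict[int, FitResult],
    axis_rule: str = "mean",
    pool_motion_old: bool = True,
) -> pd.DataFrame:
    """Model-predicted curves on the same axes as the data summary.

    ``fits`` maps subject id -> FitResult; every subject present in
    ``data`` must be covered.  Per-subject predicted probabilities are
    computed trial-by-trial from the fitted parameters, then summarized
    exactly like the observed responses.
    """
    subjects = set(data["subject"].unique())
    missing = subjects - set(fits)
    if missing:
        raise ValueError(f"no fit provided for subjects: {sorted(missing)}")

    d = data.copy()
    pred = np.empty(len(d), dtype=float)
    for subject, idx in d.groupby("subject").groups.items():
        fr = fits[subject]
        sub = d.loc[idx]
        pred[d.index.get_indexer(idx)] = response_probabilities(
            fr.model,
            sub["condition"].to_numpy(),
            sub["s_m"].to_numpy(),
            sub["s_f"].to_numpy(),
            sub["c"].to_numpy(),
            fr.params,
        )
    d["predicted"] = pred
    curves = psychometric_summary(
        d, axis_rule=axis_rule, pool_motion_old=pool_motion_old, value_col="predicted"
    )
    return curves.rename(columns={"mean_pct": "predicted_pct"})
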