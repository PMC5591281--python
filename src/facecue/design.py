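"""Experimental trial structure for the two-identity (Laura/Susan) categorization task.

The stimulus space is a two-dimensional morph continuum: a motion morph level
``s_m`` and a form morph level ``s_f``, both in [0, 1] with 0 = Laura and
1 = Susan.  Five conditions sample this space:

* ``FORM``    — form varies over the level grid, motion fixed at 0.5;
* ``MOTION``  — motion varies, form fixed at 0.5;
* ``COMB``    — congruent combined cue, ``s_m = s_f``;
* ``COMB_PLUS``  — incongruent, form carries more "Susan" information
  (``s_f − s_m = Δ`` under the default sign convention);
* ``COMB_MINUS`` — incongruent, motion carries more (``s_m − s_f = Δ``).

Each stimulus additionally carries an "old" level ``c ∈ {0, 0.35}``: the form
cue is morphed toward an aged average face (situated at form level 0.6) by a
fraction ``c``, which lowers form reliability without touching motion.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Stimulus",
    "DesignSpec",
    "ValidationReport",
    "OLD_LEVEL",
    "OLD_AVERAGE_FORM",
    "build_design",
    "validate_design",
    "write_trial_table",
    "read_trial_table",
]

#: The "old" morph fraction used in the old-on conditions.
OLD_LEVEL = 0.35
#: Form-morph position of the aged average face on the Laura–Susan axis.
OLD_AVERAGE_FORM = 0.6

SINGLE_CUE_CONDITIONS = ("FORM", "MOTION")
COMBINED_CONDITIONS = ("COMB", "COMB_PLUS", "COMB_MINUS")

TRIAL_COLUMNS = ["trial", "condition", "s_m", "s_f", "c"]


class Condition(str, enum.Enum):
    FORM = "FORM"
    MOTION = "MOTION"
    COMB = "COMB"
    COMB_PLUS = "COMB_PLUS"
    COMB_MINUS = "COMB_MINUS"


class InvalidDesignError(ValueError):
    """Raised when a DesignSpec violates its own invariants."""


@dataclass(frozen=True)
class Stimulus:
    """One presented face: condition label, morph levels and old level."""

    condition: Condition
    s_m: float
    s_f: float
    c: float = 0.0

    def violations(self, delta: float = 0.15, atol: float = 1e-9) -> list[str]:
        """Invariant breaches of this stimulus (empty list = valid)."""
        v: list[str] = []
        if not (0.0 <= self.s_m <= 1.0):
            v.append(f"s_m={self.s_m} outside [0,1]")
        if not (0.0 <= self.s_f <= 1.0):
            v.append(f"s_f={self.s_f} outside [0,1]")
        if not (abs(self.c) <= atol or abs(self.c - OLD_LEVEL) <= atol):
            v.append(f"c={self.c} not in {{0, {OLD_LEVEL}}}")
        cond = Condition(self.condition)
        if cond is Condition.FORM and abs(self.s_m - 0.5) > atol:
            v.append(f"FORM trial with s_m={self.s_m} != 0.5")
        elif cond is Condition.MOTION and abs(self.s_f - 0.5) > atol:
            v.append(f"MOTION trial with s_f={self.s_f} != 0.5")
        elif cond is Condition.COMB and abs(self.s_m - self.s_f) > atol:
            v.append(f"COMB trial with s_m={self.s_m} != s_f={self.s_f}")
        elif cond is Condition.COMB_PLUS and abs((self.s_f - self.s_m) - delta) > atol:
            v.append(f"COMB_PLUS trial with s_f - s_m = {self.s_f - self.s_m} != {delta}")
        elif cond is Condition.COMB_MINUS and abs((self.s_m - self.s_f) - delta) > atol:
            v.append(f"COMB_MINUS trial with s_m - s_f = {self.s_m - self.s_f} != {delta}")
        return v


def _default_levels() -> tuple[float, ...]:
    return tuple(np.round(np.linspace(0.0, 1.0, 11), 10))


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the factorial trial design.

    Parameters
    ----------
    morph_levels
        Strictly increasing levels in [0, 1] of the morph grid
        (default: 11 equally spaced levels, 0 to 1 in steps of 0.1).
    delta
        Cue-conflict magnitude for incongruent combined trials (morph units).
    n_reps
        Repetitions of each unique stimulus.
    include_old
        Whether to cross every condition with the old-on manipulation.
    collapse_motion_old
        Mark MOTION trials (generated at both old levels) as poolable for
        analysis; motion reliability is unaffected by the old manipulation.
    incongruent_anchor
        How incongruent (s_m, s_f) pairs sit on the grid: ``"mean"`` anchors
        the pair mean at a grid level with symmetric ±delta/2 offsets
        (default); ``"form"``/``"motion"`` anchor that cue at the grid level
        and offset the other by the full delta.
    plus_is_form_greater
        Sign convention for the conflict: when True (default), the +Δ
        condition has more form than motion information (s_f = s_m + Δ).
    """

    morph_levels: tuple[float, ...] = field(default_factory=_default_levels)
    delta: float = 0.15
    n_reps: int = 8
    include_old: bool = True
    collapse_motion_old: bool = True
    incongruent_anchor: str = "mean"
    plus_is_form_greater: bool = True

    def validate(self) -> None:
        levels = np.asarray(self.morph_levels, dtype=float)
        if levels.size == 0:
            raise InvalidDesignError("morph_levels is empty")
        if np.any(np.diff(levels) <= 0):
            raise InvalidDesignError("morph_levels must be strictly increasing")
        if np.any(levels < 0) or np.any(levels > 1):
            raise InvalidDesignError("morph_levels must lie in [0,1]")
        if not (0 < self.delta < 1):
            raise InvalidDesignError(f"delta={self.delta} must lie in (0,1)")
        if self.n_reps < 1:
            raise InvalidDesignError(f"n_reps={self.n_reps} must be >= 1")
        if self.incongruent_anchor not in ("mean", "form", "motion"):
            raise InvalidDesignError(
                f"incongruent_anchor={self.incongruent_anchor!r} not one of mean/form/motion"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidDesignError(f"unknown design keys: {sorted(unknown)}")
        d = dict(d)
        if "morph_levels" in d:
            d["morph_levels"] = tuple(float(x) for x in d["morph_levels"])
        return cls(**d)


@dataclass
class ValidationReport:
    violations: list[str]

    @property
    def is_valid(self) -> bool:
        return not self.violations


def _incongruent_pairs(spec: DesignSpec, positive: bool) -> tuple[list[tuple[float, float]], int]:
    """(s_m, s_f) pairs for one incongruent condition, plus dropped-pair count.

    ``positive`` selects the +Δ condition.  Under the default convention
    +Δ means form > motion.  Pairs with either member outside [0,1] are
    dropped rather than clipped, so the nominal conflict is always exact.
    """
    form_greater = positive == spec.plus_is_form_greater
    pairs, dropped = [], 0
    for lev in spec.morph_levels:
        if spec.incongruent_anchor == "mean":
            lo, hi = lev - spec.delta / 2.0, lev + spec.delta / 2.0
        elif spec.incongruent_anchor == "form":
            sf = lev
            lo, hi = (sf - spec.delta, sf) if form_greater else (sf, sf + spec.delta)
        else:  # anchor motion
            sm = lev
            lo, hi = (sm, sm + spec.delta) if form_greater else (sm - spec.delta, sm)
        s_m, s_f = (lo, hi) if form_greater else (hi, lo)
        if 0.0 <= lo and hi <= 1.0:
            pairs.append((s_m, s_f))
        else:
            dropped += 1
    return pairs, dropped


def build_design(spec: DesignSpec, seed: int = 0) -> pd.DataFrame:
    """Build the full factorial trial table and shuffle it.

    Returns a DataFrame with columns ``trial, condition, s_m, s_f, c`` and a
    boolean ``poolable`` column marking MOTION trials whose old levels may be
    pooled at analysis time.  The number of incongruent pairs dropped for
    falling outside [0,1]² is stored in ``table.attrs["n_dropped_pairs"]``.
    Deterministic given (spec, seed); the seed only permutes trial order.
    """
    spec.validate()
    old_levels = [0.0, OLD_LEVEL] if spec.include_old else [0.0]

    rows: list[tuple[str, float, float]] = []
    for lev in spec.morph_levels:
        rows.append((Condition.FORM.value, 0.5, lev))
        rows.append((Condition.MOTION.value, lev, 0.5))
        rows.append((Condition.COMB.value, lev, lev))
    dropped_total = 0
    for cond, positive in ((Condition.COMB_PLUS, True), (Condition.COMB_MINUS, False)):
        pairs, dropped = _incongruent_pairs(spec, positive)
        dropped_total += dropped
        rows.extend((cond.value, s_m, s_f) for s_m, s_f in pairs)

    records = [
        (cond, s_m, s_f, c)
        for cond, s_m, s_f in rows
        for c in old_levels
        for _ in range(spec.n_reps)
    ]
    table = pd.DataFrame(records, columns=["condition", "s_m", "s_f", "c"])

    rng = np.random.default_rng(seed)
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    table.insert(0, "trial", np.arange(len(table)))
    table["poolable"] = spec.collapse_motion_old & (table["condition"] == Condition.MOTION.value)
    table.attrs["n_dropped_pairs"] = dropped_total
    table.attrs["delta"] = spec.delta
    return table


def validate_design(table: pd.DataFrame, delta: float | None = None) -> ValidationReport:
    """Check every row of a trial table against the Stimulus invariants.

    Violations are returned as data, not raised; an empty list means valid.
    """
    if delta is None:
        delta = table.attrs.get("delta", 0.15)
    violations: list[str] = []
    trials = table["trial"].to_numpy()
    if len(np.unique(trials)) != len(trials) or not np.array_equal(
        np.sort(trials), np.arange(len(trials))
    ):
        violations.append("trial indices are not unique and contiguous from 0")
    for row in table.itertuples(index=False):
        try:
            stim = Stimulus(Condition(row.condition), row.s_m, row.s_f, row.c)
        except ValueError:
            violations.append(f"trial {row.trial}: unknown condition {row.condition!r}")
            continue
        violations.extend(f"trial {row.trial}: {msg}" for msg in stim.violations(delta))
    return ValidationReport(violations)


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Serialize as CSV with the canonical header trial,condition,s_m,s_f,c."""
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trial_table(path, collapse_motion_old: bool = True) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidDesignError(f"trial table missing columns: {sorted(missing)}")
    table["poolable"] = collapse_motion_old & (table["condition"] == Condition.MOTION.value)
    return table


def design_spec_from_config(config: dict | str) -> DesignSpec:
    """Read a DesignSpec from a config mapping (or JSON text) under key "design"."""
    if isinstance(config, str):
        config = json.loads(config)
    block = config.get("design", config)
    return DesignSpec.from_dict(block)
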