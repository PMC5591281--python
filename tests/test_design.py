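"""Trial-structure construction and validation."""

import numpy as np
import pandas as pd
import pytest

from facecue import DesignSpec, build_design, validate_design
from facecue.design import InvalidDesignError, write_trial_table, read_trial_table


def test_tiny_grid_enumeration_mean_anchor(tiny_design):
    """Hand enumeration on levels {0, 0.5, 1}, delta 0.15, mean anchoring:
    the +Δ pair at mean 0 has s_m = -0.075 and at mean 1 has s_f = 1.075
    (mirror for −Δ), so only the mean-0.5 pair survives per incongruent
    condition; four pairs are dropped in total."""
    table = build_design(tiny_design, seed=0)
    counts = table["condition"].value_counts().to_dict()
    assert counts == {"FORM": 3, "MOTION": 3, "COMB": 3, "COMB_PLUS": 1, "COMB_MINUS": 1}
    assert table.attrs["n_dropped_pairs"] == 4
    plus = table[table["condition"] == "COMB_PLUS"].iloc[0]
    assert (plus.s_m, plus.s_f) == (0.5 - 0.075, 0.5 + 0.075)


def test_tiny_grid_enumeration_member_anchor(tiny_design):
    """Anchoring one cue on the grid and offsetting the other by the full
    delta keeps two pairs per incongruent condition (only one end of the
    grid pushes the partner cue out of [0,1])."""
    spec = DesignSpec(
        morph_levels=(0.0, 0.5, 1.0),
        delta=0.15,
        n_reps=1,
        include_old=False,
        incongruent_anchor="form",
    )
    table = build_design(spec, seed=0)
    counts = table["condition"].value_counts().to_dict()
    assert counts["COMB_PLUS"] == 2 and counts["COMB_MINUS"] == 2
    assert table.attrs["n_dropped_pairs"] == 2


def test_n_reps_multiplies_count_only(tiny_design):
    t1 = build_design(tiny_design, seed=0)
    spec2 = DesignSpec(
        morph_levels=tiny_design.morph_levels,
        delta=tiny_design.delta,
        n_reps=2,
        include_old=False,
    )
    t2 = build_design(spec2, seed=0)
    assert len(t2) == 2 * len(t1)
    key = ["condition", "s_m", "s_f", "c"]
    u1 = t1[key].drop_duplicates().sort_values(key).reset_index(drop=True)
    u2 = t2[key].drop_duplicates().sort_values(key).reset_index(drop=True)
    pd.testing.assert_frame_equal(u1, u2)


def test_conflict_magnitude_exact():
    """Every incongruent pair differs by delta exactly, and under the
    default sign convention +Δ means more form than motion."""
    table = build_design(DesignSpec(), seed=3)
    plus = table[table["condition"] == "COMB_PLUS"]
    minus = table[table["condition"] == "COMB_MINUS"]
    assert len(plus) and len(minus)
    assert np.allclose(plus["s_f"] - plus["s_m"], 0.15, atol=1e-12)
    assert np.allclose(minus["s_m"] - minus["s_f"], 0.15, atol=1e-12)


def test_sign_convention_switch():
    spec = DesignSpec(plus_is_form_greater=False)
    table = build_design(spec, seed=3)
    plus = table[table["condition"] == "COMB_PLUS"]
    assert np.allclose(plus["s_m"] - plus["s_f"], 0.15, atol=1e-12)


def test_old_crossing_and_poolable_flag():
    table = build_design(DesignSpec(n_reps=1), seed=0)
    assert set(np.round(table["c"].unique(), 10)) == {0.0, 0.35}
    motion = table["condition"] == "MOTION"
    assert table.loc[motion, "poolable"].all()
    assert not table.loc[~motion, "poolable"].any()
    # motion trials exist at both old levels even though poolable
    assert set(np.round(table.loc[motion, "c"].unique(), 10)) == {0.0, 0.35}


def test_determinism_and_seed_permutes_multiset(tiny_design):
    a = build_design(tiny_design, seed=5)
    b = build_design(tiny_design, seed=5)
    pd.testing.assert_frame_equal(a, b)
    c = build_design(tiny_design, seed=6)
    key = ["condition", "s_m", "s_f", "c"]
    assert not a[key].equals(c[key])  # order differs...
    sa = a[key].sort_values(key).reset_index(drop=True)
    sc = c[key].sort_values(key).reset_index(drop=True)
    pd.testing.assert_frame_equal(sa, sc)  # ...but the multiset does not


def test_validate_design_accepts_own_output(default_trials):
    assert validate_design(default_trials).is_valid


@pytest.mark.parametrize(
    "mutation, fragment",
    [
        (dict(condition="FORM", s_m=0.6, s_f=0.3, c=0.0), "FORM trial with s_m"),
        (dict(condition="COMB", s_m=0.4, s_f=0.4, c=0.2), "not in"),
        (dict(condition="COMB", s_m=1.4, s_f=1.4, c=0.0), "outside [0,1]"),
        (dict(condition="NOPE", s_m=0.5, s_f=0.5, c=0.0), "unknown condition"),
    ],
)
def test_validate_design_flags_violations(default_trials, mutation, fragment):
    table = default_trials.copy()
    for col, val in mutation.items():
        table.loc[table.index[0], col] = val
    report = validate_design(table)
    assert not report.is_valid
    trial = table.loc[table.index[0], "trial"]
    assert any(fragment in v and f"trial {trial}" in v for v in report.violations)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(morph_levels=()),
        dict(delta=1.0),
        dict(delta=-0.1),
        dict(morph_levels=(0.5, 0.2)),
        dict(n_reps=0),
        dict(incongruent_anchor="midpoint"),
    ],
)
def test_invalid_spec_rejected(kwargs):
    with pytest.raises(InvalidDesignError):
        build_design(DesignSpec(**kwargs), seed=0)


def test_trial_table_csv_roundtrip(tmp_path, default_trials):
    path = tmp_path / "design.csv"
    write_trial_table(default_trials, path)
    assert path.read_text().splitlines()[0] == "trial,condition,s_m,s_f,c"
    back = read_trial_table(path)
    pd.testing.assert_frame_equal(
        back[["trial", "condition", "s_m", "s_f", "c"]],
        default_trials[["trial", "condition", "s_m", "s_f", "c"]],
    )
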