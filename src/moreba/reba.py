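"""Classic REBA scoring from packaged lookup-table fixtures.

Implements the standard Rapid Entire Body Assessment: group-A
(trunk/neck/legs) and group-B (upper arm/lower arm/wrist) posture tables,
load/force and coupling adjustments, table C, and the activity score.
Used here both as the comparison method in the validation pipeline and as
a front-end producing the posture_a / posture_b inputs of the modified
score.

Table cell values are shipped as human-readable CSV fixtures under
``moreba/data/`` (transcribed from the published method) rather than
hard-coded, so they can be audited cell by cell.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .core import ValidationError

__all__ = [
    "RebaPostureObservation",
    "table_a_score",
    "table_b_score",
    "table_c_score",
    "reba_final_score",
    "reba_final_from_profile",
    "reba_action_level",
    "DEFAULT_ACTION_BREAKPOINTS",
]

#: Four-level binning of the 1..15 final score used when comparing REBA
#: against four-level methods: published action levels with the two lowest
#: (negligible, score 1, and low, 2-3) merged.  ``breakpoints[i]`` is the
#: smallest final score belonging to level i+2.
DEFAULT_ACTION_BREAKPOINTS: tuple[int, int, int] = (4, 8, 11)


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("moreba.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


@functools.cache
def _table_a() -> dict[tuple[int, int, int], int]:
    df = _read_fixture("reba_table_a.csv")
    return {
        (int(r.trunk), int(r.neck), int(r.legs)): int(r.score)
        for r in df.itertuples()
    }


@functools.cache
def _table_b() -> dict[tuple[int, int, int], int]:
    df = _read_fixture("reba_table_b.csv")
    return {
        (int(r.upper_arm), int(r.lower_arm), int(r.wrist)): int(r.score)
        for r in df.itertuples()
    }


@functools.cache
def _table_c() -> dict[tuple[int, int], int]:
    df = _read_fixture("reba_table_c.csv").set_index("score_a")
    return {
        (int(a), b): int(df.at[a, f"b{b}"])
        for a in df.index
        for b in range(1, 13)
    }


def _check_range(name: str, value: int, lo: int, hi: int) -> int:
    try:
        ivalue = int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{name} must be an integer, got {value!r}") from None
    if ivalue != value or not lo <= ivalue <= hi:
        raise ValidationError(f"{name}={value!r} outside the range {lo}..{hi}")
    return ivalue


def table_a_score(trunk: int, neck: int, legs: int) -> int:
    """Group-A posture score (1..9) for trunk 1..5, neck 1..3, legs 1..4."""
    key = (
        _check_range("trunk", trunk, 1, 5),
        _check_range("neck", neck, 1, 3),
        _check_range("legs", legs, 1, 4),
    )
    return _table_a()[key]


def table_b_score(upper_arm: int, lower_arm: int, wrist: int) -> int:
    """Group-B posture score (1..9) for upper arm 1..6, lower arm 1..2, wrist 1..3."""
    key = (
        _check_range("upper_arm", upper_arm, 1, 6),
        _check_range("lower_arm", lower_arm, 1, 2),
        _check_range("wrist", wrist, 1, 3),
    )
    return _table_b()[key]


def table_c_score(score_a: int, score_b: int) -> int:
    """Table-C combination (1..12) of adjusted scores A and B (each 1..12)."""
    key = (
        _check_range("score_a", score_a, 1, 12),
        _check_range("score_b", score_b, 1, 12),
    )
    return _table_c()[key]


@dataclass(frozen=True)
class RebaPostureObservation:
    """Joint-position categories plus adjustments for one observed posture."""

    trunk_score: int
    neck_score: int
    legs_score: int
    upper_arm_score: int
    lower_arm_score: int
    wrist_score: int
    load_force_score: int = 0
    coupling_score: int = 0
    activity_score: int = 0

    def __post_init__(self) -> None:
        _check_range("trunk_score", self.trunk_score, 1, 5)
        _check_range("neck_score", self.neck_score, 1, 3)
        _check_range("legs_score", self.legs_score, 1, 4)
        _check_range("upper_arm_score", self.upper_arm_score, 1, 6)
        _check_range("lower_arm_score", self.lower_arm_score, 1, 2)
        _check_range("wrist_score", self.wrist_score, 1, 3)
        _check_range("load_force_score", self.load_force_score, 0, 3)
        _check_range("coupling_score", self.coupling_score, 0, 3)
        _check_range("activity_score", self.activity_score, 0, 3)


def reba_final_score(obs: RebaPostureObservation) -> int:
    """Classic REBA final score, 1..15.

    score A = table A + load/force; score B = table B + coupling;
    score C = table C lookup; final = score C + activity.
    """
    score_a = (
        table_a_score(obs.trunk_score, obs.neck_score, obs.legs_score)
        + obs.load_force_score
    )
    score_b = (
        table_b_score(obs.upper_arm_score, obs.lower_arm_score, obs.wrist_score)
        + obs.coupling_score
    )
    return table_c_score(score_a, score_b) + obs.activity_score


def reba_final_from_profile(profile) -> int:
    """Classic REBA final score for an exposure profile.

    The profile already carries the group-A/group-B table scores, so
    tables A and B need not be re-entered; the REBA adjustments are
    derived from the profile's raw ratings:

    * load/force: max load weight < 5 kg -> 0, 5-10 kg -> 1, heavier -> 2,
      +1 for shock-like loading (rapid/sudden movement rated >= 3), cap 3;
    * coupling: the 0-4 coupling rating capped at REBA's 0-3 scale;
    * activity: +1 each for static, repetitive and rapid activity rated
      >= 2, capped at 3.

    This bridge is only used for method comparison on synthetic cohorts.
    """
    load_force = min(2, int(profile.load_weight_score))
    if profile.rapid_movement >= 3:
        load_force = min(3, load_force + 1)
    coupling = min(3, int(profile.coupling))
    activity = min(
        3,
        int(profile.static_activity >= 2)
        + int(profile.repetitive_activity >= 2)
        + int(profile.rapid_movement >= 2),
    )
    score_a = min(12, int(profile.posture_a) + load_force)
    score_b = min(12, int(profile.posture_b) + coupling)
    return table_c_score(score_a, score_b) + activity


def reba_action_level(
    final: int, breakpoints: tuple[int, int, int] = DEFAULT_ACTION_BREAKPOINTS
) -> int:
    """Map the final score onto a four-level ordinal risk category (1..4).

    The default breakpoints (4, 8, 11) follow the published REBA action
    levels with the two lowest merged: 1-3 -> 1, 4-7 -> 2, 8-10 -> 3,
    11-15 -> 4.  Pass different ``breakpoints`` to change the binning.
    """
    final = _check_range("final", final, 1, 15)
    if not (1 < breakpoints[0] < breakpoints[1] < breakpoints[2] <= 15):
        raise ValidationError(f"breakpoints must be increasing in 2..15: {breakpoints}")
    level = 1
    for bp in breakpoints:
        if final >= bp:
            level += 1
    return level
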