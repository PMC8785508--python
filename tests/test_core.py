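"""Unit and property tests for the weighted score equation."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from moreba.core import (
    DEFAULT_DIRECT_EFFECTS,
    DEFAULT_STRAIN_COEFFICIENT,
    FACTORS,
    ExposureProfile,
    RiskLevel,
    RiskThresholds,
    ValidationError,
    WeightSet,
    classify_risk,
    default_weights,
    derive_weights,
    force_subscore,
    load_subscore,
    moreba_score,
)

# Published indirect coefficients, used to pin the derivation algebra.
PRINTED_INDIRECT = {
    "posture_a": 0.734,
    "posture_b": 0.714,
    "coupling": 0.582,
    "contact_stress": 0.272,
    "load": 0.658,
    "force": 0.638,
    "static_activity": 0.585,
    "repetitive_activity": 0.586,
    "rapid_movement": 0.525,
    "throwing_motion": 0.588,
    "hand_arm_vibration": 0.349,
    "whole_body_vibration": 0.257,
    "air_temperature": 0.346,
    "work_rest_cycle": 0.481,
}


def profile_strategy():
    ords = {
        name: st.integers(0, 4)
        for name in FACTORS
        if name not in ("posture_a", "posture_b", "load", "force")
    }
    return st.builds(
        ExposureProfile,
        posture_a=st.integers(1, 9),
        posture_b=st.integers(1, 8),
        load_weight_score=st.integers(0, 4),
        load_time_score=st.integers(0, 4),
        force_value_score=st.integers(0, 4),
        work_time_score=st.integers(0, 4),
        **ords,
    )


@pytest.mark.parametrize(
    "func, a, b, expected",
    [
        (load_subscore, 4, 4, 4.0),
        (load_subscore, 0, 3, 0.0),
        (load_subscore, 2, 3, 1.5),
        (force_subscore, 4, 4, 4.0),
        (force_subscore, 1, 0, 0.0),
        (force_subscore, 3, 2, 1.5),
    ],
)
def test_subscores(func, a, b, expected):
    assert func(a, b) == expected


def test_subscore_range_error_names_field():
    with pytest.raises(ValidationError, match="load_time_score"):
        load_subscore(5, 2)
    with pytest.raises(ValidationError, match="force_value_score"):
        force_subscore(2, -1)


def test_derive_weights_reproduces_published_coefficients():
    ws = derive_weights()
    assert ws.indirect_effects == PRINTED_INDIRECT


@pytest.mark.parametrize(
    "direct, strain, expected",
    [(0.937, 0.783, 0.734), (0.328, 0.783, 0.257), (1.0, 1.0, 1.0)],
)
def test_weight_rounding_half_up(direct, strain, expected):
    ws = derive_weights(
        {f: direct for f in FACTORS}, strain_coefficient=strain
    )
    assert ws.indirect_effects["posture_a"] == expected


def test_derive_weights_reports_symmetric_difference():
    bad = dict(DEFAULT_DIRECT_EFFECTS)
    bad.pop("coupling")
    bad["postural_sway"] = 0.5
    with pytest.raises(ValidationError, match="coupling") as exc:
        derive_weights(bad)
    assert "postural_sway" in str(exc.value)


def test_nonfinite_weight_rejected():
    ind = dict(PRINTED_INDIRECT)
    ind["load"] = float("nan")
    with pytest.raises(ValidationError, match="load"):
        WeightSet(indirect_effects=ind)


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        (dict(posture_a=1, posture_b=1), 1.448),
        (dict(posture_a=1, posture_b=1, coupling=1), 2.030),
        (
            dict(
                posture_a=9,
                posture_b=9,
                coupling=4,
                contact_stress=4,
                static_activity=4,
                repetitive_activity=4,
                rapid_movement=4,
                throwing_motion=4,
                hand_arm_vibration=4,
                whole_body_vibration=4,
                air_temperature=4,
                work_rest_cycle=4,
                load_weight_score=4,
                load_time_score=4,
                force_value_score=4,
                work_time_score=4,
            ),
            36.500,
        ),
    ],
)
def test_score_anchor_points(kwargs, expected, recwarn):
    profile = ExposureProfile(**kwargs)
    assert moreba_score(profile) == pytest.approx(expected, abs=1e-9)


@given(profile_strategy())
def test_score_matches_brute_force_dot_product(profile):
    ws = default_weights()
    values = profile.factor_values()
    expected = 0.0
    for f in FACTORS:  # independent explicit loop, no vectorization
        expected += ws.indirect_effects[f] * values[f]
    assert abs(moreba_score(profile, ws) - expected) < 1e-12


@given(profile_strategy(), st.sampled_from(FACTORS))
def test_score_monotone_in_every_factor(profile, factor):
    import dataclasses

    ws = default_weights()
    base = moreba_score(profile, ws)
    if factor == "load":
        field, hi = "load_time_score", 4
    elif factor == "force":
        field, hi = "work_time_score", 4
    else:
        field, hi = factor, 8 if factor == "posture_b" else 9 if factor == "posture_a" else 4
    current = getattr(profile, field)
    if current >= hi:
        return
    bumped = dataclasses.replace(profile, **{field: current + 1})
    assert moreba_score(bumped, ws) >= base


def test_profile_rejects_out_of_range():
    with pytest.raises(ValidationError, match="posture_a"):
        ExposureProfile(posture_a=0, posture_b=1)
    with pytest.raises(ValidationError, match="coupling"):
        ExposureProfile(posture_a=1, posture_b=1, coupling=5)


def test_posture_b_above_observed_range_warns():
    with pytest.warns(UserWarning, match="posture_b=9"):
        ExposureProfile(posture_a=1, posture_b=9)


@pytest.mark.parametrize(
    "score, level",
    [
        (10.0, RiskLevel.LOW),
        (12.37, RiskLevel.MODERATE),
        (16.50, RiskLevel.MODERATE),
        (16.51, RiskLevel.HIGH),
        (24.35, RiskLevel.HIGH),
        (24.36, RiskLevel.VERY_HIGH),
    ],
)
def test_classification_boundaries(score, level):
    assert classify_risk(score) is level


@given(st.floats(min_value=-100, max_value=200, allow_nan=False))
def test_classification_partitions_the_line(score):
    assert classify_risk(score) in RiskLevel


def test_classification_rejects_nan():
    with pytest.raises(ValidationError):
        classify_risk(math.nan)


def test_thresholds_must_increase():
    with pytest.raises(ValidationError):
        RiskThresholds(10.0, 9.0, 20.0)


def test_all_levels_reachable_on_coarse_grid(recwarn):
    seen = set()
    for pa in (1, 3, 5, 7, 9):
        for ords in (0, 1, 2, 3, 4):
            p = ExposureProfile(
                posture_a=pa,
                posture_b=min(pa, 8),
                coupling=ords,
                contact_stress=ords,
                static_activity=ords,
                repetitive_activity=ords,
                rapid_movement=ords,
                throwing_motion=ords,
                hand_arm_vibration=ords,
                whole_body_vibration=ords,
                air_temperature=ords,
                work_rest_cycle=ords,
                load_weight_score=ords,
                load_time_score=ords,
                force_value_score=ords,
                work_time_score=ords,
            )
            seen.add(classify_risk(moreba_score(p)))
    assert seen == set(RiskLevel)


def test_default_strain_coefficient_is_published_value():
    assert DEFAULT_STRAIN_COEFFICIENT == 0.783
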