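"""Core MOREBA scoring: exposure model, weights, score equation, risk levels.

MOREBA (Modified Rapid Entire Body Assessment) scores whole-body
musculoskeletal-disorder risk as a weighted linear composite of 14
physical risk-factor scores.  The two posture factors are classic REBA
group-A/group-B table scores; the remaining factors are 0-4 ordinal
ratings, except load and force which are derived sub-scores::

    L = (t_L * W_L) / 4        (load-carrying time x max load weight)
    F = (t_w * V_F) / 4        (work time x max force value)

Each factor enters the score with an indirect-effect coefficient equal to
its direct loading on a latent physical-strain construct multiplied by the
strain -> symptoms path coefficient (0.783).  Scores are banded into four
risk levels by ROC-derived cutoffs.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

__all__ = [
    "FACTORS",
    "DEFAULT_DIRECT_EFFECTS",
    "DEFAULT_STRAIN_COEFFICIENT",
    "ExposureProfile",
    "WeightSet",
    "RiskThresholds",
    "RiskLevel",
    "ValidationError",
    "load_subscore",
    "force_subscore",
    "derive_weights",
    "default_weights",
    "moreba_score",
    "classify_risk",
]

#: Canonical factor order used in the score equation and everywhere a
#: factor vector appears (CSV columns, correlation matrices, weights).
FACTORS: tuple[str, ...] = (
    "posture_a",
    "posture_b",
    "coupling",
    "contact_stress",
    "load",
    "force",
    "static_activity",
    "repetitive_activity",
    "rapid_movement",
    "throwing_motion",
    "hand_arm_vibration",
    "whole_body_vibration",
    "air_temperature",
    "work_rest_cycle",
)

def _load_default_weight_config() -> dict:
    # Weights are data, not code: the canonical coefficient set ships as a
    # versioned JSON config so alternative sets can be dropped in.
    import json
    from importlib import resources

    with resources.files("moreba.data").joinpath("default_weights.json").open("r") as fh:
        return json.load(fh)


_DEFAULT_WEIGHT_CONFIG = _load_default_weight_config()

#: Standardized direct loadings of each factor on the latent strain
#: construct, estimated on a 300-worker steel-factory cohort.
DEFAULT_DIRECT_EFFECTS: dict[str, float] = dict(
    _DEFAULT_WEIGHT_CONFIG["direct_effects"]
)

#: Path coefficient of latent strain on musculoskeletal symptoms.
DEFAULT_STRAIN_COEFFICIENT: float = float(
    _DEFAULT_WEIGHT_CONFIG["strain_coefficient"]
)

#: Observed posture-B table scores only reached 8 in the development
#: cohort although the REBA table can emit 9; above this we warn.
_OBSERVED_POSTURE_B_MAX = 8


class ValidationError(ValueError):
    """An input violates the scoring rubric (range or type)."""


class RiskLevel(enum.IntEnum):
    """Ordered four-level musculoskeletal-disorder risk category."""

    LOW = 1
    MODERATE = 2
    HIGH = 3
    VERY_HIGH = 4

    def __str__(self) -> str:  # "LOW" -> "low" etc. for CSV output
        return self.name.lower()


def _check_ordinal(name: str, value: object, lo: int, hi: int) -> int:
    if isinstance(value, bool) or not isinstance(value, (int,)):
        # numpy integers pass through int() cleanly; accept them
        try:
            if value != int(value):  # type: ignore[arg-type]
                raise TypeError
            value = int(value)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise ValidationError(
                f"{name} must be an integer, got {value!r}"
            ) from None
    if not lo <= value <= hi:
        raise ValidationError(
            f"{name}={value} outside the rubric range {lo}..{hi}"
        )
    return int(value)


@dataclass(frozen=True)
class ExposureProfile:
    """One worker's raw MOREBA factor scores.

    Posture scores come from the classic REBA group-A (trunk/neck/legs)
    and group-B (upper arm/lower arm/wrist) lookup tables, 1..9.  All
    other raw fields are 0-4 ordinal ratings.  Load and force enter the
    score equation through derived sub-scores, see :func:`load_subscore`
    and :func:`force_subscore`.
    """

    posture_a: int
    posture_b: int
    coupling: int = 0
    contact_stress: int = 0
    static_activity: int = 0
    repetitive_activity: int = 0
    rapid_movement: int = 0
    throwing_motion: int = 0
    hand_arm_vibration: int = 0
    whole_body_vibration: int = 0
    air_temperature: int = 0
    work_rest_cycle: int = 0
    load_weight_score: int = 0  # W_L, max load weight
    load_time_score: int = 0  # t_L, load-carrying time
    force_value_score: int = 0  # V_F, max force value
    work_time_score: int = 0  # t_w, work time

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "posture_a", _check_ordinal("posture_a", self.posture_a, 1, 9)
        )
        object.__setattr__(
            self, "posture_b", _check_ordinal("posture_b", self.posture_b, 1, 9)
        )
        if self.posture_b > _OBSERVED_POSTURE_B_MAX:
            warnings.warn(
                f"posture_b={self.posture_b} exceeds the development-cohort "
                f"maximum of {_OBSERVED_POSTURE_B_MAX}; accepted (REBA table "
                "B can emit 9) but outside the calibration range",
                stacklevel=2,
            )
        for f in fields(self):
            if f.name in ("posture_a", "posture_b"):
                continue
            object.__setattr__(
                self, f.name, _check_ordinal(f.name, getattr(self, f.name), 0, 4)
            )

    @property
    def load(self) -> float:
        """Derived load sub-score L = (t_L * W_L) / 4."""
        return load_subscore(self.load_time_score, self.load_weight_score)

    @property
    def force(self) -> float:
        """Derived force sub-score F = (t_w * V_F) / 4."""
        return force_subscore(self.work_time_score, self.force_value_score)

    def factor_values(self) -> dict[str, float]:
        """The 14 factor values entering the score equation, in order."""
        out: dict[str, float] = {}
        for name in FACTORS:
            if name == "load":
                out[name] = self.load
            elif name == "force":
                out[name] = self.force
            else:
                out[name] = float(getattr(self, name))
        return out


def load_subscore(t_l: int, w_l: int) -> float:
    """Load sub-score L = (t_L x W_L) / 4.

    ``t_l`` is the load-carrying-time rating and ``w_l`` the maximum
    load-weight rating, both ordinal 0..4; the product is rescaled back
    onto 0..4.
    """
    t_l = _check_ordinal("load_time_score", t_l, 0, 4)
    w_l = _check_ordinal("load_weight_score", w_l, 0, 4)
    return (t_l * w_l) / 4.0


def force_subscore(t_w: int, v_f: int) -> float:
    """Force sub-score F = (t_w x V_F) / 4.

    ``t_w`` is the work-time rating and ``v_f`` the maximum force-value
    rating, both ordinal 0..4.
    """
    t_w = _check_ordinal("work_time_score", t_w, 0, 4)
    v_f = _check_ordinal("force_value_score", v_f, 0, 4)
    return (t_w * v_f) / 4.0


def _round_half_up(x: float, ndigits: int = 3) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class WeightSet:
    """Per-factor score-equation coefficients.

    ``indirect_effects`` are the coefficients actually used in the score
    equation; when derived via :func:`derive_weights` each equals
    round(direct x strain_coefficient, 3), half-up.
    """

    strain_coefficient: float = DEFAULT_STRAIN_COEFFICIENT
    direct_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIRECT_EFFECTS)
    )
    indirect_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.indirect_effects:
            object.__setattr__(
                self,
                "indirect_effects",
                {
                    f: _round_half_up(v * self.strain_coefficient)
                    for f, v in self.direct_effects.items()
                },
            )
        _require_all_factors(self.indirect_effects, what="indirect_effects")
        for name, coef in self.indirect_effects.items():
            if not math.isfinite(coef):
                raise ValidationError(f"non-finite weight for {name}: {coef!r}")

    def vector(self) -> list[float]:
        """Coefficients in canonical :data:`FACTORS` order."""
        return [float(self.indirect_effects[f]) for f in FACTORS]


def _require_all_factors(mapping: Mapping[str, float], what: str) -> None:
    got = set(mapping)
    want = set(FACTORS)
    if got != want:
        missing = sorted(want - got)
        extra = sorted(got - want)
        raise ValidationError(
            f"{what} must cover exactly the 14 MOREBA factors; "
            f"missing={missing}, unexpected={extra}"
        )


def derive_weights(
    direct_effects: Mapping[str, float] | None = None,
    strain_coefficient: float = DEFAULT_STRAIN_COEFFICIENT,
) -> WeightSet:
    """Build a :class:`WeightSet` from direct loadings and the strain path.

    Each factor's score-equation weight is its direct loading on latent
    strain times the strain -> symptoms coefficient, rounded half-up to
    three decimals (the precision the coefficients are reported at).

    Raises
    ------
    ValidationError
        If the factor set is not exactly the 14 MOREBA factors, or a
        coefficient lies outside (0, 1].
    """
    if direct_effects is None:
        direct_effects = dict(DEFAULT_DIRECT_EFFECTS)
    _require_all_factors(direct_effects, what="direct_effects")
    for name, coef in direct_effects.items():
        if not (0.0 < coef <= 1.0) or not math.isfinite(coef):
            raise ValidationError(
                f"direct effect for {name} must lie in (0, 1], got {coef!r}"
            )
    if not (0.0 < strain_coefficient <= 1.0):
        raise ValidationError(
            f"strain_coefficient must lie in (0, 1], got {strain_coefficient!r}"
        )
    return WeightSet(
        strain_coefficient=strain_coefficient,
        direct_effects=dict(direct_effects),
    )


def default_weights() -> WeightSet:
    """The published coefficient set (strain path 0.783)."""
    return derive_weights()


def moreba_score(profile: ExposureProfile, weights: WeightSet | None = None) -> float:
    """Weighted linear MOREBA score of one exposure profile.

    With the default weights and valid inputs the score lies in
    [1.448, 36.500]; it is non-decreasing in every factor.
    """
    if weights is None:
        weights = default_weights()
    values = profile.factor_values()
    return float(
        sum(weights.indirect_effects[f] * values[f] for f in FACTORS)
    )


@dataclass(frozen=True)
class RiskThresholds:
    """Three score cutoffs partitioning MOREBA scores into four levels.

    Defaults are the ROC-derived optimal cutoffs (nearest point to the
    sensitivity = specificity = 1 corner) from the development cohort.
    """

    low_moderate: float = 12.37
    moderate_high: float = 16.51
    high_very_high: float = 24.35

    def __post_init__(self) -> None:
        if not (self.low_moderate < self.moderate_high < self.high_very_high):
            raise ValidationError(
                "thresholds must be strictly increasing: "
                f"{self.low_moderate}, {self.moderate_high}, {self.high_very_high}"
            )


def classify_risk(
    score: float, thresholds: RiskThresholds | None = None
) -> RiskLevel:
    """Map a MOREBA score onto the four-level risk scale.

    Partition (total and disjoint over the reals):

    * LOW        score <  low_moderate
    * MODERATE   low_moderate <= score < moderate_high
    * HIGH       moderate_high <= score <= high_very_high
    * VERY_HIGH  score >  high_very_high

    The published banding leaves boundary inclusivity implicit; these
    half-open/closed choices are configurable via ``thresholds``.
    """
    if thresholds is None:
        thresholds = RiskThresholds()
    score = float(score)
    if math.isnan(score):
        raise ValidationError("cannot classify a NaN score")
    if score < thresholds.low_moderate:
        return RiskLevel.LOW
    if score < thresholds.moderate_high:
        return RiskLevel.MODERATE
    if score <= thresholds.high_very_high:
        return RiskLevel.HIGH
    return RiskLevel.VERY_HIGH
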