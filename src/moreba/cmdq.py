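"""Cornell Musculoskeletal Discomfort Questionnaire (CMDQ) scoring.

Each body-region item asks how often discomfort occurred during the last
week, how severe it was, and how much it interfered with work.  The item
score is the product of the three category weights (frequency 0 / 1.5 /
3.5 / 5 / 10, severity 1..3, interference 1..3); the questionnaire total
is the sum over items.  Totals are banded into four risk levels at
450 / 900 / 1350, the banding used to binarize the criterion when
deriving score cutoffs by ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import ValidationError

__all__ = [
    "FREQUENCY_WEIGHTS",
    "SEVERITY_WEIGHTS",
    "INTERFERENCE_WEIGHTS",
    "REGIONS_12",
    "REGIONS_BILATERAL",
    "DEFAULT_BAND_BOUNDARIES",
    "CmdqItem",
    "CmdqResult",
    "item_score",
    "total_score",
    "cmdq_band",
    "score_responses",
]

FREQUENCY_WEIGHTS: dict[str, float] = {
    "never": 0.0,
    "1-2/week": 1.5,
    "3-4/week": 3.5,
    "daily": 5.0,
    "several/day": 10.0,
}

SEVERITY_WEIGHTS: dict[str, float] = {
    "slight": 1.0,
    "moderate": 2.0,
    "very": 3.0,
}

INTERFERENCE_WEIGHTS: dict[str, float] = {
    "none": 1.0,
    "slight": 2.0,
    "substantial": 3.0,
}

#: The 12 body regions of the standard questionnaire body map.
REGIONS_12: tuple[str, ...] = (
    "neck",
    "shoulder",
    "upper_back",
    "upper_arm",
    "lower_back",
    "forearm",
    "wrist",
    "hip",
    "thigh",
    "knee",
    "lower_leg",
    "foot",
)

#: The 20-item layout with the 8 paired regions split left/right, as on
#: the printed body map (12 anatomical regions, 20 questionnaire items).
REGIONS_BILATERAL: tuple[str, ...] = tuple(
    f"{r}_{side}"
    if r in ("shoulder", "upper_arm", "forearm", "wrist", "thigh", "knee", "lower_leg", "foot")
    else r
    for r in REGIONS_12
    for side in (("left", "right") if r in (
        "shoulder", "upper_arm", "forearm", "wrist", "thigh", "knee", "lower_leg", "foot"
    ) else ("",))
)

DEFAULT_BAND_BOUNDARIES: tuple[float, float, float] = (450.0, 900.0, 1350.0)


def _weight(table: dict[str, float], value: str | float, what: str) -> float:
    """Resolve a category label (case-insensitive) or literal weight."""
    if isinstance(value, str):
        key = value.strip().lower()
        if key not in table:
            raise ValidationError(
                f"unknown {what} category {value!r}; expected one of "
                f"{sorted(table)}"
            )
        return table[key]
    w = float(value)
    if w not in table.values():
        raise ValidationError(
            f"{what} weight {value!r} is not one of {sorted(set(table.values()))}"
        )
    return w


@dataclass(frozen=True)
class CmdqItem:
    """One body-region response: frequency, severity, interference."""

    region: str
    frequency: str | float = "never"
    severity: str | float = "slight"
    interference: str | float = "none"

    @property
    def score(self) -> float:
        return item_score(self.frequency, self.severity, self.interference)


@dataclass(frozen=True)
class CmdqResult:
    """Scored questionnaire: per-item scores, total, and risk band."""

    item_scores: dict[str, float]
    total: float
    band: int


def item_score(
    frequency: str | float, severity: str | float, interference: str | float
) -> float:
    """Product of the frequency, severity and interference weights."""
    return (
        _weight(FREQUENCY_WEIGHTS, frequency, "frequency")
        * _weight(SEVERITY_WEIGHTS, severity, "severity")
        * _weight(INTERFERENCE_WEIGHTS, interference, "interference")
    )


def total_score(items: Iterable[CmdqItem]) -> float:
    """Sum of item scores; 0 for an empty or all-'never' questionnaire."""
    return float(sum(item.score for item in items))


def cmdq_band(
    total: float,
    boundaries: Sequence[float] = DEFAULT_BAND_BOUNDARIES,
) -> int:
    """Four-level discomfort band of a questionnaire total.

    Left-closed banding: band 1 if total < boundaries[0], band k+1 if
    boundaries[k-1] <= total < boundaries[k], band 4 if
    total >= boundaries[2].
    """
    total = float(total)
    if total < 0:
        raise ValidationError(f"CMDQ total cannot be negative: {total}")
    b1, b2, b3 = (float(b) for b in boundaries)
    if not (0 < b1 < b2 < b3):
        raise ValidationError(f"band boundaries must be increasing: {boundaries}")
    band = 1
    for b in (b1, b2, b3):
        if total >= b:
            band += 1
    return band


def score_responses(
    items: Iterable[CmdqItem],
    boundaries: Sequence[float] = DEFAULT_BAND_BOUNDARIES,
) -> CmdqResult:
    """Score a full questionnaire and band the total."""
    per_region: dict[str, float] = {}
    for item in items:
        if item.region in per_region:
            raise ValidationError(f"duplicate region {item.region!r} in responses")
        per_region[item.region] = item.score
    total = float(sum(per_region.values()))
    return CmdqResult(item_scores=per_region, total=total, band=cmdq_band(total, boundaries))
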