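"""Development/validation computations for the weighted risk score.

Covers the statistical machinery of the score's development procedure:

* Fisher-z sample-size formula for detecting a minimum correlation;
* ROC analysis: Mann-Whitney AUC, nearest-to-ideal optimal cutoffs, and
  derivation of the three score cutoffs from questionnaire band
  boundaries (450 / 900 / 1350);
* simple-OLS R-squared for comparing how much symptom variation each
  method explains;
* four-level risk frequency distributions;
* measurement-quality indices (average variance extracted, composite
  reliability) from standardized loadings;
* an end-to-end pipeline on synthetic cohorts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cmdq import DEFAULT_BAND_BOUNDARIES, cmdq_band
from .core import (
    FACTORS,
    RiskLevel,
    RiskThresholds,
    ValidationError,
    WeightSet,
    classify_risk,
    default_weights,
    moreba_score,
)
from .reba import reba_action_level, reba_final_from_profile
from .simulate import PopulationSpec, generate_cmdq, generate_profiles

__all__ = [
    "RocAnalysis",
    "fisher_z",
    "sample_size",
    "auc",
    "roc_points",
    "optimal_cutoff",
    "roc_analysis",
    "derive_thresholds",
    "r_squared",
    "risk_distribution",
    "measurement_quality",
    "run_validation",
]


def fisher_z(r: float) -> float:
    """Fisher z-transform w = 0.5 * ln((1+r)/(1-r)) = arctanh(r)."""
    if not -1.0 < r < 1.0:
        raise ValidationError(f"correlation must lie in (-1, 1), got {r}")
    return math.atanh(r)


def sample_size(
    r_min: float,
    z_alpha: float = 1.96,
    z_beta: float = 1.29,
    w: float | None = None,
) -> int:
    """Minimum n to detect a correlation of at least ``r_min``.

    Standard Fisher-z formula n = ((z_alpha + z_beta) / w)^2 + 3 with
    w = arctanh(r_min), rounded to the nearest integer.  ``w`` may be
    supplied directly to reproduce a computation done with a rounded
    transform (e.g. w = 0.203 for r = 0.2 gives n = 259; the unrounded
    w = 0.20273 gives 260).
    """
    if not 0.0 < r_min < 1.0:
        raise ValidationError(f"r_min must lie in (0, 1), got {r_min}")
    if w is None:
        w = fisher_z(r_min)
    if w <= 0:
        raise ValidationError(f"w must be positive, got {w}")
    return int(round(((z_alpha + z_beta) / w) ** 2 + 3))


def _check_binary(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be 1-d and equal length")
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1}:
        raise ValidationError(f"labels must be binary 0/1, got {sorted(uniq)}")
    if uniq != {0, 1}:
        raise ValidationError("labels contain a single class; ROC/AUC undefined")
    return s, y.astype(int)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(random positive outscores a random negative),
    ties counted half (midranks)."""
    s, y = _check_binary(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(
    scores: Sequence[float], labels: Sequence[int]
) -> list[tuple[float, float, float]]:
    """ROC curve as (1 - specificity, sensitivity, threshold) triples.

    Thresholds sit at midpoints between sorted unique scores, plus one
    below the minimum and one above the maximum; a case is predicted
    positive when score >= threshold.  Points are ordered by increasing
    threshold.
    """
    s, y = _check_binary(scores, labels)
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.empty(0)
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    pts = []
    for t in thresholds:
        pred = s >= t
        sens = float((pred & (y == 1)).sum() / n_pos)
        spec = float((~pred & (y == 0)).sum() / n_neg)
        pts.append((1.0 - spec, sens, float(t)))
    return pts


def optimal_cutoff(
    points: Sequence[tuple[float, float, float]],
) -> tuple[float, float, float]:
    """Nearest-to-ideal ROC point: minimizes the Euclidean distance
    sqrt((1-sens)^2 + (1-spec)^2) to the perfect-classification corner.

    Returns (cutoff, sensitivity, specificity); ties broken toward the
    lower cutoff.
    """
    if not points:
        raise ValidationError("empty ROC curve")
    best = None
    for fpr, sens, thr in sorted(points, key=lambda p: p[2]):
        d = math.hypot(1.0 - sens, fpr)
        if best is None or d < best[0] - 1e-12:
            best = (d, thr, sens, 1.0 - fpr)
    assert best is not None
    return best[1], best[2], best[3]


@dataclass(frozen=True)
class RocAnalysis:
    """One boundary's ROC summary."""

    boundary: float
    points: list[tuple[float, float, float]]
    auc: float
    optimal_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float


def roc_analysis(
    scores: Sequence[float], totals: Sequence[float], boundary: float
) -> RocAnalysis:
    """ROC of score against the questionnaire total binarized at ``boundary``."""
    totals = np.asarray(totals, dtype=float)
    labels = (totals >= boundary).astype(int)
    if labels.min() == labels.max():
        raise ValidationError(
            f"boundary {boundary}: all cases fall on one side; ROC undefined"
        )
    pts = roc_points(scores, labels)
    cut, sens, spec = optimal_cutoff(pts)
    return RocAnalysis(
        boundary=float(boundary),
        points=pts,
        auc=auc(scores, labels),
        optimal_cutoff=cut,
        sens_at_cutoff=sens,
        spec_at_cutoff=spec,
    )


def derive_thresholds(
    scores: Sequence[float],
    cmdq_totals: Sequence[float],
    band_boundaries: Sequence[float] = DEFAULT_BAND_BOUNDARIES,
) -> RiskThresholds:
    """Derive the three score cutoffs from questionnaire band boundaries.

    For each boundary the questionnaire total is binarized and the
    nearest-to-ideal ROC cutoff of the score is taken.  The three cutoffs
    must come out strictly increasing, else the cohort does not support a
    four-level banding and an error is raised.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) and scores.min() == scores.max():
        raise ValidationError("all scores identical; no discrimination possible")
    cuts = []
    for b in band_boundaries:
        try:
            cuts.append(roc_analysis(scores, cmdq_totals, b).optimal_cutoff)
        except ValidationError as err:
            raise ValidationError(f"band boundary {b}: {err}") from None
    if not (cuts[0] < cuts[1] < cuts[2]):
        raise ValidationError(
            f"derived cutoffs are not strictly increasing: {cuts}"
        )
    return RiskThresholds(*cuts)


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation = R-squared of simple OLS of y on x.

    Returns 0 (with a warning) when either variable has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("x and y must be equal-length 1-d with n >= 2")
    if np.var(x) == 0 or np.var(y) == 0:
        warnings.warn("zero-variance input; R-squared set to 0 by convention")
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def risk_distribution(levels: Sequence[int]) -> dict[str, dict[int, float]]:
    """Counts and relative frequencies of the four risk levels.

    Accepts RiskLevel members or integers 1..4; frequencies sum to 1
    (all-zero for empty input).
    """
    counts = {level: 0 for level in (1, 2, 3, 4)}
    for lv in levels:
        lv = int(lv)
        if lv not in counts:
            raise ValidationError(f"risk level must be 1..4, got {lv}")
        counts[lv] += 1
    n = sum(counts.values())
    freqs = {lv: (c / n if n else 0.0) for lv, c in counts.items()}
    return {"counts": counts, "frequencies": freqs}


def measurement_quality(
    direct_effects: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Average variance extracted and composite reliability of a
    single-factor measurement model with standardized loadings.

    AVE = mean(lambda^2); CR = (sum lambda)^2 / ((sum lambda)^2 +
    sum(1 - lambda^2)).
    """
    if direct_effects is None:
        direct_effects = default_weights().direct_effects
    lam = np.asarray(list(direct_effects.values()), dtype=float)
    if len(lam) == 0 or not np.isfinite(lam).all():
        raise ValidationError("loadings must be a non-empty finite collection")
    ave = float(np.mean(lam**2))
    s = float(lam.sum())
    cr = s**2 / (s**2 + float(np.sum(1.0 - lam**2)))
    return {"ave": ave, "composite_reliability": float(cr)}


def _bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    level: float = 0.95,
) -> tuple[float, float]:
    n = len(scores)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        y = labels[idx]
        if y.min() == y.max():
            continue
        vals.append(auc(scores[idx], y))
    if not vals:
        return (float("nan"), float("nan"))
    lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def run_validation(
    spec: PopulationSpec | None = None,
    weights: WeightSet | None = None,
    band_boundaries: Sequence[float] = DEFAULT_BAND_BOUNDARIES,
    n_bootstrap: int = 200,
) -> dict:
    """End-to-end development pipeline on a synthetic cohort.

    Simulates profiles and questionnaire totals, scores the cohort with
    both the weighted method and classic REBA, derives ROC cutoffs from
    the questionnaire bands, and compares explained variance and risk
    distributions.  Fully deterministic under ``spec.seed``.
    """
    if spec is None:
        spec = PopulationSpec()
    if weights is None:
        weights = default_weights()
    profiles = generate_profiles(spec)
    totals = generate_cmdq(profiles, weights, spec)
    scores = np.array([moreba_score(p, weights) for p in profiles])
    reba_finals = np.array([reba_final_from_profile(p) for p in profiles])

    rocs = []
    for b in band_boundaries:
        try:
            ra = roc_analysis(scores, totals, b)
        except ValidationError as err:
            rocs.append({"boundary": float(b), "error": str(err)})
            continue
        ci = _bootstrap_auc_ci(
            scores,
            (np.asarray(totals) >= b).astype(int),
            n_bootstrap,
            np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2,))),
        )
        rocs.append(
            {
                "boundary": ra.boundary,
                "auc": ra.auc,
                "auc_ci95": list(ci),
                "optimal_cutoff": ra.optimal_cutoff,
                "sensitivity": ra.sens_at_cutoff,
                "specificity": ra.spec_at_cutoff,
            }
        )

    report: dict = {
        "n": spec.n,
        "seed": spec.seed,
        "roc": rocs,
        "r_squared": {
            "moreba": r_squared(scores, totals),
            "reba": r_squared(reba_finals, totals),
        },
    }
    try:
        thresholds = derive_thresholds(scores, totals, band_boundaries)
        report["derived_thresholds"] = [
            thresholds.low_moderate,
            thresholds.moderate_high,
            thresholds.high_very_high,
        ]
    except ValidationError as err:
        thresholds = None
        report["derived_thresholds_error"] = str(err)

    cls_thresholds = thresholds if thresholds is not None else RiskThresholds()
    moreba_levels = [int(classify_risk(s, cls_thresholds)) for s in scores]
    reba_levels = [reba_action_level(int(f)) for f in reba_finals]
    cmdq_levels = [cmdq_band(t, band_boundaries) for t in totals]
    report["risk_distributions"] = {
        "cmdq": risk_distribution(cmdq_levels),
        "reba": risk_distribution(reba_levels),
        "moreba": risk_distribution(moreba_levels),
    }
    return report
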