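"""Synthetic worker cohorts with realistic exposure structure.

Generates exposure profiles whose marginal distributions match the
development cohort (per-factor mean/SD on each ordinal scale) and whose
inter-factor correlations match the cohort's observed correlation matrix,
via a Gaussian copula: a latent multivariate-normal draw is mapped
factor-by-factor onto the integer scale by quantile discretization
against a truncated normal with the target mean/SD.

Questionnaire outcomes (CMDQ totals) come from a latent-strain model: the
outcome is an affine function of the weighted exposure score plus
Gaussian noise, calibrated so that a simple linear regression of outcome
on score explains a target share of variance (default 67%), and floored
at zero like the real bounded questionnaire total.

No generative model for the original cohort was published; everything
here is this package's own emulation, intended as a test bed for the
validation pipeline rather than as a claim about real workplaces.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core import FACTORS, ExposureProfile, WeightSet, default_weights, moreba_score

__all__ = [
    "MarginalSpec",
    "OutcomeSpec",
    "PopulationSpec",
    "DEFAULT_MARGINALS",
    "DEFAULT_CORRELATION",
    "generate_profiles",
    "generate_cmdq",
    "calibrate_outcome",
    "nearest_psd_correlation",
]


@dataclass(frozen=True)
class MarginalSpec:
    """Target marginal for one ordinal factor: integer range + moments."""

    lo: int
    hi: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.hi <= self.lo:
            raise ValueError(f"empty range {self.lo}..{self.hi}")
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")


#: Development-cohort marginals (observed range, mean, SD) per factor.
DEFAULT_MARGINALS: dict[str, MarginalSpec] = {
    "posture_a": MarginalSpec(1, 9, 4.76, 1.93),
    "posture_b": MarginalSpec(1, 8, 4.66, 2.02),
    "coupling": MarginalSpec(0, 4, 1.29, 1.28),
    "contact_stress": MarginalSpec(0, 4, 0.52, 0.28),
    "load": MarginalSpec(0, 4, 0.94, 0.69),
    "force": MarginalSpec(0, 4, 1.27, 1.20),
    "static_activity": MarginalSpec(0, 4, 2.29, 1.06),
    "repetitive_activity": MarginalSpec(0, 4, 2.09, 1.19),
    "rapid_movement": MarginalSpec(0, 4, 1.24, 1.21),
    "throwing_motion": MarginalSpec(0, 4, 1.14, 0.98),
    "hand_arm_vibration": MarginalSpec(0, 4, 1.14, 0.65),
    "whole_body_vibration": MarginalSpec(0, 4, 1.01, 0.47),
    "air_temperature": MarginalSpec(0, 4, 1.24, 1.15),
    "work_rest_cycle": MarginalSpec(0, 4, 2.78, 0.77),
}

# Development-cohort correlation matrix over the 14 factors, in FACTORS
# order (lower triangle as observed; symmetrized here).
_CORR_LOWER: list[list[float]] = [
    [],
    [0.843],
    [0.698, 0.734],
    [0.327, 0.301, 0.119],
    [0.760, 0.793, 0.590, 0.315],
    [0.746, 0.765, 0.583, 0.281, 0.695],
    [0.653, 0.705, 0.523, 0.364, 0.646, 0.600],
    [0.687, 0.727, 0.512, 0.361, 0.589, 0.606, 0.581],
    [0.610, 0.635, 0.450, 0.224, 0.580, 0.536, 0.517, 0.491],
    [0.703, 0.692, 0.506, 0.290, 0.673, 0.633, 0.587, 0.531, 0.483],
    [0.397, 0.404, 0.325, 0.143, 0.383, 0.387, 0.353, 0.325, 0.291, 0.280],
    [0.260, 0.357, 0.257, 0.076, 0.298, 0.260, 0.191, 0.184, 0.165, 0.273, 0.192],
    [0.394, 0.394, 0.368, 0.103, 0.383, 0.319, 0.343, 0.281, 0.297, 0.316, 0.333, 0.173],
    [0.550, 0.572, 0.440, 0.203, 0.501, 0.534, 0.442, 0.526, 0.438, 0.458, 0.504, 0.175, 0.333],
]


def _build_default_correlation() -> np.ndarray:
    k = len(FACTORS)
    mat = np.eye(k)
    for i, row in enumerate(_CORR_LOWER):
        for j, r in enumerate(row):
            mat[i, j] = mat[j, i] = r
    return mat


DEFAULT_CORRELATION: np.ndarray = _build_default_correlation()
DEFAULT_CORRELATION.setflags(write=False)


@dataclass(frozen=True)
class OutcomeSpec:
    """Latent-strain outcome model for questionnaire totals."""

    target_r2: float = 0.67
    outcome_mean: float = 536.82
    outcome_sd: float = 511.51
    floor_at_zero: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.target_r2 <= 1.0:
            raise ValueError(f"target_r2 must be in (0, 1], got {self.target_r2}")
        if self.outcome_sd <= 0:
            raise ValueError("outcome_sd must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """Full recipe for one synthetic cohort."""

    n: int = 300
    seed: int = 0
    marginals: dict[str, MarginalSpec] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_CORRELATION.copy()
    )
    outcome: OutcomeSpec = field(default_factory=OutcomeSpec)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if set(self.marginals) != set(FACTORS):
            raise ValueError("marginals must cover exactly the 14 factors")
        corr = np.asarray(self.correlation, dtype=float)
        k = len(FACTORS)
        if corr.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k}, got {corr.shape}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have a unit diagonal")
        object.__setattr__(self, "correlation", corr)

    def with_(self, **changes) -> "PopulationSpec":
        return replace(self, **changes)


def nearest_psd_correlation(
    corr: np.ndarray, min_eigenvalue: float = 1e-10, max_adjustment: float = 0.05
) -> np.ndarray:
    """Repair a near-PSD correlation matrix by eigenvalue clipping.

    Rounded published correlations can be slightly indefinite; negative
    eigenvalues are clipped to ``min_eigenvalue`` and the matrix rescaled
    back to unit diagonal.  A matrix needing more repair than
    ``max_adjustment`` (smallest eigenvalue below -max_adjustment) is
    rejected as genuinely invalid.
    """
    corr = np.asarray(corr, dtype=float)
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals[0] >= 0:
        return corr
    if eigvals[0] < -max_adjustment:
        raise ValueError(
            f"correlation matrix is not positive semi-definite beyond repair "
            f"tolerance: smallest eigenvalue {eigvals[0]:.6f}"
        )
    clipped = np.clip(eigvals, min_eigenvalue, None)
    repaired = (eigvecs * clipped) @ eigvecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _discrete_pmf(m: MarginalSpec, loc: float, scale: float) -> np.ndarray:
    """Pmf over the integer levels: normal(loc, scale) truncated to
    [lo-0.5, hi+0.5] and binned at half-integer edges."""
    levels = np.arange(m.lo, m.hi + 1)
    a = (m.lo - 0.5 - loc) / scale
    b = (m.hi + 0.5 - loc) / scale
    edges = np.concatenate(([m.lo - 0.5], levels + 0.5))
    cdf = stats.truncnorm.cdf(edges, a, b, loc=loc, scale=scale)
    probs = np.diff(cdf)
    return probs / probs.sum()


@functools.lru_cache(maxsize=256)
def _matched_quantile_table(m: MarginalSpec) -> tuple[np.ndarray, np.ndarray]:
    """Moment-matched discretization of one marginal.

    Discretizing a truncated normal shifts its moments (truncation pulls
    the mean toward the scale centre, binning adds granularity), so
    using the target mean/SD directly as the parent parameters biases
    the generated means.  Here the parent (loc, scale) are solved by
    least squares so that the *discretized* distribution reproduces the
    target mean and, as far as the integer lattice allows, the target SD.
    """
    levels = np.arange(m.lo, m.hi + 1).astype(float)

    def residuals(theta: np.ndarray) -> np.ndarray:
        loc, log_scale = theta
        p = _discrete_pmf(m, loc, float(np.exp(log_scale)))
        mean = float(p @ levels)
        sd = float(np.sqrt(p @ (levels - mean) ** 2))
        return np.array([mean - m.mean, sd - m.sd])

    fit = optimize.least_squares(
        residuals, x0=np.array([m.mean, np.log(m.sd)]), method="lm"
    )
    loc, scale = float(fit.x[0]), float(np.exp(fit.x[1]))
    probs = _discrete_pmf(m, loc, scale)
    return levels.astype(int), np.cumsum(probs)


def _profiles_from_factor_matrix(values: np.ndarray) -> list[ExposureProfile]:
    """Turn an (n, 14) integer factor matrix into exposure profiles.

    The composite load/force levels v are decomposed into raw components
    as (time=v, weight/value=4), with v=0 -> (0, 0), so the sub-score
    formulas reproduce v exactly.
    """
    idx = {f: i for i, f in enumerate(FACTORS)}
    profiles = []
    for row in values:
        load_v = int(row[idx["load"]])
        force_v = int(row[idx["force"]])
        profiles.append(
            ExposureProfile(
                posture_a=int(row[idx["posture_a"]]),
                posture_b=int(row[idx["posture_b"]]),
                coupling=int(row[idx["coupling"]]),
                contact_stress=int(row[idx["contact_stress"]]),
                static_activity=int(row[idx["static_activity"]]),
                repetitive_activity=int(row[idx["repetitive_activity"]]),
                rapid_movement=int(row[idx["rapid_movement"]]),
                throwing_motion=int(row[idx["throwing_motion"]]),
                hand_arm_vibration=int(row[idx["hand_arm_vibration"]]),
                whole_body_vibration=int(row[idx["whole_body_vibration"]]),
                air_temperature=int(row[idx["air_temperature"]]),
                work_rest_cycle=int(row[idx["work_rest_cycle"]]),
                load_time_score=load_v,
                load_weight_score=4 if load_v else 0,
                work_time_score=force_v,
                force_value_score=4 if force_v else 0,
            )
        )
    return profiles


def _rng(spec: PopulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(stream,)))


def generate_profiles(spec: PopulationSpec) -> list[ExposureProfile]:
    """Draw a cohort of exposure profiles from the copula model.

    Deterministic under a fixed spec + seed.  The latent correlation
    matrix is PSD-repaired if needed; heavily indefinite matrices raise.
    """
    corr = nearest_psd_correlation(spec.correlation)
    if spec.n == 0:
        return []
    rng = _rng(spec, stream=0)
    # Latent Gaussian draw via Cholesky of the (jittered) repaired matrix.
    try:
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(FACTORS)))
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(corr + 1e-6 * np.eye(len(FACTORS)))
    z = rng.standard_normal((spec.n, len(FACTORS))) @ chol.T
    u = stats.norm.cdf(z)
    values = np.empty((spec.n, len(FACTORS)), dtype=int)
    for j, name in enumerate(FACTORS):
        levels, cum = _matched_quantile_table(spec.marginals[name])
        values[:, j] = levels[np.searchsorted(cum, u[:, j], side="left").clip(0, len(levels) - 1)]
    return _profiles_from_factor_matrix(values)


def calibrate_outcome(signal_variance: float, target_r2: float) -> float:
    """Closed-form noise SD giving an exact population R-squared.

    For outcome = a + b*score + eps with Var(b*score) = ``signal_variance``,
    the infinite-sample OLS R-squared equals ``target_r2`` when

        sd(eps) = sqrt(signal_variance * (1 - R2) / R2).
    """
    if not 0.0 < target_r2 <= 1.0:
        raise ValueError(f"target_r2 must be in (0, 1], got {target_r2}")
    if signal_variance < 0:
        raise ValueError("signal_variance must be non-negative")
    return float(np.sqrt(signal_variance * (1.0 - target_r2) / target_r2))


def _censored_r2(scores: np.ndarray, a: float, b: float, sd: float) -> float:
    """Population R-squared of score vs max(a + b*score + eps, 0).

    Exact over the Gaussian noise (conditional moments of the censored
    normal), averaged over the realized score distribution.
    """
    c = a + b * scores
    if sd == 0:
        y_mean = np.maximum(c, 0.0)
        y_sq = y_mean**2
    else:
        z = c / sd
        phi = stats.norm.pdf(z)
        Phi = stats.norm.cdf(z)
        y_mean = c * Phi + sd * phi
        y_sq = (c**2 + sd**2) * Phi + c * sd * phi
    var_y = float(np.mean(y_sq) - np.mean(y_mean) ** 2)
    cov = float(np.mean(scores * y_mean) - np.mean(scores) * np.mean(y_mean))
    var_s = float(np.var(scores))
    if var_y <= 0 or var_s <= 0:
        return 0.0
    return cov**2 / (var_s * var_y)


def generate_cmdq(
    profiles: Sequence[ExposureProfile],
    weights: WeightSet | None = None,
    spec: PopulationSpec | None = None,
) -> np.ndarray:
    """Simulate questionnaire totals from the latent-strain model.

    outcome_i = a + b * score_i + eps_i, floored at zero when
    ``spec.outcome.floor_at_zero``.  The slope matches the target
    R-squared share of the outcome variance (b = sqrt(R2) * sd_out / sd_s),
    the intercept matches the outcome mean, and the noise SD comes from
    :func:`calibrate_outcome`; with flooring on, the noise SD is further
    adjusted (1-d root solve on the exact censored-normal moments) so the
    floored cohort still attains the target R-squared.
    """
    if weights is None:
        weights = default_weights()
    if spec is None:
        spec = PopulationSpec(n=len(profiles))
    out = spec.outcome
    scores = np.array([moreba_score(p, weights) for p in profiles], dtype=float)
    n = len(scores)
    if n == 0:
        return np.empty(0)
    sd_s = float(scores.std())
    if sd_s == 0:
        raise ValueError("degenerate cohort: all scores identical")
    b = float(np.sqrt(out.target_r2) * out.outcome_sd / sd_s)
    a = float(out.outcome_mean - b * scores.mean())
    sd_eps = calibrate_outcome(b**2 * sd_s**2, out.target_r2)
    if out.floor_at_zero and sd_eps > 0:
        # Censoring at zero attenuates R^2; shrink the noise so the
        # censored population R^2 still hits the target, when reachable.
        f = lambda sd: _censored_r2(scores, a, b, sd) - out.target_r2
        if f(1e-9) > 0 and f(sd_eps) < 0:
            sd_eps = float(optimize.brentq(f, 1e-9, sd_eps, xtol=1e-6 * sd_eps))
    rng = _rng(spec, stream=1)
    y = a + b * scores + rng.normal(0.0, sd_eps, size=n) if sd_eps > 0 else a + b * scores
    if out.floor_at_zero:
        y = np.maximum(y, 0.0)
    return y
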