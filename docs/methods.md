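# Methods

## The weighted risk score

The score is a linear composite of 14 physical risk-factor values. The
two posture factors are classic REBA group-A (trunk/neck/legs, 1–9) and
group-B (upper arm/lower arm/wrist, 1–9) table scores; ten factors are
0–4 ordinal ratings; load and force are derived sub-scores
`L = t_L·W_L/4` and `F = t_w·V_F/4` mapping the product of two 0–4
ratings back onto 0–4. Each factor's weight is its standardized direct
loading on a latent physical-strain construct multiplied by the
strain→symptoms path coefficient (0.783), rounded **half-up to three
decimals** — the precision at which the coefficient set is published and
distributed (`moreba/data/default_weights.json`; weights are data, not
code, so alternative coefficient sets can be loaded). With the default
weights the score spans [1.448, 36.500] and is non-decreasing in every
factor.

The structural model itself is *not* re-estimated here; the package
consumes the published loadings and verifies their internal algebra
(every published indirect coefficient equals round(direct × 0.783, 3),
and the mean indirect/direct ratio recovers 0.783). Measurement quality
is summarized by AVE = mean(λ²) and composite reliability
CR = (Σλ)²/((Σλ)² + Σ(1−λ²)); on the published (3-decimal-rounded)
loadings these evaluate to 0.483 and 0.923, within rounding tolerance of
the reported 0.50 / 0.91.

### Risk banding

Scores band at 12.37 / 16.51 / 24.35 into low / moderate / high / very
high. The published banding leaves boundary inclusivity implicit for
continuous scores; we fix *low* `< 12.37` ≤ *moderate* `< 16.51` ≤
*high* `≤ 24.35` < *very high*, which is total and disjoint over the
reals. Thresholds are a plain configurable dataclass.

The two posture inputs are taken as pure REBA table scores, without
REBA's load/coupling adjustments: load, force and coupling already enter
the composite as separate factors, and double-counting them inside the
posture terms would be inconsistent with the model's factor structure.

## Classic REBA

Tables A, B and C are shipped as commented CSV fixtures transcribed from
the published method, loaded and validated for completeness at test
time; score A = table A + load/force (0–3), score B = table B + coupling
(0–3), final = table C + activity (0–3), range 1–15. For four-level
comparisons the published five action levels are binned with the two
lowest merged (1–3 / 4–7 / 8–10 / 11–15); the breakpoints are
configurable because no canonical four-level binning exists.

`reba_final_from_profile` bridges an exposure profile to a classic REBA
final score for method comparison: the profile's posture table scores
are reused directly, load/force maps the 0–4 weight rating onto REBA's
0–2 (+1 for shock-like loading when rapid/sudden movement ≥ 3), coupling
is capped at 3, and the activity adjustment adds one point each for
static, repetitive and rapid activity rated ≥ 2. This bridge is an
artifact convention for synthetic comparisons, not part of either
published method.

## CMDQ scoring

Item score = frequency weight (0, 1.5, 3.5, 5, 10) × severity (1–3) ×
interference (1–3); maximum 90 per item; the total is the sum over
items. Totals band at 450 / 900 / 1350, left-closed (the published
banding again leaves inclusivity implicit; both the boundaries and the
convention are configurable). Two body-map layouts ship: the 12-region
list and a 20-item bilateral layout (the 8 paired regions split
left/right). The development cohort's observed maximum of 1674 exceeds
12 × 90 = 1080, so the bilateral layout is the one consistent with the
observed range (20 × 90 = 1800); the exact instrument layout used is
not recoverable, and the region list is configurable for that reason.

## Synthetic cohorts

No generative model of the development cohort was published; the
generator is this package's own emulation and every choice below is an
artifact decision.

**Exposures.** A Gaussian copula: latent draws from N(0, R) with R the
published 14×14 inter-factor correlation matrix (symmetrized;
eigenvalue-clipped to the nearest unit-diagonal PSD matrix if rounding
made it slightly indefinite — repairs needing more than 0.05 in the
smallest eigenvalue are rejected), mapped through Φ to uniforms and then
through the inverse CDF of a **moment-matched discretized truncated
normal** per factor. Moment matching matters: binning a truncated normal
at half-integer edges shifts its mean (e.g. a 0–4 scale with target mean
1.29, SD 1.28 drifts to ≈1.48 if the target moments are used as parent
parameters), so the parent (loc, scale) are solved by least squares so
the *discretized* distribution reproduces the target mean and SD. One
target is unattainable by construction: a lattice distribution with mean
0.52 cannot have SD 0.28 (minimum ≈0.50); the solver then matches the
mean and gets as close as the lattice allows. At n = 10 000 every factor
mean lands within ±0.03 of target.

Copula correlations are specified on the latent scale; discretization
attenuates observed correlations by a few percent (posture A–B: latent
0.843 → observed ≈0.82), hence the ±0.07 fidelity tolerance. The
composite load/force levels are drawn as integers 0–4 and decomposed as
(time = v, weight = 4) so the sub-score formulas reproduce the drawn
value exactly. The published CMDQ correlation row is *not* used by the
generator; outcomes come from the latent-strain model below.

**Outcomes.** `total = a + b·score + ε`, `ε ~ N(0, σ)`, floored at zero
(the questionnaire total is bounded below and the observed minimum is
0). `b = √R²·σ_out/σ_score` and `a` matches the target outcome mean
(defaults 536.82 / 511.51); the closed-form `σ = √(b²·Var(score)·
(1−R²)/R²)` gives the target explained variance exactly for the
unfloored model (`calibrate_outcome`). Flooring censors ~15% of draws
and attenuates the realized R², so when flooring is on the noise SD is
shrunk by a 1-d Brent root solve on the exact censored-normal moments so
the *floored* population R² equals the target (default 0.67). Measured
OLS R² at n = 10 000 lands within ±0.01 of target. Post-floor outcome
mean/SD deviate modestly from the targets; the calibration prioritizes
the R² contract.

Determinism: all draws derive from `SeedSequence(seed, spawn_key)` with
separate streams for exposures, outcomes and bootstrap; identical spec +
seed reproduces the cohort bit-for-bit.

**What passing tests show.** The generator emulates marginals, pairwise
correlations and a linear strain→symptom link with Gaussian noise. Real
questionnaire totals are skewed, heteroscedastic and zero-inflated
beyond what censored-Gaussian noise produces, and real exposure ratings
carry rater effects the copula has none of. Pipeline results on
synthetic cohorts therefore demonstrate internal consistency of the
machinery, not field validity; in particular the weighted score
out-explaining classic REBA on these cohorts is partly by construction
(the outcome is generated from the weighted score).

## Validation machinery

* **Sample size**: standard Fisher-z formula
  `n = ((z_α+z_β)/w)² + 3`, `w = arctanh(r)`, rounded to nearest. With
  the inputs as published (z = 1.96, 1.29 and the 3-decimal `w = 0.203`)
  this gives 259; the unrounded transform gives 260. (The formula as
  typeset in the source, with the ratio unsquared, evaluates to ≈82 and
  cannot reproduce the published 259; the standard formula does, and is
  what is implemented.)
* **AUC**: Mann–Whitney rank estimator, ties counted half via midranks;
  cross-checked in tests against an exhaustive pairwise oracle and
  scikit-learn.
* **ROC cutoffs**: thresholds at midpoints between sorted unique scores
  plus one below/above the extremes; predicted-positive is
  score ≥ threshold; the optimal cutoff minimizes the Euclidean distance
  to (sensitivity = 1, specificity = 1), ties broken toward the lower
  cutoff. Deriving the three risk cutoffs binarizes the questionnaire
  total at 450/900/1350 and requires the three cutoffs to come out
  strictly increasing (error otherwise, naming the failing band).
  Bootstrap percentile CIs (default 200 replicates, seeded) accompany
  each AUC.
* **R²**: squared Pearson correlation (simple OLS); zero-variance input
  returns 0 with a warning, by documented convention.

## Problem sizes

The shipped tests and the acceptance script use cohorts of n = 300 (the
development cohort's size, and the default `PopulationSpec.n`) for
pipeline runs and n = 10 000 for fidelity/calibration checks; both run
in seconds. The 20-seed cutoff-stability check uses n = 300 per seed.

## Known limitations

* The SEM is not re-estimated; goodness-of-fit indices are out of scope.
* Demographic covariates (age, BMI, tenure) are absent from the outcome
  model, as in the source model.
* The published AUC confidence intervals contain typographical errors
  and are recomputed by bootstrap rather than matched.
* One published marginal SD (contact stress, 0.28) is unattainable on an
  integer lattice with its mean and is matched as closely as possible.
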