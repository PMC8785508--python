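"""Score a single worker's exposure profile.

Builds one exposure profile from rubric ratings, computes the load and
force sub-scores, the weighted risk score, and the four-level risk band.
"""

from moreba import ExposureProfile, classify_risk, moreba_score

# A machining-station worker: moderately awkward posture, frequent
# repetitive work, light loads carried a couple of hours per shift.
worker = ExposureProfile(
    posture_a=5,            # REBA group-A table score (trunk/neck/legs)
    posture_b=4,            # REBA group-B table score (arms/wrist)
    coupling=2,             # acceptable handholds
    contact_stress=1,
    static_activity=3,
    repetitive_activity=3,
    rapid_movement=1,
    throwing_motion=0,
    hand_arm_vibration=2,
    whole_body_vibration=0,
    air_temperature=1,
    work_rest_cycle=3,      # only ~15 min rest per 2 h
    load_weight_score=1,    # 5-10 kg
    load_time_score=2,      # 2-4 h
    force_value_score=2,    # 2-4 kg
    work_time_score=3,      # 6-8 h
)

score = moreba_score(worker)
print(f"load sub-score L  = {worker.load:.2f}   (time x weight / 4)")
print(f"force sub-score F = {worker.force:.2f}   (time x value / 4)")
print(f"weighted score    = {score:.3f}")
print(f"risk level        = {classify_risk(score)}")
# The score is a weighted sum of all 14 factor ratings; the level comes
# from the ROC-derived cutoffs 12.37 / 16.51 / 24.35.
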