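"""Classic REBA scoring from joint-position categories.

Walks one observed posture through the REBA lookup chain: table A
(trunk/neck/legs) + load, table B (arms/wrist) + coupling, table C, and
the activity adjustment.
"""

from moreba import (
    RebaPostureObservation,
    reba_action_level,
    reba_final_score,
    table_a_score,
    table_b_score,
)

obs = RebaPostureObservation(
    trunk_score=3,       # trunk flexed 20-60 degrees
    neck_score=2,
    legs_score=2,
    upper_arm_score=4,
    lower_arm_score=2,
    wrist_score=1,
    load_force_score=1,  # 5-10 kg
    coupling_score=2,    # poor grip
    activity_score=2,    # static + repeated
)

a = table_a_score(obs.trunk_score, obs.neck_score, obs.legs_score)
b = table_b_score(obs.upper_arm_score, obs.lower_arm_score, obs.wrist_score)
final = reba_final_score(obs)
print(f"table A posture score = {a}  (+{obs.load_force_score} load)")
print(f"table B posture score = {b}  (+{obs.coupling_score} coupling)")
print(f"REBA final score      = {final}  (1..15)")
print(f"4-level action band   = {reba_action_level(final)}")
# Final 11 falls in the top action band: change is required immediately.
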