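{
  "version": "1.0",
  "description": "Default MOREBA coefficient set: standardized direct loadings of each factor on latent physical strain and the strain->symptoms path coefficient, estimated on the 300-worker development cohort. Indirect (score-equation) weights are direct x strain, rounded half-up to 3 decimals.",
  "strain_coefficient": 0.783,
  "direct_effects": {
    "posture_a": 0.937,
    "posture_b": 0.912,
    "coupling": 0.743,
    "contact_stress": 0.348,
    "load": 0.840,
    "force": 0.815,
    "static_activity": 0.747,
    "repetitive_activity": 0.748,
    "rapid_movement": 0.670,
    "throwing_motion": 0.751,
    "hand_arm_vibration": 0.446,
    "whole_body_vibration": 0.328,
    "air_temperature": 0.442,
    "work_rest_cycle": 0.614
  },
  "thresholds": {
    "low_moderate": 12.37,
    "moderate_high": 16.51,
    "high_very_high": 24.35
  }
}
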