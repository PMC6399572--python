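# UK time-trade-off value set for EQ-5D-3L (general-population scoring
# algorithm). Utility = 1 - any_dysfunction (if any level > 1)
#                        - sum of per-dimension level decrements
#                        - n3 (if any level = 3).
# Floor (state 33333) = -0.594.
name: UK TTO value set (EQ-5D-3L)
any_dysfunction: 0.081
n3: 0.269
decrements:
  mobility: {2: 0.069, 3: 0.314}
  self_care: {2: 0.104, 3: 0.214}
  usual_activities: {2: 0.036, 3: 0.094}
  pain_discomfort: {2: 0.123, 3: 0.386}
  anxiety_depression: {2: 0.071, 3: 0.236}
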