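# Canonical layout of the sequential two-choice Markov decision task.
# Two stages of binary (left/right) choice with 70%/30% probabilistic
# transitions and monetary outcomes of 0, 10 or 25 yen.  This layout
# satisfies the task's published optimal values: Q*(S0,right) = 14.5 yen,
# best stage-2 value 17.5 yen (at R1,left), Q*(S0,left) = 9.25 yen.
start_state: S0
stage2_states: [L1, L2, R1, R2]
outcome_states: [O0, O10, O25]
reward_yen:
  O0: 0
  O10: 10
  O25: 25
# Rewards are rescaled to unitless {0, 0.4, 1} for all model learning.
reward_scaled:
  0: 0.0
  10: 0.4
  25: 1.0
n_trials: 200
transitions:
  S0:
    left:  [[L1, 0.7], [L2, 0.3]]
    right: [[R1, 0.7], [R2, 0.3]]
  L1:
    left:  [[O10, 0.7], [O0, 0.3]]
    right: [[O0, 0.7], [O10, 0.3]]
  L2:
    left:  [[O10, 0.7], [O25, 0.3]]
    right: [[O0, 0.7], [O10, 0.3]]
  R1:
    left:  [[O25, 0.7], [O0, 0.3]]
    right: [[O0, 0.7], [O25, 0.3]]
  R2:
    left:  [[O0, 0.7], [O25, 0.3]]
    right: [[O0, 0.7], [O10, 0.3]]
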