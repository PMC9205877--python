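# Example study configuration (schema_version 1).
# Any omitted key falls back to its default; unknown keys are rejected.

schema_version: 1
seed: 0

task:
  payoff: {cc: 20, cd: 0, dc: 30, dd: 5}   # points to the player
  enforce_deception_dominance: true        # require dc > cc and dd > cd
  p_cooperative: 0.7                       # cooperative-style opponent
  p_deceitful: 0.3                         # deceitful-style opponent
  p_random: 0.5
  tft_first_move: mirror                   # mirror | cooperate | deceive
  time_limit_s: 10.0                       # responses beyond this are invalid
  opponent_rt_min_s: 1.0
  opponent_rt_max_s: 3.0

cohort:
  n_subjects: 19
  traits:
    age_mean: 45.0
    age_sd: 12.0
    p_female: 0.684
    neo_mean: 50.0
    neo_sd: 10.0
    p_believed_live: 0.632
  effect:
    boundary: 1.6            # a, evidence units
    nondecision: 0.35        # t0, seconds
    drift_sham: -0.3463      # negative = toward deception
    bias_shift_tvns: 0.075   # starting-bias increment under tVNS
    drift_shift_tvns: 0.011  # drift increment under tVNS (toward zero)
    neuroticism_modulation: -0.9   # bias-shift slope per SD neuroticism
    extraversion_modulation: 0.2
    subject_drift_sd: 0.32   # between-subject baseline drift SD
    invalid_rate: 0.0035     # undefined-key trials
    reciprocity: 0.0         # drift drop after being deceived (0 = off)
    dt: 0.001                # Euler step, seconds
    bridge: false            # Brownian-bridge crossing correction

fit:
  objective: ml              # ml | qmle (quantile-binned multinomial)
  restarts: 3
  rt_floor: 0.2              # exclude faster RTs from fitting only
  min_trials: 10
  grouping: stim_condition
  free_params: [a, t0, eta, b, sz, st, v]

stats:
  alpha: 0.05
  r2_threshold: 0.7          # collinearity screen on squared Pearson r
  power_target: 0.95
  agq: 7                     # adaptive Gauss-Hermite nodes for the GLMM
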