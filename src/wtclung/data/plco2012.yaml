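# Six-year lung cancer risk model coefficients (PLCOm2012 family),
# transcribed by the package authors from the source publication.
# Field mapping:
#   var        -> RiskProfile covariate name (see microsim._PROFILE_VARS)
#   center     -> value subtracted after the transform (model centering)
#   transform  -> identity, or inverse_div10 = (x/10)^-1 for smoking intensity
#   smoker_only-> term contributes 0 for never smokers (reference level);
#                 the source model was derived in ever-smokers.
# The sha256 checksum covers intercept+terms and guards the transcription.
name: plco2012
sha256: 7a71f34b8739d7948f25c164d784a3473877d4b0f53da98decc7712bf3a6351f
intercept: -4.532506
terms:
  - {name: age, coef: 0.0778868, var: age, center: 62.0}
  - {name: education, coef: -0.0812744, var: education, center: 4.0}
  - {name: bmi, coef: -0.0274194, var: bmi, center: 27.0}
  - {name: copd, coef: 0.3553063, var: copd}
  - {name: personal_cancer_history, coef: 0.4589971, var: prior_cancer}
  - {name: family_history_lung_cancer, coef: 0.587185, var: family_history}
  - {name: race_black, coef: 0.3944778, var: race_black}
  - {name: race_hispanic, coef: -0.7434744, var: race_hispanic}
  - {name: race_asian, coef: -0.466585, var: race_asian}
  - {name: current_smoker, coef: 0.2597431, var: current_smoker, smoker_only: true}
  - {name: smoking_intensity, coef: -1.822606, var: cigs_per_day,
     transform: inverse_div10, center: 0.4021541613, smoker_only: true}
  - {name: smoking_duration, coef: 0.0317321, var: smoking_duration,
     center: 27.0, smoker_only: true}
  - {name: quit_years, coef: -0.0308572, var: quit_years, center: 10.0,
     smoker_only: true}
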