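# Toy 6-year risk model used by the test suite and synthetic pipelines.
# Same functional form as the transcribed model, but with round coefficients
# chosen to give a realistic overall event yield on synthetic cohorts
# (roughly 25/100k p-y for never smokers, 150/100k for current smokers).
name: toy
intercept: -6.5
terms:
  - {name: age, coef: 0.07, var: age, center: 44.0}
  - {name: bmi, coef: -0.02, var: bmi, center: 29.0}
  - {name: copd, coef: 0.4, var: copd}
  - {name: family_history_lung_cancer, coef: 0.5, var: family_history}
  - {name: current_smoker, coef: 1.8, var: current_smoker, smoker_only: true}
  - {name: smoking_duration, coef: 0.02, var: smoking_duration, center: 20.0,
     smoker_only: true}
  - {name: quit_years, coef: -0.02, var: quit_years, center: 10.0,
     smoker_only: true}
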