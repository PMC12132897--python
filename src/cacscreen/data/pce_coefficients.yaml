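# Pooled cohort equations (2013 ACC/AHA risk assessment work group):
# sex- and race-group-specific proportional-hazards coefficients for
# 10-year first hard ASCVD risk.  Four equation groups; "white" covers
# non-Hispanic White and all other/unspecified groups, per the source
# convention.  Transcribed by double entry: a second, independent
# transcription lives in the test suite and the two are cross-checked
# term by term.
#
# Terms (all logs natural):
#   ln_age, ln_age_sq, ln_tc, ln_age_x_ln_tc, ln_hdl, ln_age_x_ln_hdl,
#   ln_sbp_treated, ln_age_x_ln_sbp_treated, ln_sbp_untreated,
#   ln_age_x_ln_sbp_untreated, smoker, ln_age_x_smoker, diabetes
# Risk = 1 - s10 ^ exp(LP - mean_lp)
schema_version: 1
units: {age: years, total_chol: mg/dL, hdl_chol: mg/dL, sbp: mm Hg}
groups:
  white_male:
    s10: 0.9144
    mean_lp: 61.18
    coefficients:
      ln_age: 12.344
      ln_tc: 11.853
      ln_age_x_ln_tc: -2.664
      ln_hdl: -7.990
      ln_age_x_ln_hdl: 1.769
      ln_sbp_treated: 1.797
      ln_sbp_untreated: 1.764
      smoker: 7.837
      ln_age_x_smoker: -1.795
      diabetes: 0.658
  black_male:
    s10: 0.8954
    mean_lp: 19.54
    coefficients:
      ln_age: 2.469
      ln_tc: 0.302
      ln_hdl: -0.307
      ln_sbp_treated: 1.916
      ln_sbp_untreated: 1.809
      smoker: 0.549
      diabetes: 0.645
  white_female:
    s10: 0.9665
    mean_lp: -29.18
    coefficients:
      ln_age: -29.799
      ln_age_sq: 4.884
      ln_tc: 13.540
      ln_age_x_ln_tc: -3.114
      ln_hdl: -13.578
      ln_age_x_ln_hdl: 3.149
      ln_sbp_treated: 2.019
      ln_sbp_untreated: 1.957
      smoker: 7.574
      ln_age_x_smoker: -1.665
      diabetes: 0.661
  black_female:
    s10: 0.9533
    mean_lp: 86.61
    coefficients:
      ln_age: 17.114
      ln_tc: 0.940
      ln_hdl: -18.920
      ln_age_x_ln_hdl: 4.475
      ln_sbp_treated: 29.291
      ln_age_x_ln_sbp_treated: -6.432
      ln_sbp_untreated: 27.820
      ln_age_x_ln_sbp_untreated: -6.087
      smoker: 0.691
      diabetes: 0.874
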