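# Count/percent pairs printed in the published analysis of the emulated
# cohort (n=4564).  Each case is recomputed as 100*numerator/denominator,
# rounded half-up to the printed precision, and compared to the printed
# percent with a +-0.1 pp tolerance (absorbs half-up vs truncation
# ambiguity in the source, e.g. 373/1519 = 24.56%).
# printed values are strings so their decimal precision is explicit.
cases:
  - {description: "male participants", numerator: 2121, denominator: 4564, printed: "46.5"}
  - {description: "White participants", numerator: 1792, denominator: 4564, printed: "39.3"}
  - {description: "Chinese participants", numerator: 563, denominator: 4564, printed: "12.3"}
  - {description: "Black participants", numerator: 1212, denominator: 4564, printed: "26.6"}
  - {description: "Hispanic participants", numerator: 997, denominator: 4564, printed: "21.8"}
  - {description: "CACS = 0", numerator: 2691, denominator: 4564, printed: "59"}
  - {description: "CACS 1-99", numerator: 1125, denominator: 4564, printed: "25"}
  - {description: "CACS >= 100", numerator: 746, denominator: 4564, printed: "16.3"}
  - {description: "PCE low (<7.5%)", numerator: 2566, denominator: 4564, printed: "56.2"}
  - {description: "PCE intermediate", numerator: 1519, denominator: 4564, printed: "33.3"}
  - {description: "PCE high (>=20%)", numerator: 479, denominator: 4564, printed: "10.5"}
  - {description: "all CHD events", numerator: 216, denominator: 4564, printed: "4.7"}
  - {description: "hard CHD events", numerator: 134, denominator: 4564, printed: "2.9"}
  - {description: "all CVD events", numerator: 304, denominator: 4564, printed: "6.7"}
  - {description: "hard CVD events", numerator: 236, denominator: 4564, printed: "5.2"}
  - {description: "intermediate-risk with CACS >= 100", numerator: 373, denominator: 1519, printed: "24.5"}
  - {description: "treatment eligible, guideline strategy", numerator: 852, denominator: 4564, printed: "18.7"}
  - {description: "scanned self-report with CACS > 0", numerator: 1034, denominator: 1519, printed: "68"}
  - {description: "scanned self-report with CACS >= 100", numerator: 557, denominator: 1519, printed: "37"}
  - {description: "events captured, guideline strategy", numerator: 103, denominator: 216, printed: "47.7"}
  - {description: "events captured, self-report strategy", numerator: 120, denominator: 216, printed: "55.6"}
  - {description: "event rate among guideline-treated", numerator: 103, denominator: 852, printed: "12"}
  - {description: "event rate among self-report-treated", numerator: 120, denominator: 852, printed: "14"}
  - {description: "high-risk PCE among guideline-treated", numerator: 479, denominator: 852, printed: "56"}
  - {description: "zero CACS among high-risk PCE", numerator: 123, denominator: 479, printed: "26"}
  - {description: "treatment eligible, age/sex-adjusted guideline", numerator: 758, denominator: 4564, printed: "17"}
exclusion_flow:
  initial: 6814
  exclusions:
    missing_followup: 29
    missing_pce_inputs: 24
    age_over_75: 803
    lipid_lowering_therapy: 944
    diabetes: 450
  final: 4564
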