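# ILLUSTRATIVE risk registry.
#
# Cause groups mirror the reporting structure of the mortality tables; the
# dose-response coefficients are illustrative log-linear fits with the right
# qualitative shapes (monotone increase for most chronic causes, J-shaped
# protection for diabetes and ischemic heart disease, high categorical RRs
# for injuries).  They are NOT meta-analytic estimates; replace this file
# with study-specific coefficients for substantive work.
#
# Schema: see aafburden.risk.  log_linear coefficients are polynomial terms
# of log RR in dose (g/day), starting at the linear term.
cap: 150.0
causes:
- label: Infectious and parasitic diseases
  icd10: A00-B99 excl. B20-B24
  bucket: communicable
  method: chronic
  functions:
  - {sex: men, form: log_linear, coefficients: [0.004], rr_former: 1.10}
  - {sex: women, form: log_linear, coefficients: [0.004], rr_former: 1.10}
- label: HIV/AIDS
  icd10: B20-B24
  bucket: communicable
  method: hiv
  hiv:
    threshold_gpd: 48.0
    rr_nonadherent: {men: 1.50, women: 1.50}
- label: Respiratory infections
  icd10: J09-J22
  bucket: communicable
  method: chronic
  functions:
  - {sex: men, form: log_linear, coefficients: [0.005], rr_former: 1.10}
  - {sex: women, form: log_linear, coefficients: [0.005], rr_former: 1.10}
- label: Malignant neoplasms
  icd10: C00-C97
  bucket: noncommunicable
  method: chronic
  functions:
  - {sex: men, form: log_linear, coefficients: [0.008], rr_former: 1.10}
  - {sex: women, form: log_linear, coefficients: [0.009], rr_former: 1.10}
- label: Diabetes
  icd10: E10-E14
  bucket: noncommunicable
  method: chronic
  protective_ok: true
  functions:
  - {sex: men, form: log_linear, coefficients: [-0.020, 0.00012], rr_former: 1.00}
  - {sex: women, form: log_linear, coefficients: [-0.022, 0.00013], rr_former: 1.00}
- label: Neuro-psychiatric conditions
  icd10: F10, G31.2, G40-G41, ...
  bucket: noncommunicable
  method: chronic
  functions:
  - {sex: men, form: log_linear, coefficients: [0.007], rr_former: 1.20}
  - {sex: women, form: log_linear, coefficients: [0.007], rr_former: 1.20}
- label: Cardiovascular disease
  icd10: I10-I99
  bucket: noncommunicable
  method: ihd
  protective_ok: true
  functions:
  - {sex: men, role: protective, form: log_linear, coefficients: [-0.015, 0.00011],
    rr_former: 1.15}
  - {sex: men, role: detrimental, form: log_linear, coefficients: [0.004], rr_former: 1.15}
  - {sex: women, role: protective, form: log_linear, coefficients: [-0.016, 0.00012],
    rr_former: 1.15}
  - {sex: women, role: detrimental, form: log_linear, coefficients: [0.004], rr_former: 1.15}
- label: Digestive diseases
  icd10: K20-K93
  bucket: noncommunicable
  method: chronic
  functions:
  - {sex: men, form: log_linear, coefficients: [0.009], rr_former: 1.30}
  - {sex: women, form: log_linear, coefficients: [0.011], rr_former: 1.30}
- label: Unintentional injuries
  icd10: V01-X59, Y40-Y86, Y88
  bucket: injury
  method: injury
  injury_cells:
    men:
      nonbinge: [1.10, 1.60, 2.20, 3.20]
      binge: [1.90, 2.80, 3.90, 5.50]
    women:
      nonbinge: [1.10, 1.60, 2.20, 3.20]
      binge: [1.90, 2.80, 3.90, 5.50]
- label: Intentional injuries
  icd10: X60-Y09, Y87
  bucket: injury
  method: injury
  injury_cells:
    men:
      nonbinge: [1.05, 1.40, 1.90, 2.60]
      binge: [1.60, 2.30, 3.10, 4.20]
    women:
      nonbinge: [1.05, 1.40, 1.90, 2.60]
      binge: [1.60, 2.30, 3.10, 4.20]
- label: Underdetermined intent
  icd10: Y10-Y34
  bucket: injury
  method: injury
  injury_cells:
    men:
      nonbinge: [1.05, 1.40, 1.90, 2.60]
      binge: [1.60, 2.30, 3.10, 4.20]
    women:
      nonbinge: [1.05, 1.40, 1.90, 2.60]
      binge: [1.60, 2.30, 3.10, 4.20]
- label: Alcohol use disorders
  icd10: F10, K70, X45, ...
  bucket: noncommunicable
  method: wholly_attributable
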