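# Prior probability of pathogenicity per Align-GVGD grade for BRCA2
# missense substitutions, following the calibration of Align-GVGD grades
# against clinically classified BRCA1/2 missense variants used by the
# multifactorial likelihood framework (C65 -> 0.81 anchor).  Replace with a
# user table to change gene or calibration.
gene: BRCA2
source: calibration of Align-GVGD grades against classified BRCA missense substitutions; C65 anchor 0.81
priors:
  C0: 0.02
  C15: 0.29
  C25: 0.29
  C35: 0.66
  C45: 0.66
  C55: 0.81
  C65: 0.81
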