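# Align-GVGD grade decision boundaries.
#
# A substitution is graded by its Grantham Deviation (GD) when the Grantham
# Variation (GV) of the alignment column is below gv_cap (a conserved
# position); columns more variable than gv_cap tolerate substitution and the
# grade collapses to C0.  Bands are half-open: grade Cx applies when
# GD >= x threshold and below the next band.  C65 collects the most likely
# deleterious changes, C0 the least.
gv_cap: 61.3
bands:
  - {grade: C65, min_gd: 65}
  - {grade: C55, min_gd: 55}
  - {grade: C45, min_gd: 45}
  - {grade: C35, min_gd: 35}
  - {grade: C25, min_gd: 25}
  - {grade: C15, min_gd: 15}
  - {grade: C0,  min_gd: 0}
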