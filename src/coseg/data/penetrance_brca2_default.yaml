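# Default penetrance model for a high-risk BRCA2-like breast/ovarian allele.
#
# Carrier cumulative risks follow published BRCA2 penetrance estimates in
# broad strokes: ~45% breast and ~11% ovarian cancer by age 70, with a broad
# onset distribution centred in the late 40s (breast) and around 60
# (ovarian), and an elevated contralateral rate of roughly 2%/year after a
# first breast cancer.  Noncarrier curves approximate population registry
# cumulative incidence (~9% breast / ~1% ovarian by 70, ~0.5%/year
# contralateral).  The contralateral axis is years since the first breast
# event on the same grid.  All curves are package defaults, intended to be
# replaced by a user-supplied table when a specific published set is wanted.
name: brca2_default
source: package default; carrier risks patterned on published BRCA2 penetrance (~45% breast / ~11% ovarian to age 70), noncarrier on registry-style population incidence
age_grid: [0, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 95]
cumulative_risk:
  carrier:
    breast_first:         [0, 0, 0, 0, 0.002, 0.010, 0.030, 0.070, 0.120, 0.180, 0.250, 0.310, 0.370, 0.410, 0.450, 0.480, 0.510, 0.530, 0.540, 0.545]
    breast_contralateral: [0, 0.120, 0.220, 0.300, 0.370, 0.420, 0.470, 0.500, 0.520, 0.535, 0.550, 0.560, 0.570, 0.575, 0.580, 0.585, 0.590, 0.592, 0.594, 0.595]
    ovarian:              [0, 0, 0, 0, 0, 0, 0.001, 0.002, 0.005, 0.010, 0.025, 0.045, 0.070, 0.090, 0.110, 0.125, 0.140, 0.150, 0.155, 0.160]
  noncarrier:
    breast_first:         [0, 0, 0, 0, 0.0002, 0.0005, 0.002, 0.005, 0.010, 0.020, 0.030, 0.045, 0.060, 0.075, 0.090, 0.100, 0.110, 0.120, 0.125, 0.130]
    breast_contralateral: [0, 0.025, 0.050, 0.070, 0.090, 0.110, 0.120, 0.130, 0.140, 0.148, 0.155, 0.161, 0.166, 0.170, 0.174, 0.177, 0.180, 0.182, 0.184, 0.185]
    ovarian:              [0, 0, 0, 0, 0, 0, 0.0002, 0.0005, 0.001, 0.002, 0.003, 0.0045, 0.006, 0.008, 0.010, 0.0115, 0.013, 0.014, 0.0145, 0.015]
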