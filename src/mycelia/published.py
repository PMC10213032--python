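"""Reference growth measurements for *Podospora anserina* thalli.

Values from triplicate whole-thallus growth experiments on standard
dextrin medium (M2) and carbon-depleted medium (M0), plus the reference
simulation, used here as calibration defaults and as printed inputs for
the media-comparison statistics.  ω is the base-2 growth rate of the
apex count N1 = C·2^(ωt); D = C/(B1·B2) is the density-model prefactor
built from the linear eigenvalue slopes B_i.
"""

#: apex-count growth rates ω (h⁻¹) per replicate
M2_OMEGA_PER_H = (0.48, 0.46, 0.49)
M0_OMEGA_PER_H = (0.37, 0.33, 0.33)
SIMULATION_OMEGA_PER_H = 0.59

#: density-model prefactors D (h²·mm⁻²) per replicate
M2_D_H2_PER_MM2 = (194.0, 266.0, 207.0)
M0_D_H2_PER_MM2 = (416.0, 489.0, 420.0)
SIMULATION_D_H2_PER_MM2 = 454.0

#: eigenvalue-root slopes for the M2 reference experiment (mm h⁻¹)
M2_B_MM_PER_H = (0.098, 0.107)

#: measured arc-chord tortuosity per medium
TORTUOSITY_M2 = 0.038
TORTUOSITY_M0 = 0.041

#: apex-cloud sphericity 2λ2/(λ1+λ2), constant during growth
SPHERICITY = 0.88

#: orientation collections: clockwise share of n=198 branchings
ORIENTATION_N = 198
CW_SHARE_SUBAPICAL_M2 = 0.54
CW_SHARE_LATERAL_M2 = 0.56

#: isolated lateral branch rate (µm⁻¹ per 90-min window)
P_ISOLATED_PER_UM = 6e-3
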