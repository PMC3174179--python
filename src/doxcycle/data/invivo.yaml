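# Cellular (in vivo) doxorubicin bioactivation models for the EU1-Res
# (doxorubicin-resistant) and EU3-Sens (doxorubicin-sensitive) ALL lines.
# Concentrations in M; bimolecular constants in M^-1 s^-1; k7 is a membrane
# permeability in cm s^-1; k8 a zero-order NADPH supply capacity in M s^-1;
# k9 the Michaelis constant of the G6PD supply term in M.
# EU1-Res values are the reference set; EU3-Sens values are the measured
# fold-change-scaled counterparts (printed verbatim below; the builders
# derive the multipliers from these so both representations agree exactly).
initial_conditions_eu1:
  CPR_red: 1.3e-6       # literature microsomal CPR content
  CPR_ox: 0.0
  Ex_Dox_q: 1.0e-5      # 10 uM dose; 100 nM condition uses 1.0e-7
  In_Dox_q: 0.0
  In_Dox_sq: 0.0
  NADPH: 3.0e-5         # basal cytosolic NADPH
  NADP: 0.0             # set to 0.01 * NADPH (basal redox poise) by the builder
  O2: 1.5e-9            # intracellular O2 estimated from leukemia O2 consumption
  O2minus: 1.5e-11
  H2O2: 1.5e-11
eu3_measured:           # measured fold-change-scaled values, printed verbatim
  CPR_red: 8.9e-7
  NADPH: 5.4e-5
  k4: 9.7e+3
  k8: 3.3e-6
nadp_ratio: 0.01        # initial NADP = ratio * initial NADPH
doses:
  high: 1.0e-5
  low: 1.0e-7
parameters_eu1:
  k1: 1.2e+4             # carried over from the cell-free model
  # k2 = k1 by construction
  k3: 3.0e+5             # intracellular semiquinone reoxidation
  k4: 4.2e+4             # NOX4-catalysed NADPH + O2 -> superoxide
  k5: 5.5e+7             # carried over from the cell-free model
  k6: 6.4e+9             # SOD1-dependent dismutation (lumped second order)
  k8: 1.8e-6            # G6PD NADPH supply capacity (fitted to NADPH depletion)
  k9: 5.7e-5            # Michaelis constant for NADP of the supply term
k7_by_dose:
  high: 1.1e-6          # fitted to extracellular depletion at 10 uM
  low: 1.1e-5           # 10x higher permeability at 100 nM (literature)
# Aggregate surface factor A = 1e-3 (L cm^-3) * 6.15e-6 (cm^2) * 1e+9 (cells/L)
surface_factor_terms: [1.0e-3, 6.15e-6, 1.0e+9]
r4_dox_modulation_K: 1.0e-7   # half-saturation of NOX activation by In_Dox_q
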