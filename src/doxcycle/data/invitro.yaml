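# Cell-free (in vitro) doxorubicin bioactivation model: initial conditions
# and rate constants. Concentrations in M, bimolecular constants in M^-1 s^-1.
# Sources: published cell-free CPR/NADPH doxorubicin assays (Kostrzewa-Nowak
# et al. redox-cycling / reductive-conversion time courses) and radical
# chemistry literature for the diffusion-limited steps.
initial_conditions:
  CPR_red: 1.0e-6       # reduced cytochrome P450 reductase, assay loading
  CPR_ox: 0.0           # all CPR starts reduced
  Dox_q: 1.0e-4         # quinone doxorubicin, assay loading
  Dox_sq: 0.0           # semiquinone radical absent at t=0
  NADPH: 1.0e-4         # low-NADPH condition; high condition uses 5.0e-4
  NADP: 0.0
  O2: 2.7e-4            # air-saturated aqueous buffer
  O2minus: 0.0
  H2O2: 0.0
nadph_high: 5.0e-4      # reductive-conversion condition
parameters:
  k1: 1.2e+4             # CPR_red + Dox_q (fitted to redox-cycling data)
  # k2 = k1 by construction (CPR_ox re-reduction by NADPH)
  k3: 3.0e+8             # O2 + Dox_sq, diffusion-limited reoxidation
  k4: 2.9e+1             # non-enzymatic NADPH + O2 (fitted to reductive conversion)
  k5: 5.5e+7             # O2- + Dox_q (fitted to SOD-induced redox cycling)
  k6: 6.4e+9             # superoxide self-dismutation
sod_condition:
  k_sod: 2.0e+9          # enzymatic dismutation, diffusion-limited order
  sod_conc: 1.0e-6      # default enzyme concentration for the +SOD assay
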