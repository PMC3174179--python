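# EU3-Sens at the 100 nM dose with 20% G6PD inhibition (DHEA)
kind: invivo
cell_line: EU3-Sens
dose: low
interventions:
  - [DHEA, 0.2]
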