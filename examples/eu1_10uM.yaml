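# EU1-Res (doxorubicin-resistant ALL line) treated with 10 uM doxorubicin
kind: invivo
cell_line: EU1-Res
dose: high
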