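# Cell-free reductive-conversion condition: 500 uM NADPH, no SOD
kind: invitro
nadph0: high
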