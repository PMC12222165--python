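# criterion directions for the stack performance matrix
Ac: benefit
Pr: benefit
Sp: benefit
Sn: benefit
F1: benefit
MCC: benefit
MAE: cost
Tt: cost
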