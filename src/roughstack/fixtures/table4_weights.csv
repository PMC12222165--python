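criterion,weight
Ac,0.0669
Pr,0.0683
Sp,0.0732
Sn,0.0574
F1,0.0695
MCC,0.0496
MAE,0.2264
Tt,0.3685
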