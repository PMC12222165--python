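model,Ac,Pr,Sp,Sn,F1,MCC,MAE,Tt
Stack-1,0.75,0.74,0.79,0.70,0.76,0.49,0.25,0.17
Stack-2,0.98,0.96,1.00,0.96,0.98,0.96,0.02,1.33
Stack-3,0.98,0.96,1.00,0.96,0.98,0.96,0.02,1.83
Stack-4,0.98,0.96,1.00,0.96,0.98,0.96,0.02,0.59
Stack-5,0.98,0.96,1.00,0.96,0.98,0.96,0.02,3.16
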