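# Cardiology tabular schema: 13 condition attributes + binary target.
# Numeric attributes carry their observed [min, max] range; nominal ones
# list their coded levels.
age:      {type: numeric, range: [29, 77]}
sex:      {type: nominal, levels: [0, 1]}
cp:       {type: nominal, levels: [1, 2, 3, 4]}
trestbps: {type: numeric, range: [94, 200]}
chol:     {type: numeric, range: [126, 564]}
fbs:      {type: nominal, levels: [0, 1]}
restecg:  {type: nominal, levels: [0, 1, 2]}
thalach:  {type: numeric, range: [71, 202]}
exang:    {type: nominal, levels: [0, 1]}
oldpeak:  {type: numeric, range: [0.0, 6.2]}
slope:    {type: nominal, levels: [1, 2, 3]}
ca:       {type: numeric, range: [0, 4]}
thal:     {type: nominal, levels: [3, 6, 7]}
target:   {type: nominal, levels: [0, 1]}
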