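# Baseline parameterisation of the two-subject game
# (lead hospital x primary healthcare institutions).

I = 26.0
U = 5.0
Sl = 14.0
Tp = 12.0
R = 3.0
Sp = 2.0
D = 25.0
v = 0.5
pi = 0.5
eps = 0.5
xi = 0.5
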