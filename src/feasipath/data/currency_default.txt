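# Default currency-metabolite list (ubiquitous cofactors and carriers).
# One identifier per line; replace with your reconstruction's namespace.
H2O
H+
ATP
ADP
AMP
O2
CO2
Pi
PPi
NAD+
NADH
NADP+
NADPH
CoA
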