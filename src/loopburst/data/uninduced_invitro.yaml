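# Alternative uninduced set: association propensity 0.73 s^-1, the value
# obtained by propagating the in vitro O1 dissociation rate through the
# equilibrium constants fitted to operator-deletion repression data.
# Note this candidate does not reproduce the derived large-burst statistics
# (l_c, rho); see docs/methods.md.
nu: 0.12
g_m: 0.011
k_p: 0.044
g_p: 0.0002
k_a: 0.73
k_d1: 0.0016
k_d2: 0.019
k_d3: 0.73
kl_12: 4.0
kl_13: 24.0
has_aux_operators: true
transcribing_operator: 2
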