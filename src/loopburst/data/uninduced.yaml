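# Uninduced (no inducer) kinetic parameters for the six-state lac operon
# scheme, all in s^-1.  The association propensity k_a is the effective
# value 0.073, calibrated so that the derived burst statistics reproduce
# the model-based reference values (rho = 0.2 with K = k_d2/k_a ~ 0.25,
# l_c = 0.55 with auxiliary operators and 1.65 without).  The alternative
# in vitro (0.73) and in vivo (0.14) candidates ship alongside this file.
nu: 0.12        # mRNA synthesis in an active state
g_m: 0.011      # mRNA degradation
k_p: 0.044      # protein synthesis per mRNA  (b = k_p/g_m = 4)
g_p: 0.0002     # protein dilution            (a = nu/g_p = 600)
k_a: 0.073      # repressor association to any one operator
k_d1: 0.0016    # dissociation from the main operator O1
k_d2: 0.019     # dissociation from the downstream auxiliary operator O2
k_d3: 0.73      # dissociation from the upstream auxiliary operator O3
kl_12: 4.0      # O1-O2 loop formation (from B1 or B2)
kl_13: 24.0     # O1-O3 loop formation (from B1 or B3)
has_aux_operators: true
transcribing_operator: 2
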