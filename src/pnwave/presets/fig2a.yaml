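# Single-component EGFR front model: bistable kinetics mu*h(E) - k*E with
# mu/k = 4, n = 3 (printed Hill form, threshold 1).  Position is measured in
# cell spacings; eta = 4 puts the diffusion length at two cell spacings so
# the front profile is resolved on the lattice.
variant: E_ONLY
eta: 4.0
mu_E: 4.0
k_E: 1.0
hills:
  E_auto: {exponent: 3.0, threshold: 1.0}
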