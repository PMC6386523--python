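# Integrated model for the 1D signalling/expression profile: the
# reconstructed defaults with eta = 0.03.
variant: INTEGRATED
eta: 0.03
mu_E: 8.0
k_E: 1.0
mu_L: 0.4
k_L: 0.2
mu_D: 4.0
k_D: 1.0
mu_N: 10.0
k_N: 2.0
beta: 10.0
basal_D: 0.15
sigma_N: 0.05
k_Omega: 0.4
gamma: 0.0
hills:
  E_auto:
    exponent: 3.0
    threshold: 1.0
  L_on_E:
    exponent: 3.0
    threshold: 1.0
  N_on_E:
    exponent: 3.0
    threshold: 1.0
  E_on_L:
    exponent: 3.0
    threshold: 1.0
  N_on_L:
    exponent: 3.0
    threshold: 3.0
  E_on_D:
    exponent: 3.0
    threshold: 1.0
  N_on_D:
    exponent: 3.0
    threshold: 3.0
  D_trans:
    exponent: 3.0
    threshold: 0.5
  D_cis:
    exponent: 3.0
    threshold: 1.0
  L_on_N:
    exponent: 3.0
    threshold: 0.3
  L_on_Omega:
    exponent: 2.0
    threshold: 0.35
  E_on_Omega:
    exponent: 3.0
    threshold: 1.0
  N_on_Omega:
    exponent: 3.0
    threshold: 2.0
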