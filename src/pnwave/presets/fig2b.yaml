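# Excitable EGFR + L'sc pulse model: E parameters as in the front model,
# L'sc parameters mu_L = 0.4, k_L = 0.2.
variant: E_L
eta: 4.0
mu_E: 4.0
k_E: 1.0
mu_L: 0.4
k_L: 0.2
hills:
  E_auto: {exponent: 3.0, threshold: 1.0}
  L_on_E: {exponent: 3.0, threshold: 1.0}
  E_on_L: {exponent: 3.0, threshold: 1.0}
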