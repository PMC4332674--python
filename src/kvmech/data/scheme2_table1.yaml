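# Scheme 1 plus a slow-inactivated state I (voltage-independent rates).
scheme: scheme2
alpha0: 1120.0   # s^-1
beta0: 373.0     # s^-1
z_alpha: 0.25    # e
z_beta: 1.0      # e
k_o: 8000.0      # s^-1
k_c: 100.0       # s^-1
inac: 0.05       # s^-1
recov: 0.005     # s^-1
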