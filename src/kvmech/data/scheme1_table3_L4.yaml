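# 6-state scheme with Hodgkin-Huxley-style sensor rate functions;
# L = 400/100 = 4.  voltage_shift displaces the rate arguments so the
# rest-tension normalized Popen(V) midpoint coincides with the HH n^4
# midpoint (calibrated once; see docs/methods.md).
scheme: scheme1
rate_form: hh
alpha_prefactor: 15.5   # s^-1/mV  (10 x 1.55)
alpha_offset: -55.0     # mV
alpha_slope: 12.0       # mV
beta_prefactor: 193.75  # s^-1    (1.55 x 125)
beta_offset: -65.0      # mV
beta_slope: 85.0        # mV
voltage_shift: -23.681   # mV; baseline-matching offset (see docs/methods.md)
k_o: 400.0              # s^-1
k_c: 100.0              # s^-1
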