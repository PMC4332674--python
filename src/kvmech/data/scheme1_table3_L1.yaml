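# As scheme1_table3_L4 but with L = 100/100 = 1 and the rate-function
# voltage arguments displaced a further +18 mV; the net voltage_shift is
# that displacement plus the same baseline-matching offset as the L = 4
# variant.  The residual left placement relative to the HH n^4 curve
# gives this family its higher excitation threshold (see docs/methods.md).
scheme: scheme1
rate_form: hh
alpha_prefactor: 15.5   # s^-1/mV
alpha_offset: -55.0     # mV
alpha_slope: 12.0       # mV
beta_prefactor: 193.75  # s^-1
beta_offset: -65.0      # mV
beta_slope: 85.0        # mV
voltage_shift: -5.681   # mV; +18 relative displacement - 23.681 matching offset
k_o: 100.0              # s^-1
k_c: 100.0              # s^-1
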