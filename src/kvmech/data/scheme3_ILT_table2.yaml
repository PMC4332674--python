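# 7-state Shaker-ILT: left-shifted independent sensors, severely
# right-shifted and slowed concerted step; thermal opening as in WT.
scheme: scheme3
alpha0: 1540.0   # s^-1
beta0: 0.16      # s^-1
z_alpha: 0.5     # e
z_beta: 2.5      # e
f0: 0.072        # s^-1
b0: 0.162        # s^-1
z_f: 1.0         # e
z_b: 0.8         # e
k_o: 400.0       # s^-1
k_c: 100.0       # s^-1
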