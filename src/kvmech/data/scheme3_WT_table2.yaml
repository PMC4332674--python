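# 7-state wild-type Shaker: sensors, concerted pre-opening C5<->C6,
# thermal opening C6<->O (L = 400/100 = 4, Popen_max = 0.8).
scheme: scheme3
alpha0: 2000.0   # s^-1
beta0: 100.0     # s^-1
z_alpha: 0.5     # e
z_beta: 1.5      # e
f0: 1000.0       # s^-1
b0: 200.0        # s^-1
z_f: 0.2         # e
z_b: 0.8         # e
k_o: 400.0       # s^-1
k_c: 100.0       # s^-1
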