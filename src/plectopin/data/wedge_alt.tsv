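# Alternative wedge-style dinucleotide geometry in the gel-mobility-calibrated
# tradition: a pronounced negative A-tract roll wedge and larger
# pyrimidine-purine rolls. Shipped to expose the sensitivity of density
# predictions to the choice of dinucleotide parameter set; same axis and sign
# conventions and the same calibrated stiffness table as the default set.

name wedge-alt
rise_nm 0.334
bulk_persistence_length_nm 50.0
# step tilt roll twist var_tilt var_roll cov_tilt_roll
AA -0.9 -1.8 34.5 5.12133333e-03 1.02426667e-02 0.0
AC 0.4 0.5 32.0 4.67600000e-03 9.35200000e-03 0.0
AG -1.2 4.0 32.5 4.45333333e-03 8.90666667e-03 0.0
AT 0.0 0.5 30.5 5.12133333e-03 1.02426667e-02 0.0
CA 0.8 5.6 36.5 4.89866667e-03 9.79733333e-03 0.0
CC -0.3 4.2 33.0 3.56266667e-03 7.12533333e-03 0.0
CG 0.0 6.2 35.5 3.78533333e-03 7.57066667e-03 0.0
CT 1.2 4.0 32.5 4.45333333e-03 8.90666667e-03 0.0
GA -1.3 1.2 36.0 4.23066667e-03 8.46133333e-03 0.0
GC 0.0 0.1 34.0 3.34000000e-03 6.68000000e-03 0.0
GG 0.3 4.2 33.0 3.56266667e-03 7.12533333e-03 0.0
GT -0.4 0.5 32.0 4.67600000e-03 9.35200000e-03 0.0
TA 0.0 4.6 37.0 5.12133333e-03 1.02426667e-02 0.0
TC 1.3 1.2 36.0 4.23066667e-03 8.46133333e-03 0.0
TG -0.8 5.6 36.5 4.89866667e-03 9.79733333e-03 0.0
TT 0.9 -1.8 34.5 5.12133333e-03 1.02426667e-02 0.0
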