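# Null-geometry analytic control: zero tilt and roll (a perfectly straight
# ground state) with uniform 34.3 degree twist (10.5 bp/turn) and isotropic
# per-step stiffness calibrated to the 50 nm bulk persistence length.

name null
rise_nm 0.334
bulk_persistence_length_nm 50.0
# step tilt roll twist var_tilt var_roll cov_tilt_roll
AA 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
AC 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
AG 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
AT 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
CA 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
CC 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
CG 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
CT 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
GA 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
GC 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
GG 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
GT 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
TA 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
TC 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
TG 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
TT 0.0 0.0 34.3 4.45333333e-03 8.90666667e-03 0.0
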