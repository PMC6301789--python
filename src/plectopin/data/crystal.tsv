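# Crystallography-derived dinucleotide step geometry (tilt/roll/twist, degrees)
# transcribed from the protein-DNA crystal-structure consensus tables of the
# Olson-lab lineage of dinucleotide parameter sets. Axis conventions: twist is
# the rotation about the local helical axis (tangent t), roll the rotation
# about the long base-pair axis (normal n, opening toward the grooves), tilt
# the rotation about the short base-pair axis (binormal b); signs follow the
# standard right-handed base-pair step convention, and a step XY and its
# reverse complement share twist and roll with tilt negated.
# Stiffness: per-step (tilt, roll) fluctuation covariance in radians^2,
# calibrated so the sequence-averaged directional persistence length over
# uniform-random sequence equals the bulk value of 50 nm
# (sum of per-plane variances = 2 * rise / A = 0.01336 rad^2 per step),
# with a 1:2 tilt:roll split and per-step softness factors following the
# relative step flexibilities reported by MD simulation studies.

name crystal
rise_nm 0.334
bulk_persistence_length_nm 50.0
# step tilt roll twist var_tilt var_roll cov_tilt_roll
AA -1.4 0.7 35.1 5.12133333e-03 1.02426667e-02 0.0
AC -0.1 0.7 31.5 4.67600000e-03 9.35200000e-03 0.0
AG -1.7 4.5 31.9 4.45333333e-03 8.90666667e-03 0.0
AT 0.0 1.1 29.3 5.12133333e-03 1.02426667e-02 0.0
CA 0.5 4.7 37.3 4.89866667e-03 9.79733333e-03 0.0
CC -0.1 3.6 32.9 3.56266667e-03 7.12533333e-03 0.0
CG 0.0 5.4 36.1 3.78533333e-03 7.57066667e-03 0.0
CT 1.7 4.5 31.9 4.45333333e-03 8.90666667e-03 0.0
GA -1.5 1.9 36.3 4.23066667e-03 8.46133333e-03 0.0
GC 0.0 0.3 33.6 3.34000000e-03 6.68000000e-03 0.0
GG 0.1 3.6 32.9 3.56266667e-03 7.12533333e-03 0.0
GT 0.1 0.7 31.5 4.67600000e-03 9.35200000e-03 0.0
TA 0.0 3.3 37.8 5.12133333e-03 1.02426667e-02 0.0
TC 1.5 1.9 36.3 4.23066667e-03 8.46133333e-03 0.0
TG -0.5 4.7 37.3 4.89866667e-03 9.79733333e-03 0.0
TT 1.4 0.7 35.1 5.12133333e-03 1.02426667e-02 0.0
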