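# plectopin

Predict where supercoiled DNA pins its plectonemes — from sequence alone.

When DNA is overwound, torsional strain is released by writhing into
plectonemes: intertwined loops whose apical tip is bent into a sharp ~240°
arc. Forming that tip costs a large bending energy, and the cost depends on
the local sequence: a stretch with high *intrinsic curvature* is pre-bent
and pins plectoneme tips, while straight DNA resists them. `plectopin`
implements a parameter-free physical model of this effect for people who
study supercoiled DNA mechanics and its genomic consequences (e.g.
plectonemic hot spots upstream of prokaryotic promoters), and provides
genome-scanning and TSS meta-profile tooling on top of it.

## The model

For a tip loop of `N` bp under tension `F` the total energy (in units of
k<sub>B</sub>T) is

    E_total(N, i, φ) = C·N + E_bend(N, i, φ),        C = F / 12.16  (F in pN)

where the work term pulls `r·N` of contour into the loop (`r` = 0.334 nm
base-pair rise) and the bending term follows the worm-like chain with the
law of cosines for an arbitrary bend direction `φ` around the helical axis:

    E_bend(N, i, φ) = (2/3)² · 2π² · A(N, i, φ) / (r·N)
                      · [ 1 + (θ/240°)² − 2·(θ/240°)·cos(φ − φ_B) ]

* `θ(N, i)` — intrinsic curvature of the `N`-bp stretch centered at `i`,
  from the ground-state 3D path built out of per-dinucleotide tilt/roll/
  twist angles, comparing chord tangents (11-bp windows, one helical turn)
  at the two ends;
* `φ_B(N, i)` — the bend direction aligned with that intrinsic curvature;
* `A(N, i, φ)` — direction-dependent local persistence length, from
  dinucleotide tilt/roll covariance matrices summed over the loop, each
  co-rotated by the intrinsic twist;
* `(2/3)²` — the (240°/360°)² partial-arc factor for the tip loop.

Each conformation gets a Boltzmann weight `W = exp(−E_total)`; summing over
loop sizes 40–120 bp (step 8) and eight bend directions starting at `φ_B`
gives the total weight `W_tot(i)`, whose mean-normalized profile is the
predicted plectoneme density and `−ln W_tot(i)` the free-energy landscape.
For homogeneous DNA the optimum is `N* = √(B/C)`: 109 bp for a full circle
and 73 bp for a 240° tip loop at 3 pN.

## Worked example

```python
import numpy as np
import plectopin as pp

eng = pp.LoopEnergetics()          # F = 3 pN, 240° tip, A = 50 nm
print(eng.describe())
print(round(pp.bend_energy(73, 50, 0), 2))    # straight stretch
print(round(pp.bend_energy(73, 50, 60), 2))   # 60° pre-bent stretch

from plectopin.fixtures import GC_CURVED_UNIT
seq = pp.make_fixture(pp.FixtureSpec(
    kind="insert_in_backbone", length=10_000,
    insert=GC_CURVED_UNIT, insert_position=5000, seed=5))
prof = pp.density_profile(seq).smoothed(1600)
i = int(np.nanargmax(prof.smoothed_density))
print(f"smoothed density peak: {prof.smoothed_density[i]:.2f} at bp {i}")
```

prints

```
F=3.0 pN, C=0.2467/bp, B360=2955, B240=1313, tip angle=240.0 deg, N*=73 bp
17.99
10.12
smoothed density peak: 5.20 at bp 5029
```

Bending a straight 73-bp stretch into the 240° tip costs ~18 k_BT; 60° of
aligned intrinsic curvature cuts that by ~8 k_BT, which is why a single
curved 75-bp insert in an otherwise flat 10-kb molecule produces a 5.2×
density peak at the insert even after smoothing to the ~1.6-kb optical
resolution of single-molecule assays.

## Command line

```sh
plectopin predict molecule.fa -o profile.tsv          # per-base density
plectopin scan genome.fa -o tracks --circular         # bedGraph tracks
plectopin tss-profile tracks.chr.density.bedgraph tss.tsv -o meta.tsv
plectopin fixture --kind phased_tract --seed 7 -o curved.fa
plectopin params list
```

Every run logs the tension, parameter set (name + provenance), smoothing
and seed. Parameter sets are plain-text tables (`plectopin params default`
validates one); `load_param_set` accepts user files in the same format.

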