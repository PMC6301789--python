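# Methods

## Model overview

`plectopin` treats a plectoneme tip as a partial loop of `N` base pairs
bent through 240° in a DNA molecule under tension `F`, and asks how the
energy of forming that loop varies with where it is centered. The energy
has a tension work term, `C·N` with `C = F/12.16` (F in pN), and a
worm-like-chain bending term in which the local sequence enters twice: the
intrinsic curvature `θ(N,i)` reduces the arc that still has to be bent
thermally, and the directional persistence length `A(N,i,φ)` sets the
price per radian². Both are computed from dinucleotide step parameters; no
quantity is fitted to plectoneme data. Boltzmann weights
`W = exp(−E_total)` are summed over a grid of loop sizes (40–120 bp, step
8) and eight bend directions anchored at the preferred direction `φ_B`,
giving `W_tot(i)`; its unit-mean normalization is the predicted plectoneme
density and `−ln W_tot` the free-energy landscape. The grid spans the
homogeneous-DNA optimum (73 bp at 3 pN) widely enough that the sum is
insensitive to its bounds.

Assumptions worth stating: only the tip loop is modeled (no stem
electrostatics, no multi-plectoneme statistics, no torque or
linking-number bookkeeping); the ground-state path is athermal (curvature
is intrinsic, not an ensemble average); twist stiffness, stretching and
twist–bend coupling are neglected; positive and negative supercoiling are
not distinguished (no duplex melting).

## Geometry conventions

The ground state is traced with a local right-handed material frame
(tangent `t`, normal `n`, binormal `b`). Per dinucleotide step the frame
is rotated intrinsically in the fixed order **twist about `t`, then roll
about `n`, then tilt about `b`** (`F ← F·Rx(Ω)·Ry(ρ)·Rz(τ)` with frame-
local axes x=t, y=n, z=b), then the position advances one rise
(0.334 nm) along the new tangent. The literature does not fix this order;
any consistent convention reproduces the model's behavior, and residual
sensitivity is absorbed into the parameter set. Under this convention a
small tilt deflects the tangent along `+n` and a small roll along `−b`, so
a physical bend azimuth `φ` (measured in the (n, b) plane, as `φ_B` is)
corresponds to the direction `(cos φ, −sin φ)` in (tilt, roll)
coordinates; the stiffness module applies this mapping so that `φ` and
`φ_B` share one angular origin.

Local tangents are **chords over an 11-bp window** (one helical turn),
which cancels intra-turn wobble of the helical path; `θ(N,i)` is the angle
between the windowed tangents at `i ± N/2`, and `φ_B` is the azimuth, in
the material frame at `i` (the mid-loop frame — a documented choice, since
start-frame and mid-frame definitions differ only by the intrinsic twist
offset), of the end-tangent change projected perpendicular to the center
tangent. For a straight stretch `φ_B` is undefined and set to 0; it is
then irrelevant because `θ = 0` removes the direction dependence.

Sequence coordinates are 0-based internally; exported tracks follow their
format's convention (bedGraph 0-based half-open, TSV 1-based). Circular
molecules are handled by tracing a padded copy of the sequence so every
window that crosses the origin sees the correct local geometry; all
profile quantities are rigid-motion invariant, so the result is exactly
rotation-equivariant. Ambiguity codes are rejected by default; an explicit
`ambiguous="substitute"` policy maps IUPAC codes to fixed representative
bases with a logged warning, so genome N-runs never change silently.

## Stiffness model

Each step contributes a symmetric 2×2 covariance of its (tilt, roll)
fluctuations. Over a loop these are summed with each matrix co-rotated by
the cumulative intrinsic twist **relative to the loop center**, expressing
all contributions in the frame where `φ_B` lives. The worm-like-chain
relation `⟨Δθ²⟩ = L/A` per bending plane then gives

    A(N, i, φ) = r·N / (u(φ)ᵀ Σ_tot u(φ)).

When the directional variance underflows (e.g. a degenerate user-supplied
matrix) `A` is capped at a configurable ceiling (default 10⁴ nm) with a
logged warning. The shipped table is calibrated so the sequence-averaged
persistence length over uniform-random sequence is exactly the 50 nm bulk
value (`var_tilt + var_roll = 2r/A` per step on average), split 1:2
between tilt and roll and modulated by per-step softness factors that
follow the MD-literature ordering (AT-rich steps softer, GC-rich stiffer);
cross-covariances default to zero. This keeps the stiffness table and the
bulk constant of the closed-form energetics mutually consistent.

## Energetic constants

`C = F/12.16` is used exactly as printed in the source derivation, which
pins k_BT to `0.334 × 12.16 ≈ 4.06 pN·nm`; substituting the textbook
4.114 pN·nm would shift the optimal loop sizes off their quoted integer
values (109/73 bp at 3 pN). The `(2/3)²` prefactor of the bending energy
is the `(240°/360°)²` partial-arc factor kept explicit in code. Default
tension is 3 pN (characteristic of flow-stretched molecules in the
single-molecule assay this model was built against) and is configurable
everywhere.

## Parameter sets

Parameter values are data, not code: flat key-value text files with
citation headers (step, tilt, roll, twist in degrees; var_tilt, var_roll,
cov_tilt_roll in radians²), converted to radians exactly once at load.
Three sets ship: `default` (crystallography-derived step geometry in the
Olson-lab consensus lineage, with reverse-complement symmetry — step XY
and its reverse complement share twist and roll with tilt negated),
`wedge-alt` (a gel-mobility-tradition variant with a pronounced negative
A-tract roll wedge, shipped to expose the sensitivity of predictions to
the parameter choice), and `null` (zero curvature, uniform 34.3° twist,
isotropic calibrated stiffness — the analytic control used throughout the
test suite). Validation enforces completeness of the 16 steps, symmetric
PSD covariances, twist sanity (20°–45°), and positive rise/persistence
length. Files round-trip losslessly (degree values are printed so their
radian conversion is bit-exact).

## Synthetic fixtures

The fixture generator emulates the *design rules* of the experimentally
tested constructs, not their literal sequences (which are not in the main
text): phased A-tract repeats (A₅ at the helical repeat, curved because
the near-zero A-tract roll alternates in phase with larger mixed-sequence
rolls), flat random sequences (homopolymer runs ≥ 4 excluded, no phased
curvature), inserts embedded in flat backbones, and a 75-bp GC-rich
(~59%) curved unit. That unit was designed in silico once — a seeded
hill-climb maximizing the 73-bp intrinsic curvature of its tandem repeat
under the default parameter set, with GC fraction constrained — and frozen
in source; it carries ~98° of curvature across 73 bp. All fixtures are
pure functions of their spec and seed.

What the fixtures do **not** emulate: real genomic base composition
statistics, methylation or protein occupancy, and the specific constructs
of the original experiments. Passing tests therefore demonstrate the
model's internal correctness and its qualitative mechanism (curved inserts
pin, flat ones do not, GC-richness is no obstacle), not quantitative
agreement with any particular measured molecule.

## Numerical choices

* The density scan is vectorized: the covariance sums use the rotation
  decomposition of symmetric 2×2 matrices (invariant trace + deviator
  rotating at twice the frame angle) with prefix sums, O(L) per loop size.
* Chunked genome scanning overlaps chunks by the 65-bp support radius, so
  chunked and monolithic scans agree to floating-point roundoff.
* Gaussian smoothing (`σ = FWHM/√(8 ln 2)`, default FWHM 1600 bp matching
  the ~optical resolution the predictions are compared against) wraps for
  circular molecules; linear masked profiles use a truncated,
  per-position renormalized kernel followed by an exact rescale of the
  mean, so a constant profile is unchanged and the mean is preserved.
* TSS meta-profiles average the **unsmoothed** density (a 1600-bp kernel
  would erase ~100-bp promoter features), strand-aware (minus-strand
  windows reversed so negative offsets are upstream), each site weighted
  once, then boxcar-smoothed over 51 bp; sites without full track support
  are dropped with a logged count.
* Unsupported leading/trailing 65 bp of linear molecules are reported as
  absent (NaN / no bedGraph records), never as zeros, which would
  fabricate pinning deserts.
* Problem sizes in the test suite and acceptance script (20-kb random
  sequences, 5–10-kb synthetic genomes) were chosen as the smallest scales
  at which the landscape statistics and meta-profile recovery are stable.

## Known limitations

* Predictions inherit the uncertainty of dinucleotide parameter sets;
  different published sets visibly shift the profiles (compare `default`
  vs `wedge-alt`), and beyond-nearest-neighbor effects are not modeled.
* The model scores tip-loop formation only; it does not predict plectoneme
  size, number, dynamics, or linking-number dependence.
* Negative supercoiling adds sequence-dependent duplex melting that this
  model deliberately omits; applying it to strongly underwound DNA will
  miss melting-driven pinning.
* The free-energy roughness of random sequence under the shipped table is
  ~0.8 k_BT (SD), at the lower edge of the ~1 k_BT scale expected from
  plectoneme-diffusion measurements — consistent given the "~", but a
  reminder that absolute energy scales depend on the geometry table.
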