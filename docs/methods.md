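# Methods

This note documents the models and procedures implemented in `oraikit`, the
assumptions behind them, the parameters that matter, and what the synthetic
benchmarks do and do not establish.

## Coordinate conventions and the pore frame

All trajectory analyses assume the membrane plane is *xy*, the pore axis is
*z*, and the extracellular side lies at higher *z*. Frames are expected to be
whole-molecule imaged; no periodic-boundary wrapping is applied (a
pre-centering helper, `conformation.center_frame`, translates a frame so a
selection's centroid sits at the origin). Residue numbers are 1-based human
Orai1 numbering and ranges are inclusive on both ends. The transmembrane
presets are TM1 = 80–110, TM2 = 120–150, TM3 = 170–195, TM4 = 235–262, with
an additional narrow TM3 fitting range 179–185 (`TM3_FIT`). Both TM3 ranges
are deliberately kept: the wide one is the display/selection convention, the
narrow one the superposition-fit convention, and they are not
interchangeable.

The **pore centre** is the arithmetic mean of the Cα positions of residues
80–110 over all subunits (TM1 lines the conducting pore in the hexamer).
Every cylinder, axial histogram and in-plane distance is referred to the
vertical line through this point — a straight z-aligned axis, not a fitted
curvilinear one. This matches the fixed-cylinder definition of the water
analyses and keeps the geometry exactly reproducible.

## Pore-radius profile (maximal-sphere search)

At each axial position `z_k` the pore radius is the largest probe sphere
centred at `(c, z_k)` that touches no atom:

    R(z_k) = max_c min_i ( ||(c, z_k) − x_i|| − r_vdw,i )

Atoms constrain a slice when `|z_i − z_k| ≤ r_vdw,i + 3 Å` (the 3 Å margin
is a probe allowance; slices with no atoms in that band are reported as NaN,
i.e. undefined rather than blocked; negative radii mark sterically occluded
slices and are preserved as-is). With `optimize_center=False` the probe
centre is pinned to the pore-centre *xy*; with `optimize_center=True` it is
refined by Nelder-Mead (xatol 1e-3 Å), each slice seeded from its inner
neighbour's optimum, walking outward from the slice nearest the pore centre.
A deterministic local optimiser replaces the Monte-Carlo annealing of the
classic cavity-profiling approach: the objective is piecewise-smooth and the
seeded walk tracks the channel lumen well, while determinism makes profiles
bit-reproducible and testable against an exhaustive grid-search oracle
(tests use a 0.05 Å grid). The optimised radius can never fall below the
fixed-centre value — the seed is kept when the optimiser fails to improve.

Van der Waals radii come from a Bondi-type element table (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20 Å), overridable per call; trajectory formats do not
carry radii.

Replica aggregation: per replica, frame profiles inside the requested time
window are averaged; across replicas the profile reports the mean and the
standard deviation of the mean (sample SD across replica means divided by
√n_replicas). The same estimator is used by every replica-aggregated
quantity in the package. With a single replica the SD is reported as zero.

## Hydration

Waters are represented by their oxygen atom only; recognition is by residue
name ∈ {HOH, SOL, TIP3, WAT, TIP, SPC} and atom name ∈ {O, OW, OH2}, a
superset of the common MD water naming conventions. All distance cutoffs are
**inclusive** (≤), fixed once for determinism.

* `axial_water_histogram` bins the z positions (relative to the pore centre)
  of waters whose *xy* distance from the pore axis is ≤ the cylinder radius
  — 10 Å for the conducting pore, 30 Å to take in the peripheral back-pore
  crevices. Default bin width 1 Å. When no explicit z range is given the
  bins are taken from the data snapped to the dz grid, so the histogram
  conserves the total in-cylinder count exactly (a tested invariant).
* `shell_count_distribution` counts waters within a cutoff (default 6 Å) of
  a chosen atom (default Cα of residue 181) per frame and subunit. The
  pooled per-shell samples form the reported distribution; the per-channel
  mean sums the six subunit shells per frame, double-counting any water
  lying in two shells — the overlap convention is stated because nothing
  forces the shells to be disjoint in real structures. Both reductions are
  exposed since the pooling convention of the figure being emulated is not
  fixed by its caption.

Neighbour queries go through a k-d tree; an exhaustive pairwise-distance
oracle in the test suite confirms exact agreement (the boundary convention
of the tree query is ≤, matching the package's).

## Conformational descriptors

* **Rotation angle** (degrees, [0, 180]): both vectors originate at the Cα —
  u = xy-projection of (Cγ − Cα), v = xy-projection of (pore centre − Cα);
  the angle is arccos of their normalised dot product. 0° means the side
  chain points straight at the pore. The prose definition of this angle is
  directionally ambiguous about vector order; anchoring both at Cα is the
  choice under which "distribution shifted to lower values" reads as
  "side chain reoriented toward the pore". Projections shorter than 1e-6 Å
  are degenerate and yield NaN (flagged missing, never an exception).
* **Moiety distance** (Å): *xy*-plane distance between the geometric centre
  of the charge-carrying group and the pore centre. Default atom sets:
  Lys NZ; Arg CZ/NH1/NH2/NE (guanidinium); Glu CD/OE1/OE2 and Asp
  CG/OD1/OD2 (carboxylate) — the chemistry names the group, these are the
  conventional heavy-atom names.
* **Triangle area** (Å²): full 3-D area ½‖AB × AC‖ of the Cα triangle,
  default residues (143, 177, 253) framing the TM3/TM4 interface.
* **Dihedral**: signed IUPAC torsion in (−180°, 180°], atan2 formulation;
  the sign convention is cross-checked against MDAnalysis in the tests.
* **Kabsch RMSD**: optimal rotation+translation (no reflection) of the fit
  selection via `scipy.spatial.transform.Rotation.align_vectors`, RMSD then
  measured over a possibly different selection (default: measure = fit).
  Symmetry and the fitted ≤ unfitted inequality are tested invariants; a
  brute-force Nelder-Mead optimiser over rigid moves serves as the
  independent oracle.

`series_over_trajectory` evaluates any of these per frame and subunit and
returns a frame × subunit matrix; `pooled_histogram` normalises the pooled
values (default bin widths where used in examples: 5° for angles, 1 for
water counts — the figure conventions being emulated do not state theirs).

## Hydropathy profiles

Unweighted centred moving average of per-residue scale values; odd window,
default 9, conventional range 9–25 for locating TM helices; window 1 is an
explicit override degenerating to the raw lookup. Termini receive no score
(no padding — edge handling is not specified by the source convention, and
truncation is the least-assumption choice). The bundled default is the
Roseman side-chain scale; the profile machinery is linear in the scale, and
tests exercise it with a toy scale so they are independent of the bundled
numbers. `profile_delta` returns the element-wise mutant − wild-type
difference plus its mean over a stated residue range; a single substitution
perturbs exactly `window` consecutive outputs, each by Δscale/window — a
tested identity.

## FRET and NFAT quantification

Apparent FRET efficiency per pixel, after per-channel background
subtraction:

    E_app = (I_FRET − a·I_YFP − b·I_CFP) / (I_FRET − a·I_YFP + (G − b)·I_CFP)

with `a` (YFP cross-excitation), `b` (CFP crosstalk) and `G` (microscope
constant, typical calibrated value 2.75) supplied per measurement day.
Pixels are gated to CFP:YFP ratios in [0.01, 100] (the 0.1:10 … 10:0.1
window), bounds inclusive — "between" is ambiguous and inclusivity is fixed
for determinism — and both intensities must be positive. Zero denominators
yield NaN (invalid pixel), never an exception. Background subtraction clamps
negatives to zero; pixels whose *numerator* is negative keep their negative
E_app as a diagnostic but are excluded from summary statistics. Summaries
offer mean (default) and median, since per-cell reduction conventions vary.

NFAT translocation: ratio = nuclear / cytosolic background-subtracted mean
intensity; < 0.85 inactive, [0.85, 1.15] homogeneous (closed interval,
matching the printed "0.85–1.15"), > 1.15 active. The three categories
partition (0, ∞); the population summary reports counts and fractions with
fraction-active as the headline statistic.

## Synthetic ground truth

`ChannelSpec`/`build_channel` produce a pseudo-hexameric channel: each TM
helix is a vertical rod of Cα pseudo-atoms at its ring radius (defaults
TM1 8, TM2 14, TM3 18, TM4 22 Å; 1.5 Å axial rise), six subunits at 60°
spacing, so the pore-defining selection centres exactly on the origin. A
pseudo-Cγ sits 1.5 Å from the residue-181 Cα in the membrane plane at a
deviation from the pore-pointing direction drawn from von Mises(μ, κ)
(defaults μ = 60°, κ = 8 — a concentrated but clearly non-degenerate
orientation preference, σ ≈ 20°). Waters are homogeneous Poisson point
processes per region: a pore cylinder (default radius 10 Å, half-height
10 Å) and per-subunit 6 Å shells around the residue-181 Cα; shell placement
can instead plant an exact count. Poisson placement is the weakest
assumption that still validates counting, binning and replica-aggregation
machinery; it deliberately does not emulate correlated water dynamics,
density layering or excluded volume, so recovery tests certify the
*measurement* code, not any statement about real trajectories.

Because waters are drawn independently per frame, frame atom counts would
differ; trajectory frames must share one atom count and ordering (as in any
MD trajectory file), so every frame is padded to the replica maximum with
reservoir waters parked 500 Å out on *x* — far outside every analysis
region. The padding preserves the Poisson statistics of every counted
region and the multi-MODEL PDB round trip.

`ImageSpec` drives both image generators. FRET triples invert the
efficiency equation: given a cell's donor-channel level C and planted E,
the sensitized emission is F_c = G·C·E/(1−E) and
I_FRET = a·I_YFP + b·I_CFP + F_c; backgrounds are added last and Poisson
shot noise (optional) is drawn per pixel at the expected count. Cells are
discs on a non-overlapping grid; no optics/PSF model is attempted. NFAT
fields are discs with an inner nuclear disc at ratio × cytosol level;
category fractions are apportioned to cell counts by largest remainder so
planted fractions are exact. All generators are bit-deterministic under a
fixed seed and return their ground truth beside the data.

## Numerical choices and degenerate inputs

- All distance/ratio boundaries inclusive; chosen once, stated above.
- Slice optimiser: Nelder-Mead, xatol 1e-3 Å, fatol 1e-6, seeded walk;
  ties resolved toward the seed (optimised ≥ fixed guaranteed).
- Missing values are NaN and flagged, not raised: empty slice
  neighbourhoods, degenerate angle projections, zero FRET denominators.
  Empty *selections* and empty time windows raise, naming the offender.
- PDB coordinates round-trip to the fixed-column precision of 1e-3 Å;
  equality tests on coordinates use that bound.
- Replica SD with one replica is 0 (a plottable convention, not an
  estimate).

## Problem sizes

The test and acceptance workloads use 100-frame hydration runs, 84-frame ×
6-subunit orientation runs (504 samples), 204 shell samples, 256² images
and 100-cell populations — sizes at which every stochastic recovery has
comfortable statistical resolution (e.g. orientation circular-mean standard
error ≈ 0.9°) while the whole suite runs in seconds.

## Limitations

- The pore axis is straight and z-aligned; strongly tilted or kinked pores
  would need a curvilinear axis the package does not fit.
- No periodic-boundary handling: pre-imaged frames are the caller's
  responsibility.
- The cavity search optimises per slice; it does not enforce continuity of
  the probe path between slices beyond seeding, and it does not reproduce
  any particular legacy parameter set, so absolute agreement with other
  cavity profilers is not a target — analytic geometries and the grid
  oracle are.
- The synthetic generators validate measurement machinery only; passing
  recovery tests says nothing about force fields, water structure, optics
  or segmentation quality in real data.
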