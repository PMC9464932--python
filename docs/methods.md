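# Methods

This note documents the models, conventions and numerical choices behind
`syctqa`, in the order the pipeline applies them, together with what the
synthetic fixtures do and do not establish about real data.

## Geometry and DICOM conventions

All computation happens in the DICOM patient coordinate system in mm.
Grids store arrays in `(z, y, x)` order with spacing/origin in `(x, y, z)`
order; the origin is the center of the first voxel. Only axial series are
accepted — this keeps contour rasterization strictly two-dimensional per
slice and removes any ambiguity about which plane a planar contour lives
in. CT series are written as int16 with rescale intercept −1024 (round
trips are exact for integer HU); dose grids as uint32 with
`DoseGridScaling = max/(2³² − 1)`, so quantization error is below one
scaling unit per voxel. When the reference and evaluated dose grids differ
in geometry they are trilinearly resampled onto the CT grid before any
analysis; points outside a dose grid's extent resample to zero dose. The
source data leaves resampling behaviour unspecified, so it is performed
explicitly and identically for both distributions rather than left to the
comparison tool.

## HU → ED calibration

The calibration is a piecewise-linear curve through user-supplied
`(HU, ED)` anchors, clamped beyond the end anchors. Only two points of the
curve are physically fixed — air (−1000 HU → 0.0) and water (0 HU → 1.0) —
and the constructor enforces them. The default table
(−1000, 0.00), (−200, 0.80), (0, 1.00), (100, 1.07), (1000, 1.60),
(3000, 2.30) is a generic scanner curve; any site should override it from
the config with its own. ED throughout means *relative electron density*
(water = 1). Per-structure statistics use the population standard
deviation: a rasterized mask is the complete voxel population of the
structure, not a sample.

## Rasterization and priority resolution

A voxel belongs to a structure iff its center lies inside the slice's
polygon(s) under the even–odd rule; multiple polygons on one slice XOR
together, which encodes holes. Points within 1e-9 mm of an edge count as
inside (a deterministic tie-break). There is no partial-volume weighting:
bulk assignment is binary per voxel, and whole-voxel masks keep every
downstream quantity exactly recomputable. This can differ slightly from
TPS-internal fractional-voxel structures; the difference shows up as a
small systematic offset in absolute DVH values but cancels in
reference-vs-evaluated *differences*, which is what the verdict uses.
Contours are attached to the nearest slice plane (they must lie within half
a slice spacing). Overlaps resolve to the structure with the numerically
higher priority; a flag inverts the polarity for systems that rank 1 as
highest. Labels are assigned in ascending-priority order, making the label
map independent of input order.

## The ideal syCT

`build_syct` forces every voxel to the mean ED of its winning structure,
with background ED (default 0.0, air) elsewhere — deliberately so: anything
not contoured does not exist dosimetrically, which is precisely the failure
mode of un-contoured support hardware. Mean EDs computed from the CT are
rounded to 3 decimals (configurable) to match typical TPS display precision
and keep reports bit-reproducible. The builder is idempotent and
permutation-invariant, and an exhaustive per-voxel scan over all structures
reproduces it exactly on every tested phantom.

## DVH engine

All dosimetric parameters are evaluated on the raw masked voxel doses, not
on a binned curve, because the clinical tolerances (1 Gy, 1.5 %-volume)
are smaller than any reasonable bin. D_y% / D_ycc accumulate volume in
whole-voxel steps down the descending sorted dose list and interpolate
linearly between adjacent order statistics; requests for less than one
voxel's volume return the hottest voxel (Dmax). Curves for display and for
point-wise gap measures use 0.01 Gy bins by default.

The agreement rule for "the target dose difference in any point of the
DVH is lower than 1.5 % or 1 Gy" is implemented as a band test: a DVH
point agrees when the other curve passes within 1.5 %-volume of it
somewhere inside a ±1 Gy dose window, and the reported gap is the worst
%-volume distance under that window, symmetrized over both curves. The
*or* matters: a purely vertical (%-volume) gap is unbounded on a steep
target DVH — a 0.1 Gy shift, far inside clinical agreement, already moves
a steep curve by several %-volume — so a vertical-only reading would fail
every well-matched plan pair with a small target. The plain maximum
vertical gap is still computed and reported for every structure; only the
verdict clause uses the band form. Parameter deltas are classified by
unit: V-type in %-volume against 1.5 %, D-type in Gy against 1 Gy, strict
inequalities.

## Gamma engine

Global 3D gamma with the dose criterion taken as a percentage of the
reference maximum (or an explicit normalization dose). Reference voxels
below the low-dose cutoff (default 10 % of normalization, configurable
including 0) are excluded and carry NaN in the stored γ field; γ is stored
unthresholded so criteria can be re-applied without recomputation. The
minimization samples the evaluated dose by trilinear interpolation on a
cubic offset lattice with step `interpolation_step × δ` (default 0.1, i.e.
0.3 mm at 3 mm DTA) inside a sphere of radius `search_radius_factor × δ`
(default 3). Offsets are visited in ascending distance with per-voxel
early termination: once a voxel's running minimum is below the pure
distance term of all remaining offsets, no farther offset can improve it.
The pruning is exact — the engine returns the same minimum as an
unrestricted sweep of the full lattice, and the test suite verifies
voxelwise agreement (≤ 1e-6) with an independently written exhaustive
search built on a different interpolator. Those equivalence checks run
both engines on a reduced lattice (factor 2, step 0.25) to keep the
brute-force side tractable; the lattice is identical on both sides, so the
comparison is exact, not approximate. Positions outside the evaluated
grid's voxel-center hull are never searched. Pass rates count γ < 1
strictly; a mask containing no included voxels yields an *undefined* rate
(None), never 0 or 100.

Loosening both criteria components (2 %/2 mm → 3 %/3 mm) scales both
penalty terms down and enlarges the search sphere, so each voxel's γ can
only decrease; pass rates at 3 %/3 mm therefore dominate those at
2 %/2 mm. The two lattices are not nested (0.2 vs 0.3 mm), which could in
principle flip a voxel balanced exactly on γ = 1; this has not been
observed in any fixture and the property is asserted across the whole
fixture cohort.

## Verdict

PASS requires, with strict inequalities: body γ(3 %/3 mm) pass rate
> 99 %; every target's DVH band gap < 1.5 %-volume; every listed V-metric
delta < 1.5 %; every listed D-metric delta < 1 Gy. The 2 %/2 mm analysis
is always computed and reported but never gates the verdict. Every clause
is emitted with its value and threshold, so the verdict is a pure,
auditable function of the report's numbers. The gamma clause is evaluated
on the body mask (configurable to the whole grid); whether the original
workflow used the body or the full dose grid is not documented, and the
body is the conservative, anatomy-restricted choice.

## Troubleshooting heuristics

All advisory, each carrying its triggering numbers:

* `INHOMOGENEOUS_STRUCTURE` — ED standard deviation above 0.15 inside a
  structure. Applied by default to target-class structures only: real
  bodies are legitimately inhomogeneous (bone, gas), and the clinical
  failure signature is a density gradient *within the target*.
* `PRIORITY_SHADOWING` — ≥ 95 % of a structure covered by a single
  higher-priority structure, so its bulk ED never reaches the syCT (the
  lost-skull signature).
* `ED_MISMATCH` — |assigned − recomputed| mean ED > 0.05, the signature of
  contours drawn on a different image than the reference CT.
* `UNASSIGNED_HARDWARE` — at least 20 voxels above 200 HU outside every
  structure (the un-contoured plate signature); contoured structures lying
  outside the body are reported separately by the coverage check.

All four thresholds are configurable.

## Phantom fixtures and the surrogate dose model

Phantoms are built from analytic primitives (ellipsoids, z-cylinders,
boxes) painted into a 24×48×48 grid at 3 mm spacing (144×144×72 mm — a
desk-scale torso section) with Gaussian HU noise from a single seeded
draw; contours are 96-gon traces of the analytic boundaries, and masks are
obtained by rasterizing those contours exactly as the pipeline would.
Organ HU means and noise (body 0±15, cord 35±10, organ 55±10, target
40±12, lung −700±30, bone 300±30, plate 400±15) are ordinary clinical
magnitudes.

The surrogate dose model is broad-beam exponential attenuation:
`dose = Σ_b weight × profile × exp(−μ_water × radiological path)` with
μ_water = 0.005/mm and the radiological path integrated exactly under the
piecewise-constant voxel ED model from the beam entry face to the voxel
center. Beams are axis-aligned (±x, ±y) with a rectangular aperture
smoothed by a 3 mm Gaussian penumbra; weights are scaled once so the
reference mean target dose equals the prescription (default 25 Gy), and
the *same* scale is applied to the syCT recalculation — recalculated, not
reoptimized. The model omits scatter, beam divergence, beam hardening and
all magnetic-field dose effects; it is a fixture, not a dose engine. Its
single load-bearing property — dose is monotone non-increasing in every
upstream density — is what the QA method actually relies on, so passing
tests demonstrate that the *pipeline* detects density-assignment errors,
not that any clinical dose engine would produce these exact numbers.

The five case kinds map to the documented failure taxonomy: `concordant`
(near-homogeneous organs; passes), `lung_inhomogeneous` (half-aerated /
half-solid target inside a lung, irradiated by non-opposed beams — opposed
pairs cancel heterogeneity errors to first order and would mask the
failure), `priority_error` (whole-brain contour outranking the skull
annulus it encloses), `missing_plate` (a dense un-contoured plate in the
posterior beam path), and `ed_mismatch` (one organ's bulk ED offset by
+0.2 from its anatomy). Each non-concordant kind is constructed to trip
its intended clause or finding across seeds, and the tests assert the
outcome, not specific dose values.

## Problem sizes and tolerances

Fixture grids are 55k voxels; gamma equivalence checks run on ≤ 32³ grids
where the exhaustive oracle is tractable; the acceptance script runs five
seeds per case kind. Floating-point tolerances: DVH metrics vs oracle at
1e-9 relative; gamma vs oracle at 1e-6 absolute; syCT equality is exact
(bitwise), as is determinism of repeated runs (timestamps excluded).

## Known limitations

* Inter-slice contour interpolation is not performed; contours bind to
  their nearest slice.
* Whole-voxel masks (no fractional occupancy) — small absolute DVH offsets
  against TPS exports are expected.
* The surrogate dose model cannot reproduce magnetic-field effects (e.g.
  the electron return effect) that make density errors *more* consequential
  on an MR-Linac; real commissioning must use the clinical engine's
  recalculation as the evaluated dose, which the pipeline accepts as an
  ordinary RTDOSE input.
* Local-normalization gamma is available (`normalization="local"`), but
  the built-in criteria and the verdict default to global normalization.
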