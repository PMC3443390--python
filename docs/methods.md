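# Methods

This note records the models, conventions, parameter choices and known
limitations behind `gatemap`. Coordinates are in Angstroms throughout; the
pore axis is Z, Z = 0 at mid-membrane, extracellular side positive.

## The phantom pentamer

The synthetic phantom stands in for experimental single-tube
reconstructions of a muscle-type pentameric ligand-gated channel. It is
deliberately minimal: enough geometry to exercise every analysis operation
with exact ground truth, and no more.

**Architecture.** Five subunits — `alpha_g`, `gamma`, `alpha_d`, `delta`,
`beta`, placed clockwise (viewed from the extracellular side) at 72°
spacing; this ring order puts β between δ and αγ, matching the receptor.
Per subunit:

* a four-helix membrane bundle of ideal α-helices (24 residues, 1.5 Å
  rise/residue, 2.3 Å Cα radius, 100°/residue twist) spanning
  z = ±17.25 Å: M2 innermost at 8.8 Å axis radius, M1/M3 at 14.5 Å
  (±22° azimuth), M4 outermost at 19.5 Å;
* an extracellular β-sandwich proxy: two parallel slabs of four vertical
  strands (10 residues at 3.4 Å rise, z = 22–52.6 Å) at radii 9.5 Å
  (inner sheet) and 16 Å (outer sheet);
* a short binding-site loop proxy (8 residues, tangential arc at radius
  18 Å, z = 40 Å).

With all perturbations zero the model is exactly C5-symmetric by
construction.

**Closed state.** Every M2 bows inward with a quadratic deviation profile
(zero at both helix ends, maximum at the midpoint, i.e. at mid-membrane):
αγM2 with amplitude 1.5 Å radially inward, δM2 with amplitude 2.0 Å along
a mixed direction (radial component matched to the common bow, tangential
dominant), and the remaining three with a common 1.0 Å inward "gate bow".
In addition both α subunits carry a 1.0 Å tangential offset of their
sheets — the closed-state strain that ligand binding relieves. The M2
ring radius and bow amplitudes were chosen so that the closed gate admits
a sphere of about 6 Å diameter and opening widens it by roughly 1 Å,
the regime the analysis is meant to resolve.

**Open state.** αγM2 and δM2 straighten (bows → 0); the β subunit's
extracellular part translates 1.0 Å radially outward as a rigid body while
its four membrane helices rotate 2.0° outward about a tangential axis
through their intracellular ends (so the displacement grows toward the
extracellular leaflet); the αγ binding-site loop rotates 10° toward the
pocket; the α-subunit sheet distortion is relieved. All other subunits
are identical between states.

The quadratic bow parameterisation makes every programmed amplitude
recoverable analytically: the maximum Cα deviation along a bowed helix
equals the amplitude, a pure translation gives that rmsd exactly, and the
rigid helix rotation gives the tilt angle exactly. The parameter-recovery
tests assert these identities to 5% / 0.3°.

**Why the closed/open asymmetry is distributed this way.** Two regional
symmetry signatures are built in deliberately: the closed membrane M2 ring
is near-pentagonal and is broken on opening (two straightened helices
plus the tilted β bundle), most strongly in the extracellular leaflet
(z ≈ 10–17 Å); conversely the closed ligand-binding domain carries the
α-subunit distortions, so the *open* form is the more five-fold-symmetric
one in the lower sheet-packing region (z ≈ 22–35 Å). Both orderings are
asserted on the rendered maps.

**Rendering.** Atoms are deposited with cloud-in-cell weights, blurred
with a fixed 1 Å real-space Gaussian and band-limited by the soft-edge
Fourier lowpass to the target resolution (default 8 Å on a 2 Å grid of
32×32×48 voxels, origin (−32, −32, −30)). The integral is proportional to
atom count; the renderer rejects voxel sizes coarser than resolution/3.

**Noise.** Reconstruction noise is emulated as white Gaussian noise
smoothed to a correlation length (default 4 Å) and scaled to a fraction
σ of the clean render's peak. Ensembles draw each map's state
(closed/open/intermediate, the last being the mean of the two renders —
a tube containing similar numbers of both channel forms) and add
independent noise; every draw descends from one seed via spawned
`SeedSequence` children, so ensembles are bit-reproducible.
An `exact_fractions` switch allocates the state counts deterministically
(positions still shuffled), used when a scenario's purpose is to recover a
known injected fraction rather than to emulate Bernoulli sampling.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: no real side chains or sequence, no projection
imaging, CTF, or helical-lattice reconstruction artifacts, no
inter-molecule lattice contacts, no conformational heterogeneity beyond
the two discrete states plus their mean, and noise that is stationary and
Gaussian rather than structured. Results on the phantom validate the
*operations*; they do not certify performance on any particular
experimental dataset.

## Map primitives

* `DensityMap` holds a cubic-voxel grid indexed (x, y, z) with a physical
  origin; MRC 2014 mode-2 I/O goes through gemmi, with non-orthogonal
  cells and non-cubic voxels rejected on read.
* The lowpass filter retains spatial frequencies below 1/cutoff with a
  cosine roll-off five Fourier voxels wide (ringing suppression). The
  zero-frequency term is always preserved. A soft-edged filter is exactly
  idempotent only outside its edge band; for band-limited content the
  second application changes the map by well under 5% in norm.
* Correlation is Pearson (mean-subtracted, variance-normalised) over an
  optional mask — invariant to affine rescaling of either map. Both a 3D
  correlation and a per-Z-section variant are provided; classification
  uses the 3D form by default (configurable), since on the phantom the
  two give nearly identical discrimination.
* The central mask keeps the central fraction (default 2/3) of Z planes
  with full XY extent.

## Classification

References are voxel-wise averages of labelled single-map
reconstructions. Scoring lowpasses the map and references to the
resolution limit (default 20 Å), masks to the central fraction, and takes
Δcc = cc₊ − cc₋. Assignment is by sign outside a weak-preference band.

* **Weak band.** When not set explicitly it is estimated from the data as
  one third of the half-distance between the positive- and negative-mode
  means of the Δcc sample (falling back to std/3 for one-sided samples).
* **Noise calibration.** The default ensemble noise (σ = 0.015 of the
  render peak) was calibrated so the sorting procedure operates just
  inside its working regime: ≥95% correct assignment on 60-map ensembles
  while injected intermediate-state maps land in the weak band. On this
  phantom the coherent closed/open correlation gap after the 20 Å
  lowpass and central mask is ~0.004–0.01 in Δcc; pushing the noise until
  |Δcc| reaches the few-percent scale familiar from experimental work
  makes Δcc noise-dominated, because experimental map pairs also differ
  by systematic effects (lattice family, CTF, disorder) that the phantom
  deliberately omits. Δcc magnitudes are therefore reported as computed,
  not matched to any external scale.
* **Refinement.** `class_average_and_iterate` recomputes class averages
  from the assignments and optionally re-sorts once against them,
  reporting convergence — a deliberate single pass, not an EM loop.
* The Δcc histogram bin width defaults to 0.0005, matched to the phantom
  Δcc scale, and is configurable.

## Voxel t-maps

Per-voxel ensemble means and (n−1)-denominator standard deviations feed a
two-sample statistic: Welch's t with Welch–Satterthwaite degrees of
freedom by default; the pooled-variance variant (df = n₁ + n₂ − 2) is
available for comparison with older literature. Voxels with zero variance
in both ensembles (exact background) are flagged undefined, set to t = 0
and excluded from contouring. Contours threshold |t| at the Student-t
tail quantile for the requested P (two-sided by default, P = 0.001
following common practice for such difference maps), and supra-threshold
voxels are grouped by 6-connectivity into signed components with voxel
counts, centroids (map coordinates) and peak |t|. Type-I calibration is
asserted on white-noise ensembles (empirical rate within [0.0005, 0.002]
at P = 0.001, n = 30/30, 20 repeats); with spatially correlated noise the
voxel tests are no longer independent, so the empirical rate is reported
but not asserted. No multiple-testing correction is applied — components
are descriptive localisations, not corrected hypothesis tests.

## FSC and symmetry

FSC bins Fourier coefficients into spherical shells (default width: one
Fourier voxel of the largest dimension, coefficients above Nyquist
excluded); shells with fewer than 10 coefficients merge outward. The
0.5-criterion resolution interpolates the first downward crossing
linearly between shell centres; a curve that never crosses reports the
Nyquist period.

The five-fold profile resamples each 1 Å section on rings about the axis
(1° angular, 1 Å radial steps) across an annulus from 8 Å (excluding the
pore) to the molecular envelope (outermost density above mean + 1 σ by
default), takes the azimuthal power spectrum summed over radii, and
reports power in harmonics {5, 10} over the total in n = 1–12 (n = 0
carries no symmetry information). The numerator-{5}-only variant is
returned alongside. Absolute values depend on this normalisation choice,
so only orderings and differences are asserted, never absolute levels.

## Model metrics

Annotated models keep one Cα per residue with subunit and segment labels;
PDB I/O (gemmi) pairs each file with a JSON manifest mapping chains to
subunits and residue ranges (possibly discontinuous) to segments. An
*approximate* manifest for the deposited Torpedo-receptor models ships as
package data, flagged as such; its ranges must be refreshed against the
entries' secondary-structure records before per-residue quantitative use.

* rmsd: matched-order Cα, optionally after Kabsch superposition (the
  superposed value can never exceed the fixed-frame value). For
  deposited-model comparisons both deposited-frame and globally
  superposed numbers are relevant; `superpose_global` provides the
  latter.
* Helix axes: principal component of the Cα cloud, oriented
  extracellular-positive; ≥6 Cα required.
* **Bend profiles and de-coiling.** A raw Cα trace deviates from its
  chord by up to the full 2.3 Å helical coil, swamping genuine axis
  curvature. Each coordinate is therefore fit as a cubic polynomial in
  residue index plus a sinusoid at the helical twist frequency (twist
  estimated by residual minimisation over 80–120°/residue); the
  polynomial part is the local axis trace, with no end-effects even for
  24-residue helices. Bend quantities (per-residue deviation from the
  axis-trace chord, maximum, and the radial/tangential decomposition of
  the deviation direction at the maximum, relative to the pore axis) are
  computed on that trace. On ideal-geometry phantoms this recovers
  programmed bows to ~0.3%. The cubic axis model is an approximation for
  strongly kinked real helices.
* Displacement at a level: mean displacement-vector magnitude over
  residues within a Z window (default 6 Å) of the level; the
  extracellular-leaflet level is taken as z = +10 Å.
* Sheet summary: per-subunit, per-sheet rmsd and mean displacement vector
  in the given frames (no superposition), in ring order.

## Pore profiling

The limiting radius at level z maximises, over probe centres in that
plane, the clearance to the nearest van der Waals surface (3D distances,
atoms within a 6 Å half-width slab). The maximisation is deterministic: a
0.5 Å coarse scan of the 5 Å disc around the axis seeds four Nelder–Mead
refinements; solutions are projected back onto the disc, negative best
clearances clamp to 0 with an `occluded` flag. Profiles warm-start each
section from the previous centre. The optimiser agrees with an
exhaustive 0.05 Å grid search within 0.05 Å across random atom
configurations. The confinement disc is what makes the problem
well-posed — without it the clearance grows without bound outside the
molecule.

Van der Waals radii: C 1.70, N 1.55, O 1.52, S 1.80 Å; phantom Cα-only
pseudo-atoms use 2.0 Å as a stand-in for a full residue. Sphere-probe
dimensions inherit the radii set and side-chain placement, so absolute
values carry roughly ±0.75 Å systematic uncertainty; closed-versus-open
*differences* are much more reliable.

## Problem sizes and determinism

The default study conditions — 60-map ensembles (plus 10-map reference
sets) on 32×32×48 grids at 2 Å voxels and 8 Å render resolution, t-map
calibration over 20 seeded repeats of 30+30 white-noise ensembles,
50-configuration pore-oracle comparisons — were chosen as the smallest
sizes at which every statistical assertion is stable across seeds; all
stages together run in seconds on one CPU. Every stochastic stage takes
an explicit seed, and identical configuration plus seed reproduces
identical outputs (the pipeline report includes SHA-256 hashes of all
artifacts to make this checkable).

## Known limitations

* The phantom's simplifications listed above; in particular, absolute
  Δcc and five-fold-strength scales are phantom-specific.
* Segment annotations for deposited models are approximate until
  refreshed from the entries themselves.
* The t-map offers no multiplicity control by design.
* `fivefold_strength` assumes the symmetry axis is parallel to Z; tilted
  axes must be rectified upstream (e.g. via `resample_to`).
* The pore probe is confined to a disc about a straight vertical axis;
  strongly curved or off-axis channels would need a curved-axis variant.
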