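# gatemap

Analytics for detecting and quantifying the closed→open gating movement of
pentameric ligand-gated ion channels — the muscle-type nicotinic
acetylcholine receptor in particular — from ensembles of 3D density maps
and fitted atomic models.

When such a receptor is activated, the conformational change is small:
roughly a 1 Å outward displacement of the β subunit's extracellular
portion, a ~2° tilt of its four membrane helices, and the straightening of
two pore-lining M2 helices (αγM2 radially, δM2 mostly tangentially) that
bow inward in the closed state to form the mid-membrane hydrophobic gate.
Resolving movements this small from noisy single-particle or single-tube
reconstructions requires a specific toolbox, which this package provides:

* **Δcc classification** — each single reconstruction *m* is scored
  against two reference maps by the difference of Pearson correlations,
  Δcc = cc(m, Ref₊) − cc(m, Ref₋), after lowpass filtering to a
  resolution limit (default 20 Å) and masking to the central two-thirds of
  the molecule along the pore axis. The sign of Δcc assigns the class; maps
  with |Δcc| below a weak-preference band stay unassigned.
* **Voxel t-maps** — Welch's two-sample statistic
  t = (μ₁ − μ₂) / √(s₁²/n₁ + s₂²/n₂) per voxel between two map ensembles,
  contoured at a chosen tail probability (P = 0.001 by default) and
  summarised as signed connected components with centroids, which
  localises reproducible density changes.
* **FSC and half-split validation** — Fourier shell correlation with the
  0.5-criterion resolution, plus seeded random half-dataset splitting.
* **Five-fold symmetry profiles** — per-1 Å-section azimuthal Fourier
  power in the pentamer harmonics (n = 5, 10) relative to n = 1…12,
  a sensitive detector of departures from C5 symmetry.
* **Model geometry** — annotated Cα pentamer models with per-subunit /
  per-segment selections: backbone rmsd (with or without superposition),
  helix-axis tilt angles, helix bend profiles with radial/tangential
  decomposition of the flexure direction, displacement at an axial level,
  and per-subunit sheet-displacement tables.
* **Pore profiling** — HOLE-style sphere-probe limiting radius per axial
  section, R(z) = max over in-plane centres of min over atoms of
  (|c − a| − vdW(a)), and the limiting gate diameter.
* **Synthetic phantoms** — a parameterised toy pentamer (four-helix
  membrane bundle per subunit, two-slab β-sandwich proxy, binding-site
  loop) in closed/open conformations, rendered to density maps with
  band-limited noise, which provides fully ground-truthed ensembles for
  calibrating and validating every step above.

## Worked example

Run the full synthetic pipeline (simulate → sort → t-map → FSC →
symmetry → model metrics → pore) from the shell:

```sh
gatemap replay --seed 1 --out run1/
```

or from Python:

```python
from gatemap.pipeline import RunConfig, replay
report = replay(RunConfig(seed=1, n_maps=30), "run1")
```

On a single CPU this takes a few seconds and prints, among other things:

```
"sort":          accuracy_vs_truth 1.0, weak_fraction 0.0, mean |Δcc| 0.0095
"fsc":           resolution_at_half ≈ 5.7 Å for both class half-splits
"model_metrics": beta_ec_displacement 1.000 Å, beta_helix_tilt 2.000°,
                 αγM2 bend 1.497 Å (radial), δM2 bend 1.996 Å (tangential)
"pore":          gate diameter closed 6.67 Å → open 7.55 Å (increase 0.88 Å)
```

Reading the numbers: all 30 simulated single-tube maps were assigned to
their true class by Δcc sorting; the class averages' half-split FSC
supports the ~6 Å nominal resolution of the renders; the geometry metrics
recover the programmed gating amplitudes (1 Å β displacement, 2° helix
tilt, 1.5/2.0 Å helix flexures) from the noise-free models; and the pore
profile shows a closed gate of about 6 Å limiting diameter that widens by
roughly 1 Å on opening, with the constriction near mid-membrane (Z = 0).

Individual stages are exposed as subcommands: `gatemap simulate`,
`gatemap sort`, `gatemap fsc`, `gatemap symmetry`,
`gatemap compare-models`, `gatemap pore` — see `--help` on each.

Deposited maps and models (e.g. EMD-2071/2072, PDB 4AQ5/4AQ9) can be fed
through the same functions; an *approximate* subunit/segment annotation
manifest for the deposited Torpedo-receptor models ships with the package
(`gatemap.models.packaged_annotation_manifest()`) and should be refreshed
against the entries' secondary-structure records before quantitative use.

## Layout

```
src/gatemap/
  maps.py      DensityMap/Mask, MRC I/O, lowpass, masking, averaging, correlation
  phantom.py   toy pentamer models, density rendering, noisy ensembles
  classify.py  reference building, Δcc scoring, sorting, class averaging
  tmap.py      voxel statistics, Welch/pooled t maps, significance contours
  mapqc.py     FSC, half-splits, five-fold symmetry profiles
  models.py    annotated models, rmsd, helix axes, bends, displacements
  pore.py      sphere-probe limiting radius and pore profiles
  pipeline.py  seeded end-to-end replay with a JSON report
  cli.py       the `gatemap` command group
```

`docs/methods.md` documents the model assumptions, parameter choices and
numerical conventions in detail.
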