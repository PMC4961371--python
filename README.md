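# phmem

Trajectory analysis of peripheral membrane protein binding: orientation
and distance order parameters, normalized 2D density landscapes with
binding-mode detection, ensemble convergence checks, per-residue
protein–lipid contacts, leaflet-resolved lateral radial distribution
functions, and geometric hydrogen-bond persistence.

The package targets the workflow used to characterise how a Pleckstrin
Homology (PH) domain associates with phosphoinositide-containing
bilayers in ensembles of replicate MD simulations: a rigid protein is
released in water above a planar PC/PS/PIP bilayer, binds (or not,
depending on composition), and settles into one or more preferred
orientations while anionic PIP lipids cluster laterally around its basic
patch.  It is written for simulators who have such ensembles (multi-model
PDB, concatenated GRO, or any `(time, coordinates, box)` frame source)
and for method developers, who can exercise every stage against the
bundled synthetic-trajectory generator without an MD engine.

## The order parameters and the landscape

Each frame is reduced to two scalars:

* **R<sub>zz</sub>** — the *zz* element of the least-squares (Kabsch)
  rotation matrix fitting the frame's protein conformation onto a
  reference conformation, computed after first removing the optimal
  rotation about the membrane normal (the in-plane pre-fit).
  R<sub>zz</sub> ∈ [−1, 1]; it equals +1 when the protein is in the
  reference orientation and behaves like cos θ of the tilt away from it.
* **d<sub>z</sub>** — the perpendicular distance between the centres of
  mass of the protein and of the bilayer, in nm.

All replicates are merged into a 2D histogram over (R<sub>zz</sub>,
d<sub>z</sub>).  Each bin count is divided by
(n<sub>sims</sub> × frames per sim × bin area), and the resulting
densities are divided by the density at the global free-energy minimum,
so the normalized landscape lies in [0, 1] with the dominant binding
mode (M1) at 1; minor modes (M2, …) appear as secondary basins found by
local-maximum detection with steepest-ascent basin assignment.

Around the landscape sit the supporting analyses: per-replicate binding
times from sustained d<sub>z</sub> threshold crossings; a 4×5-style
convergence split comparing block landscapes by Jensen–Shannon
divergence; per-residue, species- and lipid-part-resolved contact
profiles (max-normalized per species); lateral, leaflet-resolved
g(r) around the protein with a clustering enrichment factor; and a
geometric D–H···A hydrogen-bond criterion (0.35 nm / 30°) for atomistic
inputs.

## Worked example

```sh
phmem run-all --config examples/demo.yaml
```

generates a scaled synthetic ensemble (5 replicates × 400 ns, 120-lipid
75/20/5 PC/PS/PIP₂ bilayer, mean binding time 100 ns) and runs the full
analysis in a few seconds.  The summary it prints includes:

```json
 "binding_fraction": 1.0,
 "mean_binding_time_ns": 94.4,
 "modes": [
  {"rank": 1, "rzz": 0.975,    "dz_nm": 2.5, "normalized_density": 1.0},
  {"rank": 2, "rzz": 0.216499, "dz_nm": 2.5, "normalized_density": 0.090052}
 ],
 "clustering_enrichment": {"PC": 0.750763, "PIP2": 70.695926, "PS": 0.990506},
 "convergence": {"dominant_mode_consistent": true}
```

Read: every replicate bound, with a mean detected binding time of
94.4 ns against the generator's 100 ns; the landscape recovers the
dominant mode near R<sub>zz</sub> = 1 at the bound height
(d<sub>z</sub> ≈ 2.5 nm) and the minor mode near the generator's
R<sub>zz</sub>\* = 0.2 at 9% of the peak density; PIP₂ is ~70-fold
enriched at contact range around the bound protein while PC and PS show
no enrichment; and both convergence blocks agree on the dominant mode.
`demo_out/` holds the per-stage artifacts (`samples.csv`,
`landscape.tsv` + heat map, `modes.json`, `contacts.csv`, `rdf.csv`,
`convergence_jsd.csv`, `summary.json`).

The same stages are available individually (`phmem simulate | orient |
landscape | modes | converge | contacts | rdf | hbonds`) and as library
functions (`phmem.orientation_series`, `phmem.build_landscape`,
`phmem.find_modes`, `phmem.contact_profile`, `phmem.rdf_lateral`,
`phmem.hbond_series`, …).

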