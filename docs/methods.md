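# Methods

This note documents the models, conventions and numerical choices behind
`phmem`: what each analysis computes, what the synthetic-trajectory
generator does and does not emulate, and where the design was genuinely
open.

## Conventions

Lengths are nm (PDB Å are divided by 10 on read), times ns, masses u.
The bilayer normal is +z; the bilayer midplane defines the z origin for
reported heights.  Boxes are orthorhombic; triclinic input is rejected
rather than mishandled.  Periodic images are applied laterally (x, y)
where distances are computed; no whole-molecule re-wrapping is done.
PDB alternate locations: the first conformer is kept, the rest dropped
with a logged warning.  Masses default to element inference from atom
names; unrecognised (coarse-grained bead) names default to 72 u, the
MARTINI 4-to-1 mapping convention, and the annotation table can override
any mass.

## Orientation order parameters

`compute_rzz` uses a two-step fitting sequence (the trjconv-then-g_rotmat
order of the GROMACS toolchain): first the optimal rotation about z is
removed with a
closed-form 2D least-squares fit (θ\* = atan2(Σ(x<sub>m</sub>y<sub>r</sub>
− y<sub>m</sub>x<sub>r</sub>), Σ(x<sub>m</sub>x<sub>r</sub> +
y<sub>m</sub>y<sub>r</sub>)) on COM-centred coordinates, z untouched),
then the full 3D Kabsch rotation onto the reference is computed and its
(3,3) element reported.  Composing the fitted rotation with any rotation
about z leaves the zz element unchanged, so R<sub>zz</sub> is invariant
to the protein spinning in the membrane plane — it measures tilt only —
and equals cos θ exactly for a tilt θ about any in-plane axis.  The
Kabsch implementation corrects the reflection branch
(det = +1 enforced via the sign of det(VU<sup>T</sup>)) and raises on
collinear or coincident point sets (second singular value ≤ 1e−9 of the
first).

d<sub>z</sub> is the |Δz| of mass-weighted COMs, protein vs all lipid
particles; a signed variant is kept for leaflet-side diagnostics.  The
protein COM uses all protein particles, mass-weighted (a backbone-only
selection can be passed instead).

**Reference selection.** There is no standard recipe for choosing the
preferred-orientation reference frame from trajectories; this package's
documented convention is: subsample up to 100 bound frames
(d<sub>z</sub> ≤ threshold, seeded), and take the medoid under pairwise
RMSD computed after COM centring and the in-plane pre-fit *only*.  A
full-superposition RMSD would be blind to orientation for a near-rigid
protein (any two orientations superpose to ~0), whereas the pre-fit-only
RMSD treats in-plane spins as equivalent but registers tilts, so the
medoid of a dominantly-oriented ensemble lands in the major mode.

## Density landscape

Half-open bins [lo, hi), last bin closed; defaults 40 × 40 over
R<sub>zz</sub> ∈ [−1, 1] (width 0.05, resolving modes 0.2 apart) and
d<sub>z</sub> ∈ [0, 8] nm (width 0.2).  Out-of-range samples are dropped
and counted.  Density = counts / (n<sub>sims</sub> × frames per sim ×
bin area), computed per bin so non-uniform grids are handled.  The final
division "by the density at the global minimum" is implemented as
division by the maximum bin density — the density at the global
free-energy minimum — giving normalized values in [0, 1]; dividing by
the *smallest* density would be undefined for empty bins.  All frames
enter the histogram, including the pre-binding approach; this makes the
composition dependence visible (a non-binding ensemble shows only a
high-d<sub>z</sub> band) at the cost of extra block-to-block variance in
the convergence check (below).

**Mode detection.** Local maxima of the normalized grid
(8-neighbourhood) above `min_relative_density` (default 0.02 — a
~20%-occupancy minor mode spread over a few bins sits near 5–10% of the
peak, and features of that size are what "minor minimum" means here) are
accepted greedily in descending density order with a minimum peak
separation (Chebyshev, default 3 bins).  Bins are assigned to basins by
steepest ascent; rejected summits merge into the nearest accepted peak.
The reported mode center is the density-weighted centroid of the *basin
core* — basin bins at ≥ half the mode's peak density.  A literal
all-basin centroid would be dragged several bins off the summit by the
broad low-density approach region that steepest ascent funnels into the
bound basin; the half-max core keeps the center on the feature the mode
names.  Ties break toward lower d<sub>z</sub>, then lower R<sub>zz</sub>.

**Binding detection.** A replicate binds at the first time
d<sub>z</sub> ≤ threshold holds for ≥ `min_persist` (default 10)
consecutive frames; sustained recrossings are reported as dissociation
events.  The default threshold is bilayer half-thickness + the protein's
radius of gyration (2.0 + ~0.7 ≈ 2.7 nm for the synthetic system),
overridable since the bound-height line is system-specific.

**Convergence.** Replicates are split into disjoint blocks (default 4);
each block's landscape is compared pairwise by Jensen–Shannon divergence
(natural log; 0 identical, ln 2 maximum) of the count-normalized
distributions, and each block's dominant-mode peak is checked against
the full ensemble's within one bin.  Note the caveat: with exponential
binding times of mean ~0.25 of the trajectory length, 5-replicate
blocks differ substantially in their bound/unbound frame-mass split, and
that mass difference alone contributes several hundredths of a nat of
pairwise JSD before any landscape-shape disagreement.  The
dominant-mode consistency flag is the robust convergence statement; the
JSD matrix quantifies, it does not threshold.

## Contacts, RDFs, hydrogen bonds

A contact is counted once per (protein residue, lipid molecule, frame)
when any particle of the molecule is within the cutoff of any particle
of the residue (3D distance, minimum image in x, y).  Default cutoff
0.6 nm for coarse three-bead lipids, 0.4 nm recommended for atomistic
input.  Profiles are averaged over frames (optionally bound frames only,
d<sub>z</sub> ≤ threshold) and replicates, normalized per species by the
maximum residue value — the convention used for "normalized
interaction" plots; the absolute normalization constant of such plots is
not standardized, so only the per-species shape is comparable.  With
`parts=True` the same count is resolved by headgroup / phosphate / tail.

The RDF is lateral (2D): distances in the membrane plane from the
protein's lateral COM to the headgroup COM of each molecule of the
species within one leaflet, annulus-normalized by the uniform lateral
density of that species in that leaflet, averaged over (by default,
bound) frames and replicates; r<sub>max</sub> must stay below half the
smaller lateral box edge.  Lateral-2D was chosen over 3D because lipid
clustering is an in-plane, single-leaflet phenomenon; the 3D variant
would convolve the bilayer geometry into g(r).  The clustering summary
is mean g at contact range (r ≤ 0.7 nm) over mean far-field g (top
quartile of r); > 1 indicates enrichment.  Leaflet membership is
assigned by headgroup-COM side of the bilayer COM on the first frame
(flat bilayers; a curved or flip-flopping system would need per-frame
assignment).

Hydrogen bonds use the geometric criterion d(D, A) ≤ 0.35 nm and
H–D···A ≤ 30°, the GROMACS toolchain default, since no criterion is
standard-free.  Donor/acceptor typing comes from a bundled lookup for
standard residues and lipid phosphate/ester oxygens, extensible through
the annotation table; topologies without hydrogens fall back (logged) to
the distance-only heavy-atom criterion, and the pipeline skips the
H-bond stage entirely for coarse-grained input rather than report
pseudo-bonds.

## Synthetic-trajectory generator

The generator produces replicate ensembles with known ground truth for
every quantity the analyses measure.  The defaults describe a typical
coarse-grained binding study: a 356-lipid planar bilayer at 75/20/5 PC/PS/PIP₂
(largest-remainder apportionment; per-species leaflet difference ≤ 1;
area per lipid 0.65 nm² giving a ~10.8 nm box), 20 replicates × 1000
frames × 1 ns, protein released 7 nm above the midplane, exponential
binding times of mean 250 ns, bound modes at R<sub>zz</sub>\* = 1.0
(occupancy 0.75) and 0.2 (0.20) with a 0.05 transient remainder.

Mechanics: the protein is a rigid 50-bead cloud (radius 0.9 nm, one bead
per residue, the 8 lowest-z beads named LYS/ARG as the basic patch).
Unbound, its COM holds near the start height under an
Ornstein–Uhlenbeck tether (it emulates "diffusing in the water slab"
without ever wandering to the membrane, so PIP-free compositions show
strictly zero binding) and its orientation diffuses with angular noise
0.5 rad/√ns — a tumbling time of ~8 ns, the Stokes–Einstein–Debye scale
for a ~2 nm domain.  At the drawn binding time it descends at 0.3 nm/ns;
inside the capture radius a bound mode is sampled by occupancy and the
tilt relaxes toward the mode's θ\* = arccos R<sub>zz</sub>\* at 1 /ns
against angular noise 0.1 rad/√ns, a bound wobble of ~4° typical of a
stably bound peripheral domain and narrow enough that the two modes are
distinct basins; the bound mode is resampled at 0.01 /ns so mode
occupancies equilibrate within each replicate.  Orientations are
propagated as rotation compositions (rotation-vector increments applied
to the full matrix), never Euler angles.  Lipids are three beads
(headgroup 2.0, phosphate 1.7, tail 0.8 nm from the midplane) on a
common lateral position that random-walks at 0.14 nm/√ns
(D ≈ 0.01 nm²/ns); while the protein is bound, PIP lipids in its leaflet
drift at 0.05 nm/ns toward the basic patch's lateral position inside a
3 nm attraction range, with a 0.45 nm lateral hard core that produces
the contact-distance peak in g(r).  The master seed fully determines the
output via spawned per-replicate generators.

What it does **not** emulate: forces, energetics, water and ions, lipid
z-fluctuations and flip-flop, protein flexibility, membrane undulations,
lipid–lipid excluded volume, or any electrostatics — kinetics and
clustering are phenomenological.  Passing tests therefore certify the
*analysis machinery* (geometry, counting, normalization, detection and
statistics) under realistic statistical structure, not the physics of
any real protein–membrane system.

## Problem sizes in the test suite

The full study-scale fixture (20 × 1000 frames, 356 lipids) backs the
landscape/mode-recovery and convergence checks.  Statistics that need
many seeds or replicates use reduced systems chosen for statistical
power per unit work: binding-time recovery uses 100 replicates on a
16-lipid bilayer (d<sub>z</sub> dynamics are independent of lipid
count), uniformity and clustering checks use 64–120 lipids, and the
exponential-distribution check (Anderson–Darling at α = 0.01) uses 200
drawn binding times.  The demo config runs 5 × 400 frames on 120 lipids.

## Known limitations

* The in-plane pre-fit assumes the membrane normal is exactly +z; tilted
  or curved membranes are out of scope.
* Leaflet assignment is first-frame static.
* `select_reference` assumes a near-rigid protein; for genuinely
  flexible proteins its pre-fit-only RMSD mixes conformational and
  orientational differences.
* The JSD convergence number inherits bound/unbound mass variance from
  binding kinetics (see above); compare blocks of similar binding
  history, or read the dominant-mode flag, when kinetics are slow.
* Contact counting is O(N_protein × N_lipid) per frame with no cell
  lists; fine at the few-thousand-particle scale this targets.
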