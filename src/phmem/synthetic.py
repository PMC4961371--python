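"""Synthetic bilayer structures and replicate binding-trajectory ensembles.

The generator emulates the statistical structure of ensembles of
coarse-grained simulations of a rigid peripheral protein released ~7 nm
above a planar PC/PS/PIP bilayer: composition-dependent exponential binding
kinetics, a dominant bound orientation plus a minor alternative, and
lateral PIP clustering around the bound protein.  There are no physical
forces — kinetics and clustering are phenomenological — but every quantity
the analysis modules measure (binding times, orientation modes, leaflet
occupancy, contacts, radial distributions) has a known ground truth.

Each lipid is three pseudo-particles on a common lateral position:
headgroup (HD), phosphate (PO4) and tail (TA) at fixed z offsets from the
bilayer midplane, so part-resolved contact analyses are exercisable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    CG_BEAD_MASS,
    EnsembleSet,
    MolecularTopology,
    PackingError,
    SimulationFrame,
    Trajectory,
    lateral_minimum_image,
    read_annotation,
    read_trajectory,
    write_annotation,
    write_trajectory,
)

# --- fixed geometry / dynamics constants (nm, ns) --------------------------
HEAD_OFFSET = 2.0       # headgroup plane height above midplane (half thickness)
PHOS_OFFSET = 1.7
TAIL_OFFSET = 0.8
MIDPLANE_Z = 4.0        # absolute z of the bilayer midplane in the box
BOX_HEIGHT = 14.0
MIN_AREA_PER_LIPID = 0.2   # packing limit, nm^2

PROT_LATERAL_STEP = 0.08   # protein lateral diffusion, nm / sqrt(ns)
Z_RELAX_UNBOUND = 0.05     # OU rate keeping the unbound protein near its start
Z_NOISE_UNBOUND = 0.2      # nm / sqrt(ns)
DESCENT_SPEED = 0.3        # nm/ns once the drawn binding time has passed
Z_RELAX_BOUND = 0.5
Z_NOISE_BOUND = 0.05
BOUND_CLEARANCE = 0.5      # bound protein COM height above the headgroup plane
ROT_DIFF_UNBOUND = 0.5     # rad / sqrt(ns); tumbling time ~8 ns, the
                           # Stokes-Einstein-Debye scale of a ~2 nm domain
TILT_RELAX = 1.0           # 1/ns restoring rate toward the mode tilt
MODE_SWITCH_RATE = 0.01    # 1/ns resampling rate of the bound mode
LIPID_STEP = 0.14          # nm / sqrt(ns)  (D ~ 0.01 nm^2/ns)
PIP_DRIFT = 0.05           # nm/ns drift toward the protein at unit strength
PIP_CORE = 0.45            # lateral hard-core radius around the protein COM

_PATCH_RESNAMES = ("LYS", "ARG")
_FILLER_RESNAMES = ("ALA", "SER", "THR", "VAL", "LEU", "ILE", "GLY", "ASP",
                    "GLU", "ASN", "GLN", "PHE", "TYR", "TRP", "MET", "HIS")


@dataclass
class BilayerSpec:
    """Planar bilayer: lipid count, composition and packing."""

    total_lipids: int = 356
    composition: dict = field(default_factory=lambda: {
        "PC": 0.75, "PS": 0.20, "PIP2": 0.05})
    area_per_lipid: float = 0.65       # nm^2
    leaflet_separation: float = 2 * HEAD_OFFSET  # headgroup-to-headgroup, nm

    def __post_init__(self) -> None:
        tot = sum(self.composition.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"mole fractions sum to {tot}, not 1")
        if self.total_lipids < 2:
            raise ValueError("need at least 2 lipids")
        if self.area_per_lipid < MIN_AREA_PER_LIPID:
            raise PackingError(
                f"area per lipid {self.area_per_lipid} nm^2 below packing "
                f"limit {MIN_AREA_PER_LIPID} nm^2")

    @property
    def pip_fraction(self) -> float:
        return sum(v for k, v in self.composition.items()
                   if k in ("PIP2", "PIP3"))

    @property
    def box_xy(self) -> float:
        n_upper = (self.total_lipids + 1) // 2
        return math.sqrt(n_upper * self.area_per_lipid)


@dataclass
class ToyDynamicsSpec:
    """Phenomenological rigid-body binding dynamics of one ensemble.

    ``mode_centers`` lists bound orientations as (Rzz*, occupancy); the
    occupancy remainder is spent in transient (freely tumbling) bound
    orientations.  ``mean_binding_time`` is the mean of the exponential
    binding-time draw; ``inf`` disables binding (as does a PIP-free
    bilayer).  The seed fully determines the output.
    """

    n_replicates: int = 20
    n_frames: int = 1000
    dt: float = 1.0                 # ns per frame
    start_height: float = 7.0       # nm above the midplane
    capture_radius: float = 3.5     # nm; orientation relaxation engages here
    mean_binding_time: float = 250.0  # ns; inf = non-binding
    mode_centers: tuple = ((1.0, 0.75), (0.2, 0.20))
    orientation_noise: float = 0.1  # rad / sqrt(ns) bound angular noise
    pip_attraction_range: float = 3.0  # nm
    pip_cluster_strength: float = 1.0  # 0 disables clustering
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        occ = sum(f for _, f in self.mode_centers)
        if occ > 1.0 + 1e-9:
            raise ValueError(f"mode occupancies sum to {occ} > 1")
        for rzz, _ in self.mode_centers:
            if not -1.0 <= rzz <= 1.0:
                raise ValueError(f"mode Rzz* {rzz} outside [-1, 1]")


# ---------------------------------------------------------------------------
# apportionment and bilayer construction
# ---------------------------------------------------------------------------

def largest_remainder(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Integer apportionment of ``total`` across categories matching the
    target fractions: floors first, then one extra to the largest
    remainders (ties broken by listed order)."""
    items = list(fractions.items())
    raw = [f * total for _, f in items]
    counts = [int(math.floor(r)) for r in raw]
    short = total - sum(counts)
    order = sorted(range(len(items)),
                   key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return {k: c for (k, _), c in zip(items, counts)}


def split_leaflets(counts: dict[str, int]) -> tuple[dict[str, int], dict[str, int]]:
    """Split per-species counts across leaflets with at most one lipid
    difference per species and balanced totals."""
    total = sum(counts.values())
    n_upper = (total + 1) // 2
    upper = {k: c // 2 for k, c in counts.items()}
    deficit = n_upper - sum(upper.values())
    for k, c in counts.items():
        if deficit == 0:
            break
        if c % 2 == 1:
            upper[k] += 1
            deficit -= 1
    lower = {k: counts[k] - upper[k] for k in counts}
    return upper, lower


def build_bilayer(spec: BilayerSpec, seed: int = 0,
                  residue_offset: int = 0,
                  ) -> tuple[MolecularTopology, SimulationFrame]:
    """Place lipids on two jittered lattices with species randomly
    interleaved laterally; three pseudo-particles per lipid."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB11A]))
    counts = largest_remainder(spec.composition, spec.total_lipids)
    upper_counts, lower_counts = split_leaflets(counts)
    box_xy = spec.box_xy
    half = spec.leaflet_separation / 2.0
    offsets = {
        "upper": (MIDPLANE_Z + half, MIDPLANE_Z + half - (HEAD_OFFSET - PHOS_OFFSET),
                  MIDPLANE_Z + half - (HEAD_OFFSET - TAIL_OFFSET)),
        "lower": (MIDPLANE_Z - half, MIDPLANE_Z - half + (HEAD_OFFSET - PHOS_OFFSET),
                  MIDPLANE_Z - half + (HEAD_OFFSET - TAIL_OFFSET)),
    }

    names, resid, resname, species_arr, part_arr = [], [], [], [], []
    coords = []
    res_counter = residue_offset
    for leaflet, leaf_counts in (("upper", upper_counts), ("lower", lower_counts)):
        n_leaf = sum(leaf_counts.values())
        if n_leaf == 0:
            continue
        n_side = math.ceil(math.sqrt(n_leaf))
        a = box_xy / n_side
        sites = [((i + 0.5) * a, (j + 0.5) * a)
                 for i in range(n_side) for j in range(n_side)][:n_leaf]
        jitter = rng.uniform(-0.15 * a, 0.15 * a, size=(n_leaf, 2))
        species_list = [sp for sp, c in leaf_counts.items() for _ in range(c)]
        rng.shuffle(species_list)
        zh, zp, zt = offsets[leaflet]
        for (sx, sy), (jx, jy), sp in zip(sites, jitter, species_list):
            res_counter += 1
            x, y = (sx + jx) % box_xy, (sy + jy) % box_xy
            for nm, prt, z in (("HD", "headgroup", zh),
                               ("PO4", "phosphate", zp),
                               ("TA", "tail", zt)):
                names.append(nm)
                resid.append(res_counter)
                resname.append(sp)
                species_arr.append(sp)
                part_arr.append(prt)
                coords.append((x, y, z))

    n = len(names)
    topo = MolecularTopology(
        names=np.array(names, dtype=object),
        residue_index=np.array(resid, dtype=np.int64),
        residue_name=np.array(resname, dtype=object),
        segment=np.array(["MEMB"] * n, dtype=object),
        category=np.array(["lipid"] * n, dtype=object),
        lipid_species=np.array(species_arr, dtype=object),
        lipid_part=np.array(part_arr, dtype=object),
        mass=np.full(n, CG_BEAD_MASS),
    )
    frame = SimulationFrame(time=0.0, coordinates=np.array(coords),
                            box=np.array([box_xy, box_xy, BOX_HEIGHT]))
    return topo, frame


# ---------------------------------------------------------------------------
# synthetic protein
# ---------------------------------------------------------------------------

def make_protein(n_particles: int = 50, radius: float = 0.9,
                 n_patch: int = 8, seed: int = 0,
                 ) -> tuple[MolecularTopology, np.ndarray]:
    """A rigid one-bead-per-residue protein: particles uniform in a sphere,
    centred on its COM, with the ``n_patch`` lowest-z residues named
    LYS/ARG to mark the membrane-facing basic patch.  Returns the topology
    and the template coordinates (nm, COM at the origin); in the template
    orientation (identity rotation, Rzz = +1) the patch faces -z.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA0]))
    u = rng.uniform(size=n_particles) ** (1.0 / 3.0)
    v = rng.normal(size=(n_particles, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    x = radius * u[:, None] * v
    x -= x.mean(axis=0)
    order = np.argsort(x[:, 2])
    patch = set(order[:n_patch].tolist())
    resnames = []
    fill = 0
    for i in range(n_particles):
        if i in patch:
            resnames.append(_PATCH_RESNAMES[i % len(_PATCH_RESNAMES)])
        else:
            resnames.append(_FILLER_RESNAMES[fill % len(_FILLER_RESNAMES)])
            fill += 1
    topo = MolecularTopology(
        names=np.array(["BB"] * n_particles, dtype=object),
        residue_index=np.arange(1, n_particles + 1, dtype=np.int64),
        residue_name=np.array(resnames, dtype=object),
        segment=np.array(["PROT"] * n_particles, dtype=object),
        category=np.array(["protein"] * n_particles, dtype=object),
        lipid_species=np.array([""] * n_particles, dtype=object),
        lipid_part=np.array([""] * n_particles, dtype=object),
        mass=np.full(n_particles, CG_BEAD_MASS),
    )
    return topo, x


def basic_patch_index(topology: MolecularTopology) -> np.ndarray:
    """Particle indices of basic-patch (LYS/ARG) protein residues."""
    return np.flatnonzero((topology.category == "protein")
                          & np.isin(topology.residue_name, _PATCH_RESNAMES))


def merge_topologies(protein: MolecularTopology, bilayer: MolecularTopology,
                     ) -> MolecularTopology:
    """Protein particles first, then lipids; lipid residue indices are kept
    distinct from protein residue indices (bilayer built with an offset)."""
    cat = lambda a, b: np.concatenate([a, b])
    return MolecularTopology(
        names=cat(protein.names, bilayer.names),
        residue_index=cat(protein.residue_index, bilayer.residue_index),
        residue_name=cat(protein.residue_name, bilayer.residue_name),
        segment=cat(protein.segment, bilayer.segment),
        category=cat(protein.category, bilayer.category),
        lipid_species=cat(protein.lipid_species, bilayer.lipid_species),
        lipid_part=cat(protein.lipid_part, bilayer.lipid_part),
        mass=cat(protein.mass, bilayer.mass),
    )


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def _sample_mode(rng: np.random.Generator, spec: ToyDynamicsSpec):
    """Return the target tilt angle of a sampled bound mode, or None for a
    transient (unrestrained) orientation."""
    u = rng.uniform()
    acc = 0.0
    for rzz_star, occ in spec.mode_centers:
        acc += occ
        if u < acc:
            return math.acos(max(-1.0, min(1.0, rzz_star)))
    return None


def _rotate_step(R: np.ndarray, target_tilt, noise_sd: float, relax: float,
                 rng: np.random.Generator, dt: float) -> np.ndarray:
    """One orientation update: optional tilt relaxation toward the target
    plus isotropic angular noise, composed as a lab-frame rotation."""
    rotvec = noise_sd * math.sqrt(dt) * rng.normal(size=3)
    if target_tilt is not None:
        a = R[:, 2]
        czz = max(-1.0, min(1.0, a[2]))
        theta = math.acos(czz)
        axis = np.array([a[1], -a[0], 0.0])  # a x ez
        norm = np.linalg.norm(axis)
        if norm < 1e-10:
            axis = np.array([1.0, 0.0, 0.0])
            norm = 1.0
        rotvec = rotvec + (axis / norm) * (relax * (theta - target_tilt) * dt)
    return Rotation.from_rotvec(rotvec).as_matrix() @ R


def generate_replicate(bilayer_topo: MolecularTopology,
                       bilayer_frame: SimulationFrame,
                       protein_topo: MolecularTopology,
                       protein_template: np.ndarray,
                       dynamics: ToyDynamicsSpec,
                       replicate_id: int,
                       topology: MolecularTopology,
                       pip_fraction: float,
                       rng: np.random.Generator,
                       condition: str,
                       patch_idx: np.ndarray | None = None) -> Trajectory:
    """Propagate one replicate; see the module docstring for the model."""
    dt = dynamics.dt
    box = bilayer_frame.box.copy()
    n_lip = len(np.unique(bilayer_topo.residue_index))
    lip_coords0 = bilayer_frame.coordinates.reshape(n_lip, 3, 3)
    lip_xy = lip_coords0[:, 0, :2].copy()          # shared lateral position
    lip_z = lip_coords0[:, :, 2].copy()            # fixed bead heights
    lip_species = bilayer_topo.lipid_species.reshape(n_lip, 3)[:, 0]
    upper = lip_z[:, 0] > MIDPLANE_Z
    pip_upper = np.flatnonzero(upper & np.isin(lip_species, ("PIP2", "PIP3")))

    if patch_idx is None or patch_idx.size == 0:
        patch_idx = np.arange(len(protein_template))
    binds = np.isfinite(dynamics.mean_binding_time) and pip_fraction > 0
    t_bind = float(rng.exponential(dynamics.mean_binding_time)) if binds else math.inf

    R = _random_rotation(rng)
    com = np.array([box[0] / 2.0, box[1] / 2.0,
                    MIDPLANE_Z + dynamics.start_height])
    z_bound = MIDPLANE_Z + HEAD_OFFSET + BOUND_CLEARANCE
    state = "unbound"
    mode_tilt = None
    captured = False
    first_bound_frame = None

    frames = []
    sqdt = math.sqrt(dt)
    for i in range(dynamics.n_frames):
        t = i * dt
        prot = protein_template @ R.T + com
        lip = np.empty((n_lip, 3, 3))
        lip[:, :, 0] = lip_xy[:, None, 0]
        lip[:, :, 1] = lip_xy[:, None, 1]
        lip[:, :, 2] = lip_z
        frames.append(SimulationFrame(
            time=t, coordinates=np.vstack([prot, lip.reshape(-1, 3)]),
            box=box.copy()))

        # --- protein update ---
        com[:2] += PROT_LATERAL_STEP * sqdt * rng.normal(size=2)
        com[:2] %= box[:2]
        if state == "unbound":
            com[2] += (Z_RELAX_UNBOUND * (MIDPLANE_Z + dynamics.start_height
                                          - com[2]) * dt
                       + Z_NOISE_UNBOUND * sqdt * rng.normal())
            R = _rotate_step(R, None, ROT_DIFF_UNBOUND, 0.0, rng, dt)
            if t + dt >= t_bind:
                state = "descending"
        elif state == "descending":
            com[2] -= DESCENT_SPEED * dt
            if not captured and com[2] - MIDPLANE_Z <= dynamics.capture_radius:
                mode_tilt = _sample_mode(rng, dynamics)
                captured = True
            if captured:
                R = _rotate_step(R, mode_tilt, dynamics.orientation_noise,
                                 TILT_RELAX, rng, dt)
            else:
                R = _rotate_step(R, None, ROT_DIFF_UNBOUND, 0.0, rng, dt)
            if com[2] <= z_bound:
                com[2] = z_bound
                state = "bound"
                first_bound_frame = i + 1
        else:  # bound
            com[2] += (Z_RELAX_BOUND * (z_bound - com[2]) * dt
                       + Z_NOISE_BOUND * sqdt * rng.normal())
            if rng.uniform() < MODE_SWITCH_RATE * dt:
                mode_tilt = _sample_mode(rng, dynamics)
            R = _rotate_step(R, mode_tilt, dynamics.orientation_noise,
                             TILT_RELAX, rng, dt)

        # --- lipid update ---
        lip_xy += LIPID_STEP * sqdt * rng.normal(size=(n_lip, 2))
        if state == "bound" and dynamics.pip_cluster_strength > 0 \
                and pip_upper.size:
            # PIPs drift toward the basic patch's lateral position
            patch_xy = (protein_template[patch_idx] @ R.T
                        + com)[:, :2].mean(axis=0)
            d = lateral_minimum_image(patch_xy - lip_xy[pip_upper], box)
            dist = np.linalg.norm(d, axis=1)
            in_range = (dist < dynamics.pip_attraction_range) & (dist > 1e-9)
            drift = np.zeros_like(d)
            drift[in_range] = (d[in_range] / dist[in_range, None]
                               * PIP_DRIFT * dynamics.pip_cluster_strength * dt)
            lip_xy[pip_upper] += drift
            # lateral hard core around the patch position
            d = lateral_minimum_image(lip_xy[pip_upper] - patch_xy, box)
            dist = np.linalg.norm(d, axis=1)
            close = dist < PIP_CORE
            if np.any(close):
                dist_safe = np.where(dist[close] < 1e-9, 1e-9, dist[close])
                lip_xy[pip_upper[close]] = (
                    patch_xy + d[close] / dist_safe[:, None] * PIP_CORE)
        lip_xy %= box[:2]

    return Trajectory(
        replicate_id=replicate_id, frames=frames, topology=topology,
        condition=condition,
        meta={"t_bind_drawn": None if math.isinf(t_bind) else t_bind,
              "first_bound_frame": first_bound_frame,
              "bound": state == "bound"})


def iter_replicates(bilayer: BilayerSpec, dynamics: ToyDynamicsSpec,
                    protein: tuple[MolecularTopology, np.ndarray] | None = None,
                    condition: str | None = None) -> Iterator[Trajectory]:
    """Yield replicate trajectories one at a time (memory-friendly)."""
    if protein is None:
        protein = make_protein(seed=dynamics.seed)
    protein_topo, template = protein
    if template.shape[0] < 3:
        raise ValueError("protein needs at least 3 particles")
    bl_topo, bl_frame = build_bilayer(
        bilayer, seed=dynamics.seed,
        residue_offset=int(protein_topo.residue_index.max()) + 100)
    topology = merge_topologies(protein_topo, bl_topo)
    if condition is None:
        condition = "/".join(f"{k}:{v:g}" for k, v in bilayer.composition.items())
    patch_idx = basic_patch_index(protein_topo)
    seqs = np.random.SeedSequence([int(dynamics.seed), 0xE27]).spawn(
        dynamics.n_replicates)
    for rep, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        yield generate_replicate(bl_topo, bl_frame, protein_topo, template,
                                 dynamics, rep, topology,
                                 bilayer.pip_fraction, rng, condition,
                                 patch_idx=patch_idx)


def generate_ensemble(bilayer: BilayerSpec, dynamics: ToyDynamicsSpec,
                      protein: tuple[MolecularTopology, np.ndarray] | None = None,
                      condition: str | None = None) -> EnsembleSet:
    """Generate the full replicate ensemble in memory."""
    trajs = list(iter_replicates(bilayer, dynamics, protein, condition))
    return EnsembleSet(trajectories=trajs, topology=trajs[0].topology,
                       condition=trajs[0].condition)


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_ensemble(ensemble: EnsembleSet, directory: str | Path,
                   specs: dict | None = None) -> dict:
    """Write one multi-model PDB per replicate, the shared annotation table
    and a JSON manifest (specs, seeds and frame times); returns the
    manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_annotation(directory / "topology.tsv", ensemble.topology)
    manifest = {
        "condition": ensemble.condition,
        "topology": "topology.tsv",
        "specs": specs or {},
        "replicates": [],
    }
    for traj in ensemble.trajectories:
        fname = f"replicate_{traj.replicate_id:03d}.pdb"
        write_trajectory(directory / fname, traj)
        manifest["replicates"].append({
            "replicate_id": traj.replicate_id,
            "file": fname,
            "times_ns": [float(f.time) for f in traj.frames],
            "boxes_nm": [[float(v) for v in f.box] for f in traj.frames],
            "meta": {k: (None if v is None else
                         (bool(v) if isinstance(v, (bool, np.bool_)) else float(v)))
                     for k, v in traj.meta.items()},
        })
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_ensemble(directory: str | Path) -> EnsembleSet:
    """Load an ensemble written by :func:`write_ensemble`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    topo = read_annotation(directory / manifest["topology"])
    trajs = []
    for rep in manifest["replicates"]:
        traj = read_trajectory(directory / rep["file"], topo,
                               replicate_id=rep["replicate_id"],
                               times=rep["times_ns"],
                               boxes=rep.get("boxes_nm"),
                               condition=manifest["condition"])
        traj.meta.update(rep.get("meta", {}))
        trajs.append(traj)
    return EnsembleSet(trajectories=trajs, topology=topo,
                       condition=manifest["condition"])


def spec_dict(bilayer: BilayerSpec, dynamics: ToyDynamicsSpec) -> dict:
    d = {"bilayer": asdict(bilayer), "dynamics": asdict(dynamics)}
    d["dynamics"]["mode_centers"] = [list(m) for m in dynamics.mode_centers]
    return d
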