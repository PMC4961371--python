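"""Domain types, structure/trajectory I/O and rigid-body geometry.

Conventions used throughout the package:

* lengths are in nanometres (PDB Angstroms are converted on read),
* times are in nanoseconds,
* the bilayer normal is +z and the bilayer midplane defines the z origin
  for reported quantities,
* simulation boxes are orthorhombic (triclinic input is rejected).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("phmem")

A_PER_NM = 10.0  # Angstrom per nanometre

LIPID_SPECIES = ("PC", "PS", "PIP2", "PIP3", "other")
LIPID_PARTS = ("headgroup", "phosphate", "tail")

#: residue names recognised as lipids when no annotation table is given
_LIPID_RESNAMES = {
    "PC": "PC", "POPC": "PC", "DPPC": "PC",
    "PS": "PS", "POPS": "PS",
    "PIP2": "PIP2", "PI24": "PIP2", "POP2": "PIP2",
    "PIP3": "PIP3", "PI34": "PIP3", "POP3": "PIP3",
}

#: bead-name -> lipid part for the three-bead coarse lipid model
_PART_BY_NAME = {"HD": "headgroup", "PO4": "phosphate", "TA": "tail"}

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06,
}

CG_BEAD_MASS = 72.0  # MARTINI-style default bead mass, u


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class PhmemError(Exception):
    """Base class for package errors."""


class ParseError(PhmemError):
    """A structure or table file could not be parsed."""


class UnsupportedFormatError(PhmemError):
    """The requested file format is not supported."""


class DegenerateGeometryError(PhmemError):
    """A geometric operation received a degenerate point set."""


class SelectionError(PhmemError):
    """An empty or invalid particle selection."""


class PackingError(PhmemError):
    """Lipids cannot be packed at the requested area per lipid."""


class ConfigError(PhmemError):
    """Invalid analysis configuration."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MolecularTopology:
    """Per-particle annotation: identity, residue, category and mass.

    ``category`` is ``"protein"`` or ``"lipid"``; ``lipid_species`` and
    ``lipid_part`` are the empty string for protein particles and one of
    :data:`LIPID_SPECIES` / :data:`LIPID_PARTS` for lipid particles.
    """

    names: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    segment: np.ndarray
    category: np.ndarray
    lipid_species: np.ndarray
    lipid_part: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        arrays = (self.residue_index, self.residue_name, self.segment,
                  self.category, self.lipid_species, self.lipid_part, self.mass)
        if any(len(a) != n for a in arrays):
            raise ValueError("topology arrays must have equal length")
        bad = set(np.unique(self.category)) - {"protein", "lipid"}
        if bad:
            raise ValueError(f"unknown particle categories: {sorted(bad)}")
        is_lip = self.category == "lipid"
        if np.any((self.lipid_species != "") != is_lip):
            raise ValueError("lipid_species must be set iff category is lipid")
        if np.any((self.lipid_part != "") != is_lip):
            raise ValueError("lipid_part must be set iff category is lipid")
        # residue indices within a segment must be non-decreasing
        for seg in np.unique(self.segment):
            resi = self.residue_index[self.segment == seg]
            if np.any(np.diff(resi) < 0):
                raise ValueError(f"residue indices decrease within segment {seg!r}")

    @property
    def n_particles(self) -> int:
        return len(self.names)

    def protein_index(self) -> np.ndarray:
        return np.flatnonzero(self.category == "protein")

    def lipid_index(self, species: str | None = None,
                    part: str | None = None) -> np.ndarray:
        mask = self.category == "lipid"
        if species is not None:
            mask &= self.lipid_species == species
        if part is not None:
            mask &= self.lipid_part == part
        return np.flatnonzero(mask)

    def lipid_residues(self, species: str | None = None) -> np.ndarray:
        """Residue indices (unique, ordered) of lipid molecules."""
        idx = self.lipid_index(species=species)
        return np.unique(self.residue_index[idx])

    def protein_residues(self) -> np.ndarray:
        return np.unique(self.residue_index[self.protein_index()])

    def species_present(self) -> list[str]:
        sp = np.unique(self.lipid_species[self.category == "lipid"])
        return [s for s in LIPID_SPECIES if s in sp]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "particle_id": np.arange(self.n_particles),
            "name": self.names,
            "residue_index": self.residue_index,
            "residue_name": self.residue_name,
            "segment": self.segment,
            "category": self.category,
            "lipid_species": self.lipid_species,
            "lipid_part": self.lipid_part,
            "mass": self.mass,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MolecularTopology":
        df = df.sort_values("particle_id")
        def col(name, dtype=object):
            return np.asarray(df[name].fillna("") if dtype is object else df[name],
                              dtype=dtype)
        return cls(
            names=col("name"), residue_index=col("residue_index", np.int64),
            residue_name=col("residue_name"), segment=col("segment"),
            category=col("category"), lipid_species=col("lipid_species"),
            lipid_part=col("lipid_part"), mass=col("mass", np.float64),
        )


@dataclass
class SimulationFrame:
    """One frame: time (ns), coordinates (N, 3) in nm, orthorhombic box (nm)."""

    time: float
    coordinates: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 strictly positive edge lengths")

    def validate_against(self, topology: MolecularTopology) -> None:
        if len(self.coordinates) != topology.n_particles:
            raise ValueError(
                f"frame has {len(self.coordinates)} coordinates for "
                f"{topology.n_particles} topology particles")


@dataclass
class Trajectory:
    """Ordered frames of one replicate simulation."""

    replicate_id: int
    frames: list[SimulationFrame]
    topology: MolecularTopology
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.array([f.time for f in self.frames])
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass
class EnsembleSet:
    """Replicate trajectories sharing one topology and condition."""

    trajectories: list[Trajectory]
    topology: MolecularTopology
    condition: str = ""

    def __post_init__(self) -> None:
        for traj in self.trajectories:
            if traj.topology is not self.topology and \
                    traj.topology.n_particles != self.topology.n_particles:
                raise ValueError("all replicates must share the ensemble topology")
            if traj.condition and self.condition and traj.condition != self.condition:
                raise ValueError("all replicates must share the ensemble condition")

    @property
    def n_replicates(self) -> int:
        return len(self.trajectories)


# ---------------------------------------------------------------------------
# structure / trajectory I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.upper()
    else:
        fmt = Path(path).suffix.lstrip(".").upper()
    if fmt not in ("PDB", "GRO"):
        raise UnsupportedFormatError(f"unsupported structure format: {fmt!r}")
    return fmt


def _infer_mass(name: str, resname: str) -> float:
    """Element mass from the leading letter of an atom name; coarse bead
    names (two+ letter codes with no element match) fall back to the CG
    default of 72 u."""
    stripped = name.lstrip("0123456789")
    if stripped[:1].upper() in _ELEMENT_MASSES and (
            len(stripped) == 1 or not stripped[:2].isalpha()
            or stripped[:2].upper() in ("CA", "CB", "CD", "CE", "CG", "CZ",
                                        "ND", "NE", "NH", "NZ", "OD", "OE",
                                        "OG", "OH", "OP", "HA", "HB", "HD",
                                        "HE", "HG", "HH", "HZ", "SD", "SG")):
        return _ELEMENT_MASSES[stripped[0].upper()]
    return CG_BEAD_MASS


def _classify(resnames: np.ndarray, names: np.ndarray):
    """Heuristic category / species / part assignment from residue and
    particle names; an annotation table overrides this."""
    n = len(resnames)
    category = np.array(["protein"] * n, dtype=object)
    species = np.array([""] * n, dtype=object)
    part = np.array([""] * n, dtype=object)
    for i in range(n):
        sp = _LIPID_RESNAMES.get(str(resnames[i]).upper())
        if sp is not None:
            category[i] = "lipid"
            species[i] = sp
            part[i] = _PART_BY_NAME.get(str(names[i]).upper(), _part_from_atom(names[i]))
    return category, species, part


def _part_from_atom(name: str) -> str:
    """Atomistic lipid atoms: phosphorus and its oxygens -> phosphate,
    other heteroatom-rich head atoms -> headgroup, aliphatic chain -> tail."""
    u = name.upper()
    if u.startswith("P") or u.startswith("OP") or u in ("O1P", "O2P", "O3P", "O4P"):
        return "phosphate"
    if u.startswith(("N", "O", "H1", "H2", "H3")):
        return "headgroup"
    return "tail"


def read_structure(path: str | Path, fmt: str | None = None,
                   annotation: "str | Path | MolecularTopology | None" = None,
                   ) -> tuple[MolecularTopology, SimulationFrame]:
    """Read a single-frame PDB or GRO file.

    Coordinates are returned in nm whatever the source convention.  If an
    annotation table (path or :class:`MolecularTopology`) is supplied it
    overrides the name-based category/species/part/mass inference.
    """
    import MDAnalysis as mda

    fmt = _infer_format(path, fmt)
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise ParseError(f"could not parse {path} as {fmt}: {exc}") from exc

    atoms = u.atoms
    if hasattr(atoms, "altLocs"):
        alts = atoms.altLocs
        keep = np.array([a in ("", "A") for a in alts])
        if not keep.all():
            logger.warning("dropping %d alternate-location atoms from %s",
                           (~keep).sum(), path)
            atoms = atoms[keep]

    dims = u.dimensions
    if dims is None or np.all(dims[:3] == 0):
        box = np.array([10.0, 10.0, 10.0])
        logger.warning("%s has no box record; assuming 10 nm cube", path)
    else:
        if not np.allclose(dims[3:6], 90.0, atol=1e-3):
            raise UnsupportedFormatError(
                f"{path}: triclinic boxes are not supported (angles {dims[3:6]})")
        box = np.asarray(dims[:3], dtype=float) / A_PER_NM

    names = atoms.names.astype(object)
    resnames = atoms.resnames.astype(object)
    resids = atoms.resids.astype(np.int64)
    segids = (atoms.segids.astype(object) if hasattr(atoms, "segids")
              else np.array(["SYS"] * len(names), dtype=object))
    coords = atoms.positions.astype(np.float64) / A_PER_NM

    category, species, part = _classify(resnames, names)
    mass = np.array([_infer_mass(n, r) for n, r in zip(names, resnames)])

    topo = MolecularTopology(names=names, residue_index=resids,
                             residue_name=resnames, segment=segids,
                             category=category, lipid_species=species,
                             lipid_part=part, mass=mass)
    if annotation is not None:
        topo = apply_annotation(topo, annotation)
    frame = SimulationFrame(time=0.0, coordinates=coords, box=box)
    frame.validate_against(topo)
    return topo, frame


def write_structure(path: str | Path, topology: MolecularTopology,
                    frame: SimulationFrame, fmt: str | None = None) -> None:
    """Write one frame as PDB or GRO (coordinates converted back to the
    format's native unit)."""
    fmt = _infer_format(path, fmt)
    u = _build_universe(topology, frame)
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_particles, format=fmt) as w:
            w.write(u.atoms)


def write_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    """Write a replicate as a multi-model PDB (frame times go in the
    ensemble manifest; the PDB carries only coordinates and box)."""
    import MDAnalysis as mda
    topo = trajectory.topology
    u = _build_universe(topo, trajectory.frames[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topo.n_particles,
                        format="PDB", multiframe=True) as w:
            for fr in trajectory.frames:
                u.atoms.positions = fr.coordinates * A_PER_NM
                u.dimensions = [*(fr.box * A_PER_NM), 90.0, 90.0, 90.0]
                w.write(u.atoms)


def read_trajectory(path: str | Path, topology: MolecularTopology,
                    replicate_id: int = 0, times: Sequence[float] | None = None,
                    dt: float = 1.0, t0: float = 0.0, condition: str = "",
                    boxes: Sequence[Sequence[float]] | None = None,
                    ) -> Trajectory:
    """Read a multi-model PDB as a :class:`Trajectory`.

    PDB has no time field; frame times come from ``times`` or ``t0 + i*dt``.
    Multi-model PDB carries CRYST1 only once, so per-frame boxes may be
    supplied via ``boxes`` (the ensemble manifest stores them); otherwise
    the file-level box is used for every frame.
    """
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="PDB")
    frames = []
    box = np.array([10.0, 10.0, 10.0])
    file_dims = u.dimensions
    if file_dims is not None and np.any(file_dims[:3] > 0):
        box = np.asarray(file_dims[:3], dtype=float) / A_PER_NM
    for i, ts in enumerate(u.trajectory):
        t = times[i] if times is not None else t0 + i * dt
        if boxes is not None:
            box = np.asarray(boxes[i], dtype=float)
        elif ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
            box = np.asarray(ts.dimensions[:3], dtype=float) / A_PER_NM
        frames.append(SimulationFrame(
            time=float(t),
            coordinates=u.atoms.positions.astype(np.float64) / A_PER_NM,
            box=box))
    traj = Trajectory(replicate_id=replicate_id, frames=frames,
                      topology=topology, condition=condition)
    for fr in frames:
        fr.validate_against(topology)
    return traj


def frames_from_source(source: Iterable[tuple[float, np.ndarray, np.ndarray]],
                       topology: MolecularTopology, replicate_id: int = 0,
                       condition: str = "") -> Trajectory:
    """Adapt any (time, coordinates, box) iterator — e.g. an XTC/DCD
    reader — into a :class:`Trajectory`."""
    frames = [SimulationFrame(time=t, coordinates=x, box=b)
              for t, x, b in source]
    traj = Trajectory(replicate_id=replicate_id, frames=frames,
                      topology=topology, condition=condition)
    for fr in frames:
        fr.validate_against(topology)
    return traj


def _build_universe(topology: MolecularTopology, frame: SimulationFrame):
    import MDAnalysis as mda
    n = topology.n_particles
    # map (segment, residue_index) -> contiguous residue codes
    keys = list(zip(topology.segment, topology.residue_index))
    res_codes = np.zeros(n, dtype=int)
    seen: dict = {}
    for i, k in enumerate(keys):
        if k not in seen:
            seen[k] = len(seen)
        res_codes[i] = seen[k]
    n_res = len(seen)
    seg_of_res = {}
    resid_of_res = {}
    resname_of_res = {}
    for i, k in enumerate(keys):
        c = seen[k]
        seg_of_res[c] = k[0]
        resid_of_res[c] = k[1]
        resname_of_res[c] = topology.residue_name[i]
    segnames = sorted({str(s) for s in topology.segment})
    seg_codes = {s: j for j, s in enumerate(segnames)}
    res_seg = np.array([seg_codes[str(seg_of_res[c])] for c in range(n_res)])

    u = mda.Universe.empty(n, n_residues=n_res, atom_resindex=res_codes,
                           residue_segindex=res_seg,
                           n_segments=len(segnames), trajectory=True)
    u.add_TopologyAttr("names", topology.names.astype(str))
    u.add_TopologyAttr("resnames",
                       np.array([str(resname_of_res[c]) for c in range(n_res)]))
    u.add_TopologyAttr("resids",
                       np.array([int(resid_of_res[c]) for c in range(n_res)]))
    u.add_TopologyAttr("segids", np.array(segnames))
    u.add_TopologyAttr("masses", topology.mass)
    u.atoms.positions = frame.coordinates * A_PER_NM
    u.dimensions = [*(frame.box * A_PER_NM), 90.0, 90.0, 90.0]
    return u


# annotation table -----------------------------------------------------------

ANNOTATION_COLUMNS = ["particle_id", "name", "residue_index", "residue_name",
                      "segment", "category", "lipid_species", "lipid_part",
                      "mass"]


def write_annotation(path: str | Path, topology: MolecularTopology) -> None:
    topology.to_dataframe().to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> MolecularTopology:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"lipid_species": str, "lipid_part": str,
                            "segment": str, "name": str, "residue_name": str,
                            "category": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"annotation table missing columns: {sorted(missing)}")
    return MolecularTopology.from_dataframe(df)


def apply_annotation(topology: MolecularTopology,
                     annotation: "str | Path | MolecularTopology",
                     ) -> MolecularTopology:
    """Override the inferred category/species/part/mass with the table's."""
    table = (annotation if isinstance(annotation, MolecularTopology)
             else read_annotation(annotation))
    if table.n_particles != topology.n_particles:
        raise ParseError(
            f"annotation table covers {table.n_particles} particles, "
            f"structure has {topology.n_particles}")
    return MolecularTopology(
        names=topology.names, residue_index=topology.residue_index,
        residue_name=topology.residue_name, segment=topology.segment,
        category=table.category, lipid_species=table.lipid_species,
        lipid_part=table.lipid_part, mass=table.mass)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def center_of_mass(frame: SimulationFrame, selection: np.ndarray,
                   topology: MolecularTopology) -> np.ndarray:
    """Mass-weighted mean position (nm) of the selected particles."""
    selection = np.asarray(selection, dtype=np.int64)
    if selection.size == 0:
        raise SelectionError("center_of_mass: empty selection")
    m = topology.mass[selection]
    if np.any(m <= 0):
        raise SelectionError("center_of_mass: non-positive masses in selection")
    x = frame.coordinates[selection]
    return (m[:, None] * x).sum(axis=0) / m.sum()


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rotation matrix R minimising ``|R m - r|`` after both
    point sets are centred; the reflection branch is corrected so that
    ``det R = +1``.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matched (N, 3) arrays")
    if len(mobile) < 3:
        raise DegenerateGeometryError("kabsch_rotation needs at least 3 points")
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)
    # collinear or coincident point sets have no unique rotation
    for pts in (m, r):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1e-30) or s[0] <= 1e-12:
            raise DegenerateGeometryError(
                "kabsch_rotation: degenerate (collinear/coincident) points")
    h = m.T @ r
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose_rmsd(mobile: np.ndarray, reference: np.ndarray,
                   selection: np.ndarray | None = None,
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd_nm)`` with the transform
    ``x -> rotation @ x + translation`` attaining the minimised RMSD over
    the selection (all points when ``selection`` is None).
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if selection is not None:
        selection = np.asarray(selection, dtype=np.int64)
        mob_sel, ref_sel = mobile[selection], reference[selection]
    else:
        mob_sel, ref_sel = mobile, reference
    if mob_sel.shape != ref_sel.shape:
        raise ValueError("selections must have equal length")
    rot = kabsch_rotation(mob_sel, ref_sel)
    com_m = mob_sel.mean(axis=0)
    com_r = ref_sel.mean(axis=0)
    trans = com_r - rot @ com_m
    moved = mob_sel @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_sel) ** 2, axis=1))))
    return rot, trans, rmsd


def assign_leaflets(frame: SimulationFrame, topology: MolecularTopology,
                    ) -> dict[int, str]:
    """Assign each lipid residue to the upper or lower leaflet by the sign
    of its headgroup centre of mass relative to the bilayer centre of mass."""
    lip_idx = topology.lipid_index()
    if lip_idx.size == 0:
        raise SelectionError("assign_leaflets: no lipids in topology")
    bilayer_z = center_of_mass(frame, lip_idx, topology)[2]
    out: dict[int, str] = {}
    for resid in topology.lipid_residues():
        head = np.flatnonzero((topology.residue_index == resid)
                              & (topology.lipid_part == "headgroup"))
        if head.size == 0:  # fall back to whole-lipid COM
            head = np.flatnonzero((topology.residue_index == resid)
                                  & (topology.category == "lipid"))
        z = center_of_mass(frame, head, topology)[2]
        out[int(resid)] = "upper" if z >= bilayer_z else "lower"
    sides = set(out.values())
    if len(sides) == 1:
        logger.warning("assign_leaflets: all lipids on one side (%s leaflet)",
                       sides.pop())
    return out


def lateral_minimum_image(dxy: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image convention applied to x,y displacement(s)."""
    dxy = np.asarray(dxy, dtype=np.float64)
    lx, ly = box[0], box[1]
    out = dxy.copy()
    out[..., 0] -= lx * np.round(out[..., 0] / lx)
    out[..., 1] -= ly * np.round(out[..., 1] / ly)
    return out


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image convention applied to full 3D displacement(s)."""
    d = np.asarray(d, dtype=np.float64)
    out = d.copy()
    for k in range(3):
        out[..., k] -= box[k] * np.round(out[..., k] / box[k])
    return out
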