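"""Geometric hydrogen-bond detection between protein residues and lipids.

A bond D-H...A is scored when the donor-acceptor distance d(D, A) is at
most ``d_max`` and the H-D...A angle is at most ``angle_max``.  The
default criterion (0.35 nm, 30 degrees) is the convention of the GROMACS
toolchain.  This analysis needs explicit hydrogens, i.e. an
atomistic-resolution topology; a distance-only heavy-atom fallback is
available and logged when hydrogens are absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (
    EnsembleSet,
    MolecularTopology,
    PhmemError,
    SimulationFrame,
    logger,
    minimum_image,
)

DEFAULT_D_MAX = 0.35      # nm, donor-acceptor distance
DEFAULT_ANGLE_MAX = 30.0  # degrees, H-D...A

#: donor (heavy, hydrogen) atom-name pairs for standard residues
DONOR_LOOKUP: dict[str, list[tuple[str, str]]] = {
    "LYS": [("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")],
    "ARG": [("NE", "HE"), ("NH1", "HH11"), ("NH1", "HH12"),
            ("NH2", "HH21"), ("NH2", "HH22")],
    "HIS": [("ND1", "HD1"), ("NE2", "HE2")],
    "SER": [("OG", "HG")],
    "THR": [("OG1", "HG1")],
    "TYR": [("OH", "HH")],
    "ASN": [("ND2", "HD21"), ("ND2", "HD22")],
    "GLN": [("NE2", "HE21"), ("NE2", "HE22")],
    "TRP": [("NE1", "HE1")],
    "*backbone": [("N", "H")],
}

#: acceptor atom names on the three-part lipid model and common atomistic
#: phosphate/ester oxygens
LIPID_ACCEPTOR_NAMES = {"O1P", "O2P", "O3P", "O4P", "OP1", "OP2", "OP3",
                        "OP4", "O11", "O12", "O13", "O14", "O21", "O22",
                        "O31", "O32", "PO4", "HD"}


class HBond(NamedTuple):
    donor: int          # particle index of D
    hydrogen: int | None
    acceptor: int       # particle index of A
    donor_residue: int
    acceptor_residue: int


@dataclass
class HBondSeries:
    """Per-frame hydrogen-bond counts, total and resolved by tracked
    residue and lipid species, plus per-residue persistence (fraction of
    frames with at least one bond)."""

    times: np.ndarray
    total: np.ndarray
    per_residue: pd.DataFrame        # index time, columns residue_index
    per_species: pd.DataFrame        # index time, columns species
    persistence: pd.Series           # per residue
    criterion: tuple[float, float]   # (d_max nm, angle_max deg)


def detect_hbonds(frame: SimulationFrame, topology: MolecularTopology,
                  donors: Sequence[tuple[int, int]],
                  acceptors: np.ndarray,
                  d_max: float = DEFAULT_D_MAX,
                  angle_max: float = DEFAULT_ANGLE_MAX) -> list[HBond]:
    """All D-H...A bonds for the given (D, H) pairs and acceptor set.

    ``donors`` holds particle-index pairs; pass ``H = -1`` (or use
    :func:`detect_hbonds_heavy`) to fall back to the distance-only
    criterion for that donor.  Distances use the minimum image.
    """
    acceptors = np.asarray(acceptors, dtype=np.int64)
    cos_max = math.cos(math.radians(angle_max))
    box = frame.box
    x = frame.coordinates
    out: list[HBond] = []
    for d_idx, h_idx in donors:
        if h_idx is not None and h_idx >= 0 \
                and not str(topology.names[h_idx]).upper().startswith("H"):
            raise PhmemError(
                f"detect_hbonds: particle {h_idx} ({topology.names[h_idx]}) "
                "is not a hydrogen; supply valid (D, H) pairs or use the "
                "heavy-atom fallback")
        da = minimum_image(x[acceptors] - x[d_idx], box)
        dist = np.linalg.norm(da, axis=1)
        ok = dist <= d_max
        if h_idx is not None and h_idx >= 0:
            dh = minimum_image(x[h_idx] - x[d_idx], box)
            nh = np.linalg.norm(dh)
            if nh < 1e-9:
                raise PhmemError("detect_hbonds: zero-length D-H bond")
            # angle H-D...A at the donor
            cosang = (da @ dh) / np.maximum(dist * nh, 1e-12)
            ok &= cosang >= cos_max
        for a in acceptors[ok]:
            if a == d_idx:
                continue
            out.append(HBond(
                donor=int(d_idx),
                hydrogen=None if h_idx is None or h_idx < 0 else int(h_idx),
                acceptor=int(a),
                donor_residue=int(topology.residue_index[d_idx]),
                acceptor_residue=int(topology.residue_index[a])))
    return out


def find_donors(topology: MolecularTopology,
                residues: Sequence[int] | None = None,
                ) -> list[tuple[int, int]]:
    """(D, H) particle pairs from the bundled residue lookup.  If the
    topology carries no hydrogens the heavy donors are returned with
    ``H = -1`` (distance-only fallback, logged)."""
    donors: list[tuple[int, int]] = []
    prot = topology.protein_index()
    has_h = any(str(topology.names[i]).upper().startswith("H") for i in prot)
    for resid in (residues if residues is not None
                  else topology.protein_residues()):
        sel = np.flatnonzero((topology.residue_index == resid)
                             & (topology.category == "protein"))
        if sel.size == 0:
            continue
        resname = str(topology.residue_name[sel[0]]).upper()
        pairs = (DONOR_LOOKUP.get(resname, [])
                 + DONOR_LOOKUP["*backbone"])
        names = {str(topology.names[i]).upper(): int(i) for i in sel}
        for dn, hn in pairs:
            if dn in names:
                if hn in names:
                    donors.append((names[dn], names[hn]))
                elif not has_h:
                    donors.append((names[dn], -1))
    if donors and not has_h:
        logger.warning("find_donors: no hydrogens in topology; using "
                       "distance-only heavy-atom criterion")
    return donors


def find_acceptors(topology: MolecularTopology,
                   species: Sequence[str] | None = None) -> np.ndarray:
    """Lipid acceptor particles (phosphate/ester oxygens; headgroup and
    phosphate beads on coarse models), optionally restricted by species."""
    mask = topology.category == "lipid"
    if species is not None:
        mask &= np.isin(topology.lipid_species, list(species))
    name_ok = np.array([str(n).upper() in LIPID_ACCEPTOR_NAMES
                        or (str(n).upper().startswith("O"))
                        for n in topology.names])
    return np.flatnonzero(mask & name_ok)


def hbond_series(ensemble: EnsembleSet,
                 residues: Sequence[int] | None = None,
                 species: Sequence[str] | None = None,
                 d_max: float = DEFAULT_D_MAX,
                 angle_max: float = DEFAULT_ANGLE_MAX,
                 donors: Sequence[tuple[int, int]] | None = None,
                 acceptors: np.ndarray | None = None) -> HBondSeries:
    """Per-frame bond counts across the ensemble, resolved by tracked
    residue and lipid species."""
    topo = ensemble.topology
    if donors is None:
        donors = find_donors(topo, residues)
    if acceptors is None:
        acceptors = find_acceptors(topo, species)
    if not donors or len(acceptors) == 0:
        raise PhmemError("hbond_series: no donors or acceptors identified")

    track_res = sorted({int(topo.residue_index[d]) for d, _ in donors})
    track_sp = sorted({str(s) for s in
                       topo.lipid_species[np.asarray(acceptors)]})
    times, totals = [], []
    res_rows, sp_rows = [], []
    for traj in ensemble.trajectories:
        for fr in traj.frames:
            bonds = detect_hbonds(fr, topo, donors, acceptors, d_max,
                                  angle_max)
            times.append(fr.time)
            totals.append(len(bonds))
            rc = {r: 0 for r in track_res}
            sc = {s: 0 for s in track_sp}
            for b in bonds:
                rc[b.donor_residue] = rc.get(b.donor_residue, 0) + 1
                sp = str(topo.lipid_species[b.acceptor])
                sc[sp] = sc.get(sp, 0) + 1
            res_rows.append(rc)
            sp_rows.append(sc)
    per_residue = pd.DataFrame(res_rows, index=times).fillna(0).astype(int)
    per_species = pd.DataFrame(sp_rows, index=times).fillna(0).astype(int)
    persistence = (per_residue > 0).mean(axis=0)
    return HBondSeries(times=np.array(times), total=np.array(totals),
                       per_residue=per_residue, per_species=per_species,
                       persistence=persistence,
                       criterion=(d_max, angle_max))
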