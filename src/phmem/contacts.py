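"""Per-residue protein-lipid contact profiles and leaflet-resolved
lateral radial distribution functions.

A contact is scored once per (protein residue, lipid molecule, frame)
whenever any particle of the lipid lies within the cutoff of any particle
of the residue (3D distance, minimum image in x,y).  Profiles are averaged
over frames and replicates and normalized per species by the maximum
residue value, the convention behind "normalized interactions" plots.

The RDF is lateral (2D): lipid headgroup positions at lateral distance r
from the protein's lateral COM, within one leaflet, normalized per annulus
by the uniform lateral density of that species in that leaflet.  PIP
clustering around a bound protein shows up as g(r) > 1 at contact range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    EnsembleSet,
    SelectionError,
    assign_leaflets,
    center_of_mass,
    lateral_minimum_image,
)
from .orientation import compute_dz


@dataclass
class ContactProfile:
    """Mean per-frame contact counts per protein residue and species."""

    counts: pd.DataFrame               # index residue_index, columns species
    normalized: pd.DataFrame           # per-species max-normalized, in [0, 1]
    cutoff: float
    n_frames: int
    parts: dict = field(default_factory=dict)  # part -> counts DataFrame


@dataclass
class RadialDistribution:
    r_centers: np.ndarray
    g: np.ndarray
    species: str
    leaflet: str
    n_frames: int
    mode: str = "lateral2D"


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _group_starts(codes: np.ndarray) -> np.ndarray:
    """reduceat boundaries for a sorted integer code array."""
    return np.flatnonzero(np.r_[True, np.diff(codes) != 0])


def _min_dist_residue_molecule(prot_xyz: np.ndarray, lip_xyz: np.ndarray,
                               res_starts: np.ndarray, mol_starts: np.ndarray,
                               box: np.ndarray) -> np.ndarray:
    """(n_residues, n_molecules) minimum particle-particle distance with
    lateral minimum image."""
    d = prot_xyz[:, None, :] - lip_xyz[None, :, :]
    d[..., 0] -= box[0] * np.round(d[..., 0] / box[0])
    d[..., 1] -= box[1] * np.round(d[..., 1] / box[1])
    dist = np.sqrt(np.sum(d * d, axis=-1))
    dist = np.minimum.reduceat(dist, res_starts, axis=0)
    dist = np.minimum.reduceat(dist, mol_starts, axis=1)
    return dist


def _bound_mask(ensemble: EnsembleSet, bound_threshold: float,
                protein_sel: np.ndarray, bilayer_sel: np.ndarray,
                ) -> dict[int, np.ndarray]:
    """Per-replicate boolean mask of frames with dz <= threshold."""
    topo = ensemble.topology
    out = {}
    for traj in ensemble.trajectories:
        out[traj.replicate_id] = np.array(
            [compute_dz(fr, protein_sel, bilayer_sel, topo) <= bound_threshold
             for fr in traj.frames])
    return out


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def contact_profile(ensemble: EnsembleSet, cutoff: float = 0.6,
                    bound_only: bool = False, parts: bool = False,
                    bound_threshold: float | None = None) -> ContactProfile:
    """Species-resolved mean contact counts per protein residue.

    ``cutoff`` is in nm (0.6 suits coarse three-bead lipids, 0.4
    atomistic resolution).  With ``bound_only`` the average runs over
    frames with dz <= ``bound_threshold`` only.  With ``parts`` the
    profile is additionally broken down by lipid part
    (headgroup/phosphate/tail).
    """
    if cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    topo = ensemble.topology
    prot_idx = topo.protein_index()
    if prot_idx.size == 0:
        raise SelectionError("contact_profile: no protein particles")
    species = topo.species_present()
    if not species:
        raise SelectionError("contact_profile: topology has no lipid species")
    if bound_only and bound_threshold is None:
        raise ValueError("bound_only requires bound_threshold")

    # protein residues, sorted for reduceat
    order_p = prot_idx[np.argsort(topo.residue_index[prot_idx], kind="stable")]
    res_ids = topo.residue_index[order_p]
    res_starts = _group_starts(res_ids)
    residues = res_ids[res_starts]

    # lipid particles grouped per molecule per species (and part)
    groups = {}
    part_names = ("headgroup", "phosphate", "tail") if parts else ()
    for sp in species:
        idx = topo.lipid_index(species=sp)
        order = idx[np.argsort(topo.residue_index[idx], kind="stable")]
        mols = topo.residue_index[order]
        groups[(sp, None)] = (order, _group_starts(mols))
        for part in part_names:
            pidx = topo.lipid_index(species=sp, part=part)
            porder = pidx[np.argsort(topo.residue_index[pidx], kind="stable")]
            pmols = topo.residue_index[porder]
            groups[(sp, part)] = (porder, _group_starts(pmols))

    bound = (_bound_mask(ensemble, bound_threshold, prot_idx,
                         topo.lipid_index())
             if bound_only else None)

    acc = {key: np.zeros(len(residues)) for key in groups}
    n_frames = 0
    for traj in ensemble.trajectories:
        mask = bound[traj.replicate_id] if bound is not None else None
        for k, fr in enumerate(traj.frames):
            if mask is not None and not mask[k]:
                continue
            n_frames += 1
            prot_xyz = fr.coordinates[order_p]
            for key, (order, mol_starts) in groups.items():
                dmin = _min_dist_residue_molecule(
                    prot_xyz, fr.coordinates[order], res_starts, mol_starts,
                    fr.box)
                acc[key] += (dmin <= cutoff).sum(axis=1)

    denom = max(n_frames, 1)
    counts = pd.DataFrame(
        {sp: acc[(sp, None)] / denom for sp in species}, index=residues)
    counts.index.name = "residue_index"
    normalized = counts.copy()
    for sp in species:
        peak = normalized[sp].max()
        if peak > 0:
            normalized[sp] /= peak
    part_tables = {}
    for part in part_names:
        part_tables[part] = pd.DataFrame(
            {sp: acc[(sp, part)] / denom for sp in species}, index=residues)
        part_tables[part].index.name = "residue_index"
    return ContactProfile(counts=counts, normalized=normalized,
                          cutoff=cutoff, n_frames=n_frames,
                          parts=part_tables)


# ---------------------------------------------------------------------------
# lateral RDF
# ---------------------------------------------------------------------------

def rdf_lateral(ensemble: EnsembleSet, species: str, leaflet: str,
                r_max: float = 4.0, dr: float = 0.1,
                center_sel: np.ndarray | None = None,
                bound_only: bool = True,
                bound_threshold: float | None = None) -> RadialDistribution:
    """Leaflet-resolved lateral g(r) of a lipid species around the protein.

    Distances are lateral (x,y, minimum image) from the lateral COM of
    ``center_sel`` (default: all protein particles) to the headgroup
    position of each molecule of ``species`` in ``leaflet``.  Counts per
    annulus are divided by the expectation for a uniform lateral density
    of that species in that leaflet.
    """
    topo = ensemble.topology
    if center_sel is None:
        center_sel = topo.protein_index()
    if center_sel.size == 0:
        raise SelectionError("rdf_lateral: empty center selection")
    if bound_only and bound_threshold is None:
        raise ValueError("bound_only requires bound_threshold")

    first = ensemble.trajectories[0].frames[0]
    box = first.box
    if r_max >= min(box[0], box[1]) / 2:
        raise ValueError(
            f"r_max {r_max} must be below half the smaller lateral box edge "
            f"({min(box[0], box[1]) / 2:.3f} nm)")

    # leaflet membership from the first frame (flat bilayer: stable)
    leaflets = assign_leaflets(first, topo)
    mols = [m for m in topo.lipid_residues(species=species)
            if leaflets[int(m)] == leaflet]
    if not mols:
        raise SelectionError(
            f"rdf_lateral: no {species} molecules in {leaflet} leaflet")
    head_idx = []
    for m in mols:
        h = np.flatnonzero((topo.residue_index == m)
                           & (topo.lipid_part == "headgroup"))
        if h.size == 0:
            h = np.flatnonzero((topo.residue_index == m)
                               & (topo.category == "lipid"))
        head_idx.append(h)

    bound = (_bound_mask(ensemble, bound_threshold, topo.protein_index(),
                         topo.lipid_index())
             if bound_only else None)

    edges = np.arange(0.0, r_max + dr / 2, dr)
    counts = np.zeros(len(edges) - 1)
    n_frames = 0
    for traj in ensemble.trajectories:
        mask = bound[traj.replicate_id] if bound is not None else None
        for k, fr in enumerate(traj.frames):
            if mask is not None and not mask[k]:
                continue
            n_frames += 1
            c = center_of_mass(fr, center_sel, topo)[:2]
            heads = np.array([fr.coordinates[h].mean(axis=0)[:2]
                              for h in head_idx])
            d = lateral_minimum_image(heads - c, fr.box)
            r = np.linalg.norm(d, axis=1)
            hist, _ = np.histogram(r, bins=edges)
            counts += hist
    if n_frames == 0:
        raise SelectionError("rdf_lateral: no frames selected "
                             "(nothing bound below the threshold?)")

    area_box = box[0] * box[1]
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    expected = n_frames * len(mols) * annulus / area_box
    g = np.divide(counts, expected, out=np.zeros_like(counts),
                  where=expected > 0)
    r_centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialDistribution(r_centers=r_centers, g=g, species=species,
                              leaflet=leaflet, n_frames=n_frames)


def clustering_summary(rdf_on: RadialDistribution,
                       rdf_off: RadialDistribution | None = None,
                       r_contact: float = 0.7) -> float:
    """Enrichment factor: mean g at contact range (r <= r_contact) divided
    by the far-field mean g (top quartile of r), the latter taken from
    ``rdf_off`` when given (matched r grids required).  Values > 1
    indicate clustering."""
    far_src = rdf_off if rdf_off is not None else rdf_on
    if rdf_off is not None and not np.allclose(rdf_off.r_centers,
                                               rdf_on.r_centers):
        raise ValueError("clustering_summary: r grids do not match")
    r = rdf_on.r_centers
    near = rdf_on.g[r <= r_contact]
    far = far_src.g[r >= np.quantile(r, 0.75)]
    if near.size == 0:
        raise ValueError("clustering_summary: no bins at contact range")
    far_mean = float(far.mean())
    if far_mean <= 0:
        raise ValueError("clustering_summary: zero far-field density")
    return float(near.mean()) / far_mean
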