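"""Contact profiles and lateral RDFs against brute-force oracles."""

import numpy as np
import pytest

import phmem
from phmem import (
    EnsembleSet,
    MolecularTopology,
    RadialDistribution,
    SimulationFrame,
    Trajectory,
    clustering_summary,
    contact_profile,
    rdf_lateral,
)


def _mixed_topology(n_prot, lipid_specs):
    """n_prot one-bead protein residues + lipids given as a list of
    (species, n_beads) tuples (each lipid its own residue)."""
    names, resid, resname, seg, cat, spec, part = [], [], [], [], [], [], []
    for i in range(n_prot):
        names.append("BB")
        resid.append(i + 1)
        resname.append("ALA")
        seg.append("PROT")
        cat.append("protein")
        spec.append("")
        part.append("")
    parts_cycle = ["headgroup", "phosphate", "tail"]
    for j, (sp, nb) in enumerate(lipid_specs):
        for b in range(nb):
            names.append(["HD", "PO4", "TA"][b % 3])
            resid.append(100 + j)
            resname.append(sp)
            seg.append("MEMB")
            cat.append("lipid")
            spec.append(sp)
            part.append(parts_cycle[b % 3])
    n = len(names)
    return MolecularTopology(
        names=np.array(names, dtype=object),
        residue_index=np.array(resid, dtype=np.int64),
        residue_name=np.array(resname, dtype=object),
        segment=np.array(seg, dtype=object),
        category=np.array(cat, dtype=object),
        lipid_species=np.array(spec, dtype=object),
        lipid_part=np.array(part, dtype=object),
        mass=np.full(n, 72.0))


def _ensemble_from_coords(topo, coords_list, box=(10.0, 10.0, 10.0)):
    frames = [SimulationFrame(float(t), c, np.array(box))
              for t, c in enumerate(coords_list)]
    traj = Trajectory(replicate_id=0, frames=frames, topology=topo)
    return EnsembleSet(trajectories=[traj], topology=topo)


# ---------------------------------------------------------------------------
# contact profile
# ---------------------------------------------------------------------------

def test_single_contact_counted_once_per_molecule():
    """One PIP bead at half the cutoff from one residue: that residue
    counts exactly one molecular contact, all others zero."""
    topo = _mixed_topology(3, [("PIP2", 3)])
    coords = np.array([
        [1.0, 1.0, 5.0], [3.0, 3.0, 5.0], [5.0, 5.0, 5.0],   # protein
        [1.0, 1.0, 5.3], [1.0, 1.0, 5.45], [1.0, 1.0, 5.5],  # one lipid
    ])
    ens = _ensemble_from_coords(topo, [coords])
    prof = contact_profile(ens, cutoff=0.6)
    assert prof.counts.loc[1, "PIP2"] == 1.0    # two beads, one molecule
    assert prof.counts.loc[2, "PIP2"] == 0.0
    assert prof.counts.loc[3, "PIP2"] == 0.0
    assert prof.normalized.loc[1, "PIP2"] == 1.0


def test_no_contacts_all_zero():
    topo = _mixed_topology(2, [("PC", 3)])
    coords = np.array([[1, 1, 1.0], [2, 2, 1.0],
                       [5, 5, 9.0], [5, 5, 9.1], [5, 5, 9.2]])
    ens = _ensemble_from_coords(topo, [coords])
    prof = contact_profile(ens, cutoff=0.6)
    assert (prof.counts.to_numpy() == 0).all()
    assert (prof.normalized.to_numpy() == 0).all()


def test_bad_cutoff_rejected(small_ensemble):
    with pytest.raises(ValueError):
        contact_profile(small_ensemble, cutoff=0.0)


def _brute_force_contacts(topo, frame, cutoff):
    """O(N^2) double loop: per (residue, molecule) any-bead contact."""
    box = frame.box
    out = {}
    prot = topo.protein_index()
    for i in prot:
        ri = int(topo.residue_index[i])
        for j in topo.lipid_index():
            d = frame.coordinates[i] - frame.coordinates[j]
            d[0] -= box[0] * round(d[0] / box[0])
            d[1] -= box[1] * round(d[1] / box[1])
            if np.sqrt(d @ d) <= cutoff:
                key = (ri, str(topo.lipid_species[j]),
                       int(topo.residue_index[j]))
                out[key] = True
    counts = {}
    for (ri, sp, _mol) in out:
        counts[(ri, sp)] = counts.get((ri, sp), 0) + 1
    return counts


@pytest.mark.parametrize("seed", range(10))
def test_contacts_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    topo = _mixed_topology(6, [("PC", 3)] * 10 + [("PIP2", 3)] * 5)
    coords = rng.uniform(0, 4.0, size=(topo.n_particles, 3))
    ens = _ensemble_from_coords(topo, [coords], box=(4.0, 4.0, 8.0))
    cutoff = 0.8
    prof = contact_profile(ens, cutoff=cutoff)
    brute = _brute_force_contacts(topo, ens.trajectories[0].frames[0], cutoff)
    for ri in prof.counts.index:
        for sp in prof.counts.columns:
            assert prof.counts.loc[ri, sp] == brute.get((int(ri), sp), 0)


def test_contact_counts_monotone_in_cutoff(small_ensemble):
    sub = EnsembleSet(
        trajectories=[Trajectory(
            replicate_id=0,
            frames=small_ensemble.trajectories[0].frames[-20:],
            topology=small_ensemble.topology)],
        topology=small_ensemble.topology)
    small = contact_profile(sub, cutoff=0.5).counts
    large = contact_profile(sub, cutoff=0.8).counts
    assert (large.to_numpy() >= small.to_numpy() - 1e-12).all()


def test_part_resolved_counts_sum_consistency():
    """A molecule contacting via its headgroup only appears in the
    headgroup sub-table and not in phosphate/tail."""
    topo = _mixed_topology(1, [("PIP2", 3)])
    coords = np.array([[1.0, 1.0, 5.0],
                       [1.0, 1.0, 5.3],    # headgroup within 0.6
                       [1.0, 1.0, 6.5],    # phosphate far
                       [1.0, 1.0, 7.0]])   # tail far
    ens = _ensemble_from_coords(topo, [coords])
    prof = contact_profile(ens, cutoff=0.6, parts=True)
    assert prof.parts["headgroup"].loc[1, "PIP2"] == 1.0
    assert prof.parts["phosphate"].loc[1, "PIP2"] == 0.0
    assert prof.parts["tail"].loc[1, "PIP2"] == 0.0


def test_bound_patch_residues_dominate_pip_contacts(small_ensemble):
    """In the bound synthetic ensemble the basic-patch (membrane-facing)
    residues carry clearly elevated normalized PIP2 contacts relative to
    the rest of the protein."""
    prof = contact_profile(small_ensemble, cutoff=0.6, bound_only=True,
                           bound_threshold=2.7)
    topo = small_ensemble.topology
    patch = [int(r) for r in
             topo.residue_index[phmem.basic_patch_index(topo)]]
    norm = prof.normalized["PIP2"]
    assert norm.loc[patch].mean() > 2.0 * norm.drop(patch).mean()


# ---------------------------------------------------------------------------
# lateral RDF
# ---------------------------------------------------------------------------

def _uniform_rdf_system(rng, n_lip=60, n_frames=40, box=8.0):
    topo = _mixed_topology(3, [("PC", 3)] * n_lip)
    frames = []
    for _ in range(n_frames):
        coords = np.zeros((topo.n_particles, 3))
        coords[:3] = [[box / 2, box / 2, 7.0],
                      [box / 2 + 0.2, box / 2, 7.0],
                      [box / 2, box / 2 + 0.2, 7.0]]
        xy = rng.uniform(0, box, size=(n_lip, 2))
        for i in range(n_lip):
            for b in range(3):
                coords[3 + 3 * i + b] = [xy[i, 0], xy[i, 1],
                                         6.0 - 0.3 * b]
        frames.append(coords)
    return _ensemble_from_coords(topo, frames, box=(box, box, 10.0))


def test_uniform_rdf_is_flat(rng):
    ens = _uniform_rdf_system(rng)
    rdf = rdf_lateral(ens, "PC", "upper", r_max=3.5, dr=0.25,
                      bound_only=False)
    total_counts = rdf.n_frames * 60
    tol = 3 / np.sqrt(total_counts / len(rdf.g))
    assert np.abs(rdf.g[1:] - 1.0).mean() < tol


def test_ring_configuration_single_peak():
    n_lip = 12
    topo = _mixed_topology(1, [("PIP2", 3)] * n_lip)
    box = 10.0
    coords = np.zeros((topo.n_particles, 3))
    coords[0] = [5.0, 5.0, 7.0]
    r0 = 1.62
    for i in range(n_lip):
        a = 2 * np.pi * i / n_lip
        x, y = 5.0 + r0 * np.cos(a), 5.0 + r0 * np.sin(a)
        for b in range(3):
            coords[1 + 3 * i + b] = [x, y, 6.0 - 0.3 * b]
    ens = _ensemble_from_coords(topo, [coords], box=(box, box, 10.0))
    rdf = rdf_lateral(ens, "PIP2", "upper", r_max=4.0, dr=0.25,
                      bound_only=False)
    nonzero = np.flatnonzero(rdf.g)
    assert len(nonzero) == 1
    assert rdf.r_centers[nonzero[0]] == pytest.approx(r0, abs=0.25)


def test_unbound_leaflet_contributes_nothing():
    """Lipids in the opposite leaflet never enter the RDF."""
    topo = _mixed_topology(1, [("PIP2", 3), ("PIP2", 3)])
    coords = np.array([
        [5.0, 5.0, 7.0],
        [5.5, 5.0, 6.0], [5.5, 5.0, 5.7], [5.5, 5.0, 5.4],   # upper
        [5.5, 5.0, 2.0], [5.5, 5.0, 2.3], [5.5, 5.0, 2.6],   # lower
    ])
    ens = _ensemble_from_coords(topo, [coords])
    up = rdf_lateral(ens, "PIP2", "upper", r_max=4.0, dr=0.5,
                     bound_only=False)
    lo = rdf_lateral(ens, "PIP2", "lower", r_max=4.0, dr=0.5,
                     bound_only=False)
    assert up.g.sum() > 0 and lo.g.sum() > 0
    # each RDF sees exactly one molecule
    area = 10.0 * 10.0
    for rdf in (up, lo):
        implied = (rdf.g * np.pi
                   * (np.arange(1, 9) ** 2 - np.arange(8) ** 2) * 0.25
                   / area).sum()
        assert implied == pytest.approx(1.0, abs=1e-9)


def test_r_max_beyond_half_box_rejected(small_ensemble):
    with pytest.raises(ValueError):
        rdf_lateral(small_ensemble, "PIP2", "upper", r_max=5.0,
                    bound_threshold=2.7)


# ---------------------------------------------------------------------------
# clustering summary
# ---------------------------------------------------------------------------

def _flat_rdf(g_near, g_far, species="PIP2"):
    r = np.arange(0.05, 4.0, 0.1)
    g = np.where(r <= 0.7, g_near, g_far)
    return RadialDistribution(r_centers=r, g=g, species=species,
                              leaflet="upper", n_frames=1)


def test_enrichment_flat_is_one():
    assert clustering_summary(_flat_rdf(1.0, 1.0)) == pytest.approx(1.0)


def test_enrichment_three_near_one_far():
    assert clustering_summary(_flat_rdf(3.0, 1.0)) == pytest.approx(3.0)


def test_enrichment_zero_far_field_errors():
    with pytest.raises(ValueError):
        clustering_summary(_flat_rdf(2.0, 0.0))


def test_pip_enrichment_exceeds_pc(small_ensemble):
    """Bound synthetic ensemble: PIP2 clusters, PC does not."""
    pip = rdf_lateral(small_ensemble, "PIP2", "upper", r_max=3.0,
                      bound_threshold=2.7)
    pc = rdf_lateral(small_ensemble, "PC", "upper", r_max=3.0,
                     bound_threshold=2.7)
    e_pip = clustering_summary(pip)
    e_pc = clustering_summary(pc)
    assert e_pip > 2.0
    assert e_pip > e_pc
    assert e_pc == pytest.approx(1.0, abs=0.6)
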