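"""Structure I/O, centres of mass, rotational fitting and leaflets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import phmem
from phmem import (
    DegenerateGeometryError,
    SelectionError,
    SimulationFrame,
    UnsupportedFormatError,
    assign_leaflets,
    center_of_mass,
    kabsch_rotation,
    superpose_rmsd,
)
from phmem.core import read_annotation, write_annotation
from phmem.synthetic import build_bilayer, BilayerSpec, split_leaflets, largest_remainder


# ---------------------------------------------------------------------------
# independent rotation oracle: Horn's quaternion eigenvector method
# ---------------------------------------------------------------------------

def quaternion_rotation_oracle(mobile, reference):
    """Optimal rotation via the largest eigenvector of Horn's 4x4 matrix;
    independent of the SVD route used by the implementation."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)
    s = m.T @ r
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    vals, vecs = np.linalg.eigh(k)
    q = vecs[:, np.argmax(vals)]  # (w, x, y, z)
    return Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

PDB_3ATOM = """\
CRYST1   40.000   40.000   40.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1      11.000  12.000  13.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.500  12.000  13.000  1.00  0.00           C
ATOM      3  C   ALA A   1      13.700  13.100  13.000  1.00  0.00           C
END
"""


def test_pdb_angstrom_to_nm(tmp_path):
    """Hand-written PDB: coordinates come back divided by ten (A -> nm)."""
    p = tmp_path / "three.pdb"
    p.write_text(PDB_3ATOM)
    topo, frame = phmem.read_structure(p)
    assert topo.n_particles == 3
    assert list(topo.names) == ["N", "CA", "C"]
    np.testing.assert_allclose(frame.coordinates[0], [1.1, 1.2, 1.3])
    np.testing.assert_allclose(frame.box, [4.0, 4.0, 4.0])
    assert set(topo.category) == {"protein"}


def test_unknown_format_rejected(tmp_path):
    p = tmp_path / "x.xyz"
    p.write_text("3\n\n")
    with pytest.raises(UnsupportedFormatError):
        phmem.read_structure(p)


def test_malformed_pdb_raises(tmp_path):
    p = tmp_path / "bad.pdb"
    p.write_text("ATOM not-a-valid-record\n")
    with pytest.raises(phmem.ParseError):
        phmem.read_structure(p)


@pytest.mark.parametrize("fmt,atol", [("pdb", 2e-4), ("gro", 6e-4)])
def test_structure_round_trip(tmp_path, fmt, atol):
    """Write then read a generated bilayer: particle count, names and
    residue indices survive; coordinates to format precision (PDB stores
    0.001 A, GRO 0.001 nm)."""
    topo, frame = build_bilayer(BilayerSpec(total_lipids=20), seed=3)
    path = tmp_path / f"bilayer.{fmt}"
    phmem.write_structure(path, topo, frame)
    topo2, frame2 = phmem.read_structure(path)
    assert topo2.n_particles == topo.n_particles
    assert list(topo2.names) == list(topo.names)
    assert list(topo2.residue_index) == list(topo.residue_index)
    np.testing.assert_allclose(frame2.coordinates, frame.coordinates,
                               atol=atol)
    # species inferred from residue names on re-read
    assert set(topo2.lipid_species[topo2.category == "lipid"]) \
        == set(topo.lipid_species[topo.category == "lipid"])


def test_category_counts_match_annotation_scan(tmp_path):
    """GRO with a full bilayer + protein: per-category particle counts
    agree with an independent text scan of the file's residue names."""
    from phmem.synthetic import make_protein, merge_topologies
    ptopo, x = make_protein(seed=1)
    btopo, bframe = build_bilayer(BilayerSpec(), seed=1, residue_offset=200)
    topo = merge_topologies(ptopo, btopo)
    coords = np.vstack([x + [5.0, 5.0, 11.0], bframe.coordinates])
    frame = SimulationFrame(0.0, coords, bframe.box)
    path = tmp_path / "system.gro"
    phmem.write_structure(path, topo, frame)

    lipid_names = {"PC", "PS", "PIP2", "PIP3"}
    n_lipid_lines = 0
    n_atom_lines = 0
    lines = path.read_text().splitlines()
    for line in lines[2:-1]:           # skip title, count, box line
        resname = line[5:10].strip()
        n_atom_lines += 1
        if resname in lipid_names:
            n_lipid_lines += 1
    topo2, _ = phmem.read_structure(path)
    assert topo2.n_particles == n_atom_lines
    assert (topo2.category == "lipid").sum() == n_lipid_lines == 356 * 3
    assert (topo2.category == "protein").sum() == n_atom_lines - n_lipid_lines


def test_annotation_round_trip(tmp_path):
    topo, _ = build_bilayer(BilayerSpec(total_lipids=12), seed=0)
    path = tmp_path / "topology.tsv"
    write_annotation(path, topo)
    topo2 = read_annotation(path)
    assert list(topo2.lipid_species) == list(topo.lipid_species)
    assert list(topo2.lipid_part) == list(topo.lipid_part)
    np.testing.assert_allclose(topo2.mass, topo.mass)


def test_triclinic_box_rejected(tmp_path):
    p = tmp_path / "tric.pdb"
    p.write_text(PDB_3ATOM.replace("90.00  90.00  90.00",
                                   "90.00  90.00  60.00"))
    with pytest.raises(UnsupportedFormatError):
        phmem.read_structure(p)


# ---------------------------------------------------------------------------
# centre of mass
# ---------------------------------------------------------------------------

def _toy_frame_topo(coords, masses):
    n = len(coords)
    topo = phmem.MolecularTopology(
        names=np.array(["X"] * n, dtype=object),
        residue_index=np.arange(n, dtype=np.int64),
        residue_name=np.array(["ALA"] * n, dtype=object),
        segment=np.array(["P"] * n, dtype=object),
        category=np.array(["protein"] * n, dtype=object),
        lipid_species=np.array([""] * n, dtype=object),
        lipid_part=np.array([""] * n, dtype=object),
        mass=np.asarray(masses, dtype=float))
    frame = SimulationFrame(0.0, np.asarray(coords, dtype=float),
                            np.array([10.0, 10.0, 10.0]))
    return frame, topo


@pytest.mark.parametrize("masses,z_expected", [
    ([1.0, 1.0], 1.0),       # equal masses at z=0,2 -> midpoint
    ([1.0, 3.0], 3.0),       # masses 1:3 at z=0,4 -> weighted
])
def test_center_of_mass_weighting(masses, z_expected):
    coords = [[0, 0, 0], [0, 0, 2 if masses[0] == masses[1] else 4]]
    frame, topo = _toy_frame_topo(coords, masses)
    com = center_of_mass(frame, np.array([0, 1]), topo)
    assert com[2] == pytest.approx(z_expected)


def test_center_of_mass_matches_direct_sum(rng):
    coords = rng.normal(size=(50, 3))
    masses = rng.uniform(0.5, 3.0, size=50)
    frame, topo = _toy_frame_topo(coords, masses)
    sel = rng.choice(50, size=20, replace=False)
    com = center_of_mass(frame, sel, topo)
    expected = sum(masses[i] * coords[i] for i in sel) / sum(masses[i] for i in sel)
    np.testing.assert_allclose(com, expected, atol=1e-12)


def test_center_of_mass_empty_selection():
    frame, topo = _toy_frame_topo([[0, 0, 0]], [1.0])
    with pytest.raises(SelectionError):
        center_of_mass(frame, np.array([], dtype=int), topo)


# ---------------------------------------------------------------------------
# rotational fitting
# ---------------------------------------------------------------------------

def test_kabsch_self_fit_is_identity(protein):
    _, x = protein
    r = kabsch_rotation(x, x)
    np.testing.assert_allclose(r, np.eye(3), atol=1e-10)


def test_kabsch_reflection_branch_never_reflects(rng):
    """Near-planar cloud: the returned matrix is a proper rotation."""
    x = rng.normal(size=(30, 3)) * [1.0, 1.0, 1e-4]
    r = kabsch_rotation(x, x[:, [1, 0, 2]])
    assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_kabsch_recovers_applied_rotation(seed):
    """Random cloud under a random rotation: the fit recovers it and
    matches the independent quaternion-eigenvector oracle to 1e-8."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(25, 3))
    true = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
    moved = x @ true.T
    fit = kabsch_rotation(moved, x)
    np.testing.assert_allclose(fit @ true, np.eye(3), atol=1e-8)
    oracle = quaternion_rotation_oracle(moved, x)
    np.testing.assert_allclose(fit, oracle, atol=1e-8)
    # orthonormal, proper
    np.testing.assert_allclose(fit.T @ fit, np.eye(3), atol=1e-10)
    assert np.linalg.det(fit) == pytest.approx(1.0, abs=1e-10)


def test_kabsch_degenerate_collinear():
    line = np.outer(np.arange(5.0), [1.0, 0.5, -0.2])
    with pytest.raises(DegenerateGeometryError):
        kabsch_rotation(line, line)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def test_superpose_identity_and_displaced(protein, rng):
    _, x = protein
    _, _, rmsd0 = superpose_rmsd(x, x)
    assert rmsd0 == pytest.approx(0.0, abs=1e-12)
    rot = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
    moved = x @ rot.T + [1.0, -2.0, 0.5]
    r, t, rmsd = superpose_rmsd(moved, x)
    assert rmsd == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(moved @ r.T + t, x, atol=1e-9)


def test_superpose_symmetric(protein, rng):
    _, x = protein
    noisy = x + rng.normal(scale=0.05, size=x.shape)
    _, _, ab = superpose_rmsd(x, noisy)
    _, _, ba = superpose_rmsd(noisy, x)
    assert ab == pytest.approx(ba, abs=1e-10)


def test_superpose_matches_rotation_grid_oracle(rng):
    """4-point toy vs exhaustive grid over rotations: the analytic
    minimum is no worse than any grid rotation and matches the best grid
    value to the grid resolution."""
    x = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1.2, 0], [0.3, 0.2, 0.9]])
    noisy = x + rng.normal(scale=0.08, size=x.shape)
    _, _, rmsd = superpose_rmsd(noisy, x)
    xc = x - x.mean(axis=0)
    nc = noisy - noisy.mean(axis=0)
    grid = np.linspace(-np.pi, np.pi, 25)
    best = np.inf
    for a in grid:
        for b in np.linspace(-np.pi / 2, np.pi / 2, 13):
            for c in grid:
                rot = Rotation.from_euler("zyx", [a, b, c]).as_matrix()
                val = np.sqrt(np.mean(np.sum((nc @ rot.T - xc) ** 2, axis=1)))
                best = min(best, val)
    assert rmsd <= best + 1e-12
    assert rmsd == pytest.approx(best, abs=0.05)


def test_superpose_length_mismatch():
    with pytest.raises(ValueError):
        superpose_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# leaflet assignment
# ---------------------------------------------------------------------------

def test_assign_leaflets_by_headgroup_side():
    bl_topo, bl_frame = build_bilayer(BilayerSpec(total_lipids=8,
                                                  composition={"PC": 1.0}),
                                      seed=0)
    leaf = assign_leaflets(bl_frame, bl_topo)
    mid = bl_frame.coordinates[:, 2].mean()
    for resid, side in leaf.items():
        head = bl_frame.coordinates[
            (bl_topo.residue_index == resid)
            & (bl_topo.lipid_part == "headgroup")]
        assert (head[0, 2] >= mid) == (side == "upper")


def test_leaflet_sizes_match_generator_bookkeeping():
    spec = BilayerSpec(total_lipids=50,
                       composition={"PC": 0.7, "PS": 0.2, "PIP2": 0.1})
    counts = largest_remainder(spec.composition, spec.total_lipids)
    upper_expected, lower_expected = split_leaflets(counts)
    topo, frame = build_bilayer(spec, seed=9)
    leaf = assign_leaflets(frame, topo)
    upper = sum(1 for v in leaf.values() if v == "upper")
    assert upper == sum(upper_expected.values())
    assert len(leaf) - upper == sum(lower_expected.values())
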