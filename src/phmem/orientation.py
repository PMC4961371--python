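"""Per-frame orientation and distance order parameters.

Two scalars characterise the protein relative to the bilayer in each
frame:

* ``Rzz`` — the zz element of the least-squares (Kabsch) rotation fitting
  the frame's protein conformation onto a reference conformation, computed
  after first removing the optimal rotation about the membrane normal
  (the in-plane pre-fit).  Rzz is +1 in the reference orientation, -1
  upside-down, and behaves like the cosine of the tilt away from the
  reference.
* ``dz`` — the perpendicular (z) distance between the protein and bilayer
  centres of mass, in nm (unsigned by default).
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import (
    DegenerateGeometryError,
    EnsembleSet,
    MolecularTopology,
    SelectionError,
    SimulationFrame,
    center_of_mass,
    kabsch_rotation,
)


class OrientationSample(NamedTuple):
    replicate_id: int
    time: float
    rzz: float
    dz: float


SAMPLE_COLUMNS = ["replicate", "time_ns", "rzz", "dz_nm"]


def fit_rotation_xy(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Remove the optimal rotation about z.

    Both point sets are centred on their COM; the closed-form 2D
    least-squares angle is applied to the mobile x,y coordinates (z is
    untouched).  Returns the in-plane-aligned mobile coordinates, centred.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must be matched (N, 3) arrays")
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)
    # planar projection must carry signal
    if np.sum(m[:, 0] ** 2 + m[:, 1] ** 2) < 1e-20:
        raise DegenerateGeometryError(
            "fit_rotation_xy: all points on the z axis")
    # minimise sum |Rz(theta) m_xy - r_xy|^2
    num = np.sum(m[:, 0] * r[:, 1] - m[:, 1] * r[:, 0])
    den = np.sum(m[:, 0] * r[:, 0] + m[:, 1] * r[:, 1])
    theta = math.atan2(num, den)
    c, s = math.cos(theta), math.sin(theta)
    out = m.copy()
    out[:, 0] = c * m[:, 0] - s * m[:, 1]
    out[:, 1] = s * m[:, 0] + c * m[:, 1]
    return out


def compute_rzz(mobile: np.ndarray, reference: np.ndarray) -> float:
    """zz element of the full least-squares rotation, after the in-plane
    pre-fit; lies in [-1, 1]."""
    aligned = fit_rotation_xy(mobile, reference)
    rot = kabsch_rotation(aligned, reference)
    return float(np.clip(rot[2, 2], -1.0, 1.0))


def compute_dz(frame: SimulationFrame, protein_sel: np.ndarray,
               bilayer_sel: np.ndarray, topology: MolecularTopology,
               signed: bool = False) -> float:
    """Perpendicular COM separation between protein and bilayer (nm)."""
    zp = center_of_mass(frame, protein_sel, topology)[2]
    zb = center_of_mass(frame, bilayer_sel, topology)[2]
    d = zp - zb
    return float(d) if signed else float(abs(d))


def frame_rzz(frame: SimulationFrame, reference: np.ndarray,
              protein_sel: np.ndarray) -> float:
    return compute_rzz(frame.coordinates[protein_sel], reference)


def orientation_series(ensemble: EnsembleSet, reference: np.ndarray,
                       protein_sel: np.ndarray | None = None,
                       bilayer_sel: np.ndarray | None = None,
                       signed_dz: bool = False) -> pd.DataFrame:
    """One (replicate, time, Rzz, dz) sample per frame per replicate.

    ``reference`` is the reference protein conformation (N_sel, 3).
    Returns a DataFrame with columns ``replicate, time_ns, rzz, dz_nm``.
    """
    topo = ensemble.topology
    if protein_sel is None:
        protein_sel = topo.protein_index()
    if bilayer_sel is None:
        bilayer_sel = topo.lipid_index()
    if protein_sel.size == 0 or bilayer_sel.size == 0:
        raise SelectionError("orientation_series: empty selection")
    rows = []
    for traj in ensemble.trajectories:
        for fr in traj.frames:
            rows.append((traj.replicate_id, fr.time,
                         compute_rzz(fr.coordinates[protein_sel], reference),
                         compute_dz(fr, protein_sel, bilayer_sel, topo,
                                    signed=signed_dz)))
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def mean_dz_curve(samples: pd.DataFrame) -> pd.DataFrame:
    """Ensemble-mean dz as a function of time (binding-curve style)."""
    out = (samples.groupby("time_ns", as_index=False)["dz_nm"]
           .mean().rename(columns={"dz_nm": "mean_dz_nm"}))
    return out


def select_reference(ensemble: EnsembleSet, bound_threshold: float,
                     protein_sel: np.ndarray | None = None,
                     bilayer_sel: np.ndarray | None = None,
                     n_subsample: int = 100, seed: int = 0) -> np.ndarray:
    """Pick the reference protein conformation from the bound state.

    Bound frames (dz <= threshold) are subsampled (``n_subsample`` frames,
    seeded); the medoid — the subsampled frame with the smallest mean
    pairwise RMSD to the others — is returned as the reference
    coordinates.  The pairwise RMSD is computed after COM centring and the
    in-plane rotational pre-fit only (no full 3D fit): orientations that
    differ only by a rotation about the membrane normal are equivalent
    here, while tilt differences must register, so the medoid of a
    dominantly-oriented bound ensemble lands in the major mode.
    """
    topo = ensemble.topology
    if protein_sel is None:
        protein_sel = topo.protein_index()
    if bilayer_sel is None:
        bilayer_sel = topo.lipid_index()
    bound = []
    for traj in ensemble.trajectories:
        for fr in traj.frames:
            if compute_dz(fr, protein_sel, bilayer_sel, topo) <= bound_threshold:
                bound.append(fr.coordinates[protein_sel])
    if not bound:
        raise SelectionError(
            "select_reference: no bound frames below the threshold; "
            "supply a reference conformation explicitly")
    rng = np.random.default_rng(seed)
    if len(bound) > n_subsample:
        idx = rng.choice(len(bound), size=n_subsample, replace=False)
        idx.sort()
        bound = [bound[i] for i in idx]
    n = len(bound)
    if n == 1:
        return bound[0].copy()
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aligned = fit_rotation_xy(bound[i], bound[j])
            ref = bound[j] - bound[j].mean(axis=0)
            r = float(np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=1))))
            rmsd[i, j] = rmsd[j, i] = r
    medoid = int(np.argmin(rmsd.mean(axis=1)))
    return bound[medoid].copy()
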