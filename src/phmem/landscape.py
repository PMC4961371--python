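"""Normalized 2D density landscapes over (Rzz, dz), binding-mode
detection, representative frames, binding-time detection and ensemble
convergence checks.

All replicate samples are merged into one two-dimensional histogram.  Each
bin count is divided by (number of replicate simulations x frames per
replicate x bin area) to give a per-area density, and densities are then
divided by the density at the global free-energy minimum — the maximum bin
density — so the normalized landscape lies in [0, 1] with the dominant
basin at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .core import PhmemError, logger


@dataclass
class DensityLandscape:
    rzz_edges: np.ndarray
    dz_edges: np.ndarray
    counts: np.ndarray          # (n_rzz, n_dz) integer grid
    density: np.ndarray         # counts / (n_sims * frames_per_sim * bin area)
    normalized: np.ndarray      # density / max(density), in [0, 1]
    n_sims: int
    frames_per_sim: int
    n_dropped: int = 0

    @property
    def bin_area(self) -> np.ndarray:
        """Per-bin area grid (handles non-uniform edges)."""
        w_rzz = np.diff(self.rzz_edges)
        w_dz = np.diff(self.dz_edges)
        return np.outer(w_rzz, w_dz)

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (0.5 * (self.rzz_edges[:-1] + self.rzz_edges[1:]),
                0.5 * (self.dz_edges[:-1] + self.dz_edges[1:]))


@dataclass
class BindingMode:
    rank: int
    center: tuple[float, float]            # (rzz, dz nm)
    normalized_density: float
    basin_bins: set = field(default_factory=set)   # {(i_rzz, i_dz), ...}
    peak_bin: tuple[int, int] = (0, 0)
    representative: tuple[int, float] | None = None  # (replicate_id, time)


@dataclass
class BindingEvent:
    replicate_id: int
    binding_time: float | None
    dissociation_times: list[float] = field(default_factory=list)


DEFAULT_RZZ_EDGES = np.linspace(-1.0, 1.0, 41)   # 0.05 wide
DEFAULT_DZ_EDGES = np.linspace(0.0, 8.0, 41)     # 0.2 nm wide


def build_landscape(samples: pd.DataFrame,
                    rzz_edges: np.ndarray = DEFAULT_RZZ_EDGES,
                    dz_edges: np.ndarray = DEFAULT_DZ_EDGES,
                    n_sims: int | None = None,
                    frames_per_sim: int | None = None) -> DensityLandscape:
    """Histogram the merged orientation samples into a density landscape.

    Bins are half-open [lo, hi) with the last bin closed; out-of-range
    samples are dropped (count logged).  ``n_sims``/``frames_per_sim``
    default to the values implied by the samples.
    """
    rzz_edges = np.asarray(rzz_edges, dtype=float)
    dz_edges = np.asarray(dz_edges, dtype=float)
    for e in (rzz_edges, dz_edges):
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
    if n_sims is None:
        n_sims = max(1, samples["replicate"].nunique())
    if frames_per_sim is None:
        frames_per_sim = max(1, int(round(len(samples) / max(n_sims, 1))))

    rzz = samples["rzz"].to_numpy()
    dz = samples["dz_nm"].to_numpy()
    in_range = ((rzz >= rzz_edges[0]) & (rzz <= rzz_edges[-1])
                & (dz >= dz_edges[0]) & (dz <= dz_edges[-1]))
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info("build_landscape: dropped %d out-of-range samples", n_dropped)
    counts, _, _ = np.histogram2d(rzz[in_range], dz[in_range],
                                  bins=[rzz_edges, dz_edges])
    counts = counts.astype(np.int64)
    if counts.sum() == 0:
        logger.warning("build_landscape: zero samples in range")
    w_area = np.outer(np.diff(rzz_edges), np.diff(dz_edges))
    density = counts / (n_sims * frames_per_sim * w_area)
    peak = density.max()
    normalized = density / peak if peak > 0 else np.zeros_like(density)
    return DensityLandscape(rzz_edges=rzz_edges, dz_edges=dz_edges,
                            counts=counts, density=density,
                            normalized=normalized, n_sims=n_sims,
                            frames_per_sim=frames_per_sim,
                            n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# mode detection
# ---------------------------------------------------------------------------

def _local_maxima(grid: np.ndarray) -> list[tuple[int, int]]:
    """Bins >= all 8 neighbours and > 0 (plateau ties all reported;
    the greedy separation filter resolves them)."""
    ni, nj = grid.shape
    out = []
    for i in range(ni):
        for j in range(nj):
            v = grid[i, j]
            if v <= 0:
                continue
            neigh = grid[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
            if v >= neigh.max():
                out.append((i, j))
    return out


def find_modes(landscape: DensityLandscape, min_separation_bins: int = 3,
               min_relative_density: float = 0.02) -> list[BindingMode]:
    """Detect binding modes as local maxima of the normalized density.

    Maxima above ``min_relative_density`` are accepted greedily in
    descending density order, rejecting any peak within Chebyshev distance
    ``min_separation_bins`` of an accepted one.  Every nonzero bin is
    assigned to a basin by steepest ascent; mode centers are
    density-weighted centroids of the basin core (basin bins at or above
    half the mode's peak density, so a basin's broad low-density skirt
    does not drag the center off its summit).  Ties are broken toward
    lower dz, then lower rzz.
    """
    g = landscape.normalized
    peaks = _local_maxima(g)
    centers_rzz, centers_dz = landscape.bin_centers()
    # order: descending density, then lower dz, then lower rzz
    peaks.sort(key=lambda p: (-g[p], centers_dz[p[1]], centers_rzz[p[0]]))
    accepted: list[tuple[int, int]] = []
    for p in peaks:
        if g[p] < min_relative_density:
            continue
        if all(max(abs(p[0] - q[0]), abs(p[1] - q[1])) > min_separation_bins
               for q in accepted):
            accepted.append(p)
    if not accepted:
        return []

    # steepest-ascent basin assignment
    ni, nj = g.shape
    uphill = {}
    for i in range(ni):
        for j in range(nj):
            if g[i, j] <= 0:
                continue
            best, best_v = (i, j), g[i, j]
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    a, b = i + di, j + dj
                    if 0 <= a < ni and 0 <= b < nj and g[a, b] > best_v:
                        best, best_v = (a, b), g[a, b]
            uphill[(i, j)] = best

    def summit(cell):
        seen = set()
        while uphill.get(cell, cell) != cell and cell not in seen:
            seen.add(cell)
            cell = uphill[cell]
        return cell

    accepted_set = set(accepted)
    basin: dict[tuple[int, int], list] = {p: [] for p in accepted}
    summit_cache: dict = {}
    for cell in uphill:
        s = summit_cache.get(cell)
        if s is None:
            s = summit(cell)
            summit_cache[cell] = s
        if s in accepted_set:
            basin[s].append(cell)
        else:
            # summit was rejected by the separation filter: merge into the
            # nearest accepted peak (Chebyshev; tie toward denser peak)
            near = min(accepted,
                       key=lambda q: (max(abs(s[0] - q[0]), abs(s[1] - q[1])),
                                      -g[q]))
            basin[near].append(cell)

    modes = []
    for rank, p in enumerate(accepted, start=1):
        cells = basin[p]
        w = np.array([g[c] for c in cells])
        core = w >= 0.5 * g[p]
        w = w[core]
        cr = np.array([centers_rzz[c[0]] for c in cells])[core]
        cd = np.array([centers_dz[c[1]] for c in cells])[core]
        center = (float((w * cr).sum() / w.sum()),
                  float((w * cd).sum() / w.sum()))
        modes.append(BindingMode(rank=rank, center=center,
                                 normalized_density=float(g[p]),
                                 basin_bins=set(cells), peak_bin=p))
    modes.sort(key=lambda m: (-m.normalized_density,
                              m.center[1], m.center[0]))
    for rank, m in enumerate(modes, start=1):
        m.rank = rank
    return modes


def representative_frame(samples: pd.DataFrame, mode: BindingMode,
                         landscape: DensityLandscape) -> tuple[int, float]:
    """The (replicate, time) whose (rzz, dz) is nearest the mode center,
    among samples falling in the mode's basin (Euclidean distance after
    scaling each axis by its bin width)."""
    if not mode.basin_bins:
        raise PhmemError("representative_frame: empty mode basin")
    w_rzz = float(np.mean(np.diff(landscape.rzz_edges)))
    w_dz = float(np.mean(np.diff(landscape.dz_edges)))
    rzz = samples["rzz"].to_numpy()
    dz = samples["dz_nm"].to_numpy()
    i = np.clip(np.searchsorted(landscape.rzz_edges, rzz, side="right") - 1,
                0, len(landscape.rzz_edges) - 2)
    j = np.clip(np.searchsorted(landscape.dz_edges, dz, side="right") - 1,
                0, len(landscape.dz_edges) - 2)
    in_basin = np.array([(a, b) in mode.basin_bins for a, b in zip(i, j)])
    if not in_basin.any():
        raise PhmemError("representative_frame: no samples in mode basin")
    d2 = (((rzz - mode.center[0]) / w_rzz) ** 2
          + ((dz - mode.center[1]) / w_dz) ** 2)
    d2[~in_basin] = np.inf
    k = int(np.argmin(d2))
    return int(samples["replicate"].iloc[k]), float(samples["time_ns"].iloc[k])


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------

def jsd_nats(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in nats (0 = identical, max = ln 2)."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    return float(jensenshannon(p, q, base=np.e) ** 2)


def convergence_split(samples: pd.DataFrame, scheme: Sequence[Sequence[int]],
                      rzz_edges: np.ndarray = DEFAULT_RZZ_EDGES,
                      dz_edges: np.ndarray = DEFAULT_DZ_EDGES,
                      find_modes_kwargs: dict | None = None,
                      ) -> tuple[list[DensityLandscape], np.ndarray, list[bool]]:
    """Split replicates into disjoint blocks and compare their landscapes.

    Returns (per-block landscapes, pairwise JSD matrix in nats, and a
    per-block flag for whether the block's dominant mode peak lies within
    one bin of the full ensemble's dominant mode peak).
    """
    reps = set(samples["replicate"].unique())
    seen: set[int] = set()
    for block in scheme:
        if not block:
            raise ValueError("convergence_split: empty block")
        b = set(block)
        if b & seen:
            raise ValueError("convergence_split: blocks must be disjoint")
        seen |= b
    if seen != reps:
        raise ValueError("convergence_split: blocks must cover all replicates")

    kw = find_modes_kwargs or {}
    full = build_landscape(samples, rzz_edges, dz_edges)
    full_modes = find_modes(full, **kw)
    landscapes = []
    dominant_match = []
    for block in scheme:
        sub = samples[samples["replicate"].isin(block)]
        ls = build_landscape(sub, rzz_edges, dz_edges, n_sims=len(block))
        landscapes.append(ls)
        modes = find_modes(ls, **kw)
        if full_modes and modes:
            p, q = modes[0].peak_bin, full_modes[0].peak_bin
            dominant_match.append(max(abs(p[0] - q[0]), abs(p[1] - q[1])) <= 1)
        else:
            dominant_match.append(False)

    n = len(landscapes)
    jsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci = landscapes[i].counts.astype(float)
            cj = landscapes[j].counts.astype(float)
            jsd[i, j] = jsd[j, i] = jsd_nats(ci / ci.sum(), cj / cj.sum())
    return landscapes, jsd, dominant_match


# ---------------------------------------------------------------------------
# binding detection
# ---------------------------------------------------------------------------

def detect_binding(times: np.ndarray, dz: np.ndarray, bound_threshold: float,
                   min_persist: int = 10, replicate_id: int = 0,
                   ) -> BindingEvent:
    """First time dz stays at or below the threshold for at least
    ``min_persist`` consecutive frames; also reports sustained
    bound->unbound transitions (dissociation events)."""
    times = np.asarray(times, dtype=float)
    dz = np.asarray(dz, dtype=float)
    if times.size == 0:
        raise ValueError("detect_binding: empty series")
    below = dz <= bound_threshold
    binding_time = None
    dissociations: list[float] = []
    run_start = None
    run_len = 0
    bound = False
    above_run = 0
    for i, b in enumerate(below):
        if b:
            if run_len == 0:
                run_start = i
            run_len += 1
            above_run = 0
            if not bound and run_len >= min_persist:
                bound = True
                if binding_time is None:
                    binding_time = float(times[run_start])
        else:
            run_len = 0
            above_run += 1
            if bound and above_run >= min_persist:
                bound = False
                dissociations.append(float(times[i - min_persist + 1]))
    return BindingEvent(replicate_id=replicate_id, binding_time=binding_time,
                        dissociation_times=dissociations)


def binding_events(samples: pd.DataFrame, bound_threshold: float,
                   min_persist: int = 10) -> list[BindingEvent]:
    """Per-replicate binding detection from an orientation-sample table."""
    out = []
    for rep, grp in samples.groupby("replicate"):
        grp = grp.sort_values("time_ns")
        out.append(detect_binding(grp["time_ns"].to_numpy(),
                                  grp["dz_nm"].to_numpy(),
                                  bound_threshold, min_persist,
                                  replicate_id=int(rep)))
    return out


def default_bound_threshold(half_thickness: float,
                            protein_rg: float) -> float:
    """Bilayer half-thickness plus a protein radius-of-gyration estimate."""
    return half_thickness + protein_rg


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None,
                       ) -> float:
    coords = np.asarray(coords, dtype=float)
    if masses is None:
        masses = np.ones(len(coords))
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    d2 = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt((masses * d2).sum() / masses.sum()))
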