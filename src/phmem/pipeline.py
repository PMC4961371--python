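"""Configuration handling and the end-to-end analysis driver.

One structured-text (YAML) config drives the full sequence: ensemble
(generated or loaded) -> orientation series -> density landscape and
binding modes -> convergence split -> binding kinetics -> contact
profiles -> lateral RDFs and clustering enrichment -> hydrogen bonds
(atomistic inputs only) -> JSON summary.  Identical config and seed give
identical outputs.
"""

from __future__ import annotations

import copy
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as _contacts
from . import hbonds as _hbonds
from . import landscape as _landscape
from . import orientation as _orientation
from . import synthetic as _synthetic
from .core import ConfigError, PhmemError, logger, read_structure
from .synthetic import BilayerSpec, HEAD_OFFSET, ToyDynamicsSpec

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "phmem_out",
    "condition": "",
    "generate": {
        "enabled": True,
        "total_lipids": 356,
        "composition": {"PC": 0.75, "PS": 0.20, "PIP2": 0.05},
        "area_per_lipid_nm2": 0.65,
        "n_replicates": 20,
        "n_frames": 1000,
        "dt_ns": 1.0,
        "start_height_nm": 7.0,
        "capture_radius_nm": 3.5,
        "mean_binding_time_ns": 250.0,
        "mode_centers": [[1.0, 0.75], [0.2, 0.20]],
        "orientation_noise": 0.1,
        "pip_attraction_range_nm": 3.0,
        "pip_cluster_strength": 1.0,
        "protein_particles": 50,
        "protein_radius_nm": 0.9,
        "write_files": False,
    },
    "inputs": {
        "ensemble_dir": None,
    },
    "orientation": {
        "reference": None,          # structure path; default: bound-state medoid
        "bound_threshold_nm": None,  # default: half thickness + protein Rg
        "min_persist_frames": 10,
        "reference_subsample": 100,
    },
    "landscape": {
        "rzz_bins": 40, "rzz_min": -1.0, "rzz_max": 1.0,
        "dz_bins": 40, "dz_min_nm": 0.0, "dz_max_nm": 8.0,
        "min_separation_bins": 3,
        "min_relative_density": 0.02,
        "convergence_blocks": 4,
    },
    "contacts": {
        "cutoff_nm": 0.6,
        "bound_only": True,
        "parts": True,
    },
    "rdf": {
        "r_max_nm": 4.0,
        "dr_nm": 0.1,
        "bound_only": True,
        "r_contact_nm": 0.7,
    },
    "hbonds": {
        "d_max_nm": 0.35,
        "angle_max_deg": 30.0,
        "residues": None,
    },
    "plots": {
        "enabled": False,
    },
}


_UNIT_FACTORS = {
    "_nm": {"nm": 1.0, "a": 0.1, "å": 0.1, "ang": 0.1, "angstrom": 0.1,
            "angstroms": 0.1},
    "_nm2": {"nm2": 1.0, "nm^2": 1.0},
    "_ns": {"ns": 1.0, "us": 1000.0, "μs": 1000.0},
}


def _parse_length(value, key: str) -> float:
    """Dimensioned values are native nm / nm^2 / ns by key suffix; strings
    may carry an explicit unit ('0.6 nm', '6 A', '1 us')."""
    if isinstance(value, (int, float)):
        return float(value)
    suffix = next(s for s in ("_nm2", "_nm", "_ns") if key.endswith(s))
    factors = _UNIT_FACTORS[suffix]
    if isinstance(value, str):
        parts = value.split()
        try:
            num = float(parts[0])
        except (ValueError, IndexError) as exc:
            raise ConfigError(f"{key}: cannot parse value {value!r}") from exc
        if len(parts) == 1:
            return num
        unit = parts[1].lower()
        if unit not in factors:
            raise ConfigError(f"{key}: unknown unit {unit!r}")
        factor = factors[unit]
        if factor != 1.0:
            logger.info("config: %s given as %r; converted to %.6g",
                        key, value, num * factor)
        return num * factor
    raise ConfigError(f"{key}: expected a number, got {value!r}")


def _merge(defaults: dict, given: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in given.items():
        full = f"{path}{key}"
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {full!r}")
        if isinstance(defaults[key], dict) and key != "composition":
            if value is None:
                continue
            if not isinstance(value, dict):
                raise ConfigError(f"{full}: expected a mapping")
            out[key] = _merge(defaults[key], value, path=f"{full}.")
        elif key.endswith(("_nm", "_nm2", "_ns")) and value is not None:
            out[key] = _parse_length(value, full)
        else:
            out[key] = copy.deepcopy(value)
    return out


def validate_config(source: "str | Path | dict | None" = None) -> dict:
    """Load, check and normalize a configuration.

    ``source`` may be a YAML path, an already-parsed mapping, or None for
    pure defaults.  Unknown keys are rejected by name; lengths given in
    Angstrom are converted to nm.
    """
    if source is None:
        given: dict = {}
    elif isinstance(source, dict):
        given = source
    else:
        text = Path(source).read_text()
        given = yaml.safe_load(text) or {}
        if not isinstance(given, dict):
            raise ConfigError(f"{source}: config must be a mapping")
    cfg = _merge(DEFAULT_CONFIG, given)
    comp = cfg["generate"]["composition"]
    tot = sum(comp.values())
    if abs(tot - 1.0) > 1e-6:
        raise ConfigError(f"generate.composition sums to {tot}, not 1")
    logger.info("effective config: %s", json.dumps(cfg, sort_keys=True))
    return cfg


def _specs_from_config(cfg: dict) -> tuple[BilayerSpec, ToyDynamicsSpec]:
    g = cfg["generate"]
    bilayer = BilayerSpec(total_lipids=g["total_lipids"],
                          composition=dict(g["composition"]),
                          area_per_lipid=g["area_per_lipid_nm2"])
    dynamics = ToyDynamicsSpec(
        n_replicates=g["n_replicates"], n_frames=g["n_frames"],
        dt=g["dt_ns"], start_height=g["start_height_nm"],
        capture_radius=g["capture_radius_nm"],
        mean_binding_time=(np.inf if g["mean_binding_time_ns"] in
                           (None, "inf") else g["mean_binding_time_ns"]),
        mode_centers=tuple((float(r), float(o))
                           for r, o in g["mode_centers"]),
        orientation_noise=g["orientation_noise"],
        pip_attraction_range=g["pip_attraction_range_nm"],
        pip_cluster_strength=g["pip_cluster_strength"],
        seed=cfg["seed"])
    return bilayer, dynamics


def _blocks(replicates: list[int], n_blocks: int) -> list[list[int]]:
    reps = sorted(replicates)
    n_blocks = max(1, min(n_blocks, len(reps)))
    size = len(reps) // n_blocks
    out, k = [], 0
    for b in range(n_blocks):
        extra = 1 if b < len(reps) % n_blocks else 0
        out.append(reps[k:k + size + extra])
        k += size + extra
    return out


def run_pipeline(config: "dict | str | Path | None") -> dict:
    """Run the full analysis; returns the summary dict (also written as
    ``summary.json`` in the output directory)."""
    cfg = validate_config(config)
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"condition": cfg["condition"], "seed": cfg["seed"]}
    stage = "setup"
    t_start = _time.perf_counter()
    try:
        # --- ensemble ---
        stage = "ensemble"
        if cfg["inputs"]["ensemble_dir"]:
            ensemble = _synthetic.read_ensemble(cfg["inputs"]["ensemble_dir"])
        elif cfg["generate"]["enabled"]:
            bilayer, dynamics = _specs_from_config(cfg)
            g = cfg["generate"]
            protein = _synthetic.make_protein(
                n_particles=g["protein_particles"],
                radius=g["protein_radius_nm"], seed=cfg["seed"])
            ensemble = _synthetic.generate_ensemble(
                bilayer, dynamics, protein,
                condition=cfg["condition"] or None)
            if g["write_files"]:
                _synthetic.write_ensemble(
                    ensemble, out_dir / "ensemble",
                    specs=_synthetic.spec_dict(bilayer, dynamics))
        else:
            raise ConfigError("no input: set inputs.ensemble_dir or "
                              "generate.enabled")
        topo = ensemble.topology
        prot_sel = topo.protein_index()
        lip_sel = topo.lipid_index()
        _log_stage(stage, t_start)

        # --- bound threshold ---
        stage = "threshold"
        thr = cfg["orientation"]["bound_threshold_nm"]
        if thr is None:
            rg = _landscape.radius_of_gyration(
                ensemble.trajectories[0].frames[0].coordinates[prot_sel],
                topo.mass[prot_sel])
            thr = _landscape.default_bound_threshold(HEAD_OFFSET, rg)
        summary["bound_threshold_nm"] = float(thr)

        # --- reference ---
        stage = "reference"
        if cfg["orientation"]["reference"]:
            _, ref_frame = read_structure(cfg["orientation"]["reference"])
            reference = ref_frame.coordinates
            if len(reference) != prot_sel.size:
                reference = reference[prot_sel]
        else:
            try:
                reference = _orientation.select_reference(
                    ensemble, thr, prot_sel, lip_sel,
                    n_subsample=cfg["orientation"]["reference_subsample"],
                    seed=cfg["seed"])
            except PhmemError:
                logger.warning("no bound frames; using the first frame's "
                               "conformation as reference")
                reference = ensemble.trajectories[0].frames[0] \
                    .coordinates[prot_sel]
        _log_stage(stage, t_start)

        # --- orientation series ---
        stage = "orient"
        samples = _orientation.orientation_series(ensemble, reference,
                                                  prot_sel, lip_sel)
        samples.to_csv(out_dir / "samples.csv", index=False)
        _orientation.mean_dz_curve(samples).to_csv(
            out_dir / "mean_dz.csv", index=False)
        _log_stage(stage, t_start)

        # --- landscape + modes ---
        stage = "landscape"
        ls_cfg = cfg["landscape"]
        rzz_edges = np.linspace(ls_cfg["rzz_min"], ls_cfg["rzz_max"],
                                ls_cfg["rzz_bins"] + 1)
        dz_edges = np.linspace(ls_cfg["dz_min_nm"], ls_cfg["dz_max_nm"],
                               ls_cfg["dz_bins"] + 1)
        ls = _landscape.build_landscape(samples, rzz_edges, dz_edges)
        _write_landscape(out_dir / "landscape.tsv", ls)
        modes = _landscape.find_modes(
            ls, min_separation_bins=ls_cfg["min_separation_bins"],
            min_relative_density=ls_cfg["min_relative_density"])
        mode_table = []
        for m in modes:
            rep = _landscape.representative_frame(samples, m, ls)
            mode_table.append({
                "rank": m.rank,
                "rzz": round(m.center[0], 6),
                "dz_nm": round(m.center[1], 6),
                "normalized_density": round(m.normalized_density, 6),
                "bound": m.center[1] <= thr,
                "representative": {"replicate": rep[0], "time_ns": rep[1]},
            })
        with open(out_dir / "modes.json", "w") as fh:
            json.dump(mode_table, fh, indent=1, sort_keys=True)
        summary["modes"] = mode_table
        summary["n_bound_modes"] = sum(m["bound"] for m in mode_table)
        if cfg["plots"]["enabled"]:
            _plot_landscape(out_dir / "landscape.png", ls)
        _log_stage(stage, t_start)

        # --- convergence ---
        stage = "converge"
        reps = [t.replicate_id for t in ensemble.trajectories]
        verdict = None
        if len(reps) >= 2:
            blocks = _blocks(reps, ls_cfg["convergence_blocks"])
            _, jsd, match = _landscape.convergence_split(
                samples, blocks, rzz_edges, dz_edges,
                find_modes_kwargs={
                    "min_separation_bins": ls_cfg["min_separation_bins"],
                    "min_relative_density": ls_cfg["min_relative_density"]})
            pd.DataFrame(jsd).to_csv(out_dir / "convergence_jsd.csv",
                                     index=False)
            off = jsd[np.triu_indices_from(jsd, k=1)]
            verdict = {
                "blocks": [len(b) for b in blocks],
                "max_pairwise_jsd_nats": float(off.max()) if off.size else 0.0,
                "dominant_mode_consistent": bool(all(match)),
            }
        summary["convergence"] = verdict
        _log_stage(stage, t_start)

        # --- binding kinetics ---
        stage = "binding"
        events = _landscape.binding_events(
            samples, thr, cfg["orientation"]["min_persist_frames"])
        bt = [e.binding_time for e in events if e.binding_time is not None]
        summary["binding_fraction"] = len(bt) / max(len(events), 1)
        summary["mean_binding_time_ns"] = (float(np.mean(bt)) if bt else None)
        summary["n_dissociation_events"] = int(
            sum(len(e.dissociation_times) for e in events))
        _log_stage(stage, t_start)

        any_bound = bool(bt)

        # --- contacts ---
        stage = "contacts"
        c_cfg = cfg["contacts"]
        if any_bound or not c_cfg["bound_only"]:
            profile = _contacts.contact_profile(
                ensemble, cutoff=c_cfg["cutoff_nm"],
                bound_only=c_cfg["bound_only"] and any_bound,
                parts=c_cfg["parts"], bound_threshold=thr)
            _write_contacts(out_dir / "contacts.csv", profile)
            top = {sp: int(profile.normalized[sp].idxmax())
                   for sp in profile.counts.columns
                   if profile.counts[sp].max() > 0}
            summary["top_contact_residue"] = top
        else:
            summary["top_contact_residue"] = None
        _log_stage(stage, t_start)

        # --- RDF / clustering ---
        stage = "rdf"
        enrich = None
        if any_bound:
            leaflet = _bound_leaflet(ensemble, samples, thr)
            r_cfg = cfg["rdf"]
            box = ensemble.trajectories[0].frames[0].box
            r_max = min(r_cfg["r_max_nm"],
                        min(box[0], box[1]) / 2 - r_cfg["dr_nm"])
            if r_max < r_cfg["r_max_nm"]:
                logger.info("rdf: r_max clamped to %.2f nm for box %.2f nm",
                            r_max, min(box[0], box[1]))
            rows = []
            enrich = {}
            for sp in topo.species_present():
                try:
                    rdf = _contacts.rdf_lateral(
                        ensemble, sp, leaflet, r_max=r_max,
                        dr=r_cfg["dr_nm"], bound_only=r_cfg["bound_only"],
                        bound_threshold=thr)
                except PhmemError:
                    continue
                enrich[sp] = round(_contacts.clustering_summary(
                    rdf, r_contact=r_cfg["r_contact_nm"]), 6)
                for r, gv in zip(rdf.r_centers, rdf.g):
                    rows.append({"r_nm": r, "g": gv, "species": sp,
                                 "leaflet": leaflet})
            pd.DataFrame(rows).to_csv(out_dir / "rdf.csv", index=False)
        summary["clustering_enrichment"] = enrich
        _log_stage(stage, t_start)

        # --- hydrogen bonds ---
        stage = "hbonds"
        has_h = any(str(n).upper().startswith("H") and c == "protein"
                    for n, c in zip(topo.names, topo.category))
        if has_h:
            h_cfg = cfg["hbonds"]
            series = _hbonds.hbond_series(
                ensemble, residues=h_cfg["residues"],
                d_max=h_cfg["d_max_nm"], angle_max=h_cfg["angle_max_deg"])
            series.per_residue.to_csv(out_dir / "hbonds_per_residue.csv")
            series.persistence.to_csv(out_dir / "hbond_persistence.csv",
                                      header=["persistence"])
            summary["mean_hbonds_per_frame"] = float(series.total.mean())
        else:
            logger.info("hbonds stage skipped: no explicit hydrogens "
                        "(coarse-grained input)")
            summary["mean_hbonds_per_frame"] = None
        _log_stage(stage, t_start)

    except PhmemError as exc:
        raise PhmemError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _bound_leaflet(ensemble, samples, thr) -> str:
    """Leaflet on the protein's side in the bound state (signed dz)."""
    topo = ensemble.topology
    prot_sel = topo.protein_index()
    lip_sel = topo.lipid_index()
    for traj in ensemble.trajectories:
        for fr in reversed(traj.frames):
            d = _orientation.compute_dz(fr, prot_sel, lip_sel, topo,
                                        signed=True)
            if abs(d) <= thr:
                return "upper" if d >= 0 else "lower"
    return "upper"


def _log_stage(stage: str, t_start: float) -> None:
    logger.info("stage %-10s done at %.1f s", stage,
                _time.perf_counter() - t_start)


def _write_landscape(path: Path, ls) -> None:
    with open(path, "w") as fh:
        fh.write("# normalized density grid (rows: rzz bins, cols: dz bins)\n")
        fh.write("# rzz_edges\t" + "\t".join(f"{e:g}" for e in ls.rzz_edges)
                 + "\n")
        fh.write("# dz_edges_nm\t" + "\t".join(f"{e:g}" for e in ls.dz_edges)
                 + "\n")
        fh.write(f"# n_sims\t{ls.n_sims}\tframes_per_sim\t{ls.frames_per_sim}"
                 f"\tdropped\t{ls.n_dropped}\n")
        np.savetxt(fh, ls.normalized, fmt="%.6g", delimiter="\t")


def _write_contacts(path: Path, profile) -> None:
    rows = []
    for resid in profile.counts.index:
        for sp in profile.counts.columns:
            row = {"residue": int(resid), "species": sp,
                   "mean_contacts": profile.counts.loc[resid, sp],
                   "normalized": profile.normalized.loc[resid, sp]}
            for part, table in profile.parts.items():
                row[f"mean_contacts_{part}"] = table.loc[resid, sp]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _plot_landscape(path: Path, ls) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    pcm = ax.pcolormesh(ls.dz_edges, ls.rzz_edges, ls.normalized,
                        cmap="viridis")
    ax.set_xlabel("dz (nm)")
    ax.set_ylabel("Rzz")
    fig.colorbar(pcm, ax=ax, label="normalized density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
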