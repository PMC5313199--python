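"""End-to-end pipeline commands: dock, analyze, benchmark.

Each command is an importable function; the CLI in
:mod:`replicadock.cli` is a thin wrapper.  Every dock run writes a JSON
manifest (config echo + seed + package version) from which the run can
be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ambiguity_bias import BiasWindow
from .analysis import (RmsdSeries, first_passage, leader_cluster,
                       ligand_rmsd, near_native_fraction)
from .config import RunConfig
from .hremd import acceptance_statistics, run_hremd
from .surface_selection import select_surface_atoms
from .system_model import read_pdb, write_pdb, write_xyz_trajectory
from .toy_engine import (SimulationState, compute_energy_forces,
                         draw_maxwell_boltzmann, run_segment)
from .toy_systems import make_sticky_receptor

__all__ = ["cmd_dock", "cmd_analyze", "cmd_benchmark", "build_system"]


def build_system(config: RunConfig):
    """Materialize the configured system: toy generator or PDB input.

    Returns (system, ff, restraints, reference_coords) where the
    reference is the native complex for toy systems and the input
    structure for PDB systems.  PDB systems carry no bead force field
    and can only be used for surface/bias analysis, not dynamics.
    """
    syscfg = config["system"]
    if syscfg.get("pdb"):
        system = read_pdb(syscfg["pdb"])
        return system, None, None, system.coords.copy()
    toy = make_sticky_receptor(
        n_receptor_beads=syscfg["n_receptor_beads"],
        n_ligand_beads=syscfg["n_ligand_beads"],
        n_decoys=syscfg["n_decoys"],
        native_depth=syscfg["native_depth"],
        decoy_depth=syscfg["decoy_depth"],
        base_depth=syscfg["base_depth"],
        sigma=syscfg["sigma"],
        shell_radius=syscfg["shell_radius"],
        seed=syscfg["seed"],
    )
    return toy.system, toy.ff, toy.restraints, toy.native_pose


def _rmsd_series(frames, records, reference, system) -> RmsdSeries:
    values = [ligand_rmsd(f, reference, system.receptor_idx,
                          system.ligand_idx) for f in frames]
    steps = [r["step"] for r in records]
    return RmsdSeries(np.asarray(values), np.asarray(steps))


def _fractions_table(series_per_replica, thresholds) -> pd.DataFrame:
    """Near-native fractions per replica, split into run halves.

    Columns mirror the paired-threshold, per-time-window layout of the
    published result tables.
    """
    rows = []
    for r, series in enumerate(series_per_replica):
        n = len(series)
        half = n // 2
        row = {"replica": r}
        for label, window in (("first_half", (0, half)),
                              ("second_half", (half, n)),
                              ("full", (0, n))):
            for thr in thresholds:
                key = f"frac_lt_{thr:g}A_{label}"
                row[key] = (near_native_fraction(series, thr, window)
                            if window[1] > window[0] else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def cmd_dock(config: RunConfig, outdir, seed: int | None = None) -> Path:
    """Full docking protocol: surface groups → ladder → H-REMD → analysis.

    Writes per-replica XYZ trajectories, the exchange log, per-frame
    diagnostics, near-native fraction and cluster tables, the reference
    pose, and a manifest sufficient to reproduce the run bitwise.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config["remd"]["seed"]

    system, ff, restraints, reference = build_system(config)
    if ff is None:
        raise ValueError("docking dynamics requires a toy system "
                         "(PDB systems carry no bead force field)")
    surf = config["surface"]
    groups = select_surface_atoms(system, surf["min_area"], surf["probe"],
                                  surf["n_sphere_points"])
    ladder = config.ladder()
    eng, remd, bias = config["engine"], config["remd"], config["bias"]
    store = run_hremd(
        system, ff, restraints, groups, ladder,
        n_steps=remd["n_steps"], exchange_interval=remd["exchange_interval"],
        seed=seed, dt=eng["dt"], gamma=eng["gamma"],
        temperature=eng["temperature"], record_every=remd["record_every"],
        cutoff=surf["cutoff"], exponent=bias["exponent"],
        normalization=bias["normalization"],
        guard_trigger=bias["guard_trigger"])

    manifest = {"version": __version__, "seed": seed,
                "config": config.to_dict()}
    manifest["config"]["remd"]["seed"] = seed
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))

    for r in range(len(ladder)):
        write_xyz_trajectory(store, r, outdir / f"replica_{r}.xyz")
    store.exchange_frame().to_csv(outdir / "exchange_log.csv", index=False)
    store.diagnostics_frame().to_csv(outdir / "diagnostics.csv", index=False)
    write_pdb(system, reference, outdir / "reference.pdb")

    thresholds = config["analysis"]["thresholds"]
    series = [_rmsd_series(store.frames[r], store.records[r], reference,
                           system) for r in range(len(ladder))]
    _fractions_table(series, thresholds).to_csv(outdir / "fractions.csv",
                                                index=False)
    pd.DataFrame({
        "replica": np.repeat(np.arange(len(ladder)),
                             [len(s) for s in series]),
        "step": np.concatenate([s.steps for s in series]),
        "rmsd_lig": np.concatenate([s.values for s in series]),
    }).to_csv(outdir / "rmsd.csv", index=False)

    assign, sizes = leader_cluster(store.frames[0], reference,
                                   system.receptor_idx, system.ligand_idx,
                                   config["analysis"]["cluster_radius"])
    pd.DataFrame({"cluster": np.arange(len(sizes)), "size": sizes}).to_csv(
        outdir / "clusters.csv", index=False)

    stats = acceptance_statistics(store.exchanges)
    (outdir / "acceptance.json").write_text(json.dumps(
        {"overall": stats["overall"],
         "pairs": {f"{i}-{j}": v for (i, j), v in stats["pairs"].items()}},
        indent=2, sort_keys=True))
    return outdir


def cmd_dock_from_manifest(manifest_path, outdir) -> Path:
    """Re-run a dock exactly as recorded in a manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    return cmd_dock(RunConfig(manifest["config"]), outdir,
                    seed=manifest["seed"])


def cmd_analyze(trajectories, reference_pdb, config: RunConfig,
                outdir) -> pd.DataFrame:
    """Recompute RMSD series and fraction tables from trajectory files."""
    from .system_model import read_xyz_trajectory

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_system = read_pdb(reference_pdb)
    reference = ref_system.coords
    thresholds = config["analysis"]["thresholds"]

    all_series = []
    for path in trajectories:
        frames, _ = read_xyz_trajectory(path)
        if frames and frames[0].shape[0] != ref_system.n_atoms:
            raise ValueError(
                f"{path}: {frames[0].shape[0]} atoms per frame but the "
                f"reference has {ref_system.n_atoms}")
        values = [ligand_rmsd(f, reference, ref_system.receptor_idx,
                              ref_system.ligand_idx) for f in frames]
        all_series.append(RmsdSeries(np.asarray(values)))
    table = _fractions_table(all_series, thresholds)
    table.to_csv(outdir / "fractions.csv", index=False)
    pd.DataFrame({
        "trajectory": np.repeat(np.arange(len(all_series)),
                                [len(s) for s in all_series]),
        "frame": np.concatenate([np.arange(len(s)) for s in all_series]),
        "rmsd_lig": np.concatenate([s.values for s in all_series]),
    }).to_csv(outdir / "rmsd.csv", index=False)
    return table


def _run_cmd_trajectory(system, ff, restraints, groups, n_steps, seed,
                        dt, gamma, temperature, record_every, cutoff,
                        guard_k, **bias_opts):
    """One unbiased (tethered) trajectory: flat window, guard only."""
    from .ambiguity_bias import evaluate_bias

    window = BiasWindow(0.5, cutoff - 0.5, guard_k)

    def bias_fn(coords):
        return evaluate_bias(system, groups, coords, window, cutoff=cutoff,
                             **bias_opts)

    def energy_force_fn(coords):
        return compute_energy_forces(system, ff, restraints, bias_fn, coords)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    v = draw_maxwell_boltzmann(rng, system.masses, temperature)
    state = SimulationState(system.coords.copy(), v, 0, rng, temperature)
    _, frames, records = run_segment(state, energy_force_fn, n_steps,
                                     record_every, dt, gamma, system.masses)
    return frames, records


def cmd_benchmark(config: RunConfig, outdir=None, seeds=None) -> dict:
    """Replica-exchange vs matched-cost conventional MD on the toy system.

    Per seed the REMD arm runs ``n_replicas × n_steps`` total steps; the
    cMD arm runs the same budget as ``n_replicas`` independent unbiased
    trajectories (with only the dissociation tether active) of
    ``n_steps`` each — the parallel-wall-clock comparison.  Success is a
    reference-replica (resp. any-trajectory) ligand RMSD below one bead
    diameter before the budget; the report also carries per-arm
    first-passage steps and near-native fractions.
    """
    if seeds is None:
        seeds = config["benchmark"]["seeds"]
    if len(seeds) < 2:
        raise ValueError("benchmark needs at least 2 seeds")

    system, ff, restraints, reference = build_system(config)
    if ff is None:
        raise ValueError("benchmark requires a toy system")
    surf = config["surface"]
    groups = select_surface_atoms(system, surf["min_area"], surf["probe"],
                                  surf["n_sphere_points"])
    ladder = config.ladder()
    n_rep = len(ladder)
    eng, remd, bias = config["engine"], config["remd"], config["bias"]
    n_steps = remd["n_steps"]
    record_every = remd["record_every"]
    threshold = config["analysis"]["success_threshold"]
    if threshold is None:
        threshold = 2.0 * (config["system"]["sigma"] / 2.0)  # one bead diameter

    bias_opts = dict(cutoff=surf["cutoff"], exponent=bias["exponent"],
                     normalization=bias["normalization"],
                     guard_trigger=bias["guard_trigger"])

    results = {"remd": [], "cmd": []}
    for seed in seeds:
        store = run_hremd(system, ff, restraints, groups, ladder,
                          n_steps=n_steps,
                          exchange_interval=remd["exchange_interval"],
                          seed=seed, dt=eng["dt"], gamma=eng["gamma"],
                          temperature=eng["temperature"],
                          record_every=record_every, **bias_opts)
        series = _rmsd_series(store.frames[0], store.records[0], reference,
                              system)
        fp = first_passage(series, threshold)
        results["remd"].append({
            "seed": seed,
            "first_passage_step": None if fp is None else int(series.steps[fp]),
            "success": fp is not None,
            "frac_lt_thr": near_native_fraction(series, threshold),
        })

        sub = np.random.SeedSequence(seed).spawn(n_rep)
        best_fp, best_series = None, []
        for r in range(n_rep):
            child_seed = int(sub[r].generate_state(1)[0] % (2 ** 31))
            frames, records = _run_cmd_trajectory(
                system, ff, restraints, groups, n_steps, child_seed,
                eng["dt"], eng["gamma"], eng["temperature"], record_every,
                surf["cutoff"], guard_k=bias["k_f"])
            s = _rmsd_series(frames, records, reference, system)
            best_series.append(s)
            fp = first_passage(s, threshold)
            if fp is not None:
                step = int(s.steps[fp])
                if best_fp is None or step < best_fp:
                    best_fp = step
        all_values = np.concatenate([s.values for s in best_series])
        results["cmd"].append({
            "seed": seed,
            "first_passage_step": best_fp,
            "success": best_fp is not None,
            "frac_lt_thr": float(np.mean(all_values < threshold)),
        })

    def median_fp(arm):
        vals = [r["first_passage_step"] if r["first_passage_step"] is not None
                else np.inf for r in results[arm]]
        return float(np.median(vals))

    report = {
        "seeds": list(seeds),
        "threshold": threshold,
        "n_replicas": n_rep,
        "n_steps_per_replica": n_steps,
        "total_steps_per_arm": n_rep * n_steps,
        "remd_successes": sum(r["success"] for r in results["remd"]),
        "cmd_successes": sum(r["success"] for r in results["cmd"]),
        "remd_median_first_passage": median_fp("remd"),
        "cmd_median_first_passage": median_fp("cmd"),
        "per_seed": results,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        def _clean(o):
            if isinstance(o, dict):
                return {k: _clean(v) for k, v in o.items()}
            if isinstance(o, list):
                return [_clean(v) for v in o]
            if isinstance(o, float) and np.isinf(o):
                return "never"
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            return o
        (outdir / "benchmark.json").write_text(
            json.dumps(_clean(report), indent=2, sort_keys=True))
    return report
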