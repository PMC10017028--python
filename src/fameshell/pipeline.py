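"""End-to-end orchestration: simulate -> count -> dewet/rama -> trends.

A single flat config (YAML or dict) drives all stages; every source of
randomness derives from one seed via ``numpy.random.SeedSequence.spawn``,
so a fixed (config, seed) pair reproduces byte-identical numeric outputs.
A JSON manifest records inputs, parameters, per-file SHA-256 checksums and
a planted-vs-recovered summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import Trajectory
from .composition import ConjugateSpec, hydrophilic_fraction, peptide_mass, lipid_mass
from .dewetting import (
    AnnealingSchedule,
    NEVER_DEWETS,
    hydropathy_scores,
    occupancy_matrix,
    percent_dehydrated_curve,
    assemble_dewetting_map,
    residue_dewetting_temperature,
    validate_schedule,
)
from .dihedrals import backbone_dihedrals, region_occupancy
from .proximity import (
    ShellParams,
    count_chain_waters,
    count_intrachain_contacts,
    series_statistics,
)
from .structure_io import write_profile_table, write_trajectory
from .synth import (
    HydrationModel,
    ScanModel,
    build_fame_topology,
    simulate_annealing_series,
    simulate_dihedral_ensemble,
    simulate_temperature_scan,
)
from .trends import fit_linear_trend, normalize_series

log = logging.getLogger("fameshell")

ALL_STAGES = ("simulate", "hydration", "contacts", "dewet", "rama",
              "trends", "composition")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "fameshell_run",
    "stages": list(ALL_STAGES),
    "construct": {"n_pentads": 4, "include_lipid": True},
    "shell": {},
    "analysis": {"theta": 0.5, "window": 1.0, "min_baseline": 1.0,
                 "rama_window": 0.25},
    "simulate": {
        "annealing": {"tdw_start": 250.0, "tdw_stop": 400.0, "tdw_step": 25.0,
                      "n_frames": 20, "write_files": False},
        "hydration_model": {"baseline_low": 4.0, "baseline_high": 10.0,
                            "t50_low": 280.0, "t50_high": 380.0, "width": 5.0},
        "scan": {"temps": [250.0, 260.0, 275.0, 295.0, 310.0, 335.0],
                 "n_frames": 20,
                 "model": {"nw_intercept": 220.0, "nw_slope": -0.4,
                           "npp_intercept": -2.5, "npp_slope": 0.05,
                           "noise_sd": 1.0}},
        "dihedrals": {"kappa": 8.0, "n_frames": 200, "ls_region": "alpha_R"},
    },
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    unknown = set(cfg.get("stages", [])) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    stages = set(cfg.get("stages", []))
    needs_sim = {"hydration", "contacts", "dewet", "rama"} & stages
    if needs_sim and "simulate" not in stages:
        raise ConfigError(
            f"stage(s) {sorted(needs_sim)} require the 'simulate' stage"
        )
    if "trends" in stages and not {"hydration", "contacts"} <= stages:
        raise ConfigError("'trends' requires 'hydration' and 'contacts'")
    if cfg["construct"]["n_pentads"] < 0:
        raise ConfigError("n_pentads must be >= 0")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute the scheduled stages; returns the manifest/report dict."""
    _validate_config(config)
    outdir = Path(outdir or config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    children = np.random.SeedSequence(seed).spawn(4)
    seeds = {name: int(c.generate_state(1)[0] % (2**31))
             for name, c in zip(("topology", "annealing", "scan", "dihedral"), children)}
    stages = list(config["stages"])
    params = ShellParams(**config.get("shell", {}))
    ana = config["analysis"]
    report: dict = {"version": __version__, "seed": seed, "stages": stages,
                    "parameters": {"shell": config.get("shell", {}), "analysis": ana},
                    "outputs": {}, "recovery": {}}

    ccfg = config["construct"]
    sequence_ls = ccfg.get("ls_sequence")
    topo_kwargs = dict(n_pentads=int(ccfg["n_pentads"]),
                       include_lipid=bool(ccfg["include_lipid"]),
                       seed=seeds["topology"])
    if sequence_ls:
        topo_kwargs["ls_sequence"] = sequence_ls
    system = build_fame_topology(**topo_kwargs)
    n_pep = system.peptide_length
    log.info("construct: %d peptide residues (lipid: %s)",
             n_pep, ccfg["include_lipid"])

    artifacts: dict = {}

    if "simulate" in stages:
        sim = config["simulate"]
        hm = sim["hydration_model"]
        rng = np.random.default_rng(seeds["topology"])
        model = HydrationModel(
            baseline_counts=rng.uniform(hm["baseline_low"], hm["baseline_high"], n_pep),
            midpoints=rng.uniform(hm["t50_low"], hm["t50_high"], n_pep),
            width=float(hm["width"]),
        )
        ann = sim["annealing"]
        grid = np.arange(ann["tdw_start"], ann["tdw_stop"] + 1e-9, ann["tdw_step"])
        log.info("simulate: annealing series over %d T_dw points", len(grid))
        series = simulate_annealing_series(
            system, model, grid, int(ann["n_frames"]), seed=seeds["annealing"]
        )
        scfg = sim["scan"]
        scan_model = ScanModel(**scfg["model"])
        log.info("simulate: temperature scan at %s K", scfg["temps"])
        scan = simulate_temperature_scan(
            system, scan_model, np.asarray(scfg["temps"], float),
            int(scfg["n_frames"]), seed=seeds["scan"],
        )
        dcfg = sim["dihedrals"]
        ls_len = len(ccfg.get("ls_sequence") or "GLYASKLFSNLGHHHHHHHH")
        class_map = [dcfg["ls_region"]] * max(ls_len, 3)
        ensemble = simulate_dihedral_ensemble(
            class_map, float(dcfg["kappa"]), int(dcfg["n_frames"]),
            seed=seeds["dihedral"],
        )
        artifacts.update(model=model, series=series, scan=scan,
                         scan_model=scan_model, ensemble=ensemble)
        if ann.get("write_files"):
            simdir = outdir / "simulate"
            simdir.mkdir(exist_ok=True)
            for T, traj in series:
                write_trajectory(traj, simdir / f"T{int(round(T))}.pdb")

    if "hydration" in stages or "contacts" in stages:
        rows_w, rows_c = [], []
        for T, traj in artifacts["scan"]:
            if "hydration" in stages:
                m, sd, n = series_statistics(
                    traj, lambda fr: count_chain_waters(fr, traj.system, params)
                )
                rows_w.append({"temperature": T, "nw_mean": m, "nw_sd": sd,
                               "n_frames": n})
            if "contacts" in stages:
                m, sd, n = series_statistics(
                    traj, lambda fr: count_intrachain_contacts(fr, traj.system, params)
                )
                rows_c.append({"temperature": T, "npp_mean": m, "npp_sd": sd,
                               "n_frames": n})
        if rows_w:
            write_profile_table(rows_w, outdir / "nw_series.tsv")
            artifacts["nw_rows"] = rows_w
        if rows_c:
            write_profile_table(rows_c, outdir / "npp_series.tsv")
            artifacts["npp_rows"] = rows_c

    if "dewet" in stages:
        matrix = occupancy_matrix(
            artifacts["series"], params=params,
            window=float(ana["window"]), min_baseline=float(ana["min_baseline"]),
        )
        theta = float(ana["theta"])
        tdws = {}
        for res, flagged in zip(matrix.residue_indices, matrix.baseline_flags):
            if not flagged:
                tdws[int(res)] = residue_dewetting_temperature(matrix, int(res), theta)
        curve = percent_dehydrated_curve(matrix, theta)
        dmap = assemble_dewetting_map([(250.0, curve)], matrix.tdw_grid)
        scores = hydropathy_scores(tdws) if len(tdws) >= 2 else {}
        occ_rows = [
            {"residue_index": int(r), **{f"T{int(t)}": v for t, v in
                                         zip(matrix.tdw_grid, matrix.normalized[k])}}
            for k, r in enumerate(matrix.residue_indices)
        ]
        write_profile_table(occ_rows, outdir / "occupancy.tsv")
        tdw_rows = [
            {"residue_index": r,
             "dewetting_temperature": (t if t != NEVER_DEWETS else "never"),
             "hydropathy_score": scores.get(r, 1.0)}
            for r, t in sorted(tdws.items())
        ]
        write_profile_table(tdw_rows, outdir / "dewetting_temperatures.tsv",
                            columns=["residue_index", "dewetting_temperature",
                                     "hydropathy_score"])
        map_rows = [
            {"tmd": tmd, **{f"T{int(t)}": v for t, v in
                            zip(dmap.tdw_grid, dmap.percent_dehydrated[i])}}
            for i, tmd in enumerate(dmap.tmd_grid)
        ]
        write_profile_table(map_rows, outdir / "dewetting_map.tsv")
        # planted-vs-recovered midpoints
        model = artifacts["model"]
        errs = []
        for k, res in enumerate(matrix.residue_indices):
            t = tdws.get(int(res))
            if t is not None and t != NEVER_DEWETS:
                planted = model.midpoints[k]
                if matrix.tdw_grid[0] < planted < matrix.tdw_grid[-1]:
                    errs.append(abs(t - planted))
        report["recovery"]["t50_mean_abs_error_K"] = (
            float(np.mean(errs)) if errs else None
        )
        report["recovery"]["t50_n_recovered"] = len(errs)

    if "rama" in stages:
        series_d = backbone_dihedrals(artifacts["ensemble"])
        occ = region_occupancy(series_d, window=float(ana["rama_window"]))
        occ_rows = [
            {"residue_index": int(r), **{c: float(occ.loc[r, c]) for c in occ.columns}}
            for r in occ.index
        ]
        write_profile_table(occ_rows, outdir / "rama_occupancy.tsv")
        ls_region = config["simulate"]["dihedrals"]["ls_region"]
        report["recovery"]["rama_mean_target_fraction"] = float(
            occ[ls_region].mean()
        )

    if "trends" in stages:
        fits = {}
        for key, rows, ycol in (("nw", artifacts["nw_rows"], "nw_mean"),
                                ("npp", artifacts["npp_rows"], "npp_mean")):
            x = [r["temperature"] for r in rows]
            y = normalize_series([r[ycol] for r in rows], n_pep)
            fit = fit_linear_trend(x, y)
            fits[key] = fit
            report["recovery"][f"{key}_fitted_slope_per_residue_per_K"] = fit.slope
            report["recovery"][f"{key}_slope_ci90"] = list(fit.slope_ci90)
        sm_model = artifacts["scan_model"]
        report["recovery"]["nw_planted_slope_per_residue_per_K"] = (
            sm_model.nw_slope / n_pep
        )
        report["recovery"]["npp_planted_slope_per_residue_per_K"] = (
            sm_model.npp_slope / n_pep
        )
        with open(outdir / "trend_fits.json", "w") as fh:
            json.dump(
                {k: {"slope": f.slope, "intercept": f.intercept,
                     "slope_ci90": list(f.slope_ci90), "r_squared": f.r_squared,
                     "n_points": f.n_points} for k, f in fits.items()},
                fh, indent=2, sort_keys=True,
            )

    if "composition" in stages:
        ls = ccfg.get("ls_sequence") or _default_ls_one_letter()
        seq = ls + "GVGVP" * int(ccfg["n_pentads"])
        spec = ConjugateSpec(sequence=seq)
        schedule = AnnealingSchedule()
        comp = {
            "sequence_length": len(seq),
            "peptide_mass_Da": peptide_mass(seq),
            "lipid_mass_Da": lipid_mass(spec.lipid_formula),
            "hydrophilic_fraction": hydrophilic_fraction(spec),
            "annealing_schedule_consistent": validate_schedule(schedule),
        }
        with open(outdir / "composition.json", "w") as fh:
            json.dump(comp, fh, indent=2, sort_keys=True)
        report["recovery"]["hydrophilic_fraction"] = comp["hydrophilic_fraction"]

    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            report["outputs"][str(p.relative_to(outdir))] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _default_ls_one_letter() -> str:
    from .synth import DEFAULT_LS_SEQUENCE

    return DEFAULT_LS_SEQUENCE
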