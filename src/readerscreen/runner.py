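"""Stage execution: one validated RunConfig in, one RunReport out."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import __version__, pipelines, simulate as sim
from .config import RunConfig, RunReport, config_hash
from .equilibrium import EquilibriumSpec
from .fp import PolarizationReferences
from .ftsa import ThermoParams, vant_hoff_enthalpy, fit_melt_curve
from .io import (cetsa_to_table, melt_curves_to_table, read_cetsa_table,
                 read_fp_plate_table, read_melt_table, read_plate_table,
                 read_sensorgram_table, sensorgrams_to_table, write_table)


def _refs(config: RunConfig) -> PolarizationReferences:
    return PolarizationReferences(p_dstar=config.p_dstar,
                                  p_dstar_r=config.p_dstar_r,
                                  g_factor=config.g_factor)


def _need(config: RunConfig, key: str) -> str:
    if key not in config.inputs:
        raise ValueError(f"stage {config.assay!r} requires inputs[{key!r}]")
    return config.inputs[key]


def run_screen(config: RunConfig) -> RunReport:
    """Execute the configured stage chain and assemble the run report."""
    stages: dict = {}
    qc: dict = {}
    constants: dict = {}

    if config.assay == "qc":
        plate = read_plate_table(_need(config, "plate"))
        qc = pipelines.plate_qc(plate, z_threshold=config.z_threshold)

    elif config.assay == "alpha-ic50":
        plate = read_plate_table(_need(config, "plate"))
        res = pipelines.analyze_alpha_ic50(plate)
        stages["alpha_ic50"] = res
        qc = res["qc"]
        fit = res["fit"]
        constants = {"ic50_M": fit.ic50, "ic50_stderr_M": fit.ic50_stderr,
                     "hill": fit.hill, "converged": fit.converged,
                     "extrapolated": fit.extrapolated}

    elif config.assay == "fp-ic50":
        plate = read_fp_plate_table(_need(config, "plate"))
        res = pipelines.analyze_fp_ic50(plate, config.g_factor)
        stages["fp_ic50"] = res
        qc = {"z_prime": res["z_prime"], "z_threshold": config.z_threshold,
              "qc_pass": bool(res["z_prime"] > config.z_threshold)}
        fit = res["fit"]
        constants = {"ic50_M": fit.ic50, "ic50_stderr_M": fit.ic50_stderr,
                     "hill": fit.hill, "converged": fit.converged}

    elif config.assay == "fp-kd":
        plate = read_fp_plate_table(_need(config, "plate"))
        if config.probe_total is None:
            raise ValueError("fp-kd requires probe_total")
        res = pipelines.analyze_fp_titration(
            plate, _refs(config), config.probe_total,
            depletion_corrected=config.depletion_corrected)
        stages["fp_kd"] = {"fit": res["fit"]}
        fit = res["fit"]
        constants = {"kd_M": fit.kd, "kd_stderr_M": fit.kd_stderr,
                     "bmax_mP": fit.bmax, "reliable": fit.reliable}

    elif config.assay == "ftsa":
        curves = read_melt_table(_need(config, "melt"))
        thermo = None
        if config.ftsa_thermo is not None:
            opt = config.ftsa_thermo
            ref = next((c for c in curves if c.ligand_total == 0), None)
            dh_u = opt.dh_u
            t_r = None
            if ref is not None:
                ref_fit = fit_melt_curve(ref)
                if ref_fit.has_transition:
                    t_r = ref_fit.tm
                    if dh_u is None:
                        dh_u = vant_hoff_enthalpy(ref_fit.tm, ref_fit.steepness)
            if t_r is not None and dh_u is not None:
                thermo = ThermoParams(t_r=t_r, dh_u=dh_u,
                                      protein_total=opt.protein_total,
                                      dcp_u=opt.dcp_u, dh_b=opt.dh_b,
                                      dcp_b=opt.dcp_b, t0=opt.t0)
        res = pipelines.analyze_ftsa(curves, thermo=thermo)
        stages["ftsa"] = res
        constants = {"reference_tm_C": res["reference_tm_C"]}
        if "kd_fit" in res:
            constants.update({"kd_M": res["kd_fit"]["kd"],
                              "kd_reported_at_C": res["kd_fit"]["t0"],
                              "non_binder": res["kd_fit"]["non_binder"]})

    elif config.assay == "bli-kinetics":
        sgs = read_sensorgram_table(_need(config, "sensorgrams"))
        ref_id = config.inputs.get("reference_run", "reference")
        reference = next((s for s in sgs if s.run_id == ref_id), None)
        samples = [s for s in sgs if s.run_id != ref_id]
        res = pipelines.analyze_bli_kinetics(samples, reference)
        stages["bli_kinetics"] = res
        fit = res["fit"]
        qc = {"low_decay_curves": list(fit.low_decay_curves)}
        constants = {"ka_per_M_s": fit.ka, "kd_rate_per_s": fit.kd_rate,
                     "kd_eq_M": fit.kd_eq, "rmax_nm": fit.rmax}

    elif config.assay == "bli-displacement":
        sgs = read_sensorgram_table(_need(config, "sensorgrams"))
        ctrl_id = config.inputs.get("control_run", "control")
        ref_id = config.inputs.get("reference_run", "reference")
        control = next((s for s in sgs if s.run_id == ctrl_id), None)
        if control is None:
            raise ValueError(f"no control run {ctrl_id!r} in sensorgram table")
        reference = next((s for s in sgs if s.run_id == ref_id), None)
        samples = [s for s in sgs if s.run_id not in (ctrl_id, ref_id)]
        res = pipelines.analyze_bli_displacement(
            samples, control, reference, offset_s=config.report_point_offset_s)
        stages["bli_displacement"] = res

    elif config.assay == "cetsa":
        series = read_cetsa_table(_need(config, "table"))
        res = pipelines.analyze_cetsa(series, mode=config.normalization_mode,
                                      control_condition=config.control_condition)
        stages["cetsa"] = res
        constants = {f"delta_tagg_C[{cond}]": c["delta_tagg_C"]
                     for cond, c in res["conditions"].items()}

    elif config.assay == "simulate":
        stages["simulate"] = _run_simulation(config)

    report = RunReport(
        assay=config.assay, stages=stages, qc=qc, constants=constants,
        provenance={"config_hash": config_hash(config), "seed": config.seed,
                    "version": __version__},
    )
    report.write(config.out_dir)
    return report


def _run_simulation(config: RunConfig) -> dict:
    """Dispatch a `simulate` stage; writes canonical tables plus SimTruth."""
    kind = config.sim_kind
    p = dict(config.sim_params)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    if kind == "alpha":
        spec = EquilibriumSpec(p.get("receptor_total", 15e-9),
                               p.get("probe_total", 30e-9),
                               p.get("kd_probe", 100e-9),
                               kd_competitor=p.get("kd_competitor", 250e-9))
        grid = p.get("competitor_grid",
                     list(np.geomspace(1e-9, 1e-5, 12)))
        plate, truth = sim.simulate_displacement_plate(
            "alpha", spec, grid, seed=seed)
        write_table(plate, out / "alpha_plate.csv")
        files = ["alpha_plate.csv"]
    elif kind == "fp":
        refs = PolarizationReferences(config.p_dstar, config.p_dstar_r,
                                      config.g_factor)
        spec = EquilibriumSpec(p.get("receptor_total", 100e-9),
                               p.get("probe_total", 10e-9),
                               p.get("kd_probe", 31e-9),
                               kd_competitor=p.get("kd_competitor", 250e-9))
        grid = p.get("competitor_grid", list(np.geomspace(1e-9, 1e-5, 12)))
        plate, truth = sim.simulate_displacement_plate(
            "fp", spec, grid, seed=seed, refs=refs)
        write_table(plate, out / "fp_plate.csv")
        files = ["fp_plate.csv"]
    elif kind == "ftsa":
        thermo = ThermoParams(t_r=p.get("t_r", 54.0), dh_u=p.get("dh_u", 400.0),
                              protein_total=p.get("protein_total", 3.88e-6),
                              kb_t0=p.get("kb_t0", 1.0 / 380e-9))
        doses = p.get("ligand_doses", [0.0, 1e-6, 4e-6, 1.6e-5, 6.4e-5])
        curves, truth = sim.simulate_ftsa(thermo, doses, seed=seed)
        write_table(melt_curves_to_table(curves), out / "melt.csv")
        files = ["melt.csv"]
    elif kind == "bli":
        sgs, ref, truth = sim.simulate_bli(
            p.get("ka", 9.43e4), p.get("kd_rate", 1.35e-3),
            p.get("rmax", 1.0),
            p.get("concentrations", [12.5e-9, 25e-9, 50e-9, 100e-9,
                                     200e-9, 400e-9]),
            seed=seed)
        write_table(sensorgrams_to_table(list(sgs) + [ref]),
                    out / "sensorgrams.csv")
        files = ["sensorgrams.csv"]
    elif kind == "cetsa":
        control, treated, truth = sim.simulate_cetsa(
            p.get("t_agg_control", 54.4), p.get("delta", 5.9), seed=seed)
        write_table(cetsa_to_table([control, treated]), out / "cetsa.csv")
        files = ["cetsa.csv"]
    else:
        raise ValueError(f"unknown sim_kind {kind!r}")

    (out / "simtruth.json").write_text(truth.to_json())
    return {"kind": kind, "files": files + ["simtruth.json"],
            "seed": seed}
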