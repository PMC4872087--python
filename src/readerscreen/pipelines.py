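"""Analysis pipelines tying tables to fits.

Each function takes the canonical in-memory objects (DataFrames, curve
lists), applies the module operations in the documented order, and returns a
plain-dict stage report.  Blank correction happens exactly once, at
ingestion into a pipeline.  The reporting layer never recomputes anything.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bli as bli_mod
from . import cetsa as cetsa_mod
from . import ftsa as ftsa_mod
from .core_quant import (ControlSet, DoseResponseSeries, fit_4pl,
                         percent_inhibition, signal_to_background, z_prime)
from .fp import (FPRead, PolarizationReferences, background_correct,
                 fit_probe_kd, mp_from_intensities, specific_polarization)


def controls_from_plate(plate: pd.DataFrame, signal_col: str = "signal") -> ControlSet:
    """Plate controls with the mean blank subtracted from both arms."""
    blanks = plate.loc[plate["role"] == "blank", signal_col]
    blank = float(blanks.mean()) if len(blanks) else 0.0
    pos = plate.loc[plate["role"] == "positive", signal_col] - blank
    neg = plate.loc[plate["role"] == "negative", signal_col] - blank
    if pos.empty or neg.empty:
        missing = [r for r in ("positive", "negative")
                   if plate.loc[plate["role"] == r].empty]
        raise ValueError(f"plate is missing control roles: {missing}")
    return ControlSet(pos.tolist(), neg.tolist(),
                      blank_values=blanks.tolist())


def plate_qc(plate: pd.DataFrame, signal_col: str = "signal",
             z_threshold: float = 0.5) -> dict:
    """Z'-factor and signal/background with the standard Z' > 0.5 gate."""
    controls = controls_from_plate(plate, signal_col)
    z = z_prime(controls)
    try:
        sb = signal_to_background(controls)
    except ValueError:
        sb = np.nan
    return {"z_prime": z, "signal_to_background": sb,
            "z_threshold": z_threshold, "qc_pass": bool(z > z_threshold)}


def analyze_alpha_ic50(plate: pd.DataFrame) -> dict:
    """Alpha displacement plate -> percent inhibition -> 4PL IC50."""
    if plate.empty:
        raise ValueError("empty plate table")
    blank = float(plate.loc[plate["role"] == "blank", "signal"].mean())
    if np.isnan(blank):
        blank = 0.0
    controls = controls_from_plate(plate)
    samples = plate.loc[plate["role"] == "sample"].copy()
    samples["corrected"] = samples["signal"] - blank
    samples["inhibition"] = samples["corrected"].map(
        lambda a: percent_inhibition(a, controls))
    grouped = samples.groupby("conc_M")["inhibition"].apply(tuple).sort_index()
    series = DoseResponseSeries(grouped.index.to_numpy(), grouped.tolist(),
                                response_kind="percent_inhibition")
    fit = fit_4pl(series)
    return {"qc": plate_qc(plate), "fit": fit,
            "inhibition_by_dose": {float(c): list(v)
                                   for c, v in grouped.items()}}


def _fp_plate_mp(plate: pd.DataFrame, g: float) -> pd.DataFrame:
    """Per-well mP after blank intensity correction."""
    blanks = plate.loc[plate["role"] == "blank"]
    b_s = float(blanks["i_s"].mean()) if len(blanks) else 0.0
    b_p = float(blanks["i_p"].mean()) if len(blanks) else 0.0
    out = plate.loc[plate["role"] != "blank"].copy()
    out["mp"] = [
        mp_from_intensities(FPRead(r.i_s - b_s, r.i_p - b_p), g)
        for r in out.itertuples()
    ]
    return out


def analyze_fp_ic50(plate: pd.DataFrame, g_factor: float) -> dict:
    """FP displacement plate -> mP -> percent inhibition -> 4PL IC50.

    Positive controls are probe+receptor wells, negative controls probe-only
    wells; inhibition follows the same normalisation as the Alpha assay.
    """
    if plate.empty:
        raise ValueError("empty plate table")
    wells = _fp_plate_mp(plate, g_factor)
    pos = wells.loc[wells["role"] == "positive", "mp"]
    neg = wells.loc[wells["role"] == "negative", "mp"]
    if pos.empty or neg.empty:
        missing = [r for r in ("positive", "negative")
                   if wells.loc[wells["role"] == r].empty]
        raise ValueError(f"plate is missing control roles: {missing}")
    controls = ControlSet(pos.tolist(), neg.tolist())
    samples = wells.loc[wells["role"] == "sample"].copy()
    samples["inhibition"] = samples["mp"].map(
        lambda p: percent_inhibition(p, controls))
    grouped = samples.groupby("conc_M")["inhibition"].apply(tuple).sort_index()
    series = DoseResponseSeries(grouped.index.to_numpy(), grouped.tolist(),
                                response_kind="percent_inhibition")
    fit = fit_4pl(series)
    z = z_prime(controls)
    return {"fit": fit, "z_prime": z,
            "controls_mp": {"positive": controls.mu_max,
                            "negative": controls.mu_min}}


def analyze_fp_titration(plate: pd.DataFrame, refs: PolarizationReferences,
                         probe_total: float,
                         depletion_corrected: bool = False) -> dict:
    """FP probe titration -> correction chain -> probe K_D.

    Per receptor dose: mean sample and saturated-competitor intensities are
    background-corrected channel-wise with the matching protein-only wells,
    converted to mP (P_M, P_I), run through the specific-binding chain and
    fitted with the one-site hyperbola (free-probe baseline subtracted).
    """
    g = refs.g_factor
    points = []
    sample = plate.loc[plate["role"] == "sample"]
    for conc, grp in sample.groupby("conc_M"):
        bg = plate.loc[(plate["role"] == "protein_only")
                       & (plate["conc_M"] == conc)]
        sat = plate.loc[(plate["role"] == "saturated_competitor")
                        & (plate["conc_M"] == conc)]
        bg_read = FPRead(float(bg["i_s"].mean()) if len(bg) else 0.0,
                         float(bg["i_p"].mean()) if len(bg) else 0.0)
        m_read = background_correct(
            FPRead(float(grp["i_s"].mean()), float(grp["i_p"].mean())), bg_read)
        p_m = mp_from_intensities(m_read, g)
        if len(sat):
            i_read = background_correct(
                FPRead(float(sat["i_s"].mean()), float(sat["i_p"].mean())), bg_read)
            p_i = mp_from_intensities(i_read, g)
        else:
            p_i = refs.p_dstar  # no nonspecific wells: assume none
        points.append(specific_polarization(p_m, p_i, float(conc), refs))
    points.sort(key=lambda p: p.receptor_total)
    fit = fit_probe_kd(points, refs=refs, probe_total=probe_total,
                       depletion_corrected=depletion_corrected)
    return {"fit": fit, "points": points}


def analyze_ftsa(curves, thermo: ftsa_mod.ThermoParams | None = None) -> dict:
    """Melt-curve set -> per-curve T_m, delta T_m vs zero-dose, optional K_D.

    The reference is the zero-dose curve with a valid transition; dye-only
    negative controls come back flagged no-transition.  If ``thermo`` is
    given (all parameters but the binding constant), the dosing K_D is
    fitted from the (dose, T_m) series.
    """
    fits = [ftsa_mod.fit_melt_curve(c) for c in curves]
    ref = next((f for c, f in zip(curves, fits)
                if c.ligand_total == 0 and f.has_transition), None)
    rows = []
    for c, f in zip(curves, fits):
        rows.append({
            "label": c.label, "ligand_conc_M": c.ligand_total,
            "tm_C": f.tm if f.has_transition else np.nan,
            "has_transition": f.has_transition,
            "delta_tm_C": (ftsa_mod.delta_tm(f, ref)
                           if f.has_transition and ref is not None else np.nan),
        })
    result = {"curves": rows, "reference_tm_C": ref.tm if ref else np.nan}
    if thermo is not None and ref is not None:
        dosed = [(c.ligand_total, f.tm) for c, f in zip(curves, fits)
                 if f.has_transition]
        doses = [d for d, _ in dosed]
        if len(dosed) >= 4 and 0.0 in doses:
            series = ftsa_mod.TmDoseSeries(doses, [t for _, t in dosed])
            result["kd_fit"] = ftsa_mod.fit_kd_from_dosing(series, thermo)
    return result


def analyze_bli_kinetics(sensorgrams, reference=None,
                         min_decay: float = 0.05) -> dict:
    """Reference-subtract, re-zero, globally fit 1:1 kinetics."""
    prepared = []
    for sg in sensorgrams:
        if reference is not None:
            sg = bli_mod.reference_subtract(sg, reference)
        prepared.append(bli_mod.rezero_association(sg))
    fit = bli_mod.global_fit_1to1(prepared, min_decay=min_decay)
    return {"fit": fit, "ka": fit.ka, "kd_rate": fit.kd_rate,
            "kd_eq_M": fit.kd_eq, "rmax_nm": fit.rmax,
            "low_decay_curves": list(fit.low_decay_curves)}


def analyze_bli_displacement(samples, control, reference=None,
                             offset_s: float = 5.0) -> dict:
    """Report-point displacement percent per competitor-containing run."""
    rp = bli_mod.ReportPoint(time_offset=offset_s)

    def prep(sg):
        if reference is not None:
            sg = bli_mod.reference_subtract(sg, reference)
        return bli_mod.rezero_association(sg)

    ctrl = prep(control)
    rows = [{"run_id": sg.run_id,
             "displacement_pct": bli_mod.report_point_displacement(
                 prep(sg), ctrl, rp)}
            for sg in samples]
    return {"report_point_offset_s": offset_s, "displacement": rows}


def analyze_cetsa(series_list, mode: str = "min_max",
                  control_condition: str = "control") -> dict:
    """Normalise per membrane, fit T_agg per membrane, average per condition.

    Replicate membranes are fitted independently and their T_agg values
    averaged; shifts are reported against the control condition.
    """
    fits = {}
    for s in series_list:
        norm = cetsa_mod.normalize_cetsa(s, mode=mode)
        fits.setdefault(s.condition_label, []).append(cetsa_mod.fit_tagg(norm))
    conditions = {}
    for cond, flist in fits.items():
        tags = [f.t_agg for f in flist if f.has_transition]
        conditions[cond] = {
            "t_agg_C": float(np.mean(tags)) if tags else np.nan,
            "t_agg_sd_C": float(np.std(tags, ddof=1)) if len(tags) > 1 else np.nan,
            "n_membranes": len(flist),
            "n_transitions": len(tags),
        }
    ctrl = conditions.get(control_condition, {}).get("t_agg_C", np.nan)
    for cond, c in conditions.items():
        c["delta_tagg_C"] = (c["t_agg_C"] - ctrl
                             if cond != control_condition else 0.0)
    return {"normalization_mode": mode, "conditions": conditions,
            "control_condition": control_condition}
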