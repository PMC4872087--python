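"""Seeded generative models for every assay readout of the platform.

Each simulator emits the canonical table/object consumed by the matching
analysis module plus a :class:`SimTruth` record of the generating parameters,
so the whole pipeline is testable end-to-end with no external data.  All
randomness flows through ``numpy.random.default_rng(seed)``: the same seed
regenerates every output bit-identically.

Default noise levels (all configurable): Alpha 5% CV log-normal, FP 1 mP
additive, FTSA 2% multiplicative, BLI 0.01 nm additive, CETSA 5% CV
log-normal - chosen to match the replicate scatter typical of each readout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .bli import PHASES, Sensorgram
from .cetsa import CetsaSeries, _boltzmann_decreasing
from .core_quant import TitrationMatrix
from .equilibrium import (EquilibriumSpec, displacement_curve, solve_1to1,
                          solve_competitive)
from .fp import PolarizationReferences, intensities_from_mp
from .ftsa import MeltCurve, ThermoParams, unfolded_fraction


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth record serialised alongside every simulated dataset.

    ``kind`` names the simulator, ``seed`` plus ``params`` regenerate the
    output bit-identically.
    """

    kind: str
    seed: int
    params: dict
    schema_version: int = 1

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


@dataclass(frozen=True)
class AlphaBeadModel:
    """Bead-capacity signal model for the Alpha proximity assay.

    Signal is proportional to the ternary donor-complex-acceptor bridge, with
    an independent capacity-saturation (dilution) factor per bead species:
    once an analyte's total concentration exceeds the corresponding bead
    capacity, the surplus competes unproductively and the signal hooks over.
    """

    donor_capacity: float = 50e-9     # max biotin-peptide captured [M]
    acceptor_capacity: float = 1e-6   # max His-protein captured [M]
    signal_gain: float = 1e11         # counts per molar complex
    background: float = 50.0          # counts
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.donor_capacity <= 0 or self.acceptor_capacity <= 0:
            raise ValueError("bead capacities must be positive")


def stream_seeds(seed: int, n: int) -> list:
    """Fan one global seed out to ``n`` independent per-assay stream seeds."""
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_alpha_matrix(model: AlphaBeadModel, protein_concentrations,
                          peptide_concentrations, kd: float,
                          seed: int = 0) -> tuple:
    """Cross-titration matrix of receptor (rows) against biotin-peptide (cols).

    Per cell: complex concentration from the 1:1 equilibrium, attenuated by
    ``min(1, capacity/total)`` per bead species, scaled by the gain, plus
    background, with multiplicative log-normal noise.  Reproduces a hook on
    the peptide axis when the peptide total exceeds the donor capacity.
    """
    rng = np.random.default_rng(seed)
    rows = np.asarray(protein_concentrations, dtype=float)
    cols = np.asarray(peptide_concentrations, dtype=float)
    signal = np.empty((rows.size, cols.size))
    for i, r in enumerate(rows):
        for j, p in enumerate(cols):
            complex_c = solve_1to1(EquilibriumSpec(r, p, kd)).receptor_probe
            cap = (min(1.0, model.donor_capacity / p) if p > 0 else 1.0) * \
                  (min(1.0, model.acceptor_capacity / r) if r > 0 else 1.0)
            signal[i, j] = model.signal_gain * complex_c * cap + model.background
    signal *= _lognormal_factors(rng, model.noise_cv, signal.shape)
    truth = SimTruth("alpha_matrix", seed, {
        "kd": kd, "model": asdict(model),
        "protein_concentrations": rows.tolist(),
        "peptide_concentrations": cols.tolist()})
    return TitrationMatrix(rows, cols, signal), truth


def _well_names(n: int):
    return [f"{chr(ord('A') + i // 24)}{i % 24 + 1}" for i in range(n)]


def simulate_displacement_plate(assay: str, spec: EquilibriumSpec,
                                competitor_grid, noise: float | None = None,
                                seed: int = 0, n_replicates: int = 3,
                                n_controls: int = 6,
                                refs: PolarizationReferences | None = None,
                                gain: float = 1e13, background: float = 50.0,
                                nonspecific: float = 25.0,
                                compound_id: str = "CMPD") -> tuple:
    """Long-format displacement plate for the Alpha or FP assay.

    ``spec`` carries the assay conditions (receptor/probe totals, both K_Ds);
    the bound-probe fraction at each competitor dose comes from the
    competitive-equilibrium solver.  Sample wells are laid out in
    ``n_replicates`` replicates per dose with ``n_controls``-well positive
    (probe+receptor, no competitor), negative (probe only) and blank blocks.

    Alpha: signal = gain*[complex] + nonspecific + background with log-normal
    noise (default CV 5%); ``nonspecific`` is the small bead-proximity floor
    present in every probe-containing well, which sets the assay's
    signal/background ratio.  FP: well mP = P_D* + F_B*(P_D*R - P_D*) with additive
    noise (default 1 mP), rendered to (i_s, i_p) intensities through the
    G-factor; ``refs`` is required.
    """
    if assay not in ("alpha", "fp"):
        raise ValueError("assay must be 'alpha' or 'fp'")
    if assay == "fp" and refs is None:
        raise ValueError("fp plates require polarization references")
    rng = np.random.default_rng(seed)
    grid = np.asarray(competitor_grid, dtype=float)
    bound = displacement_curve(spec, grid)
    bound0 = solve_1to1(EquilibriumSpec(
        spec.receptor_total, spec.probe_total, spec.kd_probe)).bound_probe_fraction

    rows = []

    def emit(role, conc, frac):
        if assay == "alpha":
            cv = 0.05 if noise is None else noise
            complex_c = frac * spec.probe_total
            base = (gain * complex_c + nonspecific + background
                    if role != "blank" else background)
            sig = base * _lognormal_factors(rng, cv, ())
            rows.append({"role": role, "compound_id": compound_id if role == "sample" else "",
                         "conc_M": conc, "signal": float(sig)})
        else:
            sd = 1.0 if noise is None else noise
            if role == "blank":
                read = intensities_from_mp(0.0, refs.g_factor, i_p=1.0)
            else:
                mp = refs.p_dstar + frac * (refs.p_dstar_r - refs.p_dstar)
                mp += rng.normal(0.0, sd) if sd > 0 else 0.0
                read = intensities_from_mp(mp, refs.g_factor, i_p=1000.0)
            rows.append({"role": role, "compound_id": compound_id if role == "sample" else "",
                         "conc_M": conc, "i_s": read.i_s, "i_p": read.i_p})

    for conc, frac in zip(grid, bound):
        for _ in range(n_replicates):
            emit("sample", float(conc), frac)
    for _ in range(n_controls):
        emit("positive", 0.0, bound0)
    for _ in range(n_controls):
        emit("negative", 0.0, 0.0)
    for _ in range(n_controls):
        emit("blank", 0.0, 0.0)

    plate = pd.DataFrame(rows)
    names = _well_names(len(plate))
    plate.insert(0, "well", names)
    plate.insert(1, "row", [w[0] for w in names])
    plate.insert(2, "col", [int(w[1:]) for w in names])
    truth = SimTruth(f"{assay}_displacement_plate", seed, {
        "receptor_total": spec.receptor_total, "probe_total": spec.probe_total,
        "kd_probe": spec.kd_probe, "kd_competitor": spec.kd_competitor,
        "competitor_grid": grid.tolist(), "noise": noise,
        "n_replicates": n_replicates})
    return plate, truth


def simulate_fp_titration(refs: PolarizationReferences, kd: float,
                          receptor_grid, probe_total: float = 10e-9,
                          nonspecific_slope: float = 0.0,
                          background_slope: float = 0.0,
                          noise_mp: float = 1.0, n_replicates: int = 3,
                          seed: int = 0) -> tuple:
    """FP probe-titration plate exercising the full correction chain.

    For each receptor dose, three well roles are generated: ``sample``
    (probe + receptor; P_M wells), ``saturated_competitor`` (probe +
    receptor + saturating unlabeled peptide; P_I wells) and ``protein_only``
    (receptor autofluorescence background), plus ``probe_only`` wells at the
    free-probe polarization P_D*.

    True well polarization: P = P_D* + F_B*(P_D*R - P_D*) + ns*R with F_B the
    exact 1:1 bound fraction and ns a linear nonspecific term
    [mP/M].  Protein background adds ``background_slope * R`` to both
    intensity channels.  Additive Gaussian mP noise (default 1 mP).
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(receptor_grid, dtype=float)
    span = refs.p_dstar_r - refs.p_dstar
    rows = []

    def emit(role, r_tot, mp_true):
        mp = mp_true + (rng.normal(0.0, noise_mp) if noise_mp > 0 else 0.0)
        read = intensities_from_mp(mp, refs.g_factor, i_p=1000.0)
        bg = background_slope * r_tot
        rows.append({"role": role, "conc_M": r_tot,
                     "i_s": read.i_s + bg, "i_p": read.i_p + bg})

    for r_tot in grid:
        fb = solve_1to1(EquilibriumSpec(r_tot, probe_total, kd)).bound_probe_fraction
        ns = nonspecific_slope * r_tot
        for _ in range(n_replicates):
            emit("sample", float(r_tot), refs.p_dstar + fb * span + ns)
            emit("saturated_competitor", float(r_tot), refs.p_dstar + ns)
        bg = background_slope * r_tot
        for _ in range(n_replicates):
            rows.append({"role": "protein_only", "conc_M": float(r_tot),
                         "i_s": bg, "i_p": bg})
    for _ in range(n_replicates):
        emit("probe_only", 0.0, refs.p_dstar)

    plate = pd.DataFrame(rows)
    names = _well_names(len(plate))
    plate.insert(0, "well", names)
    plate.insert(1, "row", [w[0] for w in names])
    plate.insert(2, "col", [int(w[1:]) for w in names])
    truth = SimTruth("fp_titration", seed, {
        "kd": kd, "probe_total": probe_total,
        "receptor_grid": grid.tolist(),
        "nonspecific_slope": nonspecific_slope,
        "background_slope": background_slope,
        "noise_mp": noise_mp, "refs": asdict(refs)})
    return plate, truth


def simulate_ftsa(params: ThermoParams, ligand_doses,
                  temperatures=None, noise_cv: float = 0.02,
                  f_native: tuple = (0.05, 0.0),
                  f_unfolded: tuple = (1.0, 0.0),
                  post_peak_decay: float = 0.0,
                  include_negative_control: bool = True,
                  seed: int = 0) -> tuple:
    """Melt-curve set from the coupled unfolding-binding two-state model.

    Per temperature the unfolded fraction f_U comes from the full
    three-species equilibrium (native, native-ligand, unfolded); the dye
    fluorescence is F = F_N(T)*(1-f_U) + F_U(T)*f_U with linear native and
    unfolded baselines (intercept, slope per C above 25 C), plus
    multiplicative log-normal noise (default CV 2%).  ``post_peak_decay``
    [1/C] adds the optional exponential loss of dye signal above the
    transition (dye dissociating from aggregates); the analysis handles it
    by truncating at the curve maximum.  A dye-only negative control (flat
    trace at the native baseline) is appended by default.
    """
    rng = np.random.default_rng(seed)
    if temperatures is None:
        temperatures = np.arange(25.0, 95.0 + 1e-9, 0.5)
    t = np.asarray(temperatures, dtype=float)
    fn = f_native[0] + f_native[1] * (t - 25.0)
    fu = f_unfolded[0] + f_unfolded[1] * (t - 25.0)

    curves = []
    for dose in ligand_doses:
        f_u = np.array([unfolded_fraction(tc, float(dose), params) for tc in t])
        f = fn * (1.0 - f_u) + fu * f_u
        if post_peak_decay > 0:
            f = fn * (1.0 - f_u) + fu * f_u * np.exp(
                -post_peak_decay * np.maximum(0.0, t - (params.t_r + 5.0)))
        f = f * _lognormal_factors(rng, noise_cv, f.shape)
        curves.append(MeltCurve(t, f, ligand_total=float(dose),
                                label=f"L={dose:.3g}M"))
    if include_negative_control:
        f = fn * _lognormal_factors(rng, noise_cv, fn.shape)
        curves.append(MeltCurve(t, f, ligand_total=0.0, label="dye_only"))

    truth = SimTruth("ftsa", seed, {
        "thermo": asdict(params), "ligand_doses": list(map(float, ligand_doses)),
        "noise_cv": noise_cv, "f_native": list(f_native),
        "f_unfolded": list(f_unfolded), "post_peak_decay": post_peak_decay})
    return curves, truth


def simulate_bli(ka: float, kd_rate: float, rmax: float, concentrations,
                 phase_durations: tuple = (30.0, 120.0, 120.0),
                 dt: float = 0.4, noise: float = 0.01, drift: float = 0.0,
                 seed: int = 0) -> tuple:
    """Sensorgram set from the 1:1 Langmuir model plus a paired buffer reference.

    Phases: baseline / association / dissociation with the given durations.
    Gaussian noise (default 0.01 nm) and optional shared linear drift
    [nm/s]; the reference trace carries the same drift so reference
    subtraction removes it exactly on average.
    """
    if ka <= 0 or kd_rate <= 0:
        raise ValueError("rate constants must be positive")
    rng = np.random.default_rng(seed)
    d_base, d_assoc, d_diss = phase_durations
    t = np.arange(0.0, d_base + d_assoc + d_diss + 1e-9, dt)
    phase = np.where(t < d_base, "baseline",
                     np.where(t < d_base + d_assoc, "association",
                              "dissociation"))

    def clean_trace(c: float) -> np.ndarray:
        r = np.zeros_like(t)
        am = phase == "association"
        k_obs = ka * c + kd_rate
        r_eq = rmax * c / (c + kd_rate / ka)
        r[am] = r_eq * (1.0 - np.exp(-k_obs * (t[am] - d_base)))
        dm = phase == "dissociation"
        r_end = r_eq * (1.0 - np.exp(-k_obs * d_assoc))
        r[dm] = r_end * np.exp(-kd_rate * (t[dm] - d_base - d_assoc))
        return r

    sensorgrams = []
    for i, c in enumerate(concentrations):
        r = clean_trace(float(c)) + drift * t
        if noise > 0:
            r = r + rng.normal(0.0, noise, size=t.shape)
        sensorgrams.append(Sensorgram(t, r, phase, float(c),
                                      run_id=f"c{i}"))
    r_ref = drift * t
    if noise > 0:
        r_ref = r_ref + rng.normal(0.0, noise, size=t.shape)
    reference = Sensorgram(t, r_ref, phase, 0.0, run_id="reference")

    truth = SimTruth("bli", seed, {
        "ka": ka, "kd_rate": kd_rate, "rmax": rmax,
        "concentrations": list(map(float, concentrations)),
        "phase_durations": list(phase_durations), "dt": dt,
        "noise": noise, "drift": drift})
    return sensorgrams, reference, truth


def simulate_cetsa(t_agg_control: float, delta: float, grid=None,
                   noise_cv: float = 0.05, width: float = 2.0,
                   intensity_scale: float = 1000.0, bottom_fraction: float = 0.02,
                   seed: int = 0) -> tuple:
    """Control/treated soluble-fraction series pair for CETSA.

    Boltzmann aggregation curves at ``t_agg_control`` and
    ``t_agg_control + delta``, scaled to blot-like intensity units, with
    multiplicative log-normal noise (default CV 5%).  Default grid is the
    12-temperature protocol 40-73 C in 3 C steps.
    """
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.arange(40.0, 73.0 + 1e-9, 3.0)
    t = np.asarray(grid, dtype=float)

    def series(t_agg: float, label: str) -> CetsaSeries:
        y = _boltzmann_decreasing(t, t_agg, width, 1.0, bottom_fraction)
        y = intensity_scale * y * _lognormal_factors(rng, noise_cv, y.shape)
        return CetsaSeries(t, y, condition_label=label, membrane_id=label)

    control = series(t_agg_control, "control")
    treated = series(t_agg_control + delta, "treated")
    truth = SimTruth("cetsa", seed, {
        "t_agg_control": t_agg_control, "delta": delta,
        "grid": t.tolist(), "noise_cv": noise_cv, "width": width})
    return control, treated, truth
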