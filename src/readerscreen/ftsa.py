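"""Fluorescent thermal shift assay (FTSA / DSF) analysis.

Melting-curve fitting (T_m extraction with linear native/unfolded baselines),
ligand-induced T_m shifts, and K_D determination from the ligand-dose
dependence of T_m via the coupled unfolding-binding thermodynamic model.

The dosing model
----------------
At the melting temperature T_m half the protein is unfolded.  With a
two-state unfolding equilibrium K_U = [U]/[N] and a 1:1 binding equilibrium
K_b = [NL]/([N][L_free]) the conservation laws give, exactly at T_m,

    L_t(T_m) = (K_U - 1) * ( 1/K_b(T_m) + M_t / (2*K_U) )

where M_t is total protein and L_t total ligand.  K_U(T) follows
Gibbs-Helmholtz,

    dG_U(T) = dH_U*(1 - T/T_r) - dCp_U*[(T_r - T) + T*ln(T/T_r)]

with T_r the ligand-free melting temperature (dG_U(T_r) = 0 by construction),
and K_b(T) is extrapolated from its value at the reference temperature T_0 by
the integrated van't Hoff relation with binding enthalpy dH_b and heat
capacity change dCp_b.  Fitting K_b(T_0) to an observed (L_t, T_m) series
yields K_D = 1/K_b(T_0), reported at T_0 (default 37 C, configurable): the
choice of T_0 materially changes K_D and is always echoed in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit, minimize_scalar

R_GAS = 8.314462618  # J/(mol*K)
_K0 = 273.15


@dataclass(frozen=True)
class MeltCurve:
    """One temperature-fluorescence trace (e.g. 25-95 C in 0.5 C steps)."""

    temperatures: tuple
    fluorescence: tuple
    ligand_total: float = 0.0
    label: str = ""

    def __init__(self, temperatures, fluorescence, ligand_total=0.0, label=""):
        t = tuple(float(x) for x in temperatures)
        f = tuple(float(x) for x in fluorescence)
        if len(t) != len(f):
            raise ValueError("temperature and fluorescence arrays differ in length")
        if len(t) < 20:
            raise ValueError("melt curve must span >= 20 points")
        if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("temperatures must be strictly ascending")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)
        object.__setattr__(self, "ligand_total", float(ligand_total))
        object.__setattr__(self, "label", str(label))


@dataclass
class MeltFit:
    """Boltzmann melting-curve fit with linear pre/post baselines.

    ``has_transition`` is False for flat traces (e.g. dye-only negative
    controls), in which case ``tm`` is NaN and must not be consumed.
    """

    tm: float
    steepness: float
    pre_baseline: tuple  # (slope, intercept)
    post_baseline: tuple
    truncation_temp: float
    has_transition: bool = True
    tm_stderr: float = np.nan
    message: str = ""


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic parameters of the coupled unfolding-binding model.

    Units: temperatures in C, enthalpies in kJ/mol, heat capacities in
    kJ/(mol*K), ``kb_t0`` in 1/M at reference temperature ``t0``,
    ``protein_total`` in M.  Defaults for the parameters a dosing experiment
    does not constrain: dCp_U 8 kJ/(mol*K) (typical for a small domain),
    dH_b -42 kJ/mol, dCp_b 0; all are explicit and overridable.
    """

    t_r: float
    dh_u: float
    protein_total: float
    kb_t0: float = 1e6
    dcp_u: float = 8.0
    dh_b: float = -42.0
    dcp_b: float = 0.0
    t0: float = 37.0

    def __post_init__(self) -> None:
        if self.dh_u <= 0:
            raise ValueError("unfolding enthalpy must be positive")
        if self.kb_t0 <= 0:
            raise ValueError("binding constant must be positive")
        if self.protein_total <= 0:
            raise ValueError("protein concentration must be positive")

    @property
    def kd(self) -> float:
        """Dissociation constant 1/K_b at the reference temperature t0 [M]."""
        return 1.0 / self.kb_t0


@dataclass(frozen=True)
class TmDoseSeries:
    """Ligand doses (including zero) with the melting temperature at each."""

    ligand_totals: tuple
    tms: tuple

    def __init__(self, ligand_totals, tms):
        lt = tuple(float(x) for x in ligand_totals)
        tm = tuple(float(x) for x in tms)
        if len(lt) != len(tm):
            raise ValueError("dose and Tm arrays differ in length")
        if 0.0 not in lt:
            raise ValueError("series must contain the zero-dose reference")
        object.__setattr__(self, "ligand_totals", lt)
        object.__setattr__(self, "tms", tm)


def _boltzmann_rise(t, tm, steep, pre_s, pre_i, post_s, post_i):
    pre = pre_i + pre_s * t
    post = post_i + post_s * t
    return pre + (post - pre) / (1.0 + np.exp((tm - t) / steep))


def fit_melt_curve(curve: MeltCurve, noise_floor_sigmas: float = 6.0) -> MeltFit:
    """Extract T_m from a melt trace.

    Data are truncated at the global fluorescence maximum (post-transition
    decay from dye-aggregate dissociation would otherwise distort the fit)
    and fitted with a rising Boltzmann between linear baselines.  A flat
    trace - amplitude below ``noise_floor_sigmas`` times the point-to-point
    noise - yields an explicit no-transition result, never a fabricated T_m.
    """
    t = np.asarray(curve.temperatures)
    f = np.asarray(curve.fluorescence)

    # robust point-to-point noise estimate from first differences
    noise = np.median(np.abs(np.diff(f))) / 0.6745 / np.sqrt(2.0)
    amplitude = f.max() - f.min()
    if amplitude <= noise_floor_sigmas * max(noise, 1e-12) or amplitude == 0:
        return MeltFit(np.nan, np.nan, (0.0, 0.0), (0.0, 0.0),
                       truncation_temp=float(t[-1]), has_transition=False,
                       message="flat trace: no unfolding transition")

    i_max = int(np.argmax(f))
    if i_max < 10:
        return MeltFit(np.nan, np.nan, (0.0, 0.0), (0.0, 0.0),
                       truncation_temp=float(t[i_max]), has_transition=False,
                       message="fluorescence maximum at the start of the ramp")
    tt, ff = t[: i_max + 1], f[: i_max + 1]

    # initial guesses from a smoothed trace: the midpoint is where the
    # signal first crosses halfway between the plateau medians, and the
    # width comes from the quartile crossings; a raw-gradient guess would
    # lock onto noise spikes in the high plateau
    win = min(5, len(ff))
    smooth = np.convolve(ff, np.ones(win) / win, mode="same")
    n_edge = max(3, len(tt) // 10)
    lo = float(np.median(smooth[:n_edge]))
    hi = float(np.median(smooth[-n_edge:]))

    def first_crossing(level):
        above = smooth >= level
        idx = np.argmax(above) if above.any() else len(tt) - 1
        return float(tt[idx])

    tm0 = first_crossing((lo + hi) / 2.0)
    t25 = first_crossing(lo + 0.25 * (hi - lo))
    t75 = first_crossing(lo + 0.75 * (hi - lo))
    steep0 = max((t75 - t25) / (2.0 * np.log(3.0)), float(tt[1] - tt[0]))
    pre = np.polyfit(tt[:n_edge], ff[:n_edge], 1)
    post = np.polyfit(tt[-n_edge:], ff[-n_edge:], 1)
    p0 = [tm0, steep0, pre[0], pre[1], post[0], post[1]]
    try:
        popt, pcov = curve_fit(
            _boltzmann_rise, tt, ff, p0=p0, maxfev=20000,
            bounds=([tt[0], 1e-3, -np.inf, -np.inf, -np.inf, -np.inf],
                    [tt[-1], 30.0, np.inf, np.inf, np.inf, np.inf]),
        )
    except RuntimeError:
        return MeltFit(np.nan, np.nan, (0.0, 0.0), (0.0, 0.0),
                       truncation_temp=float(tt[-1]), has_transition=False,
                       message="melt-curve fit did not converge")
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(6, np.nan)
    return MeltFit(
        tm=float(popt[0]),
        steepness=float(popt[1]),
        pre_baseline=(float(popt[2]), float(popt[3])),
        post_baseline=(float(popt[4]), float(popt[5])),
        truncation_temp=float(tt[-1]),
        has_transition=True,
        tm_stderr=float(perr[0]),
    )


def delta_tm(sample: MeltFit, reference: MeltFit) -> float:
    """Ligand-induced melting-temperature shift: sample T_m minus reference T_m."""
    if not sample.has_transition or not reference.has_transition:
        raise ValueError("delta_tm requires two valid transitions")
    return sample.tm - reference.tm


def vant_hoff_enthalpy(tm_c: float, steepness_c: float) -> float:
    """Unfolding enthalpy [kJ/mol] implied by a Boltzmann transition width.

    For a two-state transition the midpoint slope gives
    dH_vH = R*T_m^2 / s with s the Boltzmann steepness in K.
    """
    t = tm_c + _K0
    return R_GAS * t * t / steepness_c / 1000.0


def _k_unfold(t_k: float, params: ThermoParams) -> float:
    t_r = params.t_r + _K0
    dh = params.dh_u * 1000.0
    dcp = params.dcp_u * 1000.0
    dg = dh * (1.0 - t_k / t_r) - dcp * ((t_r - t_k) + t_k * np.log(t_k / t_r))
    return np.exp(-dg / (R_GAS * t_k))


def _k_bind(t_k: float, params: ThermoParams) -> float:
    t0 = params.t0 + _K0
    dh = params.dh_b * 1000.0
    dcp = params.dcp_b * 1000.0
    dg0 = -R_GAS * t0 * np.log(params.kb_t0)
    ds0 = (dh - dg0) / t0
    dg = dh + dcp * (t_k - t0) - t_k * (ds0 + dcp * np.log(t_k / t0))
    return np.exp(-dg / (R_GAS * t_k))


def ligand_total_at_tm(tm_c: float, params: ThermoParams) -> float:
    """Total ligand concentration [M] whose melting temperature is ``tm_c``.

    The closed-form dosing relation L_t = (K_U - 1)*(1/K_b + M_t/(2*K_U)),
    evaluated at absolute temperature.  Zero at T_r, strictly increasing
    above it for a stabilising ligand.
    """
    t_k = tm_c + _K0
    ku = _k_unfold(t_k, params)
    kb = _k_bind(t_k, params)
    return (ku - 1.0) * (1.0 / kb + params.protein_total / (2.0 * ku))


def predict_tm(params: ThermoParams, ligand_total: float,
               window: float = 60.0) -> float:
    """Melting temperature [C] at a given total ligand concentration.

    Root-finds T such that ligand_total_at_tm(T) equals ``ligand_total`` on
    (T_r, T_r + window].  ligand_total = 0 returns T_r exactly.
    """
    if ligand_total < 0:
        raise ValueError("ligand concentration must be non-negative")
    if ligand_total == 0:
        return params.t_r

    def g(t_c: float) -> float:
        return ligand_total_at_tm(t_c, params) - ligand_total

    lo = params.t_r + 1e-9
    hi = params.t_r + window
    if g(hi) < 0:
        raise ValueError(
            f"no melting point within {window} C above the reference; "
            "dose or binding constant outside the model's range")
    return float(brentq(g, lo, hi, xtol=1e-10))


def unfolded_fraction(t_c: float, ligand_total: float,
                      params: ThermoParams) -> float:
    """Unfolded protein fraction from the full three-species equilibrium.

    Solves N + NL + U = M_t with U = K_U*N and NL = K_b*N*L_free by bracketed
    root finding in the free ligand.  Independent of the closed-form dosing
    relation; used to cross-check that predict_tm's output really sits at
    half-unfolding, and by the melt-curve simulator.
    """
    t_k = t_c + _K0
    ku = _k_unfold(t_k, params)
    kb = _k_bind(t_k, params)
    m_t = params.protein_total
    if ligand_total == 0:
        return ku / (1.0 + ku)

    def h(l_free: float) -> float:
        n = m_t / (1.0 + ku + kb * l_free)
        return l_free + kb * n * l_free - ligand_total

    l_free = brentq(h, 0.0, ligand_total, xtol=1e-300, rtol=8.9e-16)
    n = m_t / (1.0 + ku + kb * l_free)
    return ku * n / m_t


def fit_kd_from_dosing(series: TmDoseSeries, params_fixed: ThermoParams,
                       min_shift: float = 0.2,
                       log10_kb_bounds: tuple = (2.0, 13.0)) -> dict:
    """K_D from the ligand-dose dependence of T_m.

    Least squares over K_b(T_0) (searched on a log10 grid by bounded scalar
    minimisation) of sum_i (T_m,obs,i - predict_tm(L_i))^2, holding the
    unfolding/binding thermodynamics in ``params_fixed`` fixed.  Returns
    ``kd = 1/K_b(T_0)`` at the reference temperature ``params_fixed.t0``.

    A series whose maximum shift above the zero-dose T_m is below
    ``min_shift`` C is flagged as a non-binder (``kd`` NaN).
    """
    doses = np.asarray(series.ligand_totals)
    tms = np.asarray(series.tms)
    if doses.size < 4:
        raise ValueError("dosing fit requires >= 4 doses including zero")
    tm0 = tms[doses == 0.0].mean()
    max_shift = float(tms.max() - tm0)
    if max_shift < min_shift:
        return {"kd": np.nan, "kb_t0": np.nan, "t0": params_fixed.t0,
                "converged": False, "non_binder": True, "rss": np.nan,
                "message": f"max Tm shift {max_shift:.2f} C below {min_shift} C"}

    def sse(log_kb: float) -> float:
        p = replace(params_fixed, kb_t0=10.0 ** log_kb)
        resid = 0.0
        for l, tm in zip(doses, tms):
            try:
                resid += (tm - predict_tm(p, l)) ** 2
            except ValueError:
                resid += 1e6
        return resid

    res = minimize_scalar(sse, bounds=log10_kb_bounds, method="bounded",
                          options={"xatol": 1e-7})
    kb = 10.0 ** res.x
    return {"kd": 1.0 / kb, "kb_t0": kb, "t0": params_fixed.t0,
            "converged": bool(res.success), "non_binder": False,
            "rss": float(res.fun), "message": ""}
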