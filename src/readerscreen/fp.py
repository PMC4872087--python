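"""Fluorescence-polarization pipeline.

Intensity-to-mP conversion, grating (G) factor calibration, the
specific-binding correction chain (P_M, P_I -> F_B, P_NS, P_S), probe
linearity QC, probe K_D fitting and displacement IC50 fitting.

Conventions
-----------
``i_s`` is the blank-corrected intensity in the s-plane (perpendicular) and
``i_p`` the intensity in the p-plane (parallel); polarization is

    P = (I_S - G*I_P) / (I_S + G*I_P) * 1000   [mP]

Background correction for protein autofluorescence is applied channel-wise at
the intensity level (mP is nonlinear in the intensities, so subtracting at the
mP level would be wrong).

Total intensity is computed as ``2*I_P + I_S``, the plate-reader convention
this pipeline was built around; the more common ``I_par + 2*G*I_perp`` is
available as an alternate mode but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_quant import ControlSet, DoseResponseSeries, FourPLFit, fit_4pl, percent_inhibition
from .equilibrium import EquilibriumSpec, HyperbolaFit, fit_hyperbola, solve_1to1


@dataclass(frozen=True)
class FPRead:
    """One well's blank-corrected s-plane and p-plane intensities."""

    i_s: float
    i_p: float


@dataclass(frozen=True)
class PolarizationReferences:
    """The anchors of the correction chain.

    ``p_dstar`` is the polarization of the free probe (P_D*), ``p_dstar_r``
    that of the fully receptor-bound probe (P_D*R), and ``g_factor`` the
    instrument grating constant.
    """

    p_dstar: float
    p_dstar_r: float
    g_factor: float

    def __post_init__(self) -> None:
        if self.p_dstar_r <= self.p_dstar:
            raise ValueError("saturated-probe polarization must exceed free-probe polarization")
        if self.g_factor <= 0:
            raise ValueError("G-factor must be positive")


@dataclass(frozen=True)
class CorrectedBindingPoint:
    """One receptor dose after the specific-binding correction chain.

    Invariants: ``f_b = (p_m - P_D*)/(P_D*R - P_D*)`` and
    ``p_s = p_m - p_ns`` hold exactly by construction.
    """

    receptor_total: float
    p_m: float
    p_i: float
    f_b: float
    p_ns: float
    p_s: float


def mp_from_intensities(read: FPRead, g: float) -> float:
    """Polarization in mP from channel intensities; bounded in (-1000, 1000)."""
    denom = read.i_s + g * read.i_p
    if denom == 0:
        raise ValueError("zero total intensity: mP undefined")
    return (read.i_s - g * read.i_p) / denom * 1000.0


def intensities_from_mp(mp: float, g: float, i_p: float = 1000.0) -> FPRead:
    """Inverse of :func:`mp_from_intensities` at a chosen p-plane intensity.

    Used by the simulators; round-trips through mp_from_intensities to
    machine precision.
    """
    if not -1000.0 < mp < 1000.0:
        raise ValueError("mP must lie strictly inside (-1000, 1000)")
    frac = mp / 1000.0
    i_s = g * i_p * (1.0 + frac) / (1.0 - frac)
    return FPRead(i_s=i_s, i_p=i_p)


def total_intensity(read: FPRead, mode: str = "2p_plus_s", g: float = 1.0) -> float:
    """Total fluorescence intensity of a well.

    Default mode is ``2*I_P + I_S`` (the convention used throughout this
    pipeline); ``conventional`` gives ``I_P + 2*G*I_S``.
    """
    if mode == "2p_plus_s":
        return 2.0 * read.i_p + read.i_s
    if mode == "conventional":
        return read.i_p + 2.0 * g * read.i_s
    raise ValueError(f"unknown total-intensity mode {mode!r}")


def probe_linearity(concentrations: Sequence[float], totals: Sequence[float]) -> dict:
    """OLS line through (concentration, total intensity) with R^2.

    A fluorescent probe must report linearly over the working range; a dip at
    high concentration signals inner-filter effects or aggregation.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(totals, dtype=float)
    if x.size < 3:
        raise ValueError("linearity check requires >= 3 points")
    if np.ptp(y) == 0:
        # constant totals: a horizontal line explains none of the (zero)
        # variance; linregress would return r = nan here
        return {"slope": 0.0, "intercept": float(y[0]), "r_squared": 0.0}
    res = stats.linregress(x, y)
    return {"slope": res.slope, "intercept": res.intercept,
            "r_squared": res.rvalue ** 2}


def calibrate_g_factor(read_free_probe: FPRead, target_mp: float) -> float:
    """G-factor that makes the free-probe well read ``target_mp``.

    Closed form: G = I_S*(1000 - mP) / (I_P*(1000 + mP)).  Round-trip
    property: mp_from_intensities(read, G) == target_mp.
    """
    if read_free_probe.i_p <= 0:
        raise ValueError("p-plane intensity must be positive for calibration")
    if not -1000.0 < target_mp < 1000.0:
        raise ValueError("target mP out of range (-1000, 1000)")
    return (read_free_probe.i_s * (1000.0 - target_mp)
            / (read_free_probe.i_p * (1000.0 + target_mp)))


def background_correct(read: FPRead, background: FPRead) -> FPRead:
    """Channel-wise subtraction of protein-only autofluorescence."""
    return FPRead(i_s=read.i_s - background.i_s, i_p=read.i_p - background.i_p)


def specific_polarization(p_m: float, p_i: float, receptor_total: float,
                          refs: PolarizationReferences) -> CorrectedBindingPoint:
    """Specific-binding correction chain for one receptor dose.

    Sequential formulas, applied in this order:

        F_B  = (P_M - P_D*) / (P_D*R - P_D*)      bound probe fraction
        P_NS = (P_I - P_D*) * (1 - F_B)           nonspecific contribution
        P_S  = P_M - P_NS                         specific polarization

    ``p_i`` is the polarization measured with a saturating unlabeled
    competitor present (probe fully displaced from the specific site), which
    isolates the nonspecific component.
    """
    span = refs.p_dstar_r - refs.p_dstar
    f_b = (p_m - refs.p_dstar) / span
    p_ns = (p_i - refs.p_dstar) * (1.0 - f_b)
    p_s = p_m - p_ns
    return CorrectedBindingPoint(receptor_total=receptor_total, p_m=p_m,
                                 p_i=p_i, f_b=f_b, p_ns=p_ns, p_s=p_s)


def fit_probe_kd(points: Sequence[CorrectedBindingPoint],
                 refs: PolarizationReferences | None = None,
                 probe_total: float | None = None,
                 depletion_corrected: bool = False,
                 subtract_baseline: bool = True) -> HyperbolaFit:
    """Probe K_D from corrected binding points via the one-site hyperbola.

    By default fits against TOTAL receptor concentration (the quantity
    actually plotted in a plate titration).  When the probe concentration is
    comparable to K_D this carries a known bias of roughly half the probe
    concentration; ``depletion_corrected=True`` (requires ``probe_total``)
    instead fits the exact 1:1 bound fraction from the equilibrium solver.

    ``subtract_baseline`` removes the free-probe polarization P_D* (from
    ``refs``) before fitting, since the hyperbola passes through the origin
    while P_S tends to P_D* at zero receptor.
    """
    if len(points) < 4:
        raise ValueError("probe K_D fit requires >= 4 points")
    r = np.array([p.receptor_total for p in points])
    y = np.array([p.p_s for p in points])
    if subtract_baseline:
        if refs is None:
            raise ValueError("subtract_baseline requires refs")
        # mP noise can push near-baseline points slightly negative after the
        # subtraction; the hyperbola is defined for non-negative responses,
        # so clip at the physical floor
        y = np.maximum(y - refs.p_dstar, 0.0)

    if not depletion_corrected:
        return fit_hyperbola(r, y)

    if probe_total is None:
        raise ValueError("depletion_corrected fit requires probe_total")

    from scipy.optimize import curve_fit

    def model(rr, log_kd, bmax):
        kd = 10.0 ** log_kd
        fb = np.array([
            solve_1to1(EquilibriumSpec(rt, probe_total, kd)).bound_probe_fraction
            for rt in rr
        ])
        return bmax * fb

    kd0 = max(np.median(r), 1e-12)
    popt, pcov = curve_fit(model, r, y, p0=[np.log10(kd0), float(y.max())],
                           maxfev=20000)
    kd = 10.0 ** popt[0]
    perr = np.sqrt(np.diag(pcov))
    resid = y - model(r, *popt)
    return HyperbolaFit(kd=kd, bmax=popt[1],
                        kd_stderr=np.log(10.0) * kd * perr[0],
                        bmax_stderr=perr[1], converged=True, reliable=True,
                        residual_norm=float(np.sqrt(np.sum(resid ** 2))))


def fp_displacement_ic50(series: DoseResponseSeries,
                         controls: ControlSet) -> FourPLFit:
    """Displacement IC50 from raw mP responses and plate controls.

    Controls: positive = probe + receptor (no competitor), negative = probe
    only.  Each replicate mP is converted to percent inhibition
    (I = 100*(1 - (P - P_neg)/(P_pos - P_neg))) and the variable-slope 4PL
    is fitted on log concentration.
    """
    if series.response_kind == "percent_inhibition":
        inh = series
    else:
        inh = DoseResponseSeries(
            series.concentrations,
            tuple(tuple(percent_inhibition(v, controls) for v in reps)
                  for reps in series.responses),
            response_kind="percent_inhibition",
        )
    return fit_4pl(inh)
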