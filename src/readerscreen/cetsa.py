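"""Cellular thermal shift assay (CETSA) quantitation.

Band intensities from quantitative immunoblots of the soluble protein
fraction are normalised per membrane, fitted with a decreasing Boltzmann
sigmoid to obtain the apparent aggregation temperature T_agg, and compared
between ligand-treated and control conditions (delta T_agg).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class CetsaSeries:
    """Soluble-fraction band intensities over a temperature gradient.

    A typical protocol covers 40-76 C in 3 C intervals (12-13 points); at
    least 6 temperatures spanning the transition are required.
    """

    temperatures: tuple
    band_intensities: tuple
    condition_label: str = ""
    membrane_id: str = ""

    def __init__(self, temperatures, band_intensities,
                 condition_label="", membrane_id=""):
        t = tuple(float(x) for x in temperatures)
        b = tuple(float(x) for x in band_intensities)
        if len(t) != len(b):
            raise ValueError("temperature and intensity arrays differ in length")
        if len(t) < 6:
            raise ValueError("CETSA series requires >= 6 temperatures")
        if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("temperatures must be strictly ascending")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "band_intensities", b)
        object.__setattr__(self, "condition_label", str(condition_label))
        object.__setattr__(self, "membrane_id", str(membrane_id))


@dataclass
class AggregationFit:
    """Boltzmann aggregation-curve fit.  ``steepness`` is the transition width [C]."""

    t_agg: float
    top: float
    bottom: float
    steepness: float
    t_agg_stderr: float = np.nan
    has_transition: bool = True
    message: str = ""


def normalize_cetsa(series: CetsaSeries, mode: str = "min_max") -> CetsaSeries:
    """Normalise band intensities to percent, per membrane.

    ``min_max`` (default): highest and lowest intensity on the membrane set
    to 100 and 0%.  ``relative_to_lowest_temp``: each intensity relative to
    the lowest-temperature sample (100% there).  Both modes are invariant
    under positive rescaling of the raw intensities, which is why a saturated
    exposure does not bias the curve.
    """
    y = np.asarray(series.band_intensities)
    if mode == "min_max":
        lo, hi = y.min(), y.max()
        if hi == lo:
            raise ValueError(
                f"degenerate intensities on membrane {series.membrane_id!r}: "
                "max equals min")
        norm = 100.0 * (y - lo) / (hi - lo)
    elif mode == "relative_to_lowest_temp":
        ref = y[0]
        if ref <= 0:
            raise ValueError(
                f"non-positive reference intensity on membrane "
                f"{series.membrane_id!r}")
        norm = 100.0 * y / ref
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(series, band_intensities=tuple(float(v) for v in norm))


def _boltzmann_decreasing(t, t_agg, width, top, bottom):
    return bottom + (top - bottom) / (1.0 + np.exp((t - t_agg) / width))


def fit_tagg(series: CetsaSeries) -> AggregationFit:
    """Apparent aggregation temperature from a normalised soluble-fraction curve.

    Fits the Boltzmann sigmoid oriented so the soluble fraction decreases
    with temperature.  Monotone-increasing data are rejected (wrong
    orientation); a flat series yields an explicit no-transition result.
    """
    t = np.asarray(series.temperatures)
    y = np.asarray(series.band_intensities)
    span = y.max() - y.min()
    if span < 1e-9:
        return AggregationFit(np.nan, np.nan, np.nan, np.nan,
                              has_transition=False,
                              message="flat series: no aggregation transition")
    n_edge = max(2, t.size // 4)
    if np.mean(y[-n_edge:]) > np.mean(y[:n_edge]):
        raise ValueError(
            "soluble fraction increases with temperature: wrong orientation "
            "for an aggregation curve")

    half = y.min() + 0.5 * span
    below = np.nonzero(y <= half)[0]
    t0 = float(t[below[0]]) if below.size else float(np.median(t))
    p0 = [t0, 2.0, float(y.max()), float(y.min())]
    try:
        popt, pcov = curve_fit(
            _boltzmann_decreasing, t, y, p0=p0, maxfev=20000,
            bounds=([t[0], 0.1, -np.inf, -np.inf],
                    [t[-1], 30.0, np.inf, np.inf]))
    except RuntimeError:
        return AggregationFit(np.nan, np.nan, np.nan, np.nan,
                              has_transition=False,
                              message="aggregation fit did not converge")
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    return AggregationFit(t_agg=float(popt[0]), steepness=float(popt[1]),
                          top=float(popt[2]), bottom=float(popt[3]),
                          t_agg_stderr=float(perr[0]))


def delta_tagg(treated: AggregationFit, control: AggregationFit) -> float:
    """Ligand-induced aggregation-temperature shift with propagated uncertainty.

    Returns treated T_agg minus control T_agg.  Significance is left to the
    user: report the shift together with the quadrature-combined stderr of
    the two fits (available on the inputs).
    """
    if not treated.has_transition or not control.has_transition:
        raise ValueError("delta_tagg requires two valid transitions")
    return treated.t_agg - control.t_agg
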