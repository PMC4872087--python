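"""Plate-level quantitation shared by the Alpha and FP displacement assays.

Control statistics, percent inhibition/quench, the Z'-factor screening-window
statistic, four-parameter-logistic (4PL) IC50 fitting on log concentration,
and hook-point detection in bead cross-titration matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


class DegenerateControlsError(ValueError):
    """Raised when control statistics cannot support the requested quantity."""


@dataclass(frozen=True)
class ControlSet:
    """Positive/negative/blank control wells of one plate.

    Values are blank-corrected signal for the positive and negative arms and
    raw signal for the blanks.  Statistics are derived on access so they can
    never go stale.
    """

    positive_values: tuple
    negative_values: tuple
    blank_values: tuple = ()

    def __init__(self, positive_values, negative_values, blank_values=()):
        pos = tuple(float(v) for v in positive_values)
        neg = tuple(float(v) for v in negative_values)
        blk = tuple(float(v) for v in blank_values)
        if not pos or not neg:
            raise ValueError("each control arm must be non-empty")
        object.__setattr__(self, "positive_values", pos)
        object.__setattr__(self, "negative_values", neg)
        object.__setattr__(self, "blank_values", blk)

    @property
    def mu_max(self) -> float:
        return float(np.mean(self.positive_values))

    @property
    def mu_min(self) -> float:
        return float(np.mean(self.negative_values))

    @property
    def sd_max(self) -> float:
        return float(np.std(self.positive_values, ddof=1)) if len(self.positive_values) > 1 else 0.0

    @property
    def sd_min(self) -> float:
        return float(np.std(self.negative_values, ddof=1)) if len(self.negative_values) > 1 else 0.0


@dataclass(frozen=True)
class DoseResponseSeries:
    """Ascending dose grid with replicate responses per dose.

    ``responses`` is a tuple of tuples (one replicate set per concentration).
    ``response_kind`` is ``"raw_signal"`` or ``"percent_inhibition"``.
    """

    concentrations: tuple
    responses: tuple
    response_kind: str = "raw_signal"

    def __init__(self, concentrations, responses, response_kind="raw_signal"):
        conc = tuple(float(c) for c in concentrations)
        resp = tuple(tuple(float(v) for v in np.atleast_1d(r)) for r in responses)
        if len(conc) != len(resp):
            raise ValueError("concentrations and responses differ in length")
        if any(c <= 0 for c in conc):
            raise ValueError("concentrations must be strictly positive")
        if any(conc[i] >= conc[i + 1] for i in range(len(conc) - 1)):
            raise ValueError("concentrations must be strictly ascending")
        if response_kind not in ("raw_signal", "percent_inhibition"):
            raise ValueError(f"unknown response_kind {response_kind!r}")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        object.__setattr__(self, "response_kind", response_kind)

    def mean_responses(self) -> np.ndarray:
        return np.array([np.mean(r) for r in self.responses])


@dataclass
class FourPLFit:
    """Variable-slope sigmoidal dose-response fit result.

    ``ic50`` is in molar; ``top``/``bottom`` in percent.  ``extrapolated``
    marks an IC50 outside [c_min/10, c_max*10]; ``converged`` False marks a
    degenerate or non-convergent fit.  Standard errors come from the fit
    covariance (delta method for ic50, which is fitted on a log scale).
    """

    ic50: float
    hill: float
    top: float
    bottom: float
    ic50_stderr: float = np.nan
    hill_stderr: float = np.nan
    converged: bool = True
    extrapolated: bool = False
    residual_norm: float = np.nan
    message: str = ""


@dataclass(frozen=True)
class TitrationMatrix:
    """Blank-corrected signal grid from a two-binder cross-titration."""

    row_concentrations: tuple
    col_concentrations: tuple
    signals: tuple  # tuple of row tuples

    def __init__(self, row_concentrations, col_concentrations, signals):
        rows = tuple(float(c) for c in row_concentrations)
        cols = tuple(float(c) for c in col_concentrations)
        sig = np.asarray(signals, dtype=float)
        if sig.shape != (len(rows), len(cols)):
            raise ValueError("signal grid shape does not match axis lengths")
        for ax in (rows, cols):
            if any(ax[i] >= ax[i + 1] for i in range(len(ax) - 1)):
                raise ValueError("axis concentrations must be strictly ascending")
        object.__setattr__(self, "row_concentrations", rows)
        object.__setattr__(self, "col_concentrations", cols)
        object.__setattr__(self, "signals", tuple(map(tuple, sig)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.signals, dtype=float)


def percent_inhibition(a_i: float, controls: ControlSet) -> float:
    """Percent inhibition of a sample signal relative to plate controls.

        I = 100 * (1 - (a_i - mu_min) / (mu_max - mu_min))

    Values are returned unclipped: negative inhibition (signal above the
    positive control) and values above 100% are preserved for QC.
    """
    span = controls.mu_max - controls.mu_min
    if span == 0:
        raise DegenerateControlsError(
            "positive and negative control means are identical "
            f"(mu_max = mu_min = {controls.mu_max:g}); inhibition undefined"
        )
    return 100.0 * (1.0 - (a_i - controls.mu_min) / span)


def percent_quench(a_i: float, controls: ControlSet) -> float:
    """Percent signal quench relative to the positive control: Q = 100*(1 - a_i/mu_max).

    Used with the TruHits counter-screen to flag compounds that suppress the
    bead signal itself rather than the protein-peptide interaction.
    """
    if controls.mu_max <= 0:
        raise DegenerateControlsError(
            f"non-positive positive-control mean ({controls.mu_max:g}); quench undefined"
        )
    return 100.0 * (1.0 - a_i / controls.mu_max)


def z_prime(controls: ControlSet) -> float:
    """Z'-factor screening-window statistic.

        Z' = 1 - (3*SD_max + 3*SD_min) / |mu_max - mu_min|

    Always <= 1; equals 1 only for noiseless controls.  Invariant under any
    affine rescaling applied jointly to all signals, and symmetric in the two
    control arms.  Z' > 0.5 is the conventional bar for an excellent assay.
    """
    if len(controls.positive_values) < 2 or len(controls.negative_values) < 2:
        raise ValueError("z_prime requires >= 2 values per control arm")
    span = abs(controls.mu_max - controls.mu_min)
    if span == 0:
        raise DegenerateControlsError("identical control means; Z' undefined")
    return 1.0 - (3.0 * controls.sd_max + 3.0 * controls.sd_min) / span


def signal_to_background(controls: ControlSet) -> float:
    """Assay window mu_max / mu_min; fails on non-positive background."""
    if controls.mu_min <= 0:
        raise DegenerateControlsError(
            f"non-positive background mean ({controls.mu_min:g}); S/B undefined"
        )
    return controls.mu_max / controls.mu_min


def _4pl(logc: np.ndarray, log_ic50: float, hill: float, top: float, bottom: float) -> np.ndarray:
    # (ic50/c)^hill = 10^(hill*(log_ic50 - logc))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ic50 - logc)))


def fit_4pl(series: DoseResponseSeries) -> FourPLFit:
    """Four-parameter-logistic fit of percent inhibition on log10 concentration.

        I(c) = bottom + (top - bottom) / (1 + (ic50/c)^hill)

    Replicates are averaged per dose before the (unweighted) fit.
    Initialisation: top = max, bottom = min, ic50 = concentration at the
    half-range crossing, hill = 1.  Degenerate (flat) data or an IC50 far
    outside the titrated range are flagged, never silently accepted.
    """
    if series.response_kind != "percent_inhibition":
        raise ValueError("fit_4pl expects a percent_inhibition series")
    conc = np.asarray(series.concentrations)
    if conc.size < 4:
        raise ValueError("4PL fit requires >= 4 concentrations")
    y = series.mean_responses()
    logc = np.log10(conc)

    span = y.max() - y.min()
    if span < 1e-9:
        return FourPLFit(np.nan, np.nan, float(y.mean()), float(y.mean()),
                         converged=False, message="flat response: no transition")

    half = y.min() + 0.5 * span
    crossing = np.nonzero(np.diff(np.sign(y - half)) != 0)[0]
    ic50_0 = conc[crossing[0]] if crossing.size else float(np.sqrt(conc[0] * conc[-1]))
    p0 = [np.log10(ic50_0), 1.0, float(y.max()), float(y.min())]
    try:
        popt, pcov = curve_fit(_4pl, logc, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan,
                         converged=False, message=f"non-convergence: {exc}")
    log_ic50, hill, top, bottom = popt
    ic50 = 10.0 ** log_ic50
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.inf)
    resid = y - _4pl(logc, *popt)
    extrapolated = not (conc.min() / 10.0 <= ic50 <= conc.max() * 10.0)
    return FourPLFit(
        ic50=ic50,
        hill=hill,
        top=top,
        bottom=bottom,
        ic50_stderr=np.log(10.0) * ic50 * perr[0],
        hill_stderr=perr[1],
        converged=True,
        extrapolated=extrapolated,
        residual_norm=float(np.sqrt(np.sum(resid ** 2))),
        message="ic50 outside titrated range" if extrapolated else "",
    )


def hook_point(matrix: TitrationMatrix, axis: str = "cols",
               drop_threshold: float = 0.10) -> list:
    """Per-line hook concentration (or None) along the scanned axis.

    ``axis="cols"`` scans each grid row over the column concentrations (one
    result per row); ``axis="rows"`` scans each column over the row
    concentrations.  A hook is reported at the concentration of the raw
    per-line signal maximum when any later point drops by more than
    ``drop_threshold`` relative to that maximum.  Monotone lines return None;
    absence of a hook is a valid outcome, not an error.  No smoothing is
    applied: the grids are small and smoothing would blur the hook.
    """
    sig = matrix.as_array()
    if axis == "cols":
        lines, concs = sig, np.asarray(matrix.col_concentrations)
    elif axis == "rows":
        lines, concs = sig.T, np.asarray(matrix.row_concentrations)
    else:
        raise ValueError("axis must be 'rows' or 'cols'")
    if concs.size < 4:
        raise ValueError("hook detection requires >= 4 concentrations on the scanned axis")

    out: list = []
    for line in lines:
        i_max = int(np.argmax(line))
        peak = line[i_max]
        tail = line[i_max + 1:]
        if peak > 0 and tail.size and np.min(tail) < (1.0 - drop_threshold) * peak:
            out.append(float(concs[i_max]))
        else:
            out.append(None)
    return out
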