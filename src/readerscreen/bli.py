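"""Biolayer interferometry: 1:1 Langmuir sensorgram modelling and fitting.

A streptavidin biosensor tip loaded with biotinylated peptide is dipped into
analyte (reader protein) solution; the optical-thickness response R(t) [nm]
follows the 1:1 Langmuir model

    association:  R(t) = R_eq * (1 - exp(-k_obs*t)),
                  k_obs = k_a*c + k_d,  R_eq = R_max*c/(c + k_d/k_a)
    dissociation: R(t) = R_0 * exp(-k_d*t)

Global fitting across >= 2 analyte concentrations shares (k_a, k_d, R_max)
and yields K_D = k_d/k_a.  Competitive readouts (report-point displacement
and dissociation-rate shift) and regeneration QC complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy import stats

PHASES = ("baseline", "association", "dissociation")


@dataclass(frozen=True)
class Sensorgram:
    """Phase-annotated BLI trace at one analyte concentration.

    ``time`` ascending seconds, ``response`` nm, ``phase`` a per-point label
    from ``PHASES`` in contiguous, ordered blocks.  Association is expected
    re-zeroed (response 0 at the association start); see
    :func:`rezero_association`.
    """

    time: tuple
    response: tuple
    phase: tuple
    analyte_concentration: float
    reference_subtracted: bool = False
    run_id: str = ""

    def __init__(self, time, response, phase, analyte_concentration,
                 reference_subtracted=False, run_id=""):
        t = tuple(float(x) for x in time)
        r = tuple(float(x) for x in response)
        p = tuple(str(x) for x in phase)
        if not (len(t) == len(r) == len(p)):
            raise ValueError("time/response/phase arrays differ in length")
        if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("time must be strictly ascending")
        order = [ph for i, ph in enumerate(p) if i == 0 or p[i - 1] != ph]
        if any(ph not in PHASES for ph in order):
            raise ValueError(f"phase labels must be among {PHASES}")
        if order != sorted(set(order), key=PHASES.index):
            raise ValueError("phases must be contiguous and in order "
                             "baseline -> association -> dissociation")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)
        object.__setattr__(self, "phase", p)
        object.__setattr__(self, "analyte_concentration", float(analyte_concentration))
        object.__setattr__(self, "reference_subtracted", bool(reference_subtracted))
        object.__setattr__(self, "run_id", str(run_id))

    def _mask(self, phase: str) -> np.ndarray:
        return np.array([p == phase for p in self.phase])

    def phase_arrays(self, phase: str):
        m = self._mask(phase)
        return np.asarray(self.time)[m], np.asarray(self.response)[m]

    @property
    def association_end(self) -> float:
        t, _ = self.phase_arrays("association")
        if t.size == 0:
            raise ValueError("sensorgram has no association phase")
        return float(t[-1])


@dataclass
class KineticFit:
    """Global 1:1 fit result.  ``kd_eq`` is derived, never stored."""

    ka: float
    kd_rate: float
    rmax: float
    ka_stderr: float = np.nan
    kd_rate_stderr: float = np.nan
    per_curve_residuals: dict = field(default_factory=dict)
    low_decay_curves: tuple = ()
    converged: bool = True
    message: str = ""

    @property
    def kd_eq(self) -> float:
        """Equilibrium dissociation constant K_D = k_d/k_a [M]."""
        return kd_from_rates(self.ka, self.kd_rate)


@dataclass(frozen=True)
class ReportPoint:
    """A fixed sampling time, ``time_offset`` seconds before association end."""

    time_offset: float = 5.0


def model_association(t, ka: float, kd_rate: float, c: float, rmax: float):
    """1:1 Langmuir association response at time ``t`` after the phase start."""
    t = np.asarray(t, dtype=float)
    k_obs = ka * c + kd_rate
    r_eq = rmax * c / (c + kd_rate / ka)
    return r_eq * (1.0 - np.exp(-k_obs * t))


def model_dissociation(t, kd_rate: float, r0: float):
    """First-order dissociation decay from response ``r0`` at phase start."""
    t = np.asarray(t, dtype=float)
    return r0 * np.exp(-kd_rate * t)


def kd_from_rates(ka: float, kd_rate: float) -> float:
    """Equilibrium dissociation constant K_D = k_d/k_a [M]."""
    if ka <= 0:
        raise ValueError("association rate constant must be positive")
    return kd_rate / ka


def rezero_association(sensorgram: Sensorgram, baseline_window: float = 5.0) -> Sensorgram:
    """Shift responses so the association phase starts at 0.

    The offset is the mean response over the final ``baseline_window``
    seconds of the baseline phase (or the first association point if no
    baseline is present).
    """
    tb, rb = sensorgram.phase_arrays("baseline")
    if tb.size:
        sel = tb >= tb[-1] - baseline_window
        offset = float(np.mean(rb[sel]))
    else:
        _, ra = sensorgram.phase_arrays("association")
        offset = float(ra[0]) if ra.size else 0.0
    return replace(sensorgram,
                   response=tuple(r - offset for r in sensorgram.response))


def reference_subtract(sample: Sensorgram, reference: Sensorgram) -> Sensorgram:
    """Pointwise subtraction of a buffer-only reference trace.

    The reference is interpolated onto the sample's time grid; the grids must
    overlap fully.  Removes shared drift exactly.
    """
    ts = np.asarray(sample.time)
    tr = np.asarray(reference.time)
    if ts[0] < tr[0] - 1e-9 or ts[-1] > tr[-1] + 1e-9:
        raise ValueError("reference trace does not cover the sample's time range")
    ref_interp = np.interp(ts, tr, np.asarray(reference.response))
    return replace(sample,
                   response=tuple(np.asarray(sample.response) - ref_interp),
                   reference_subtracted=True)


def dissociation_decay_fraction(sensorgram: Sensorgram) -> float:
    """Fractional signal loss over the dissociation phase (0 = none)."""
    _, r = sensorgram.phase_arrays("dissociation")
    if r.size < 2 or r[0] <= 0:
        return 0.0
    return float((r[0] - r[-1]) / r[0])


def _init_rates(sensorgrams):
    """Two-step seeding: k_d from late-dissociation log slope, k_a from k_obs vs c."""
    kd0s = []
    for sg in sensorgrams:
        t, r = sg.phase_arrays("dissociation")
        if t.size < 4:
            continue
        half = t.size // 2
        tt, rr = t[half:], r[half:]
        pos = rr > 0
        if pos.sum() >= 3:
            slope = stats.linregress(tt[pos], np.log(rr[pos])).slope
            if slope < 0:
                kd0s.append(-slope)
    kd0 = float(np.median(kd0s)) if kd0s else 1e-3

    kobs, concs = [], []
    for sg in sensorgrams:
        t, r = sg.phase_arrays("association")
        if t.size < 5:
            continue
        t = t - t[0]
        try:
            popt, _ = curve_fit(lambda tt, req, k: req * (1.0 - np.exp(-k * tt)),
                                t, r, p0=[max(r.max(), 1e-3), 0.01], maxfev=5000)
            kobs.append(popt[1])
            concs.append(sg.analyte_concentration)
        except RuntimeError:
            continue
    if len(kobs) >= 2:
        slope = stats.linregress(concs, kobs).slope
        ka0 = slope if slope > 0 else kd0 / np.median(concs)
    else:
        ka0 = 1e5
    rmax0 = max(max(np.asarray(sg.response).max() for sg in sensorgrams), 1e-3)
    return max(ka0, 1.0), max(kd0, 1e-8), rmax0


def global_fit_1to1(sensorgrams, min_decay: float = 0.05,
                    shared_rmax: bool = True) -> KineticFit:
    """Global 1:1 Langmuir fit across association and dissociation phases.

    A single (k_a, k_d) - and by default a single R_max, appropriate for one
    loaded (or regeneration-equivalent) sensor - is fitted jointly to all
    curves by least squares; rates are searched in log space.  Curves whose
    dissociation decays less than ``min_decay`` (default 5%) are flagged:
    k_d is then poorly determined by those curves.
    """
    sgs = list(sensorgrams)
    if len(sgs) < 2:
        raise ValueError("global fit requires >= 2 analyte concentrations")
    low_decay = tuple(sg.run_id or str(i) for i, sg in enumerate(sgs)
                      if dissociation_decay_fraction(sg) < min_decay)

    ka0, kd0, rmax0 = _init_rates(sgs)
    n_rmax = 1 if shared_rmax else len(sgs)
    x0 = np.concatenate([[np.log10(ka0), np.log10(kd0)], np.full(n_rmax, rmax0)])

    assoc_abs = [sg.phase_arrays("association") for sg in sgs]
    diss_abs = [sg.phase_arrays("dissociation") for sg in sgs]
    assoc = [(t - t[0], r) for t, r in assoc_abs]
    diss = [(t - t[0], r) for t, r in diss_abs]
    concs = [sg.analyte_concentration for sg in sgs]
    # association duration runs to the true phase boundary (first
    # dissociation timestamp), not just to the last association sample
    t_assoc_end = [
        (diss_abs[i][0][0] - assoc_abs[i][0][0]) if diss_abs[i][0].size
        else assoc[i][0][-1]
        for i in range(len(sgs))
    ]

    def resid(x):
        ka, kd = 10.0 ** x[0], 10.0 ** x[1]
        out = []
        for i in range(len(sgs)):
            rmax = x[2] if shared_rmax else x[2 + i]
            ra = model_association(assoc[i][0], ka, kd, concs[i], rmax)
            out.append(ra - assoc[i][1])
            r_end = model_association(t_assoc_end[i], ka, kd, concs[i], rmax)
            out.append(model_dissociation(diss[i][0], kd, r_end) - diss[i][1])
        return np.concatenate(out)

    sol = least_squares(resid, x0, method="lm", max_nfev=20000)
    ka, kd = 10.0 ** sol.x[0], 10.0 ** sol.x[1]
    rmax = float(sol.x[2]) if shared_rmax else float(np.mean(sol.x[2:]))

    # parameter covariance from the Jacobian at the optimum
    try:
        _, s, vt = np.linalg.svd(sol.jac, full_matrices=False)
        tol = np.finfo(float).eps * max(sol.jac.shape) * s[0]
        s = s[s > tol]
        vt = vt[: s.size]
        dof = max(sol.fun.size - sol.x.size, 1)
        cov = (vt.T / s ** 2) @ vt * 2.0 * sol.cost / dof
        ka_se = np.log(10.0) * ka * np.sqrt(cov[0, 0])
        kd_se = np.log(10.0) * kd * np.sqrt(cov[1, 1])
    except np.linalg.LinAlgError:  # pragma: no cover
        ka_se = kd_se = np.nan

    per_curve = {}
    ofs = 0
    for i, sg in enumerate(sgs):
        n = assoc[i][0].size + diss[i][0].size
        per_curve[sg.run_id or str(i)] = float(
            np.sqrt(np.mean(sol.fun[ofs:ofs + n] ** 2)))
        ofs += n

    return KineticFit(
        ka=ka, kd_rate=kd, rmax=rmax,
        ka_stderr=float(ka_se), kd_rate_stderr=float(kd_se),
        per_curve_residuals=per_curve, low_decay_curves=low_decay,
        converged=bool(sol.success),
        message="" if not low_decay else
        f"dissociation decay < {min_decay:.0%} on curves {low_decay}: "
        "k_d reliability reduced",
    )


def fit_dissociation_rate(sensorgram: Sensorgram) -> float:
    """Local single-curve dissociation rate [1/s] by least squares."""
    t, r = sensorgram.phase_arrays("dissociation")
    if t.size < 4:
        raise ValueError("dissociation phase too short for a local fit")
    t = t - t[0]
    popt, _ = curve_fit(model_dissociation, t, r,
                        p0=[1e-3, max(r[0], 1e-3)], maxfev=10000)
    return float(abs(popt[0]))


def report_point_displacement(sample: Sensorgram, control: Sensorgram,
                              rp: ReportPoint = ReportPoint()) -> float:
    """Percent displacement at a report point near the association end.

    100*(1 - R_sample/R_control) evaluated ``rp.time_offset`` seconds before
    the end of the association phase.  The two curves must share
    association-phase timing.
    """
    t_end_s = sample.association_end
    t_end_c = control.association_end
    if abs(t_end_s - t_end_c) > 1e-6:
        raise ValueError("sample and control association phases are not aligned")
    t_rp = t_end_s - rp.time_offset
    ts, rs = sample.phase_arrays("association")
    tc, rc = control.phase_arrays("association")
    r_s = float(np.interp(t_rp, ts, rs))
    r_c = float(np.interp(t_rp, tc, rc))
    if r_c <= 0:
        raise ValueError("control response non-positive at the report point")
    return 100.0 * (1.0 - r_s / r_c)


def dissociation_shift(kd_sample: float, kd_control: float) -> float:
    """Fold-change of the dissociation rate; > 1 indicates competition.

    A competitor in the dissociation buffer blocks rebinding of the analyte
    to the tip-bound peptide, raising the apparent off-rate.
    """
    if kd_sample <= 0 or kd_control <= 0:
        raise ValueError("dissociation rates must be positive")
    return kd_sample / kd_control


def regeneration_qc(association_maxima, cv_threshold: float = 10.0) -> dict:
    """Stability verdict for a regenerated biosensor across cycles.

    The coefficient of variation (percent) of the per-cycle association
    maxima; the sensor is ``stable`` if CV <= ``cv_threshold``.
    """
    maxima = np.asarray(association_maxima, dtype=float)
    if maxima.size < 2:
        raise ValueError("regeneration QC requires >= 2 cycles")
    cv = 100.0 * np.std(maxima, ddof=1) / np.mean(maxima)
    return {"stable": bool(cv <= cv_threshold), "cv": float(cv),
            "usable_cycles": int(maxima.size)}
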