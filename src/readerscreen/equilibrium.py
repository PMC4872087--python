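"""Closed-form and bracketed solvers for 1:1 and competitive binding equilibria.

This module is the thermodynamic backbone of the package: every displacement
simulator and every fitting stage ultimately asks it for species
concentrations.  A receptor R (e.g. the Tudor-like domain of Spindlin1) binds a
labelled probe P (biotinylated or fluorescein-labelled H3K4me3 peptide) with
dissociation constant ``kd_probe``; an unlabelled competitor C may bind the
same site with ``kd_competitor``.  All concentrations are molar.

The competitive problem is reduced to a single monotone equation in the free
receptor concentration and solved by bracketed root finding on
``[0, receptor_total]``, which converges unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit


@dataclass(frozen=True)
class EquilibriumSpec:
    """Total concentrations and dissociation constants of a binding system.

    Parameters
    ----------
    receptor_total : float
        Total receptor concentration [M] (free + all complexes).
    probe_total : float
        Total labelled-probe concentration [M].
    kd_probe : float
        Receptor-probe dissociation constant [M]; must be > 0.
    competitor_total : float
        Total unlabelled-competitor concentration [M]; 0 for a plain 1:1 system.
    kd_competitor : float
        Receptor-competitor dissociation constant [M]; ignored when
        ``competitor_total`` is 0 but must still be positive.
    """

    receptor_total: float
    probe_total: float
    kd_probe: float
    competitor_total: float = 0.0
    kd_competitor: float = 1.0

    def __post_init__(self) -> None:
        if self.receptor_total < 0 or self.probe_total < 0 or self.competitor_total < 0:
            raise ValueError("total concentrations must be non-negative")
        if self.kd_probe <= 0 or self.kd_competitor <= 0:
            raise ValueError("dissociation constants must be positive")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations [M] of all five species of the system."""

    free_receptor: float
    free_probe: float
    free_competitor: float
    receptor_probe: float
    receptor_competitor: float

    @property
    def bound_probe_fraction(self) -> float:
        """Fraction of total probe in the receptor-probe complex."""
        total = self.free_probe + self.receptor_probe
        return self.receptor_probe / total if total > 0 else 0.0


@dataclass
class HyperbolaFit:
    """One-site binding fit Y = Bmax*[R] / (K_D + [R])."""

    kd: float
    bmax: float
    kd_stderr: float = np.nan
    bmax_stderr: float = np.nan
    converged: bool = True
    reliable: bool = True
    residual_norm: float = np.nan
    message: str = ""


def solve_1to1(spec: EquilibriumSpec) -> SpeciesState:
    """Exact quadratic solution of the single-site equilibrium R + P <-> RP.

    ``spec.competitor_total`` must be 0.  Uses the numerically stable form of
    the quadratic root (no cancellation for tight binders).
    """
    if spec.competitor_total != 0:
        raise ValueError("solve_1to1 requires competitor_total == 0")
    r_t, p_t, kd = spec.receptor_total, spec.probe_total, spec.kd_probe
    s = r_t + p_t + kd
    disc = s * s - 4.0 * r_t * p_t
    # stable root: 2ab / (s + sqrt(disc)) avoids catastrophic cancellation
    rp = 2.0 * r_t * p_t / (s + np.sqrt(max(disc, 0.0))) if s > 0 else 0.0
    return SpeciesState(
        free_receptor=r_t - rp,
        free_probe=p_t - rp,
        free_competitor=0.0,
        receptor_probe=rp,
        receptor_competitor=0.0,
    )


def solve_competitive(spec: EquilibriumSpec) -> SpeciesState:
    """Simultaneous solution of probe and competitor binding to one receptor.

    The two binding equilibria and three conservation laws collapse to

        f(Rf) = Rf*(1 + Pt/(Kp+Rf) + Ct/(Kc+Rf)) - Rt = 0

    which is strictly increasing in the free receptor Rf, so a single
    bracketed root-find on [0, Rt] is guaranteed to converge.  Reduces exactly
    to :func:`solve_1to1` when ``competitor_total`` is 0.
    """
    r_t = spec.receptor_total
    p_t, kp = spec.probe_total, spec.kd_probe
    c_t, kc = spec.competitor_total, spec.kd_competitor
    if r_t == 0:
        return SpeciesState(0.0, p_t, c_t, 0.0, 0.0)
    if c_t == 0:
        return solve_1to1(spec)

    def f(rf: float) -> float:
        return rf * (1.0 + p_t / (kp + rf) + c_t / (kc + rf)) - r_t

    rf = brentq(f, 0.0, r_t, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    rp = p_t * rf / (kp + rf)
    rc = c_t * rf / (kc + rf)
    return SpeciesState(
        free_receptor=rf,
        free_probe=p_t - rp,
        free_competitor=c_t - rc,
        receptor_probe=rp,
        receptor_competitor=rc,
    )


def displacement_curve(spec_base: EquilibriumSpec, competitor_grid) -> np.ndarray:
    """Bound-probe fraction versus competitor dose.

    ``spec_base`` carries receptor/probe totals and both K_Ds; its own
    ``competitor_total`` is ignored.  Returns an array of bound-probe fractions
    (monotone non-increasing in dose); the zero-dose point equals plain 1:1
    occupancy.
    """
    grid = np.asarray(competitor_grid, dtype=float)
    out = np.empty_like(grid)
    for i, c in enumerate(grid):
        s = EquilibriumSpec(
            receptor_total=spec_base.receptor_total,
            probe_total=spec_base.probe_total,
            kd_probe=spec_base.kd_probe,
            competitor_total=float(c),
            kd_competitor=spec_base.kd_competitor,
        )
        out[i] = solve_competitive(s).bound_probe_fraction
    return out


def half_displacement_dose(
    spec_base: EquilibriumSpec,
    lo: float = 1e-13,
    hi: float = 1e-1,
) -> float:
    """Competitor dose at which bound probe falls to half its zero-dose value.

    This is the theoretical apparent IC50 of a displacement titration under
    the given assay conditions (it generally exceeds the competitor K_D when
    the receptor is partially saturated by the probe).
    """
    f0 = displacement_curve(spec_base, [0.0])[0]
    if f0 <= 0:
        raise ValueError("no probe bound at zero competitor; IC50 undefined")

    def g(log_c: float) -> float:
        return displacement_curve(spec_base, [10.0 ** log_c])[0] - 0.5 * f0

    return 10.0 ** brentq(g, np.log10(lo), np.log10(hi), xtol=1e-12)


def competitor_kd_for_ic50(
    receptor_total: float,
    probe_total: float,
    kd_probe: float,
    target_ic50: float,
) -> float:
    """Competitor K_D whose theoretical half-displacement dose equals ``target_ic50``.

    Inverts :func:`half_displacement_dose` by bracketed root finding on
    log10 K_D.  Used by the simulators when an experiment is specified by its
    apparent IC50 rather than by the competitor affinity.
    """

    def g(log_kd: float) -> float:
        spec = EquilibriumSpec(receptor_total, probe_total, kd_probe,
                               kd_competitor=10.0 ** log_kd)
        return np.log10(half_displacement_dose(spec)) - np.log10(target_ic50)

    return 10.0 ** brentq(g, -13.0, -2.0, xtol=1e-10)


def fit_hyperbola(receptor_concentrations, responses) -> HyperbolaFit:
    """Least-squares fit of the one-site binding hyperbola Y = Bmax*R/(K_D+R).

    Requires >= 4 points with non-negative responses.  Data without curvature
    (effectively linear in R over the titrated range) yield a fit flagged
    ``reliable=False`` rather than a silent answer.
    """
    r = np.asarray(receptor_concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if r.size != y.size:
        raise ValueError("concentration and response arrays differ in length")
    if r.size < 4:
        raise ValueError("hyperbola fit requires at least 4 points")
    if np.any(y < -1e-12 * max(1.0, np.abs(y).max())):
        raise ValueError("responses must be non-negative")

    bmax0 = float(y.max()) if y.max() > 0 else 1.0
    half = 0.5 * bmax0
    above = np.nonzero(y >= half)[0]
    kd0 = float(r[above[0]]) if above.size else float(np.median(r))
    kd0 = max(kd0, r[r > 0].min() if np.any(r > 0) else 1e-9)

    def model(rr, log_kd, bmax):
        return bmax * rr / (10.0 ** log_kd + rr)

    try:
        popt, pcov = curve_fit(
            model, r, y, p0=[np.log10(kd0), bmax0], maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - hard to trigger
        return HyperbolaFit(kd=np.nan, bmax=np.nan, converged=False,
                            reliable=False, message=str(exc))
    kd = 10.0 ** popt[0]
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.inf, np.inf]
    kd_se = np.log(10.0) * kd * perr[0]
    resid = y - model(r, *popt)
    # no curvature: fitted K_D far outside the titrated range, or the
    # covariance blew up -> the data constrain only the ratio Bmax/K_D
    reliable = bool(np.isfinite(kd_se)) and kd <= 100.0 * r.max() and kd_se < 10.0 * kd
    return HyperbolaFit(
        kd=kd,
        bmax=popt[1],
        kd_stderr=kd_se,
        bmax_stderr=perr[1],
        converged=True,
        reliable=reliable,
        residual_norm=float(np.sqrt(np.sum(resid ** 2))),
        message="" if reliable else "no curvature: K_D poorly constrained",
    )
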