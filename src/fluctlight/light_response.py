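"""Steady-state light-response analysis.

Three quantities are derived from a steady-state light-response table:

* day respiration Rd, from the y-intercept of an ordinary least-squares
  regression of A against PFD over the quasi-linear low-light levels. The
  0 and 30 umol m-2 s-1 levels are always excluded to avoid the Kok-effect
  bend, which otherwise biases the intercept;
* the quantum yield of CO2 assimilation, Phi_CO2 = (A + Rd) / PFD_abs;
* a nonrectangular-hyperbola (NRH) fit

      A(I) = [phi*I + Amax - sqrt((phi*I + Amax)^2 - 4*theta*phi*I*Amax)]
             / (2*theta) - Rd

  with initial quantum efficiency phi, asymptote Amax and curvature
  theta in (0, 1], kept as a descriptive characterisation of the curve.

Rd used in the quantum-yield arithmetic is the linear-regression estimate,
not the NRH parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import EstimationError
from .gasex_io import LightResponseTable

#: PFD levels always excluded from the Rd regression (Kok-effect region)
KOK_EXCLUDED_LEVELS = (0.0, 30.0)
#: default quasi-linear levels for the Rd regression
DEFAULT_LINEAR_LEVELS = (75.0, 100.0, 200.0)

_THETA_FLOOR = 1e-9


@dataclass(frozen=True)
class NRHFit:
    """Fitted nonrectangular-hyperbola parameters."""

    phi: float      # initial quantum efficiency, CO2/photon
    a_max: float    # asymptotic gross assimilation, umol m-2 s-1
    theta: float    # curvature, (0, 1]
    rd: float       # fitted respiration offset, umol m-2 s-1
    residual_norm: float = float("nan")


@dataclass(frozen=True)
class SteadyStateReference:
    """Per species x O2 steady-state anchors for fluctuating-light analysis."""

    a_800: float
    a_100: float
    ci_800: float
    ci_100: float
    rd: float
    phi_800: float
    phi_100: float
    nrh: NRHFit | None = None


def nrh_curve(pfd, phi, a_max, theta, rd):
    """Evaluate the nonrectangular hyperbola; theta -> 0 falls back to the
    rectangular-hyperbola limit phi*I*Amax/(phi*I + Amax) - Rd."""
    pfd = np.asarray(pfd, dtype=float)
    x = phi * pfd + a_max
    if theta < _THETA_FLOOR:
        denom = np.where(x == 0, 1.0, x)
        gross = np.where(x == 0, 0.0, phi * pfd * a_max / denom)
    else:
        disc = np.maximum(x * x - 4.0 * theta * phi * pfd * a_max, 0.0)
        gross = (x - np.sqrt(disc)) / (2.0 * theta)
    return gross - rd


def estimate_rd(table: LightResponseTable,
                linear_levels=DEFAULT_LINEAR_LEVELS) -> float:
    """Day respiration from the OLS intercept over the quasi-linear levels.

    Levels 0 and 30 are dropped regardless of the request (Kok exclusion).
    Raises :class:`EstimationError` with fewer than two usable points.
    """
    levels = [lv for lv in linear_levels if lv not in KOK_EXCLUDED_LEVELS]
    mask = np.isin(table.data["pfd_in"].to_numpy(float), levels)
    pts = table.data[mask]
    if len(pts) < 2:
        raise EstimationError(
            f"Rd regression needs >= 2 usable levels, found {len(pts)}")
    slope, intercept = np.polyfit(pts["pfd_in"], pts["a"], 1)
    rd = -float(intercept)
    if rd < 0:
        warnings.warn(f"negative Rd estimate ({rd:.3g}); reported unclamped",
                      stacklevel=2)
    return rd


def fit_nrh(table: LightResponseTable, pfd_abs=None,
            rd_init: float | None = None) -> NRHFit:
    """Bounded least-squares NRH fit to a light-response table.

    ``pfd_abs`` supplies per-row absorbed PFD; incident PFD is used when
    omitted. Initialisation: phi from the Kok-excluded low-light slope,
    Amax from max(A) + Rd, theta = 0.7.
    """
    a = table.data["a"].to_numpy(float)
    pfd = (np.asarray(pfd_abs, dtype=float) if pfd_abs is not None
           else table.data["pfd_in"].to_numpy(float))
    if len(np.unique(pfd)) < 5:
        raise EstimationError("NRH fit needs >= 5 distinct light levels")

    low = (pfd > 30) & (pfd <= 250)
    if low.sum() >= 2:
        phi0, neg_rd0 = np.polyfit(pfd[low], a[low], 1)
    else:
        phi0, neg_rd0 = 0.05, 0.0
    rd0 = rd_init if rd_init is not None else max(-neg_rd0, 0.0)
    x0 = np.array([max(phi0, 1e-3), a.max() + rd0 + 1.0, 0.7, rd0])

    def resid(p):
        return nrh_curve(pfd, *p) - a

    sol = least_squares(resid, x0,
                        bounds=([1e-6, 1e-3, 1e-6, -10.0],
                                [1.0, 200.0, 1.0, 20.0]))
    fit = NRHFit(*map(float, sol.x), residual_norm=float(np.linalg.norm(sol.fun)))
    if not sol.success:
        raise EstimationError("NRH fit did not converge", last_iterate=fit)
    return fit


def quantum_yield(a, rd, pfd_abs):
    """Phi_CO2 = (A + Rd) / PFD_abs, in CO2 fixed per absorbed photon."""
    pfd_abs = np.asarray(pfd_abs, dtype=float)
    if np.any(pfd_abs <= 0):
        raise ValueError("absorbed PFD must be positive")
    out = (np.asarray(a, float) + np.asarray(rd, float)) / pfd_abs
    return float(out) if out.ndim == 0 else out


def steady_state_reference(table: LightResponseTable, rd: float,
                           l_abs: float, nrh: NRHFit | None = None,
                           fit: bool = True) -> SteadyStateReference:
    """Extract the 800/100-PFD anchors and their quantum yields.

    ``l_abs`` is the source-weighted scalar absorptance used to convert the
    two incident levels to absorbed PFD. The NRH fit is attached as a
    descriptive output (pass ``fit=False`` to skip it).
    """
    row800 = table.at_level(800.0)
    row100 = table.at_level(100.0)
    if nrh is None and fit:
        try:
            nrh = fit_nrh(table, rd_init=rd)
        except EstimationError as exc:
            warnings.warn(f"NRH fit unavailable: {exc}", stacklevel=2)
            nrh = exc.last_iterate
    return SteadyStateReference(
        a_800=float(row800["a"]), a_100=float(row100["a"]),
        ci_800=float(row800["ci"]), ci_100=float(row100["ci"]),
        rd=float(rd),
        phi_800=quantum_yield(row800["a"], rd, 800.0 * l_abs),
        phi_100=quantum_yield(row100["a"], rd, 100.0 * l_abs),
        nrh=nrh,
    )
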