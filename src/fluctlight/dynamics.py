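"""Storage-flux correction of non-steady gas-exchange measurements.

An open cuvette violates the steady-state assumption of the instrument's
rate equations whenever the sample-cell concentrations are still changing:
gas accumulating in (or draining from) the headspace masquerades as leaf
flux. The correction rests on the ideal-gas mass balance of the cuvette —
the mole count n = PV/RT times the per-log change in mole fraction is the
headspace storage term, which is added back onto the steady-state rates.

Signs follow scientific convention for assimilation: a rising CO2 mole
fraction means the leaf removed less CO2 than the steady-state equation
reports, so the CO2 storage flux carries a negative sign, while the H2O
term is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gasex_io import GasExchangeTrace

R_GAS = 8.314  # molar gas constant, J mol-1 K-1


@dataclass(frozen=True)
class CuvetteConstants:
    """Physical constants of the measuring cuvette."""

    v_cuvette: float = 8.67e-5  # cuvette volume, m3
    r_gas: float = R_GAS

    def __post_init__(self) -> None:
        if self.v_cuvette <= 0:
            raise ValueError("cuvette volume must be positive")


def _mole_count(p, t_k, const: CuvetteConstants):
    """Ideal-gas moles of air in the cuvette headspace."""
    return p * const.v_cuvette / (const.r_gas * t_k)


def storage_flux_co2(p, t_k, delta_co2, dt, s_leaf,
                     const: CuvetteConstants = CuvetteConstants()):
    """Headspace CO2 storage flux in umol m-2 s-1.

    Parameters
    ----------
    p, t_k : cuvette pressure (Pa) and air temperature (K).
    delta_co2 : change in sample CO2 mole fraction since the last log
        (umol mol-1).
    dt : time since the last log (s).
    s_leaf : enclosed leaf area (m2).
    """
    dt = np.asarray(dt, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("dt must be positive")
    if np.any(np.asarray(s_leaf, dtype=float) <= 0):
        raise ValueError("s_leaf must be positive")
    n = _mole_count(np.asarray(p, float), np.asarray(t_k, float), const)
    # n [mol] * delta [umol/mol] = umol stored; per second and leaf area
    return -n * np.asarray(delta_co2, float) / (dt * s_leaf)


def storage_flux_h2o(p, t_k, delta_h2o, dt, s_leaf,
                     const: CuvetteConstants = CuvetteConstants()):
    """Headspace H2O storage flux in mol m-2 s-1.

    ``delta_h2o`` is the change in sample H2O mole fraction (mmol mol-1).
    """
    dt = np.asarray(dt, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("dt must be positive")
    if np.any(np.asarray(s_leaf, dtype=float) <= 0):
        raise ValueError("s_leaf must be positive")
    n = _mole_count(np.asarray(p, float), np.asarray(t_k, float), const)
    # n [mol] * delta*1e-3 [mol/mol] = mol stored
    return n * np.asarray(delta_h2o, float) * 1e-3 / (dt * s_leaf)


def correct_trace(trace: GasExchangeTrace,
                  const: CuvetteConstants = CuvetteConstants(),
                  smooth_width: int = 0) -> GasExchangeTrace:
    """Append dynamics-corrected ``a_dyn``/``e_dyn`` columns to a trace.

    Per record i > 0 the storage fluxes are computed from backward first
    differences of the concentration and time columns (mirroring the
    per-log arithmetic of the instrument); the first record gets zero
    storage flux. ``smooth_width`` > 1 applies a centred boxcar to the
    concentration series before differencing (off by default; no smoothing
    is applied in the reference workflow).
    """
    if len(trace) < 2:
        raise ValueError("correction needs at least two records")
    d = trace.data
    co2 = d["co2_s"].to_numpy(float)
    h2o = d["h2o_s"].to_numpy(float)
    if smooth_width and smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        pad = smooth_width // 2
        co2 = np.convolve(np.pad(co2, pad, mode="edge"), kernel, "valid")[: len(d)]
        h2o = np.convolve(np.pad(h2o, pad, mode="edge"), kernel, "valid")[: len(d)]

    t = d["t_s"].to_numpy(float)
    dt = np.diff(t)
    sf_co2 = storage_flux_co2(
        d["p_air"].to_numpy(float)[1:], d["t_air"].to_numpy(float)[1:],
        np.diff(co2), dt, d["s_leaf"].to_numpy(float)[1:], const)
    sf_h2o = storage_flux_h2o(
        d["p_air"].to_numpy(float)[1:], d["t_air"].to_numpy(float)[1:],
        np.diff(h2o), dt, d["s_leaf"].to_numpy(float)[1:], const)

    out = d.copy()
    out["a_dyn"] = d["a_raw"].to_numpy(float) + np.concatenate(([0.0], sf_co2))
    out["e_dyn"] = d["e_raw"].to_numpy(float) + np.concatenate(([0.0], sf_h2o))
    return GasExchangeTrace(out, trace.meta)
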