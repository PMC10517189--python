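"""Synthetic gas-exchange fixtures with known kinetics.

The generator produces 2-Hz instrument-style traces for the three
phylogenetically paired C3/C4 species comparisons under the standard
fluctuation regimes, plus matching steady-state light-response tables. It
has two layers:

* a phenomenological *leaf*: within each light step the true assimilation
  relaxes exponentially toward the phase's steady-state rate (induction
  time constant ``tau_ind`` on the way up, buffering constant ``tau_buf``
  on the way down, continuous across switches), with optional pulse-shaped
  transients — the C3 post-illumination burst (a dip in the low phase,
  suppressed at 2% O2) and the NAD-ME CO2 gulp/burst at high-light onset.
  The kinetics are shape-level stand-ins for the published descriptions,
  not estimates for any real species;
* a simulated *cuvette*: a first-order mixing chamber with mole count
  n = PV/RT and flow u, integrated by explicit Euler at a 0.05-s internal
  step. Logged ``a_raw`` is back-computed from the steady-state flux
  equation u*(C_ref - C_s)/S, so the dynamic storage-flux correction can
  be validated against the known true assimilation profile.

Default steady-state anchors are the published per-species means at 800
and 100 umol m-2 s-1 PFD under each O2 level; C4 species get a larger
low-phase buffering constant than C3 (30 s vs 5 s) so the generated set
reproduces the qualitative C4-over-C3 ordering of low-phase performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import fsolve
from scipy.signal import lfilter

from .dynamics import CuvetteConstants, R_GAS
from .gasex_io import (GasExchangeTrace, LightRegime, LightResponseTable,
                       SpeciesConfig, TraceMeta)
from .light_response import NRHFit, nrh_curve

#: descending PFD gradient of the steady-state light-response protocol
LIGHT_CURVE_LEVELS = (2000.0, 1700.0, 1500.0, 1200.0, 1000.0, 800.0, 600.0,
                      400.0, 300.0, 200.0, 100.0, 75.0, 30.0, 0.0)

#: default species roster: three C3/C4 pairs spanning the decarboxylase subtypes
SPECIES: dict[str, SpeciesConfig] = {
    "A_semialata_GMT": SpeciesConfig("A_semialata_GMT", "Alloteropsis", "C3"),
    "A_semialata_MDG": SpeciesConfig("A_semialata_MDG", "Alloteropsis", "C4",
                                     subtype="NADP-ME-PEPCK"),
    "F_cronquistii": SpeciesConfig("F_cronquistii", "Flaveria", "C3"),
    "F_bidentis": SpeciesConfig("F_bidentis", "Flaveria", "C4",
                                subtype="NADP-ME"),
    "T_hassleriana": SpeciesConfig("T_hassleriana", "Cleome", "C3"),
    "G_gynandra": SpeciesConfig("G_gynandra", "Cleome", "C4",
                                subtype="NAD-ME"),
}


@dataclass(frozen=True)
class SteadyStateAnchor:
    """Published steady-state means for one species x O2 condition."""

    a_800: float   # umol m-2 s-1
    a_100: float
    ci_800: float  # umol mol-1
    ci_100: float
    rd: float      # umol m-2 s-1


#: (species, o2) -> anchor values the generator is pinned to
ANCHORS: dict[tuple[str, float], SteadyStateAnchor] = {
    ("A_semialata_GMT", 0.21): SteadyStateAnchor(11.3, 3.2, 235, 348, 0.6),
    ("A_semialata_GMT", 0.02): SteadyStateAnchor(15.0, 4.8, 207, 334, 1.5),
    ("A_semialata_MDG", 0.21): SteadyStateAnchor(12.3, 4.7, 265, 349, 1.7),
    ("A_semialata_MDG", 0.02): SteadyStateAnchor(13.1, 4.7, 245, 345, 1.5),
    ("F_cronquistii", 0.21): SteadyStateAnchor(13.8, 3.9, 246, 352, 0.4),
    ("F_cronquistii", 0.02): SteadyStateAnchor(25.0, 6.6, 230, 351, 0.6),
    ("F_bidentis", 0.21): SteadyStateAnchor(18.7, 4.2, 157, 339, 0.8),
    ("F_bidentis", 0.02): SteadyStateAnchor(21.5, 4.7, 182, 343, 0.4),
    ("T_hassleriana", 0.21): SteadyStateAnchor(14.6, 4.1, 281, 363, 1.5),
    ("T_hassleriana", 0.02): SteadyStateAnchor(27.3, 6.2, 266, 358, 2.1),
    ("G_gynandra", 0.21): SteadyStateAnchor(23.5, 3.2, 190, 352, 1.2),
    ("G_gynandra", 0.02): SteadyStateAnchor(27.4, 4.7, 192, 344, 0.8),
}


@dataclass(frozen=True)
class KineticParams:
    """Phenomenological leaf kinetics for one species x O2 condition."""

    a_ss_high: float          # steady A at 800 PFD, umol m-2 s-1
    a_ss_low: float           # steady A at 100 PFD
    tau_ind: float = 15.0     # induction time constant, s
    tau_buf: float = 5.0      # low-phase relaxation constant, s
    pib_amp: float = 0.0      # PIB dip amplitude, umol m-2 s-1
    pib_peak_s: float = 20.0  # PIB dip peak time, s
    gulp_amp: float = 0.0     # NAD-ME high-onset gulp amplitude
    burst_amp: float = 0.0    # NAD-ME high-onset burst amplitude
    gulp_peak_s: float = 3.0
    burst_peak_s: float = 15.0
    noise_sd: float = 0.15    # Gaussian noise on logged a_raw
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau_ind", "tau_buf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pib_amp", "gulp_amp", "burst_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CuvetteSimParams:
    """First-order mixing model of the measuring chamber."""

    flow: float = 600.0       # air flow, umol s-1
    co2_ref: float = 410.0    # reference CO2, umol mol-1
    p_air: float = 101325.0   # Pa
    t_air: float = 298.15     # K
    s_leaf: float = 6e-4      # enclosed leaf area, m2
    sample_hz: float = 2.0
    ode_dt: float = 0.05      # internal Euler step, s
    const: CuvetteConstants = CuvetteConstants()

    def __post_init__(self) -> None:
        for name in ("flow", "co2_ref", "p_air", "t_air", "s_leaf",
                     "sample_hz", "ode_dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def mole_count(self) -> float:
        """n = PV/RT, mol of air in the chamber."""
        return self.p_air * self.const.v_cuvette / (R_GAS * self.t_air)

    @property
    def tau_mix(self) -> float:
        """Chamber turnover time n/u, s."""
        return self.mole_count / (self.flow * 1e-6)


def default_kinetics(species: str, o2: float, seed: int = 0,
                     noise_sd: float = 0.15) -> KineticParams:
    """Default kinetic parameters for a roster species at 0.21 or 0.02 O2.

    The PIB dip is only given to C3 species at ambient O2 (photorespiration
    suppressed at 2%); NAD-ME species get the high-onset gulp/burst pair
    regardless of O2.
    """
    cfg = SPECIES[species]
    anchor = ANCHORS[(species, o2)]
    is_c4 = cfg.pathway == "C4"
    pib = 1.5 if (not is_c4 and not math.isclose(o2, 0.02)) else 0.0
    nad_me = cfg.subtype == "NAD-ME"
    return KineticParams(
        a_ss_high=anchor.a_800, a_ss_low=anchor.a_100,
        tau_ind=40.0 if is_c4 else 15.0,
        tau_buf=30.0 if is_c4 else 5.0,
        pib_amp=pib,
        gulp_amp=2.0 if nad_me else 0.0,
        burst_amp=1.5 if nad_me else 0.0,
        noise_sd=noise_sd, seed=seed)


def _pulse(t, peak_s):
    """Unit-amplitude pulse x*e^(1-x) with its maximum (=1) at t = peak_s."""
    x = np.asarray(t, dtype=float) / peak_s
    return x * np.exp(1.0 - x)


def true_assimilation(t_rel, phase: str, params: KineticParams,
                      a_entry: float) -> np.ndarray:
    """True net assimilation within one light step.

    ``a_entry`` is the leaf's rate at the switch (the exit value of the
    previous step), which makes the profile continuous across switches.
    """
    t = np.asarray(t_rel, dtype=float)
    if phase == "high":
        base = params.a_ss_high + (a_entry - params.a_ss_high) * np.exp(
            -t / params.tau_ind)
        return (base + params.gulp_amp * _pulse(t, params.gulp_peak_s)
                - params.burst_amp * _pulse(t, params.burst_peak_s))
    base = params.a_ss_low + (a_entry - params.a_ss_low) * np.exp(
        -t / params.tau_buf)
    return base - params.pib_amp * _pulse(t, params.pib_peak_s)


def true_profile(regime: LightRegime, params: KineticParams,
                 dt: float = 0.05,
                 a_start: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """True assimilation on a fine grid over the whole treatment.

    ``a_start`` is the rate at treatment start; by default it is the
    acclimation steady state, interpolated linearly in PFD between the two
    phase anchors at the 150 umol m-2 s-1 acclimation intensity.
    """
    if a_start is None:
        frac = ((regime.acclimation_pfd - regime.low_pfd)
                / (regime.high_pfd - regime.low_pfd))
        a_start = params.a_ss_low + frac * (params.a_ss_high - params.a_ss_low)
    n_steps = int(math.ceil(regime.total_s / regime.step_s))
    t_chunks, a_chunks = [], []
    a_entry = a_start
    for k in range(n_steps):
        t0 = k * regime.step_s
        t1 = min((k + 1) * regime.step_s, regime.total_s)
        t_rel = np.arange(0.0, t1 - t0 - dt / 2, dt)
        phase = str(regime.phase_at(t0 + regime.step_s / 2)[()])
        a = true_assimilation(t_rel, phase, params, a_entry)
        t_chunks.append(t_rel + t0)
        a_chunks.append(a)
        a_entry = float(true_assimilation(regime.step_s, phase, params, a_entry))
    return np.concatenate(t_chunks), np.concatenate(a_chunks)


def simulate_cuvette(t_fine: np.ndarray, a_true: np.ndarray,
                     sim: CuvetteSimParams = CuvetteSimParams(),
                     noise_sd: float = 0.0,
                     rng: np.random.Generator | None = None,
                     meta: TraceMeta | None = None) -> GasExchangeTrace:
    """Feed a true assimilation profile through the mixing chamber.

    Integrates n*dC/dt = u*(C_ref - C) - A*S by explicit Euler on the fine
    grid (the grid spacing is the Euler step) and emits records at the
    logging rate. ``a_raw`` is the steady-state flux equation applied to
    the simulated sample concentration, plus optional Gaussian noise.
    """
    dt = float(t_fine[1] - t_fine[0])
    u = sim.flow * 1e-6                      # mol s-1
    n = sim.mole_count
    c_eq = sim.co2_ref - a_true * sim.s_leaf / u   # umol mol-1
    alpha = dt / sim.tau_mix
    if alpha >= 1.0:
        # chamber turns over faster than the integration step: instantaneous
        c_s = c_eq.copy()
    else:
        # Euler recursion C[k+1] = (1-alpha)*C[k] + alpha*c_eq[k] as IIR filter
        zi = np.array([(1.0 - alpha) * c_eq[0]])
        c_s, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], c_eq, zi=zi)
        c_s = np.concatenate(([c_eq[0]], c_s[:-1]))  # C[k] before input k

    stride = max(int(round(1.0 / (sim.sample_hz * dt))), 1)
    idx = np.arange(0, len(t_fine), stride)
    t_log = t_fine[idx]
    c_log = c_s[idx]
    a_raw = u * (sim.co2_ref - c_log) / sim.s_leaf
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        a_raw = a_raw + rng.normal(0.0, noise_sd, size=a_raw.shape)

    m = len(t_log)
    frame = pd.DataFrame({
        "t_s": t_log,
        "pfd_in": np.zeros(m),
        "co2_s": c_log,
        "h2o_s": np.full(m, 20.0),
        "a_raw": a_raw,
        "e_raw": np.full(m, 2e-3),
        "ci": np.full(m, 300.0),
        "gsw": np.full(m, 0.2),
        "p_air": np.full(m, sim.p_air),
        "t_air": np.full(m, sim.t_air),
        "flow": np.full(m, sim.flow),
        "s_leaf": np.full(m, sim.s_leaf),
    })
    return GasExchangeTrace(frame, meta or TraceMeta())


def generate_trace(species: SpeciesConfig | str, regime: LightRegime,
                   o2: float, params: KineticParams | None = None,
                   sim: CuvetteSimParams = CuvetteSimParams(),
                   replicate: int = 0,
                   regime_id: str = "") -> GasExchangeTrace:
    """Generate one full fluctuating-light trace through the cuvette model.

    Reproducible under a fixed ``params.seed``; replicate-to-replicate
    variation comes from the noise stream only (seed offset by replicate).
    """
    if isinstance(species, str):
        species = SPECIES[species]
    if params is None:
        params = default_kinetics(species.name, o2)
    rng = np.random.default_rng(int(params.seed) + 1000003 * replicate)
    t_fine, a_true = true_profile(regime, params, dt=sim.ode_dt)
    meta = TraceMeta(species=species.name, o2=o2,
                     regime=regime_id or f"step{regime.step_s:g}",
                     replicate=replicate)
    trace = simulate_cuvette(t_fine, a_true, sim, noise_sd=params.noise_sd,
                             rng=rng, meta=meta)
    # smooth placeholders for columns no analysis consumes quantitatively
    anchor = ANCHORS.get((species.name, o2))
    ci0 = anchor.ci_100 if anchor else 300.0
    t_log = trace.data["t_s"].to_numpy()
    trace.data["pfd_in"] = regime.pfd_at(t_log)
    trace.data["ci"] = ci0 - 0.005 * t_log / 60.0
    trace.data["gsw"] = 0.2 + 0.0005 * np.sin(2 * np.pi * t_log / 3600.0)
    return trace


def nrh_through_anchors(anchor: SteadyStateAnchor,
                        theta: float = 0.9) -> NRHFit:
    """NRH parameters that pass exactly through the 800/100-PFD anchors.

    phi and Amax are solved so the curve (with the anchor's Rd and the
    given curvature) reproduces a_800 and a_100 at the incident levels.
    The default curvature of 0.9 keeps the sub-200-PFD limb close to
    linear, as in healthy leaves; lower curvatures make the intercept-based
    Rd regression markedly biased on these synthetic curves.
    """
    def eqs(x):
        phi, a_max = x
        return (nrh_curve(800.0, phi, a_max, theta, anchor.rd) - anchor.a_800,
                nrh_curve(100.0, phi, a_max, theta, anchor.rd) - anchor.a_100)

    phi0 = (anchor.a_100 + anchor.rd) / 100.0 * 1.1
    x, info, ok, msg = fsolve(eqs, x0=[phi0, anchor.a_800 + anchor.rd + 3.0],
                              full_output=True)
    if ok != 1:
        raise RuntimeError(f"could not anchor NRH curve: {msg}")
    return NRHFit(phi=float(x[0]), a_max=float(x[1]), theta=theta,
                  rd=anchor.rd)


def generate_light_curve(species: SpeciesConfig | str, o2: float,
                         nrh: NRHFit | None = None, noise_sd: float = 0.0,
                         seed: int = 0,
                         replicate: int = 0) -> LightResponseTable:
    """14-level steady-state light-response table from an NRH form.

    Without an explicit ``nrh`` the curve is anchored to the published
    per-species steady-state means, so a(800) and a(100) match the anchors
    up to the requested noise.
    """
    if isinstance(species, str):
        species = SPECIES[species]
    anchor = ANCHORS.get((species.name, o2))
    if nrh is None:
        if anchor is None:
            raise ValueError(f"no anchors for {species.name} at O2={o2}")
        nrh = nrh_through_anchors(anchor)
    rng = np.random.default_rng(int(seed) + 1000003 * replicate)
    levels = np.array(LIGHT_CURVE_LEVELS)
    a = nrh_curve(levels, nrh.phi, nrh.a_max, nrh.theta, nrh.rd)
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    ci_hi = anchor.ci_800 if anchor else 250.0
    ci_lo = anchor.ci_100 if anchor else 350.0
    ci = ci_lo + (ci_hi - ci_lo) * levels / levels.max()
    frame = pd.DataFrame({
        "pfd_in": levels,
        "a": a,
        "ci": ci,
        "gsw": 0.15 + 0.1 * levels / levels.max(),
    })
    meta = TraceMeta(species=species.name, o2=o2, regime="lrc",
                     replicate=replicate)
    return LightResponseTable(frame, meta)


def periodic_low_phase_mean(regime: LightRegime,
                            params: KineticParams) -> float:
    """Closed-form mean relative assimilation (%) of the low phase in the
    periodic steady state of the two-exponential leaf (no pulses, no noise).

    With d the step duration, the periodic entry rate into the high phase
    solves x = aL + (aH + (x - aH)e_i - aL)e_b; the low-phase mean is then
    aL + c*tau_buf*(1 - e_b)/d with c the low-phase entry excess. Used as
    the independent oracle for end-to-end parameter recovery.
    """
    d = regime.step_s
    aH, aL = params.a_ss_high, params.a_ss_low
    ei = math.exp(-d / params.tau_ind)
    eb = math.exp(-d / params.tau_buf)
    x = (aL * (1 - eb) + aH * eb * (1 - ei)) / (1 - ei * eb)  # enter high
    y = aH + (x - aH) * ei                                    # enter low
    mean_low = aL + (y - aL) * params.tau_buf * (1 - eb) / d
    return 100.0 * mean_low / aL
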