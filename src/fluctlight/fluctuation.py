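"""Fluctuating-light trace segmentation and performance metrics.

The analysis takes a dynamics-corrected trace, keeps the final ten minutes
of the one-hour treatment (so initial induction is excluded), cuts it into
the commanded high/low light steps, and computes per phase:

* assimilation relative to the matching steady-state rate (in % of the
  800- or 100-PFD steady-state value), averaged as a trapezoidal area
  under the curve divided by the step duration;
* the quantum yield Phi_CO2 over the step, from the same AUC averaging;
* for 30-s and 300-s steps, the relative assimilation restricted to the
  post-illumination burst (PIB) window of the low phase (10-30 s and
  10-70 s after the switch); 6-s steps are too short to express a PIB;
* the decoupling excess, i.e. how far the low-phase quantum yield exceeds
  the pathway's theoretical maximum (positive values indicate CO2 fixation
  decoupled from concurrent photochemistry).

Segmentation trusts the commanded light program rather than the measured
PFD — 2-Hz logs straddle switches — but warns when the measured PFD
contradicts the commanded phase for more than 10% of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, ValidationError
from .gasex_io import GasExchangeTrace, LightRegime, SpeciesConfig
from .light_response import SteadyStateReference, quantum_yield
from .radiometry import source_weighted_absorptance

#: analysis window of the one-hour treatment, seconds from treatment start
WINDOW_START_S = 3000.0
WINDOW_END_S = 3600.0

#: PIB window (s after the high->low switch) per step duration
PIB_WINDOWS = {30.0: (10.0, 30.0), 300.0: (10.0, 70.0)}


@dataclass
class LightStep:
    """Samples of one commanded light step.

    ``t_rel`` is the time since the switch; samples are assigned by the
    half-open interval [switch, switch + step_s), except that a sample
    falling exactly on the closing switch is appended (t_rel = step_s) so
    trapezoidal integration covers the full step span.
    """

    index: int
    phase: str          # "high" | "low"
    t_start: float
    t_end: float
    t_rel: np.ndarray
    a_dyn: np.ndarray
    pfd_in: np.ndarray


@dataclass(frozen=True)
class FluctuationMetrics:
    """Per trace summary of fluctuating-light performance."""

    rel_a_mean_high: float      # % of steady state at 800 PFD
    rel_a_mean_low: float       # % of steady state at 100 PFD
    phi_mean_high: float        # CO2/photon
    phi_mean_low: float         # CO2/photon
    pib_rel_a: float | None     # % of steady state over the PIB window
    decoupling_excess: float    # phi_mean_low - phi_max, signed


def analysis_window(trace: GasExchangeTrace, start_s: float = WINDOW_START_S,
                    end_s: float = WINDOW_END_S) -> GasExchangeTrace:
    """Return the records with start_s <= t < end_s.

    The trace must span the window at its own sampling resolution; a trace
    ending more than one sample interval before ``end_s`` is rejected.
    Windowing an already-windowed trace is a no-op.
    """
    t = trace.t
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    if t[-1] < end_s - dt - 1e-9:
        raise ValidationError(
            f"trace ends at {t[-1]:g} s, cannot cover window [{start_s:g}, {end_s:g})")
    mask = (t >= start_s) & (t < end_s)
    if not mask.any():
        raise ValidationError("analysis window contains no samples")
    return GasExchangeTrace(trace.data[mask].reset_index(drop=True), trace.meta)


def segment_steps(trace: GasExchangeTrace, regime: LightRegime,
                  a_col: str = "a_dyn") -> list[LightStep]:
    """Cut a (windowed) trace into commanded light steps.

    Step boundaries fall every ``regime.step_s`` seconds from treatment
    start (t = 0); trailing partial steps are truncated. Requires the
    dynamics-corrected assimilation column.
    """
    if a_col not in trace.data.columns:
        raise ValidationError(
            f"trace lacks {a_col!r}; run the dynamic correction first")
    t = trace.t
    a = trace.data[a_col].to_numpy(float)
    pfd = trace.data["pfd_in"].to_numpy(float)
    d = regime.step_s

    commanded = regime.pfd_at(t)
    mismatch = np.mean(np.abs(pfd - commanded) > 0.5 * abs(
        regime.high_pfd - regime.low_pfd))
    if mismatch > 0.10:
        warnings.warn(
            f"measured PFD contradicts the commanded program for "
            f"{100 * mismatch:.0f}% of samples", stacklevel=2)

    dt_sample = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    k_first = int(np.ceil(t[0] / d - 1e-9))
    # a step counts as complete when its samples reach to within one
    # sampling interval of the closing switch
    k_last = int(np.floor((t[-1] + dt_sample + 1e-9) / d))
    steps: list[LightStep] = []
    for k in range(k_first, k_last):
        lo, hi = k * d, (k + 1) * d
        sel = (t >= lo - 1e-9) & (t < hi - 1e-9)
        closing = np.abs(t - hi) <= 1e-9
        idx = np.nonzero(sel | closing)[0]
        if idx.size == 0:
            continue
        phase = str(regime.phase_at(lo + d / 2)[()])
        steps.append(LightStep(
            index=k, phase=phase, t_start=lo, t_end=hi,
            t_rel=t[idx] - lo, a_dyn=a[idx], pfd_in=pfd[idx]))
    return steps


def relative_assimilation(step: LightStep,
                          ref: SteadyStateReference) -> np.ndarray:
    """Pointwise assimilation as % of the phase's steady-state rate."""
    a_ss = ref.a_800 if step.phase == "high" else ref.a_100
    if a_ss <= 0:
        raise ValueError("steady-state reference rate must be positive")
    return 100.0 * step.a_dyn / a_ss


def auc_mean(t, y) -> float:
    """Trapezoidal integral over the observed span, divided by the span."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 2:
        raise EstimationError("AUC mean needs at least two samples")
    span = t[-1] - t[0]
    if span <= 0:
        raise EstimationError("samples must span a positive interval")
    return float(np.trapezoid(y, t) / span)


def pib_window_metric(steps: list[LightStep], ref: SteadyStateReference,
                      step_s: float) -> float | None:
    """Mean relative assimilation over the PIB window of the low steps.

    Returns ``None`` for 6-s steps, where the treatment is too short for
    the burst to be expressed.
    """
    if step_s not in PIB_WINDOWS:
        return None
    lo, hi = PIB_WINDOWS[step_s]
    means = []
    for step in steps:
        if step.phase != "low":
            continue
        mask = (step.t_rel >= lo) & (step.t_rel < hi)
        if mask.sum() < 2:
            continue
        means.append(auc_mean(step.t_rel[mask],
                              relative_assimilation(step, ref)[mask]))
    if not means:
        raise EstimationError("no low step covered the PIB window")
    return float(np.mean(means))


def decoupling_excess(phi_mean: float, phi_max: float) -> float:
    """Signed excess of the observed quantum yield over the theoretical
    maximum; positive values are conservative evidence of decoupling."""
    if phi_mean <= 0 or phi_max <= 0:
        raise ValueError("quantum yields must be positive")
    return phi_mean - phi_max


def _phase_means(steps, ref, l_abs, high_pfd, low_pfd):
    rel = {"high": [], "low": []}
    phi = {"high": [], "low": []}
    for step in steps:
        if step.t_rel.size < 2:
            continue
        pfd_abs = (high_pfd if step.phase == "high" else low_pfd) * l_abs
        rel[step.phase].append(
            auc_mean(step.t_rel, relative_assimilation(step, ref)))
        phi[step.phase].append(
            auc_mean(step.t_rel, quantum_yield(step.a_dyn, ref.rd, pfd_abs)))
    return rel, phi


def summarize(trace: GasExchangeTrace, ref: SteadyStateReference,
              regime: LightRegime, species: SpeciesConfig) -> FluctuationMetrics:
    """Window, segment and summarise one corrected fluctuating-light trace.

    Per-step AUC means are averaged (unweighted) across the steps of each
    phase inside the analysis window; the quantum yield uses the commanded
    phase PFD converted to absorbed PFD with the species' source-weighted
    absorptance and the matching-O2 Rd of the reference.
    """
    l_abs = source_weighted_absorptance(species.l_abs_red, species.l_abs_blue)
    windowed = analysis_window(trace)
    steps = segment_steps(windowed, regime)
    rel, phi = _phase_means(steps, ref, l_abs, regime.high_pfd, regime.low_pfd)
    if not rel["high"] or not rel["low"]:
        raise ValidationError("analysis window lacks complete steps of both phases")
    phi_low = float(np.mean(phi["low"]))
    pib = pib_window_metric(steps, ref, regime.step_s)
    return FluctuationMetrics(
        rel_a_mean_high=float(np.mean(rel["high"])),
        rel_a_mean_low=float(np.mean(rel["low"])),
        phi_mean_high=float(np.mean(phi["high"])),
        phi_mean_low=phi_low,
        pib_rel_a=pib,
        decoupling_excess=decoupling_excess(phi_low, species.phi_max),
    )


def relative_series(trace: GasExchangeTrace, ref: SteadyStateReference,
                    regime: LightRegime) -> pd.DataFrame:
    """Tidy pointwise relative-assimilation series for the analysis window."""
    windowed = analysis_window(trace)
    steps = segment_steps(windowed, regime)
    frames = []
    for step in steps:
        frames.append(pd.DataFrame({
            "step_index": step.index,
            "phase": step.phase,
            "t_rel": step.t_rel,
            "t_s": step.t_rel + step.t_start,
            "a_dyn": step.a_dyn,
            "rel_a_pct": relative_assimilation(step, ref),
        }))
    return pd.concat(frames, ignore_index=True)
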