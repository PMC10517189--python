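"""Windowing, segmentation, AUC means and fluctuation metrics."""

import numpy as np
import pandas as pd
import pytest

from fluctlight.errors import EstimationError, ValidationError
from fluctlight.fluctuation import (LightStep, analysis_window, auc_mean,
                                    decoupling_excess, pib_window_metric,
                                    relative_assimilation, segment_steps,
                                    summarize)
from fluctlight.gasex_io import GasExchangeTrace, LightRegime, SpeciesConfig

from conftest import trace_frame


def flat_trace(n=7200, dt=0.5, a=4.0, regime=None):
    t = np.arange(n) * dt
    pfd = regime.pfd_at(t) if regime else np.full(n, 100.0)
    frame = trace_frame(n=n, t_s=t, pfd_in=pfd,
                        a_raw=np.full(n, float(a)))
    frame["a_dyn"] = frame["a_raw"]
    return GasExchangeTrace(frame)


def test_window_keeps_last_ten_minutes():
    windowed = analysis_window(flat_trace())
    assert len(windowed) == 1200
    assert windowed.t[0] >= 3000.0
    assert windowed.t[-1] < 3600.0


def test_window_rejects_short_trace():
    with pytest.raises(ValidationError):
        analysis_window(flat_trace(n=7198))  # ends at 3598.5 s


def test_window_is_idempotent():
    once = analysis_window(flat_trace())
    twice = analysis_window(once)
    pd.testing.assert_frame_equal(once.data, twice.data)


@pytest.mark.parametrize("step_s, expected", [(300.0, 2), (30.0, 20), (6.0, 100)])
def test_segment_counts(step_s, expected):
    regime = LightRegime(step_s=step_s)
    trace = analysis_window(flat_trace(regime=regime))
    steps = segment_steps(trace, regime)
    assert len(steps) == expected
    phases = [s.phase for s in steps]
    assert all(a != b for a, b in zip(phases, phases[1:]))  # strict alternation


def test_first_sample_after_switch_convention():
    regime = LightRegime(step_s=30.0)
    steps = segment_steps(analysis_window(flat_trace(regime=regime)), regime)
    for step in steps:
        assert step.t_rel[0] >= 0.0
        assert step.t_rel[0] < 0.5  # within one sampling interval


def test_segment_warns_on_pfd_program_mismatch():
    regime = LightRegime(step_s=30.0)
    trace = analysis_window(flat_trace(regime=regime))
    trace.data["pfd_in"] = 100.0  # contradicts every high step
    with pytest.warns(UserWarning, match="commanded program"):
        segment_steps(trace, regime)


def make_step(t, a, phase="low"):
    t = np.asarray(t, dtype=float)
    a = np.asarray(a, dtype=float)
    return LightStep(index=0, phase=phase, t_start=0.0, t_end=t[-1],
                     t_rel=t, a_dyn=a, pfd_in=np.full(t.size, 100.0))


def test_relative_assimilation_values(reference):
    step = make_step([0, 1, 2], [4.0, 6.0, -2.0])
    rel = relative_assimilation(step, reference)  # a_100 = 4
    np.testing.assert_allclose(rel, [100.0, 150.0, -50.0])


def test_relative_assimilation_uses_phase_reference(reference):
    step = make_step([0, 1], [12.0, 12.0], phase="high")  # a_800 = 12
    np.testing.assert_allclose(relative_assimilation(step, reference),
                               [100.0, 100.0])


def test_auc_mean_constant_and_ramp():
    t = np.linspace(0.0, 30.0, 61)
    assert auc_mean(t, np.full_like(t, 7.0)) == pytest.approx(7.0)
    assert auc_mean(t, np.linspace(0.0, 10.0, 61)) == pytest.approx(5.0)


def test_auc_mean_irregular_matches_fine_grid():
    rng = np.random.default_rng(3)
    t = np.sort(rng.uniform(0.0, np.pi, 400))
    t[0], t[-1] = 0.0, np.pi
    coarse = auc_mean(t, np.sin(t))
    fine = np.linspace(0.0, np.pi, 200001)
    oracle = np.trapezoid(np.sin(fine), fine) / np.pi
    assert abs(coarse - oracle) / oracle < 1e-3


def test_auc_mean_needs_two_samples():
    with pytest.raises(EstimationError):
        auc_mean([1.0], [2.0])


def test_pib_window_not_applicable_for_six_second_steps(reference):
    assert pib_window_metric([], reference, 6.0) is None


def test_pib_window_flat_trace_is_100(reference):
    t = np.arange(0.0, 30.0, 0.5)
    steps = [make_step(t, np.full_like(t, 4.0))]
    assert pib_window_metric(steps, reference, 30.0) == pytest.approx(100.0)


def test_pib_dip_lowers_window_mean(reference):
    t = np.arange(0.0, 30.0, 0.5)
    dip = 1.5 * (t / 20.0) * np.exp(1 - t / 20.0)  # peak at 20 s
    steps = [make_step(t, 4.0 - dip)]
    window = pib_window_metric(steps, reference, 30.0)
    whole = auc_mean(t, relative_assimilation(steps[0], reference))
    assert window < whole


@pytest.mark.parametrize("phi_mean, phi_max, expected", [
    (0.064, 0.064, 0.0),
    (0.155, 0.064, 0.091),
    (0.050, 0.064, -0.014),
])
def test_decoupling_excess(phi_mean, phi_max, expected):
    assert decoupling_excess(phi_mean, phi_max) == pytest.approx(expected)


def test_decoupling_invariant_to_joint_rescale(reference):
    # scaling A and PFD_abs together leaves the yield, hence the excess, fixed
    a, rd, pfd = 6.0, 1.0, 85.0
    phi1 = (a + rd) / pfd
    phi2 = (3 * a + 3 * rd) / (3 * pfd)
    assert decoupling_excess(phi1, 0.064) == pytest.approx(
        decoupling_excess(phi2, 0.064))


def test_summarize_steady_trace_pinned_at_reference():
    # a genuinely steady trace (both phase references equal) is exactly 100%
    from fluctlight.light_response import SteadyStateReference
    ref = SteadyStateReference(a_800=6.0, a_100=6.0, ci_800=250.0,
                               ci_100=340.0, rd=1.0, phi_800=0.0,
                               phi_100=0.0)
    regime = LightRegime(step_s=30.0)
    t = np.arange(7200) * 0.5
    frame = trace_frame(n=7200, t_s=t, pfd_in=regime.pfd_at(t),
                        a_raw=np.full(7200, 6.0))
    frame["a_dyn"] = frame["a_raw"]
    species = SpeciesConfig("demo", "g", "C4", subtype="NADP-ME",
                            l_abs_red=1.0, l_abs_blue=1.0)
    m = summarize(GasExchangeTrace(frame), ref, regime, species)
    assert m.rel_a_mean_high == pytest.approx(100.0)
    assert m.rel_a_mean_low == pytest.approx(100.0)
    assert m.phi_mean_low == pytest.approx((6.0 + ref.rd) / 100.0)
    assert m.pib_rel_a == pytest.approx(100.0)
    assert m.decoupling_excess == pytest.approx(m.phi_mean_low - 0.064)


def test_summarize_square_wave_pinned_per_phase(reference):
    # with distinct phase references a discontinuous square wave is 100%
    # up to the single boundary-straddling sample per step
    regime = LightRegime(step_s=30.0)
    t = np.arange(7200) * 0.5
    pfd = regime.pfd_at(t)
    a = np.where(pfd == 800.0, reference.a_800, reference.a_100)
    frame = trace_frame(n=7200, t_s=t, pfd_in=pfd, a_raw=a)
    frame["a_dyn"] = frame["a_raw"]
    species = SpeciesConfig("demo", "g", "C4", subtype="NADP-ME",
                            l_abs_red=1.0, l_abs_blue=1.0)
    m = summarize(GasExchangeTrace(frame), reference, regime, species)
    assert m.rel_a_mean_high == pytest.approx(100.0, rel=0.01)
    assert m.rel_a_mean_low == pytest.approx(100.0, rel=0.02)
    assert m.pib_rel_a == pytest.approx(100.0)


def test_mean_of_relative_equals_relative_of_mean(reference):
    # with a constant per-phase reference the two orders of operation agree
    rng = np.random.default_rng(5)
    t = np.arange(0.0, 30.0, 0.5)
    a = 4.0 + rng.normal(0, 0.5, t.size)
    step = make_step(t, a)
    lhs = auc_mean(t, relative_assimilation(step, reference))
    rhs = 100.0 * auc_mean(t, a) / reference.a_100
    assert lhs == pytest.approx(rhs, rel=1e-12)


def test_summarize_requires_corrected_column(reference):
    regime = LightRegime(step_s=30.0)
    t = np.arange(7200) * 0.5
    frame = trace_frame(n=7200, t_s=t, pfd_in=regime.pfd_at(t))
    trace = GasExchangeTrace(frame)  # no a_dyn column
    species = SpeciesConfig("demo", "g", "C3")
    with pytest.raises(ValidationError, match="a_dyn"):
        summarize(trace, reference, regime, species)
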