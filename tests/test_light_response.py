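"""Day-respiration regression, NRH fitting and quantum yields."""

import numpy as np
import pandas as pd
import pytest

from fluctlight.errors import EstimationError, ValidationError
from fluctlight.gasex_io import LightResponseTable
from fluctlight.light_response import (estimate_rd, fit_nrh, nrh_curve,
                                       quantum_yield,
                                       steady_state_reference)

from conftest import make_light_response


def linear_table(slope=0.05, rd=1.2, levels=(75, 100, 200), extra=None):
    levels = list(levels) + list(extra or [])
    levels = np.asarray(levels, dtype=float)
    a = slope * levels - rd
    if extra:
        # plant outliers at the Kok-region levels
        a[-len(extra):] = -5.0
    frame = pd.DataFrame({"pfd_in": levels, "a": a,
                          "ci": 300.0, "gsw": 0.2})
    return LightResponseTable(frame)


def test_rd_from_noiseless_line():
    assert estimate_rd(linear_table()) == pytest.approx(1.2)


def test_rd_ignores_kok_region_outliers():
    table = linear_table(extra=[0.0, 30.0])
    assert estimate_rd(table) == pytest.approx(1.2)


def test_rd_on_noisy_line_seeded():
    rng = np.random.default_rng(7)
    levels = np.array([75.0, 100.0, 200.0])
    frame = pd.DataFrame({
        "pfd_in": levels,
        "a": 0.05 * levels - 1.2 + rng.normal(0, 0.1, 3),
        "ci": 300.0, "gsw": 0.2})
    rd = estimate_rd(LightResponseTable(frame))
    assert abs(rd - 1.2) < 0.15


def test_rd_needs_two_usable_points():
    with pytest.raises(EstimationError):
        estimate_rd(linear_table(levels=(100,)))


def test_negative_rd_warns_not_clamps():
    table = linear_table(rd=-0.5)
    with pytest.warns(UserWarning, match="negative Rd"):
        rd = estimate_rd(table)
    assert rd == pytest.approx(-0.5)


def test_rd_recovery_on_quasi_linear_nrh_curve():
    # when phi*200 << A_max the sub-inflection limb is effectively linear
    # and the intercept regression recovers Rd closely
    table = make_light_response(phi=0.01, a_max=50.0, theta=0.7, rd=1.0)
    assert estimate_rd(table) == pytest.approx(1.0, rel=0.05)


def test_nrh_noiseless_self_consistency():
    truth = dict(phi=0.06, a_max=25.0, theta=0.7, rd=1.0)
    fit = fit_nrh(make_light_response(**truth))
    for name, value in truth.items():
        assert getattr(fit, name) == pytest.approx(value, rel=1e-4)


def test_nrh_blackman_limit():
    # theta = 1 collapses the hyperbola to min(phi*I, Amax) - Rd exactly
    pfd = np.array([0.0, 100.0, 300.0, 417.0, 500.0, 2000.0])
    got = nrh_curve(pfd, 0.06, 25.0, 1.0, 1.0)
    expected = np.minimum(0.06 * pfd, 25.0) - 1.0
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_nrh_rectangular_limit():
    # theta -> 0 approaches phi*I*Amax/(phi*I + Amax) - Rd
    pfd = np.array([0.0, 50.0, 200.0, 800.0, 2000.0])
    rect = 0.06 * pfd * 25.0 / (0.06 * pfd + 25.0) - 1.0
    np.testing.assert_allclose(nrh_curve(pfd, 0.06, 25.0, 0.0, 1.0), rect,
                               atol=1e-12)
    np.testing.assert_allclose(nrh_curve(pfd, 0.06, 25.0, 1e-5, 1.0), rect,
                               atol=1e-3)


def test_nrh_refit_with_on_curve_point_does_not_worsen():
    table = make_light_response(noise_sd=0.3, seed=11)
    fit = fit_nrh(table)
    new_pfd = 900.0
    new_a = nrh_curve(new_pfd, fit.phi, fit.a_max, fit.theta, fit.rd)
    extended = LightResponseTable(pd.concat([
        table.data,
        pd.DataFrame({"pfd_in": [new_pfd], "a": [new_a], "ci": [300.0],
                      "gsw": [0.2]})], ignore_index=True))
    refit = fit_nrh(extended)
    assert refit.residual_norm <= fit.residual_norm + 1e-8


@pytest.mark.parametrize("a, rd, pfd_abs, expected", [
    (-1.0, 1.0, 100.0, 0.0),     # compensation point
    (5.0, 1.0, 100.0, 0.06),
    (5.0, 1.0, 200.0, 0.03),     # doubling PFD_abs halves the yield
])
def test_quantum_yield(a, rd, pfd_abs, expected):
    assert quantum_yield(a, rd, pfd_abs) == pytest.approx(expected)


def test_quantum_yield_rejects_nonpositive_pfd():
    with pytest.raises(ValueError):
        quantum_yield(5.0, 1.0, 0.0)


def test_steady_state_reference_yields():
    table = make_light_response()
    a800 = table.at_level(800.0)["a"]
    a100 = table.at_level(100.0)["a"]
    ref = steady_state_reference(table, rd=0.6, l_abs=1.0, fit=False)
    assert ref.phi_800 == pytest.approx((a800 + 0.6) / 800.0)
    assert ref.phi_100 == pytest.approx((a100 + 0.6) / 100.0)
    # published-style arithmetic: a=11.3/3.2 with rd=0.6 at full absorptance
    assert quantum_yield(11.3, 0.6, 800.0) == pytest.approx(0.0149, abs=5e-5)
    assert quantum_yield(3.2, 0.6, 100.0) == pytest.approx(0.038, abs=5e-4)


def test_steady_state_reference_requires_800():
    table = make_light_response()
    trimmed = LightResponseTable(
        table.data[table.data["pfd_in"] != 800.0].reset_index(drop=True))
    with pytest.raises(ValidationError):
        steady_state_reference(trimmed, rd=0.6, l_abs=1.0, fit=False)


def test_yield_linearity_in_assimilation():
    table = make_light_response()
    ref = steady_state_reference(table, rd=0.0, l_abs=1.0, fit=False)
    doubled = LightResponseTable(table.data.assign(a=2 * table.data["a"]))
    ref2 = steady_state_reference(doubled, rd=0.0, l_abs=1.0, fit=False)
    assert ref2.phi_800 == pytest.approx(2 * ref.phi_800)
    assert ref2.phi_100 == pytest.approx(2 * ref.phi_100)


def test_low_light_yield_exceeds_high_light_on_concave_curve():
    # concave (theta > 0) light response with rd >= 0 has phi_100 >= phi_800
    for theta in (0.3, 0.7, 0.95):
        table = make_light_response(theta=theta)
        ref = steady_state_reference(table, rd=1.0, l_abs=0.85, fit=False)
        assert ref.phi_100 >= ref.phi_800
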