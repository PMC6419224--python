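"""Continuous and discrete-lattice persistence-length theory."""

import math

import numpy as np
import pytest

from semiflex.potentials import PotentialSpec
from semiflex.theory import (
    fit_exponential_law,
    fit_power_law,
    lp_kuhn,
    lp_log,
    mean_cos_continuous,
    mean_cos_discrete,
    mean_cos_quadrature,
    solve_k_for_lp,
    theoretical_lp_curve,
)


@pytest.mark.parametrize("k", [0.1, 1.0, 5.0, 10.0, 50.0, 100.0])
@pytest.mark.parametrize("form", ["CA", "CSA"])
def test_closed_forms_match_quadrature(form, k):
    """The analytic Boltzmann averages agree with adaptive quadrature to 1e-8."""
    spec = PotentialSpec(form, k)
    if form == "CA":
        energy = lambda t: k * (1.0 - math.cos(t))
    else:
        energy = lambda t: k * (1.0 - math.cos(t)) ** 2
    assert mean_cos_continuous(spec) == pytest.approx(
        mean_cos_quadrature(energy), abs=1e-8
    )


def test_quadrature_of_zero_energy_is_isotropic():
    assert mean_cos_quadrature(lambda t: 0.0) == pytest.approx(0.0, abs=1e-12)


def test_quadrature_rejects_nonfinite_energy():
    with pytest.raises(ValueError, match="non-finite"):
        mean_cos_quadrature(lambda t: math.inf)


@pytest.mark.parametrize(
    "form, k, expected",
    [
        ("CA", 0.0, 0.0),
        ("CA", 1.0, 0.3130),  # quadrature of the Boltzmann average
        ("CSA", 1.0, 0.4435),
    ],
)
def test_mean_cos_reference_values(form, k, expected):
    assert mean_cos_continuous(PotentialSpec(form, k)) == pytest.approx(
        expected, abs=5e-5
    )


def test_small_k_series_is_continuous():
    # the series branch must join the closed form smoothly
    for form, slope in (("CA", 1 / 3), ("CSA", 2 / 3)):
        below = mean_cos_continuous(PotentialSpec(form, 9e-4))
        above = mean_cos_continuous(PotentialSpec(form, 1.1e-3))
        assert below == pytest.approx(slope * 9e-4, rel=1e-3)
        assert above == pytest.approx(slope * 1.1e-3, rel=1e-3)


@pytest.mark.parametrize("form, asym", [("CA", lambda k: k),
                                        ("CSA", lambda k: math.sqrt(math.pi * k))])
@pytest.mark.parametrize("k", [100.0, 1000.0, 10000.0])
def test_stiff_limit_asymptotes(form, asym, k):
    """l_p/l approaches k (CA) and sqrt(pi k) (CSA) in the stiff regime.

    The Kuhn-length relation carries an exact -1/2 offset against the
    leading asymptote (lp/l = k - 1/2 resp. sqrt(pi k) - 1/2), so the
    relative deviation from the bare power law shrinks like 1/asymptote.
    """
    lp = lp_kuhn(mean_cos_continuous(PotentialSpec(form, k)))
    assert lp == pytest.approx(asym(k) - 0.5, rel=0.01)
    assert abs(lp - asym(k)) / asym(k) < 0.6 / asym(k) + 0.01


def test_kuhn_formula_values_and_errors():
    assert lp_kuhn(0.0, 2.0) == pytest.approx(1.0)
    assert lp_kuhn(1 / 3, 1.0) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="infinite"):
        lp_kuhn(1.0)


def test_log_formula_values_and_errors():
    assert lp_log(math.exp(-1.0), 2.0) == pytest.approx(2.0)
    assert lp_log(math.exp(-2.0), 1.0) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        lp_log(0.0)
    with pytest.raises(ValueError):
        lp_log(-0.2)


def test_kuhn_and_log_agree_for_stiff_chains():
    for k in (15.0, 40.0, 100.0):
        c = mean_cos_continuous(PotentialSpec("CA", k))
        a, b = lp_kuhn(c), lp_log(c)
        if a > 10:
            assert abs(a - b) / a < 0.01


def test_discrete_sclm_closed_form(sclm_angles):
    """The two-class cubic-lattice average is 1 / (1 + 4 exp(-k))."""
    for k in (0.0, 1.0, 3.0, 10.0):
        got = mean_cos_discrete(sclm_angles, PotentialSpec("CA", k))
        assert got == pytest.approx(1.0 / (1.0 + 4.0 * math.exp(-k)), rel=1e-12)
    assert mean_cos_discrete(sclm_angles, PotentialSpec("CA", 0.0)) == pytest.approx(0.2)


@pytest.mark.parametrize("model", ["BFM", "LBFM", "SCLM"])
def test_discrete_zero_stiffness_is_a_priori_mean(model):
    from semiflex.lattice import enumerate_angle_classes

    dist = enumerate_angle_classes(model)
    got = mean_cos_discrete(dist, PotentialSpec("CSA", 0.0))
    assert got == pytest.approx(dist.a_priori_mean_cos(), rel=1e-12)


@pytest.mark.parametrize("model", ["continuous", "BFM", "LBFM", "SCLM"])
@pytest.mark.parametrize("form", ["CA", "CSA"])
def test_theory_curves_strictly_increase(model, form):
    grid = np.linspace(0.5, 25.0, 12)
    curve = theoretical_lp_curve(model, form, grid)
    assert np.all(np.diff(curve.mean_cos) > 0)
    assert np.all(np.diff(curve.lp_over_l) > 0)


def test_bfm_discrete_matches_continuous_at_low_k():
    """Below k ~ 15 the 87-angle lattice average tracks the continuous theory.

    The window starts at k = 2: below that the persistence length is under a
    bond length and the relative comparison is dominated by the different
    a-priori measures rather than by stiffness.
    """
    grid = np.linspace(2.0, 14.0, 13)
    cont = theoretical_lp_curve("continuous", "CA", grid)
    disc = theoretical_lp_curve("BFM", "CA", grid)
    rel = np.abs(disc.lp_over_l - cont.lp_over_l) / cont.lp_over_l
    assert rel.max() < 0.08


def test_fit_power_law_exact():
    grid = np.linspace(40.0, 100.0, 15)
    curve = theoretical_lp_curve("continuous", "CA", grid)
    synthetic = curve.__class__(
        "continuous", curve.potential_form, grid, curve.mean_cos,
        3.0 * grid**1.7, "kuhn",
    )
    assert fit_power_law(synthetic, 40, 100) == pytest.approx(1.7, abs=1e-10)
    # continuous CA theory has the unit log-log slope of lp = l k
    assert fit_power_law(curve, 40, 100) == pytest.approx(1.0, abs=0.02)


def test_fit_exponential_law_exact():
    grid = np.linspace(10.0, 40.0, 13)
    curve = theoretical_lp_curve("continuous", "CA", grid)
    synthetic = curve.__class__(
        "continuous", curve.potential_form, grid, curve.mean_cos,
        2.0 * np.exp(0.5 * grid), "kuhn",
    )
    assert fit_exponential_law(synthetic, 10, 40) == pytest.approx(0.5, abs=1e-10)


def test_fit_window_needs_five_points():
    grid = np.linspace(1.0, 100.0, 10)
    curve = theoretical_lp_curve("continuous", "CA", grid)
    with pytest.raises(ValueError, match="at least 5"):
        fit_power_law(curve, 90, 100)


def test_bfm_discrete_stiff_scaling_exponent():
    """The 87-angle lattice theory steepens to a k^2.3 power law at 40<k<100."""
    grid = np.linspace(40.0, 100.0, 25)
    exponent = fit_power_law(theoretical_lp_curve("BFM", "CA", grid), 40, 100)
    assert exponent == pytest.approx(2.3, abs=0.1)


def test_lbfm_rates_match_single_gap_asymptotes():
    """L-BFM growth rates are set by the smallest bending-energy gap.

    The closest nonstraight angle has cos = 1/sqrt(2), so the rate is
    k (1 - 1/sqrt(2)) for the cosine potential and k (1 - 1/sqrt(2))^2 for
    the squared form; the fitted rates must land within 5%.
    """
    gap = 1.0 - 1.0 / math.sqrt(2.0)
    rate_ca = fit_exponential_law(
        theoretical_lp_curve("LBFM", "CA", np.linspace(30, 80, 26)), 30, 80
    )
    assert rate_ca == pytest.approx(gap, rel=0.05)
    rate_csa = fit_exponential_law(
        theoretical_lp_curve("LBFM", "CSA", np.linspace(100, 280, 25)), 100, 280
    )
    assert rate_csa == pytest.approx(gap**2, rel=0.05)


def test_sclm_asymptote_exp_k_over_four(sclm_angles):
    """The two-angle lattice gives lp -> e^k / 4 at large k."""
    for k in (20.0, 25.0, 30.0):
        lp = lp_log(mean_cos_discrete(sclm_angles, PotentialSpec("CA", k)))
        assert math.exp(k) / lp == pytest.approx(4.0, rel=0.01)


def test_solve_k_for_target_lp():
    for form in ("CA", "CSA"):
        k = solve_k_for_lp(form, 18.0)
        assert lp_kuhn(mean_cos_continuous(PotentialSpec(form, k))) == pytest.approx(
            18.0, rel=1e-9
        )
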