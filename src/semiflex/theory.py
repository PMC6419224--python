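"""Theoretical persistence lengths of semiflexible chains.

For a chain with independent bond angles drawn from the Boltzmann weight of a
bending potential E(theta), the mean bond-angle cosine is

    <cos theta> = int_0^pi cos(t) sin(t) exp(-E(t)) dt
                  / int_0^pi sin(t) exp(-E(t)) dt

and the persistence length follows either from the Kuhn-length relation

    l_p / l = (1/2) (1 + <cos theta>) / (1 - <cos theta>)          (kuhn)

or from the exponential decay of bond-orientation memory,

    l_p / l = -1 / ln <cos theta>                                   (log)

The two coincide in the stiff regime.  Closed forms of <cos theta> exist for
both supported bending potentials:

* CA,  E = k (1 - cos t):    <cos> = coth(k) - 1/k  (the Langevin function),
  giving the worm-like-chain asymptote l_p / l -> k for k >> 1;
* CSA, E = k (1 - cos t)^2:  <cos> = 1 - (1 - e^(-4k)) / (sqrt(pi k) erf(2 sqrt k)),
  giving l_p / l -> sqrt(pi k) for k >> 1.

On a lattice the bond angle is discrete; the continuous integral is replaced
by a sum over the model's angle classes weighted by their a-priori
probabilities f_i,

    <cos theta> = sum_i f_i cos(t_i) e^(-E_i) / sum_i f_i e^(-E_i),

which produces qualitatively different stiffness laws at large k (power law
k^2.3 for the BFM with CA, exponential growth for L-BFM and SCLM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import erf

from .lattice import AngleDistribution, LatticeModel, enumerate_angle_classes
from .potentials import PotentialForm, PotentialSpec

__all__ = [
    "mean_cos_continuous",
    "mean_cos_quadrature",
    "mean_cos_discrete",
    "lp_kuhn",
    "lp_log",
    "TheoryCurve",
    "theoretical_lp_curve",
    "fit_power_law",
    "fit_exponential_law",
    "solve_k_for_lp",
]

#: below this k the closed forms lose precision to cancellation; use series
_SERIES_K = 1e-3


def mean_cos_continuous(spec: PotentialSpec) -> float:
    """Closed-form continuous Boltzmann average of cos(theta).

    CA: the Langevin function coth(k) - 1/k, written in the equivalent form
    [(k+1) e^(-2k) - 1 + k] / [k (1 - e^(-2k))].  CSA: see module docstring.
    Small k is handled by series expansion; the result lies in [0, 1).
    """
    k = spec.k
    if k < 0:
        raise ValueError("bending constant must be non-negative")
    if spec.form is PotentialForm.CA:
        if k < _SERIES_K:
            return k / 3.0 - k**3 / 45.0 + 2.0 * k**5 / 945.0
        em = math.exp(-2.0 * k)
        return ((k + 1.0) * em - 1.0 + k) / (k * (1.0 - em))
    # CSA
    if k < _SERIES_K:
        return 2.0 * k / 3.0 - 8.0 * k**2 / 45.0
    num = -math.expm1(-4.0 * k)
    den = math.sqrt(math.pi * k) * erf(2.0 * math.sqrt(k))
    return 1.0 - num / den


def mean_cos_quadrature(energy_fn) -> float:
    """Boltzmann average of cos(theta) by adaptive quadrature.

    ``energy_fn`` maps theta in [0, pi] to E/k_B T.  Serves as the
    independent oracle for the closed forms in :func:`mean_cos_continuous`.
    """
    probe = float(energy_fn(math.pi / 3.0))
    if not math.isfinite(probe):
        raise ValueError("energy function returned a non-finite value")

    def _w(theta):
        return math.sin(theta) * math.exp(-energy_fn(theta))

    # tiny absolute floor keeps the symmetric (zero-mean) case convergent
    num, _ = integrate.quad(lambda t: math.cos(t) * _w(t), 0.0, math.pi,
                            epsabs=1e-14, epsrel=1e-12, limit=200)
    den, _ = integrate.quad(_w, 0.0, math.pi, epsabs=1e-14, epsrel=1e-12,
                            limit=200)
    return num / den


def mean_cos_discrete(dist: "AngleDistribution | LatticeModel | str",
                      spec: PotentialSpec) -> float:
    """Discrete-lattice Boltzmann average of cos(theta).

    Weighted over the model's angle classes by a-priori probability times
    Boltzmann factor.  ``dist`` may be an :class:`AngleDistribution` or a
    model identifier (the distribution is then enumerated).
    """
    if not isinstance(dist, AngleDistribution):
        dist = enumerate_angle_classes(dist)
    cos = dist.cos_values
    f = dist.probabilities
    if spec.form is PotentialForm.CA:
        e = spec.k * (1.0 - cos)
    else:
        e = spec.k * (1.0 - cos) ** 2
    # subtract the minimum energy before exponentiating: at large k every
    # weight underflows otherwise while the ratio stays well defined
    w = f * np.exp(-(e - e.min()))
    return float((w @ cos) / w.sum())


def lp_kuhn(mean_cos: float, l: float = 1.0) -> float:
    """Persistence length from the Kuhn-length relation (half the Kuhn length)."""
    if mean_cos >= 1.0:
        raise ValueError("mean cos(theta) >= 1: infinite stiffness")
    return 0.5 * l * (1.0 + mean_cos) / (1.0 - mean_cos)


def lp_log(mean_cos: float, l: float = 1.0) -> float:
    """Persistence length from the bond-angle decay, -l / ln <cos theta>."""
    if mean_cos <= 0.0:
        raise ValueError("mean cos(theta) <= 0: bond-angle persistence length undefined")
    if mean_cos >= 1.0:
        raise ValueError("mean cos(theta) >= 1: infinite stiffness")
    return -l / math.log(mean_cos)


_LP_FORMULAS = {"kuhn": lp_kuhn, "log": lp_log}


@dataclass(frozen=True)
class TheoryCurve:
    """Theoretical <cos theta> and l_p/l on a grid of bending constants."""

    model: str  # "continuous" or a LatticeModel value
    potential_form: PotentialForm
    k_values: np.ndarray
    mean_cos: np.ndarray
    lp_over_l: np.ndarray
    lp_formula: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "model": self.model,
                "potential": self.potential_form.value,
                "k": self.k_values,
                "mean_cos": self.mean_cos,
                "lp_over_l": self.lp_over_l,
                "lp_formula": self.lp_formula,
            }
        )


def theoretical_lp_curve(model, potential_form, k_grid,
                         lp_formula: str = "kuhn") -> TheoryCurve:
    """Theoretical l_p/l versus bending constant for one model and potential.

    ``model`` is ``"continuous"`` for the continuous-angle closed forms or a
    lattice model identifier for the discrete sum.  ``lp_formula`` selects
    the Kuhn-length relation (default) or the logarithmic bond-angle form.
    """
    k_grid = np.asarray(k_grid, dtype=float)
    if k_grid.size and (np.any(k_grid < 0) or np.any(np.diff(k_grid) <= 0)):
        raise ValueError("k_grid must be non-negative and strictly increasing")
    form = PotentialForm(potential_form)
    if lp_formula not in _LP_FORMULAS:
        raise ValueError(f"unknown lp formula {lp_formula!r}")
    to_lp = _LP_FORMULAS[lp_formula]

    if isinstance(model, str) and model.lower() == "continuous":
        model_label = "continuous"
        mc = np.array([mean_cos_continuous(PotentialSpec(form, k)) for k in k_grid])
    else:
        lat = LatticeModel(model)
        model_label = lat.value
        dist = enumerate_angle_classes(lat)
        mc = np.array([mean_cos_discrete(dist, PotentialSpec(form, k)) for k in k_grid])
    lp = np.array([to_lp(c) for c in mc])
    return TheoryCurve(model_label, form, k_grid, mc, lp, lp_formula)


def _window(curve: TheoryCurve, k_min: float, k_max: float):
    sel = (curve.k_values >= k_min) & (curve.k_values <= k_max)
    if sel.sum() < 5:
        raise ValueError(
            f"need at least 5 grid points in [{k_min}, {k_max}], have {int(sel.sum())}"
        )
    return curve.k_values[sel], curve.lp_over_l[sel]


def fit_power_law(curve: TheoryCurve, k_min: float, k_max: float) -> float:
    """Least-squares exponent of l_p/l ~ k^a over a window (log-log slope)."""
    k, lp = _window(curve, k_min, k_max)
    return float(np.polyfit(np.log(k), np.log(lp), 1)[0])


def fit_exponential_law(curve: TheoryCurve, k_min: float, k_max: float) -> float:
    """Least-squares rate of l_p/l ~ exp(a k) over a window (semi-log slope)."""
    k, lp = _window(curve, k_min, k_max)
    return float(np.polyfit(k, np.log(lp), 1)[0])


def solve_k_for_lp(form, lp_over_l: float, lp_formula: str = "kuhn",
                   bracket=(1e-6, 1e6)) -> float:
    """Bending constant at which the continuous theory gives the target l_p/l."""
    from scipy.optimize import brentq

    form = PotentialForm(form)
    to_lp = _LP_FORMULAS[lp_formula]

    def _resid(k):
        return to_lp(mean_cos_continuous(PotentialSpec(form, k))) - lp_over_l

    return float(brentq(_resid, *bracket, xtol=1e-12, rtol=1e-12))
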