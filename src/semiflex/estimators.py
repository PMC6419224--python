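"""Persistence-length estimators for simulated chain ensembles.

Four standard routes from trajectory statistics to the persistence length:

``lp_auto``
    Exponential decay of the bond-orientation correlation
    C(s) = <b_i . b_{i+s}> / <l>^2 = exp(-s <l> / l_p); a least-squares fit
    of ln C(s) over the initial decay.

``lp_theta``
    The bond angle alone: l_p = -<l> / ln <cos theta>, the s = 1 limit of
    the same decay.  A purely local measure, insensitive to chain length.

``lp_ee``
    Flory's projection of the end-to-end vector onto the first bond,
    l_p = <sum_i b_i . b_1> / <l>.  Bounded by the contour length.

``lp_wlc``
    Inversion of the worm-like-chain expression
    <Re^2> = 2 l_p L {1 - (l_p/L)[1 - exp(-L/l_p)]} given <Re^2> and the
    contour length L = N <l>.

``estimate_all`` applies all four to an :class:`~semiflex.simulator.ObservableSeries`,
with run-to-run standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .simulator import ObservableSeries
from .theory import lp_log as _lp_log_formula

__all__ = [
    "lp_auto",
    "lp_theta",
    "lp_ee",
    "lp_wlc",
    "wlc_mean_sq_ree",
    "PersistenceEstimates",
    "estimate_all",
]

#: orientation correlation below this level is treated as noise
_CORR_FLOOR = 0.05


def lp_auto(correlation, mean_bond_length: float, corr_se=None,
            max_window: "int | None" = None,
            noise_floor: float = _CORR_FLOOR) -> float:
    """Persistence length from the decay of the orientation correlation.

    ``correlation`` holds C(s) for s = 1 .. s_max (already normalised by
    <l>^2).  Points are used while C(s) exceeds both an absolute noise floor
    of 0.05 and, when run-to-run standard errors are supplied, three times
    their standard error; the window is additionally capped at
    ``max_window`` (defaults to s_max).  Fits ln C(s) = a - s <l> / l_p by
    unweighted least squares and returns <l> times the decay constant.
    """
    c = np.asarray(correlation, dtype=float)
    s = np.arange(1, len(c) + 1)
    floor = np.full_like(c, noise_floor)
    if corr_se is not None:
        floor = np.maximum(floor, 3.0 * np.asarray(corr_se, dtype=float))
    usable = c > floor
    if max_window is not None:
        usable &= s <= max_window
    # contiguous initial window only: stop at the first unusable point
    bad = np.nonzero(~usable)[0]
    n_use = bad[0] if len(bad) else len(c)
    if n_use < 3:
        raise ValueError(
            "fewer than 3 usable correlation points; the orientation "
            "correlation is ill-defined for this ensemble (too flexible)"
        )
    slope = np.polyfit(s[:n_use], np.log(c[:n_use]), 1)[0]
    if slope >= 0:
        raise ValueError("orientation correlation does not decay")
    return float(-mean_bond_length / slope)


def lp_theta(mean_cos: float, mean_bond_length: float) -> float:
    """Persistence length from the mean bond-angle cosine, -<l>/ln<cos theta>."""
    return _lp_log_formula(mean_cos, mean_bond_length)


def lp_ee(proj_first, mean_bond_length: float) -> float:
    """Flory projection estimator.

    ``proj_first`` is the per-sample projection of the end-to-end vector on
    the first bond vector, sum_i b_i . b_1; the estimator is its ensemble
    mean divided by the ensemble mean bond length.
    """
    return float(np.mean(proj_first) / mean_bond_length)


def wlc_mean_sq_ree(lp: float, contour_length: float) -> float:
    """Worm-like-chain <Re^2> for persistence length ``lp`` and contour L."""
    x = lp / contour_length
    return 2.0 * lp * contour_length * (1.0 - x * (1.0 - math.exp(-1.0 / x)))


def lp_wlc(mean_sq_ree: float, contour_length: float) -> float:
    """Invert the worm-like-chain <Re^2>(l_p, L) relation for l_p.

    The left side is strictly increasing in l_p, so bisection on
    (1e-6 L, 1e3 L) converges; <Re^2> >= L^2 (the rod limit) is rejected.
    """
    L = contour_length
    if not 0.0 < mean_sq_ree < L * L:
        raise ValueError(
            f"mean square end-to-end distance {mean_sq_ree} outside (0, L^2); "
            "chain is at or beyond the rigid-rod limit"
        )
    lo, hi = 1e-6 * L, 1e3 * L
    f = lambda lp: wlc_mean_sq_ree(lp, L) - mean_sq_ree
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("persistence length outside the bisection bracket")
    return float(brentq(f, lo, hi, rtol=1e-10))


@dataclass
class PersistenceEstimates:
    """All four persistence-length estimates with run-to-run standard errors.

    Estimates are in lattice units.  A failed estimator (e.g. the
    orientation correlation of a nearly flexible chain) is recorded as NaN
    rather than aborting the analysis.
    """

    lp_auto: float
    lp_theta: float
    lp_ee: float
    lp_wlc: float
    se_auto: float
    se_theta: float
    se_ee: float
    se_wlc: float
    mean_bond_length: float
    contour_length: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimator": ["auto", "theta", "ee", "wlc"],
                "lp": [self.lp_auto, self.lp_theta, self.lp_ee, self.lp_wlc],
                "se": [self.se_auto, self.se_theta, self.se_ee, self.se_wlc],
            }
        )


def _mean_se(values):
    v = np.asarray([x for x in values if math.isfinite(x)], dtype=float)
    if len(v) == 0:
        return math.nan, math.nan
    se = v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else math.nan
    return float(v.mean()), se


def estimate_all(series: ObservableSeries,
                 n_bonds: "int | None" = None) -> PersistenceEstimates:
    """Apply all four estimators to an observable series, run by run.

    Each estimator is evaluated within every independent run and the
    reported value is the across-run mean with its standard error.  The mean
    bond length of the same ensemble sets the contour length L = N <l>.
    """
    if n_bonds is None:
        n_bonds = series.n_bonds
    if series.n_runs < 2:
        raise ValueError("need at least 2 independent runs for standard errors")
    corr_cols = series.corr_columns
    run_means = series.per_run()
    mean_l = float(run_means["mean_bond_length"].mean())
    L = n_bonds * mean_l
    # run-to-run scatter of C(s) feeds the fit-window noise criterion
    corr_run = run_means[corr_cols] / mean_l**2
    corr_se_global = corr_run.std(ddof=1).to_numpy() / math.sqrt(len(corr_run))

    vals = {"auto": [], "theta": [], "ee": [], "wlc": []}
    for r, row in run_means.iterrows():
        sub = series.frame[series.frame["run"] == r]
        l_r = float(row["mean_bond_length"])
        try:
            vals["auto"].append(
                lp_auto(row[corr_cols].to_numpy() / l_r**2, l_r,
                        corr_se=corr_se_global, max_window=max(3, n_bonds // 4))
            )
        except ValueError:
            vals["auto"].append(math.nan)
        try:
            vals["theta"].append(lp_theta(float(row["mean_cos_theta"]), l_r))
        except ValueError:
            vals["theta"].append(math.nan)
        vals["ee"].append(lp_ee(sub["proj_first"].to_numpy(), l_r))
        try:
            vals["wlc"].append(lp_wlc(float(row["re2"]), n_bonds * l_r))
        except ValueError:
            vals["wlc"].append(math.nan)

    (a, sa), (t, st_), (e, se_), (w, sw) = (
        _mean_se(vals["auto"]), _mean_se(vals["theta"]),
        _mean_se(vals["ee"]), _mean_se(vals["wlc"]),
    )
    return PersistenceEstimates(a, t, e, w, sa, st_, se_, sw, mean_l, L)
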