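"""Synthetic off-lattice chain ensembles with known stiffness.

Chains are built with fixed bond length and independent bond angles drawn
from the continuous Boltzmann density p(theta) ~ sin(theta) exp(-E(theta))
of a bending potential — the exact model underlying the continuous
persistence-length theory (no excluded volume, no lattice).  They provide
ground-truth ensembles for validating the persistence-length estimators:
on these chains the bond-angle estimator must recover the theoretical
-l / ln <cos theta> exactly up to sampling error.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .potentials import PotentialForm, PotentialSpec
from .simulator import ObservableSeries, _observables_from_snapshots

__all__ = ["sample_cos_theta", "ideal_chain_positions", "ideal_chain_series"]


def sample_cos_theta(spec: PotentialSpec, size: int, rng) -> np.ndarray:
    """Draw bond-angle cosines from the Boltzmann density of a potential.

    In terms of c = cos(theta) the density is proportional to exp(-E(c)) on
    [-1, 1].  The cosine-angle form admits an exact inverse CDF; the squared
    form is a Gaussian in (1 - c) truncated at c = -1, sampled by rejection.
    """
    k = spec.k
    if k < 1e-12:
        return rng.uniform(-1.0, 1.0, size)
    if spec.form is PotentialForm.CA:
        u = rng.uniform(0.0, 1.0, size)
        # inverse CDF of exp(k c), written to stay stable at large k
        return 1.0 + np.log(u + (1.0 - u) * math.exp(-2.0 * k)) / k
    sigma = 1.0 / math.sqrt(2.0 * k)
    out = np.empty(size)
    n = 0
    while n < size:
        t = np.abs(rng.normal(0.0, sigma, size - n))
        t = t[t <= 2.0]
        out[n:n + len(t)] = 1.0 - t
        n += len(t)
    return out


def ideal_chain_positions(spec: PotentialSpec, n_bonds: int, rng,
                          bond_length: float = 1.0) -> np.ndarray:
    """One freely-rotating chain with Boltzmann-distributed bond angles.

    Returns (n_bonds + 1, 3) float coordinates.  The first bond direction is
    isotropic; each subsequent bond makes a Boltzmann-drawn angle with its
    predecessor at a uniform azimuth.
    """
    cos_t = sample_cos_theta(spec, n_bonds - 1, rng) if n_bonds > 1 else np.empty(0)
    phi = rng.uniform(0.0, 2.0 * math.pi, max(0, n_bonds - 1))

    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    dirs = np.empty((n_bonds, 3))
    dirs[0] = u
    for j in range(n_bonds - 1):
        c = cos_t[j]
        s = math.sqrt(max(0.0, 1.0 - c * c))
        # orthonormal frame around the current direction
        a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        u = c * u + s * (math.cos(phi[j]) * e1 + math.sin(phi[j]) * e2)
        u /= np.linalg.norm(u)
        dirs[j + 1] = u
    pos = np.vstack([np.zeros(3), np.cumsum(bond_length * dirs, axis=0)])
    return pos


def ideal_chain_series(spec: PotentialSpec, n_bonds: int, n_samples: int,
                       n_runs: int, seed: int,
                       bond_length: float = 1.0) -> ObservableSeries:
    """An ensemble of independent ideal chains packaged as an observable series.

    Mimics the layout produced by the lattice simulator so the estimator
    pipeline applies unchanged; every sample is an independent conformation.
    """
    frames = []
    for r in range(n_runs):
        rng = np.random.default_rng(seed + r)
        snaps = np.array(
            [ideal_chain_positions(spec, n_bonds, rng, bond_length)
             for _ in range(n_samples)]
        )
        obs = _observables_from_snapshots(snaps)
        df = pd.DataFrame(obs)
        df.insert(0, "run", r)
        df.insert(1, "mcs", np.arange(n_samples))
        frames.append(df)
    return ObservableSeries(
        pd.concat(frames, ignore_index=True), n_bonds, None, spec,
    )
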