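"""Bending potentials acting between successive bonds of a chain.

Two standard forms are supported, both functions of the angle theta between
consecutive bond vectors taken head-to-tail (theta = 0 for a straight
continuation), with the bending constant k expressed in units of k_B*T:

* ``CA``  (cosine angle):          E/k_B T = k (1 - cos theta)
* ``CSA`` (cosine squared angle):  E/k_B T = k (1 - cos theta)^2

The CA form is the discretisation of the worm-like-chain bending energy; the
CSA form is a popular alternative whose force is smooth at theta = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["PotentialForm", "PotentialSpec", "bending_energy", "chain_bending_energy"]

_COS_SLACK = 1e-12


class PotentialForm(str, Enum):
    CA = "CA"
    CSA = "CSA"


@dataclass(frozen=True)
class PotentialSpec:
    """A bending potential: form (CA or CSA) and constant k >= 0 (k_B T units)."""

    form: PotentialForm
    k: float

    def __post_init__(self):
        object.__setattr__(self, "form", PotentialForm(self.form))
        if not (self.k >= 0.0):
            raise ValueError(f"bending constant must be non-negative, got {self.k}")

    def energy(self, cos_theta):
        return bending_energy(self, cos_theta)


def bending_energy(spec: PotentialSpec, cos_theta):
    """Bending energy (in k_B T) for the given bond-angle cosine.

    Accepts scalars or arrays.  Values outside [-1, 1] by more than 1e-12
    raise (they indicate a geometry bug upstream); within the slack they are
    clamped.
    """
    c = np.asarray(cos_theta, dtype=float)
    if np.any(np.abs(c) > 1.0 + _COS_SLACK):
        raise ValueError(f"cos(theta) outside [-1, 1]: {cos_theta!r}")
    c = np.clip(c, -1.0, 1.0)
    if spec.form is PotentialForm.CA:
        e = spec.k * (1.0 - c)
    else:
        e = spec.k * (1.0 - c) ** 2
    return float(e) if np.isscalar(cos_theta) or e.ndim == 0 else e


def chain_bending_energy(positions, spec: PotentialSpec) -> float:
    """Total bending energy of a chain given its monomer positions.

    Sums the potential over all consecutive bond pairs.  This is the from-
    scratch recompute used to audit incrementally updated energies in the
    Monte Carlo driver.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 3:
        return 0.0
    bonds = np.diff(pos, axis=0)
    lens = np.sqrt((bonds**2).sum(axis=1))
    if np.any(lens == 0):
        raise ValueError("zero-length bond in chain")
    dots = (bonds[:-1] * bonds[1:]).sum(axis=1)
    cos = dots / (lens[:-1] * lens[1:])
    return float(np.sum(bending_energy(spec, cos)))
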