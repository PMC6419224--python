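"""Bond-vector sets and bond-angle distributions of cubic-lattice polymer models.

Three single-chain lattice models are supported:

``BFM``
    The bond fluctuation model.  Each monomer occupies the eight corners of a
    unit cube and successive monomers are connected by one of 108 bond vectors
    with squared length in {4, 5, 6, 9, 10} (the symmetry classes of
    (2,0,0), (2,1,0), (2,1,1), (2,2,1), (3,0,0) and (3,1,0)).

``LBFM``
    The Larson-type bond fluctuation model.  Monomers occupy single lattice
    sites; bonds connect nearest and next-nearest neighbours, i.e. the 18
    vectors with squared length 1 or 2.

``SCLM``
    The simple cubic lattice model.  Single-site monomers with unit bonds
    along the six axes; the only bond angles are 0 and pi/2.

Besides the raw vector sets, this module enumerates the distinct bond-angle
classes of each model together with their a-priori probabilities: the
frequency of each angle among all ordered pairs of bonds that a two-bond
(three-monomer) chain can realise without violating excluded volume.  These
probabilities are the zero-stiffness reference measure entering the
discrete-lattice Boltzmann average of the bond-angle cosine.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "LatticeModel",
    "BondVectorSet",
    "AngleClass",
    "AngleDistribution",
    "enumerate_bond_vectors",
    "enumerate_angle_classes",
    "feasible_two_bond_chain",
]

#: grouping tolerance on cos(theta) when collecting angle classes
COS_TOL = 1e-9


class LatticeModel(str, Enum):
    """Identifier of a supported lattice polymer model."""

    BFM = "BFM"
    LBFM = "LBFM"
    SCLM = "SCLM"


#: squared bond lengths permitted by each model
ALLOWED_SQ_LENGTHS = {
    LatticeModel.BFM: frozenset({4, 5, 6, 9, 10}),
    LatticeModel.LBFM: frozenset({1, 2}),
    LatticeModel.SCLM: frozenset({1}),
}


def _as_model(model_id: "LatticeModel | str") -> LatticeModel:
    try:
        return LatticeModel(model_id)
    except ValueError:
        raise ValueError(
            f"unknown lattice model {model_id!r}; expected one of "
            f"{[m.value for m in LatticeModel]}"
        ) from None


@dataclass(frozen=True)
class BondVectorSet:
    """All bond vectors a model permits, in lexicographic order.

    Attributes
    ----------
    model_id : LatticeModel
    vectors : ndarray of shape (n, 3), dtype int64
    allowed_sq_lengths : frozenset of int
    """

    model_id: LatticeModel
    vectors: np.ndarray
    allowed_sq_lengths: frozenset

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def lengths(self) -> np.ndarray:
        """Euclidean length of every vector (lattice units)."""
        return np.sqrt((self.vectors.astype(float) ** 2).sum(axis=1))


@dataclass(frozen=True)
class AngleClass:
    """One distinct bond-angle value with its combinatorial weight.

    ``multiplicity`` counts ordered bond-vector pairs realising the angle in
    an excluded-volume-feasible two-bond chain; ``f`` is the corresponding
    a-priori probability (multiplicity / total feasible pairs).
    """

    cos_theta: float
    multiplicity: int
    f: float

    @property
    def theta(self) -> float:
        return math.acos(min(1.0, max(-1.0, self.cos_theta)))


@dataclass(frozen=True)
class AngleDistribution:
    model_id: LatticeModel
    classes: tuple

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def cos_values(self) -> np.ndarray:
        return np.array([c.cos_theta for c in self.classes])

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([c.f for c in self.classes])

    @property
    def total_pairs(self) -> int:
        return int(sum(c.multiplicity for c in self.classes))

    def a_priori_mean_cos(self) -> float:
        """Mean bond-angle cosine at zero bending stiffness."""
        return float(self.probabilities @ self.cos_values)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as columns model, cos_theta, theta_rad, multiplicity, f."""
        return pd.DataFrame(
            {
                "model": self.model_id.value,
                "cos_theta": [c.cos_theta for c in self.classes],
                "theta_rad": [c.theta for c in self.classes],
                "multiplicity": [c.multiplicity for c in self.classes],
                "f": [c.f for c in self.classes],
            }
        )


def enumerate_bond_vectors(model_id: "LatticeModel | str") -> BondVectorSet:
    """Enumerate every allowed bond vector of a lattice model.

    Returns the integer vectors whose squared length lies in the model's
    allowed set, sorted lexicographically.  BFM yields 108 vectors, LBFM 18
    and SCLM 6.
    """
    model = _as_model(model_id)
    allowed = ALLOWED_SQ_LENGTHS[model]
    reach = int(math.isqrt(max(allowed)))
    vecs = [
        v
        for v in itertools.product(range(-reach, reach + 1), repeat=3)
        if v[0] * v[0] + v[1] * v[1] + v[2] * v[2] in allowed
    ]
    vecs.sort()
    return BondVectorSet(model, np.array(vecs, dtype=np.int64), allowed)


def _cubes_overlap(delta: Iterable[int]) -> bool:
    # two 2x2x2 monomer cubes share a lattice site iff the lower-corner
    # offsets differ by at most 1 along every axis
    return all(abs(d) <= 1 for d in delta)


def feasible_two_bond_chain(b1, b2, model_id: "LatticeModel | str") -> bool:
    """Whether a three-monomer chain with consecutive bonds b1, b2 is legal.

    Monomers sit at 0, b1 and b1 + b2.  For the BFM the three monomer cubes
    must be pairwise site-disjoint; for LBFM and SCLM the three sites must be
    pairwise distinct.  Bond-length validity of b1 and b2 themselves is the
    caller's responsibility.
    """
    model = _as_model(model_id)
    b1 = tuple(int(x) for x in b1)
    b2 = tuple(int(x) for x in b2)
    third = tuple(a + b for a, b in zip(b1, b2))
    if model is LatticeModel.BFM:
        return not (
            _cubes_overlap(b1) or _cubes_overlap(b2) or _cubes_overlap(third)
        )
    return b1 != (0, 0, 0) and b2 != (0, 0, 0) and third != (0, 0, 0)


def enumerate_angle_classes(model_id: "LatticeModel | str") -> AngleDistribution:
    """Enumerate the distinct bond-angle classes of a model.

    All ordered pairs (b1, b2) of allowed bond vectors that form a feasible
    two-bond chain are grouped by cos(theta) = b1.b2 / (|b1||b2|) with an
    absolute tolerance of 1e-9; the a-priori probability of each class is its
    pair count divided by the total number of feasible pairs.

    BFM has 87 classes, LBFM 6 and SCLM 2 (the straight continuation and the
    right angle; the back-fold is forbidden by excluded volume).
    """
    model = _as_model(model_id)
    bvs = enumerate_bond_vectors(model)
    vecs = bvs.vectors
    inv_len = 1.0 / np.sqrt((vecs.astype(float) ** 2).sum(axis=1))

    # feasibility of the ordered pair, vectorised over b2 for each b1
    all_cos = []
    n = len(vecs)
    for i in range(n):
        sums = vecs[i] + vecs  # (n, 3) third-monomer offsets
        if model is LatticeModel.BFM:
            ok = ~np.all(np.abs(sums) <= 1, axis=1)
        else:
            ok = ~np.all(sums == 0, axis=1)
        dots = vecs @ vecs[i]
        all_cos.append((dots * (inv_len[i] * inv_len))[ok])
    cos = np.sort(np.concatenate(all_cos))

    # cluster sorted cos values: a gap larger than the tolerance starts a
    # new class (values within a class agree to floating-point noise)
    total = len(cos)
    breaks = np.nonzero(np.diff(cos) > COS_TOL)[0] + 1
    classes = []
    for chunk in np.split(cos, breaks):
        classes.append(
            AngleClass(float(chunk[0]), len(chunk), len(chunk) / total)
        )
    return AngleDistribution(model, tuple(classes))
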