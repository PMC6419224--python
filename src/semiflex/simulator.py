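"""Metropolis Monte Carlo of a single self-avoiding semiflexible chain.

One chain lives on a periodic simple cubic lattice.  Under the bond
fluctuation model (BFM) each monomer occupies the eight corners of a unit
cube and the elementary "L6" move displaces one randomly chosen monomer by
one lattice unit along one of the six axes; under the Larson-type model
(L-BFM) monomers are single sites and move to one of their 18 nearest or
next-nearest neighbour sites; the simple cubic lattice model (SCLM) uses
single sites with the six axial moves.  A move is rejected outright if it
breaks a bond-length constraint or lands on an occupied site, and otherwise
accepted with the Metropolis probability min{1, exp(-dE)} on the change of
bending energy (k_B T = 1).  One Monte Carlo step (MCS) is the unit of time
in which every monomer attempts one move on average.

The production path runs a numba-compiled kernel; an equivalent pure-Python
``attempt_move`` on :class:`ChainState` serves as the readable reference and
the audit oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .lattice import ALLOWED_SQ_LENGTHS, LatticeModel, enumerate_bond_vectors
from .potentials import PotentialForm, PotentialSpec, chain_bending_energy

__all__ = [
    "ModelSpec",
    "SimConfig",
    "ChainState",
    "init_chain",
    "attempt_move",
    "run",
    "ObservableSeries",
    "write_snapshots_csv",
    "series_from_snapshots_csv",
]

_AXIAL_MOVES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


def _move_set(model: LatticeModel) -> np.ndarray:
    if model is LatticeModel.LBFM:
        # the 18 nearest + next-nearest neighbour displacements
        return enumerate_bond_vectors(LatticeModel.LBFM).vectors.copy()
    return _AXIAL_MOVES.copy()


def _tables(model: LatticeModel):
    """Bond-validity and inverse-length lookup tables indexed by comp + 4."""
    allowed = np.zeros((9, 9, 9), dtype=np.bool_)
    inv_len = np.zeros((9, 9, 9), dtype=np.float64)
    for v in enumerate_bond_vectors(model).vectors:
        allowed[v[0] + 4, v[1] + 4, v[2] + 4] = True
        inv_len[v[0] + 4, v[1] + 4, v[2] + 4] = 1.0 / math.sqrt(float(v @ v))
    return allowed, inv_len


@dataclass(frozen=True)
class ModelSpec:
    """A lattice model in a periodic cubic box of edge ``box_length``."""

    model_id: LatticeModel
    box_length: int = 256

    def __post_init__(self):
        object.__setattr__(self, "model_id", LatticeModel(self.model_id))
        max_bond = math.sqrt(max(ALLOWED_SQ_LENGTHS[self.model_id]))
        # power of two so the kernel can wrap coordinates with a bitmask
        if self.box_length & (self.box_length - 1) or self.box_length < 4 * max_bond:
            raise ValueError(
                f"box_length must be a power of two >= {4 * max_bond:.0f}, "
                f"got {self.box_length}"
            )

    @property
    def cube_mode(self) -> bool:
        return self.model_id is LatticeModel.BFM

    @property
    def axial_bond(self) -> np.ndarray:
        step = 2 if self.model_id is LatticeModel.BFM else 1
        return np.array([step, 0, 0], dtype=np.int64)


@dataclass(frozen=True)
class SimConfig:
    """Monte Carlo schedule: equilibration, sampling window, runs, seed.

    ``start`` selects the initial condition: ``"rod"`` equilibrates from the
    straight initial chain, ``"coil"`` first relaxes the chain athermally
    (bending constant zero) for ``coil_mcs`` MCS before switching the
    potential on, and ``"mixed"`` alternates the two between runs.  Slow
    bond-angle modes of stiff chains approach equilibrium from above when
    started from a rod and from below when started from a coil, so the
    mixed protocol cancels the leading initialization bias.
    """

    n_equil_mcs: int
    n_sample_mcs: int
    sample_interval: int
    seed: int = 0
    n_runs: int = 1
    start: str = "rod"
    coil_mcs: int = 500_000

    def __post_init__(self):
        if min(self.n_equil_mcs, self.n_sample_mcs, self.sample_interval) < 1:
            raise ValueError("schedule lengths must be positive")
        if self.n_sample_mcs % self.sample_interval:
            raise ValueError("sample_interval must divide n_sample_mcs")
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")
        if self.start not in ("rod", "coil", "mixed"):
            raise ValueError(f"start must be rod, coil or mixed, got {self.start!r}")


@dataclass
class ChainState:
    """One self-avoiding chain: unwrapped positions + wrapped occupancy.

    ``occupancy`` is a dense uint8 box of occupied wrapped sites (eight cube
    corners per monomer in the BFM, one site otherwise); ``energy`` caches
    the total bending energy and is updated incrementally by moves.
    """

    model: ModelSpec
    positions: np.ndarray  # (n_monomers, 3) int64, unwrapped
    occupancy: np.ndarray  # (box, box, box) uint8, wrapped
    energy: float

    @property
    def n_bonds(self) -> int:
        return len(self.positions) - 1

    def bonds(self) -> np.ndarray:
        return np.diff(self.positions, axis=0)

    def occupied_sites(self, position) -> list:
        """Wrapped lattice sites a monomer at ``position`` occupies."""
        box = self.model.box_length
        x, y, z = (int(v) for v in position)
        if self.model.cube_mode:
            return [
                ((x + a) % box, (y + b) % box, (z + c) % box)
                for a in (0, 1) for b in (0, 1) for c in (0, 1)
            ]
        return [(x % box, y % box, z % box)]

    def audit(self, potential: PotentialSpec) -> None:
        """Verify every structural invariant; raise AssertionError on breach.

        Checks bond membership, site-disjoint excluded volume, occupancy
        bookkeeping and the cached bending energy against a full recompute.
        """
        allowed = ALLOWED_SQ_LENGTHS[self.model.model_id]
        bonds = self.bonds()
        sq = (bonds**2).sum(axis=1)
        assert all(int(s) in allowed for s in sq), "bond outside allowed set"
        sites: set = set()
        for p in self.positions:
            for s in self.occupied_sites(p):
                assert s not in sites, f"doubly occupied site {s}"
                sites.add(s)
        marked = {tuple(int(v) for v in s) for s in np.argwhere(self.occupancy)}
        assert marked == sites, "occupancy array inconsistent with positions"
        e = chain_bending_energy(self.positions, potential)
        assert abs(e - self.energy) <= 1e-8 * max(1.0, abs(e)), (
            f"cached energy {self.energy} != recomputed {e}"
        )


def init_chain(model: ModelSpec, n_bonds: int) -> ChainState:
    """A straight rod along x with the shortest axial bond; zero energy."""
    if n_bonds < 1:
        raise ValueError("need at least one bond")
    bond = model.axial_bond
    extent = n_bonds * int(bond[0]) + (1 if model.cube_mode else 0)
    if extent >= model.box_length:
        raise ValueError(
            f"straight chain of extent {extent} does not fit in box "
            f"{model.box_length}"
        )
    positions = np.outer(np.arange(n_bonds + 1, dtype=np.int64), bond)
    box = model.box_length
    occ = np.zeros((box, box, box), dtype=np.uint8)
    state = ChainState(model, positions, occ, 0.0)
    for p in positions:
        for s in state.occupied_sites(p):
            occ[s] = 1
    return state


def attempt_move(state: ChainState, potential: PotentialSpec, rng) -> bool:
    """Pure-Python reference move; mirrors the compiled kernel exactly.

    Picks a uniformly random monomer and move direction, applies the
    bond-length, excluded-volume and Metropolis tests and on acceptance
    updates positions, occupancy and cached energy in place.
    """
    model = state.model
    moves = _move_set(model.model_id)
    allowed = ALLOWED_SQ_LENGTHS[model.model_id]
    n_mon = len(state.positions)
    i = int(rng.integers(n_mon))
    d = moves[int(rng.integers(len(moves)))]
    new_pos = state.positions[i] + d

    for j, sign in ((i - 1, 1), (i + 1, -1)):
        if 0 <= j < n_mon:
            b = sign * (new_pos - state.positions[j])
            if int(b @ b) not in allowed:
                return False

    old_sites = set(state.occupied_sites(state.positions[i]))
    new_sites = state.occupied_sites(new_pos)
    for s in new_sites:
        if s not in old_sites and state.occupancy[s]:
            return False

    def _angle_energy(positions, a):
        b1 = positions[a + 1] - positions[a]
        b2 = positions[a + 2] - positions[a + 1]
        c = (b1 @ b2) / math.sqrt(float(b1 @ b1) * float(b2 @ b2))
        return potential.energy(c)

    trial = state.positions.copy()
    trial[i] = new_pos
    dE = 0.0
    for a in range(max(0, i - 2), min(state.n_bonds - 1, i + 1)):
        dE += _angle_energy(trial, a) - _angle_energy(state.positions, a)

    if dE > 0.0 and rng.random() >= math.exp(-dE):
        return False

    for s in old_sites:
        state.occupancy[s] = 0
    for s in new_sites:
        state.occupancy[s] = 1
    state.positions[i] = new_pos
    state.energy += dE
    return True


# ---------------------------------------------------------------------------
# observables


@dataclass
class ObservableSeries:
    """Per-sample chain observables from one or more independent runs.

    ``frame`` has one row per sample with columns run, mcs, re2, rg2,
    mean_bond_length, mean_cos_theta, proj_first and corr_1 .. corr_{N-1},
    where corr_s is the average bond-vector dot product <b_i . b_{i+s}>
    over the chain (unnormalised; divide by <l>^2 for the orientation
    correlation function) and proj_first is the projection of the
    end-to-end vector onto the first bond.
    """

    frame: pd.DataFrame
    n_bonds: int
    model_id: "LatticeModel | None"  # None for synthetic (off-lattice) ensembles
    potential: PotentialSpec
    acceptance_rate: float = math.nan

    @property
    def n_runs(self) -> int:
        return self.frame["run"].nunique()

    @property
    def corr_columns(self) -> list:
        return [c for c in self.frame.columns if c.startswith("corr_")]

    def per_run(self) -> pd.DataFrame:
        """Mean of every observable within each independent run."""
        return self.frame.groupby("run").mean(numeric_only=True)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "model", self.model_id.value if self.model_id else "synthetic")
        out.insert(1, "potential", self.potential.form.value)
        out.insert(2, "k", self.potential.k)
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ObservableSeries":
        frame = pd.read_csv(path)
        model_value = frame.pop("model").iloc[0]
        model = None if model_value == "synthetic" else LatticeModel(model_value)
        spec = PotentialSpec(
            PotentialForm(frame.pop("potential").iloc[0]), float(frame.pop("k").iloc[0])
        )
        n_bonds = max(int(c.split("_")[1]) for c in frame.columns
                      if c.startswith("corr_")) + 1
        return cls(frame, n_bonds, model, spec)


def write_snapshots_csv(snapshots: dict, path) -> None:
    """Write conformation snapshots as CSV rows run, mcs, monomer_index, x, y, z.

    ``snapshots`` maps run index to (mcs_values, positions) where positions
    has shape (n_samples, n_monomers, 3) in unwrapped integer coordinates.
    """
    frames = []
    for run_idx, (mcs_values, pos) in snapshots.items():
        n_samples, n_mon, _ = pos.shape
        frames.append(pd.DataFrame({
            "run": run_idx,
            "mcs": np.repeat(np.asarray(mcs_values), n_mon),
            "monomer_index": np.tile(np.arange(n_mon), n_samples),
            "x": pos[:, :, 0].ravel(),
            "y": pos[:, :, 1].ravel(),
            "z": pos[:, :, 2].ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def series_from_snapshots_csv(path, model_id, potential: PotentialSpec
                              ) -> ObservableSeries:
    """Rebuild an observable series from saved conformation snapshots.

    Recomputes every observable (Re2, Rg2, bond statistics, orientation
    correlations) from the integer coordinates, so previously saved
    trajectories can be re-analysed by the estimator module.
    """
    table = pd.read_csv(path)
    n_mon = table["monomer_index"].max() + 1
    frames = []
    for run_idx, sub in table.groupby("run"):
        sub = sub.sort_values(["mcs", "monomer_index"])
        mcs = sub["mcs"].unique()
        pos = sub[["x", "y", "z"]].to_numpy().reshape(len(mcs), n_mon, 3)
        df = pd.DataFrame(_observables_from_snapshots(pos))
        df.insert(0, "run", run_idx)
        df.insert(1, "mcs", mcs)
        frames.append(df)
    return ObservableSeries(
        pd.concat(frames, ignore_index=True), n_mon - 1,
        LatticeModel(model_id) if model_id else None, potential,
    )


def _observables_from_snapshots(snaps: np.ndarray) -> dict:
    """Vectorised per-sample observables from an (S, n_mon, 3) stack."""
    pos = snaps.astype(np.float64)
    com = pos.mean(axis=1, keepdims=True)
    rg2 = ((pos - com) ** 2).sum(axis=2).mean(axis=1)
    ree = pos[:, -1, :] - pos[:, 0, :]
    re2 = (ree**2).sum(axis=1)
    bonds = np.diff(pos, axis=1)  # (S, nb, 3)
    lens = np.sqrt((bonds**2).sum(axis=2))
    mean_l = lens.mean(axis=1)
    dots = (bonds[:, :-1, :] * bonds[:, 1:, :]).sum(axis=2)
    cos = dots / (lens[:, :-1] * lens[:, 1:])
    mean_cos = cos.mean(axis=1)
    proj_first = (ree * bonds[:, 0, :]).sum(axis=1)
    out = {
        "re2": re2,
        "rg2": rg2,
        "mean_bond_length": mean_l,
        "mean_cos_theta": mean_cos,
        "proj_first": proj_first,
    }
    nb = bonds.shape[1]
    for s in range(1, nb):
        out[f"corr_{s}"] = (bonds[:, :-s, :] * bonds[:, s:, :]).sum(axis=2).mean(axis=1)
    return out


def run(model: ModelSpec, potential: PotentialSpec, n_bonds: int,
        config: SimConfig, log=None, snapshots_out=None) -> ObservableSeries:
    """Simulate ``config.n_runs`` independent chains and collect observables.

    Each run equilibrates for ``n_equil_mcs`` MCS from a straight rod and
    then samples every ``sample_interval`` MCS for ``n_sample_mcs`` MCS.
    Run r uses the seeded stream ``seed + r``; identical configurations
    reproduce identical series bit for bit.  A box-extent audit at every
    sample aborts if the chain could reach its periodic image.
    """
    moves = _move_set(model.model_id)
    allowed, inv_len = _tables(model.model_id)
    n_mon = n_bonds + 1
    form_flag = 0 if potential.form is PotentialForm.CA else 1
    mask = model.box_length - 1
    half_box = model.box_length // 2
    n_samples = config.n_sample_mcs // config.sample_interval

    frames = []
    all_snaps: dict = {}
    total_acc = 0
    total_att = 0
    for r in range(config.n_runs):
        state = init_chain(model, n_bonds)
        pos, occ = state.positions, state.occupancy
        _kernels.seed_rng((config.seed + r) % 2**31)
        energy = 0.0
        coil = config.start == "coil" or (config.start == "mixed" and r % 2)
        if coil:
            # athermal pre-relaxation, then switch the bending potential on
            _, acc = _kernels.mc_sweep(
                pos, occ, mask, moves, allowed, inv_len,
                model.cube_mode, form_flag, 0.0, 0.0,
                config.coil_mcs * n_mon,
            )
            total_acc += acc
            total_att += config.coil_mcs * n_mon
            energy = chain_bending_energy(pos, potential)
        energy, acc = _kernels.mc_sweep(
            pos, occ, mask, moves, allowed, inv_len,
            model.cube_mode, form_flag, potential.k, energy,
            config.n_equil_mcs * n_mon,
        )
        total_acc += acc
        total_att += config.n_equil_mcs * n_mon
        snaps = np.empty((n_samples, n_mon, 3), dtype=np.int64)
        for s in range(n_samples):
            energy, acc = _kernels.mc_sweep(
                pos, occ, mask, moves, allowed, inv_len,
                model.cube_mode, form_flag, potential.k, energy,
                config.sample_interval * n_mon,
            )
            total_acc += acc
            total_att += config.sample_interval * n_mon
            extent = pos.max(axis=0) - pos.min(axis=0)
            if extent.max() >= half_box:
                raise RuntimeError(
                    f"chain extent {extent.max()} >= box/2 = {half_box}; "
                    "rerun with a larger box_length"
                )
            snaps[s] = pos
        recomputed = chain_bending_energy(pos, potential)
        if abs(recomputed - energy) > 1e-8 * max(1.0, abs(recomputed)):
            raise RuntimeError(
                f"incremental energy drifted: cached {energy}, "
                f"recomputed {recomputed}"
            )
        obs = _observables_from_snapshots(snaps)
        df = pd.DataFrame(obs)
        df.insert(0, "run", r)
        mcs_values = (config.n_equil_mcs
                      + config.sample_interval * np.arange(1, n_samples + 1))
        df.insert(1, "mcs", mcs_values)
        frames.append(df)
        if snapshots_out is not None:
            all_snaps[r] = (mcs_values, snaps.copy())
        if log is not None:
            log(
                f"model={model.model_id.value} potential={potential.form.value} "
                f"k={potential.k} run={r} seed={(config.seed + r) % 2**31} "
                f"acceptance={total_acc / total_att:.4f}"
            )

    if snapshots_out is not None:
        write_snapshots_csv(all_snaps, snapshots_out)
    series = ObservableSeries(
        pd.concat(frames, ignore_index=True), n_bonds, model.model_id,
        potential, total_acc / total_att,
    )
    return series
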