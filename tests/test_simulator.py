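"""Monte Carlo engine: state invariants, move rules, kernel consistency."""

import math

import numpy as np
import pytest

from semiflex.lattice import enumerate_angle_classes
from semiflex.potentials import PotentialSpec
from semiflex.simulator import (
    ChainState,
    ModelSpec,
    ObservableSeries,
    SimConfig,
    attempt_move,
    init_chain,
    run,
)
from semiflex.theory import mean_cos_discrete


@pytest.mark.parametrize(
    "model, n_bonds, span",
    [("BFM", 50, 100), ("SCLM", 3, 3), ("LBFM", 10, 10)],
)
def test_init_chain_is_straight_rod(model, n_bonds, span):
    state = init_chain(ModelSpec(model, 256), n_bonds)
    assert len(state.positions) == n_bonds + 1
    assert state.positions[-1, 0] - state.positions[0, 0] == span
    assert np.all(state.positions[:, 1:] == 0)
    assert state.energy == 0.0
    state.audit(PotentialSpec("CA", 1.0))


def test_init_chain_too_long_for_box():
    with pytest.raises(ValueError, match="does not fit"):
        init_chain(ModelSpec("BFM", 64), 200)


def test_box_length_must_be_power_of_two():
    with pytest.raises(ValueError, match="power of two"):
        ModelSpec("BFM", 100)


class _ForcedRng:
    """Deterministic monomer/move choices with a fixed uniform draw."""

    def __init__(self, seq, uniform=0.99):
        self.seq = list(seq)
        self.uniform = uniform

    def integers(self, n):
        return self.seq.pop(0)

    def random(self):
        return self.uniform


def _lbfm_move_index(vec):
    from semiflex.simulator import _move_set

    moves = _move_set(init_chain(ModelSpec("LBFM", 16), 1).model.model_id)
    return int(np.flatnonzero(np.all(moves == np.asarray(vec), axis=1))[0])


def test_zero_stiffness_moves_never_metropolis_rejected(rng):
    """At k = 0 every geometrically legal move is accepted (dE = 0 => P = 1)."""
    state = init_chain(ModelSpec("LBFM", 16), 4)
    spec = PotentialSpec("CA", 0.0)
    moved = 0
    for _ in range(3000):
        before = state.positions.copy()
        accepted = attempt_move(state, spec, rng)
        moved += accepted
        if not accepted:
            # rejection can only come from geometry, never from Metropolis
            assert np.array_equal(state.positions, before)
    assert moved > 0
    state.audit(spec)


def test_occupied_destination_rejected():
    # bent chain (0,0,0),(1,0,0),(1,1,0); pushing monomer 0 onto (1,1,0)
    # keeps the bond valid (length 1 after the move) but lands on monomer 2
    model = ModelSpec("LBFM", 16)
    state = init_chain(model, 2)
    state.positions[2] = [1, 1, 0]
    state.occupancy[:] = 0
    for p in state.positions:
        state.occupancy[tuple(np.mod(p, 16))] = 1
    from semiflex.potentials import chain_bending_energy

    spec = PotentialSpec("CA", 0.0)
    state.energy = chain_bending_energy(state.positions, spec)

    idx = _lbfm_move_index([1, 1, 0])
    assert attempt_move(state, spec, _ForcedRng([0, idx])) is False
    state.audit(spec)


def test_metropolis_acceptance_probability_half(rng):
    """A move with dE = ln 2 is accepted with probability 1/2."""
    # straight L-BFM 3-monomer chain; kinking the end bond to (1,1,0) costs
    # dE = k (1 - 1/sqrt(2)); pick k so dE = ln 2
    k = math.log(2.0) / (1.0 - 1.0 / math.sqrt(2.0))
    spec = PotentialSpec("CA", k)
    idx = _lbfm_move_index([0, 1, 0])
    n_acc = 0
    n_try = 4000
    for _ in range(n_try):
        state = init_chain(ModelSpec("LBFM", 16), 2)
        accepted = attempt_move(state, spec, _ForcedRng([2, idx], rng.random()))
        n_acc += accepted
    p = n_acc / n_try
    assert abs(p - 0.5) < 3.0 * math.sqrt(0.25 / n_try)


@pytest.mark.parametrize("model", ["BFM", "LBFM"])
def test_reference_walk_preserves_all_invariants(model, rng):
    """After thousands of reference moves the full audit still passes."""
    spec = PotentialSpec("CSA", 1.3)
    state = init_chain(ModelSpec(model, 32), 8)
    for _ in range(4000):
        attempt_move(state, spec, rng)
    state.audit(spec)
    # the chain actually moved
    assert not np.all(state.positions[:, 1:] == 0)


def test_kernel_energy_bookkeeping_against_recompute():
    """Incremental kernel energy equals a from-scratch recompute after ~1e6 moves."""
    # run() raises internally if the cached energy drifts beyond 1e-8
    config = SimConfig(10_000, 10_000, 10_000, seed=5, n_runs=1)
    series = run(ModelSpec("BFM", 64), PotentialSpec("CA", 4.0), 20, config)
    assert len(series.frame) == 1


def test_run_determinism_bit_identical():
    config = SimConfig(2_000, 4_000, 1_000, seed=123, n_runs=2)
    a = run(ModelSpec("LBFM", 64), PotentialSpec("CA", 2.0), 15, config)
    b = run(ModelSpec("LBFM", 64), PotentialSpec("CA", 2.0), 15, config)
    assert a.frame.equals(b.frame)
    c = run(ModelSpec("LBFM", 64), PotentialSpec("CA", 2.0), 15,
            SimConfig(2_000, 4_000, 1_000, seed=124, n_runs=2))
    assert not c.frame.equals(a.frame)


def test_flexible_bfm_bond_length_window():
    """The athermal BFM bond length settles near 2.7 lattice units."""
    config = SimConfig(50_000, 100_000, 2_000, seed=9, n_runs=2)
    series = run(ModelSpec("BFM", 256), PotentialSpec("CA", 0.0), 30, config)
    mean_l = series.per_run()["mean_bond_length"].mean()
    assert 2.6 < mean_l < 2.8


@pytest.mark.parametrize("model", ["LBFM", "BFM"])
def test_two_bond_chain_samples_boltzmann_angle_distribution(model):
    """A three-monomer chain equilibrates to the discrete Boltzmann law.

    For two bonds the stationary distribution over angle classes is exactly
    f_i e^(-E_i) (normalised) — the same weights as the discrete theoretical
    average — because excluded volume involves only the two bonds that the
    a-priori probabilities already account for.  The sampled mean cosine
    must match that prediction within statistical error.
    """
    spec = PotentialSpec("CA", 1.0)
    config = SimConfig(20_000, 400_000, 20, seed=42, n_runs=4)
    series = run(ModelSpec(model, 32), spec, 2, config)
    per_run = series.per_run()["mean_cos_theta"]
    predicted = mean_cos_discrete(enumerate_angle_classes(model), spec)
    se = per_run.std(ddof=1) / math.sqrt(len(per_run))
    assert abs(per_run.mean() - predicted) < max(3.0 * se, 0.01)


def test_orientation_correlation_decays_log_linearly():
    """For a stiff chain ln C(s) falls roughly linearly along the backbone."""
    config = SimConfig(100_000, 200_000, 2_000, seed=3, n_runs=2)
    series = run(ModelSpec("BFM", 256), PotentialSpec("CA", 10.0), 30, config)
    per_run = series.per_run()
    mean_l = per_run["mean_bond_length"].mean()
    corr = per_run[series.corr_columns].mean().to_numpy() / mean_l**2
    s = np.arange(1, len(corr) + 1)
    use = corr > 0.05
    resid = np.polyfit(s[use], np.log(corr[use]), 1, full=True)[1]
    # residual variance of the straight-line fit is small
    assert resid[0] / use.sum() < 0.02


def test_observable_series_csv_round_trip(tmp_path):
    config = SimConfig(1_000, 2_000, 1_000, seed=7, n_runs=2)
    series = run(ModelSpec("SCLM", 32), PotentialSpec("CSA", 0.5), 6, config)
    path = tmp_path / "series.csv"
    series.to_csv(path)
    back = ObservableSeries.read_csv(path)
    assert back.n_bonds == series.n_bonds
    assert back.model_id == series.model_id
    assert back.potential == series.potential
    np.testing.assert_allclose(
        back.frame["re2"].to_numpy(), series.frame["re2"].to_numpy()
    )


def test_snapshot_export_and_reanalysis(tmp_path):
    """Saved conformations reproduce every observable on re-analysis."""
    from semiflex.simulator import series_from_snapshots_csv

    spec = PotentialSpec("CA", 2.0)
    config = SimConfig(2_000, 4_000, 1_000, seed=13, n_runs=2)
    snap_path = tmp_path / "snapshots.csv"
    series = run(ModelSpec("LBFM", 64), spec, 10, config,
                 snapshots_out=snap_path)
    rebuilt = series_from_snapshots_csv(snap_path, "LBFM", spec)
    for col in ("re2", "rg2", "mean_bond_length", "mean_cos_theta",
                "proj_first", "corr_1"):
        np.testing.assert_allclose(
            rebuilt.frame[col].to_numpy(), series.frame[col].to_numpy(),
            err_msg=col,
        )
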