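"""Scripted reproduction of the standard result sets at configurable scale.

Each experiment orchestrates the simulator, the estimators and the theory
module, writing CSV tables (the tested surface), PNG plots (conveniences)
and a JSON manifest recording every parameter and seed so any artifact can
be regenerated bit for bit.

Two scale profiles are provided.  ``full`` matches the reference study
conditions: chains of N = 50 bonds averaged over 100 independent runs with
long equilibration.  ``reduced`` is a fast profile for smoke runs and CI:
N = 30, 10 runs, ten-fold shorter schedules and k grids of at most 8
points.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import estimate_all
from .lattice import LatticeModel, enumerate_angle_classes, enumerate_bond_vectors
from .potentials import PotentialForm, PotentialSpec
from .simulator import ModelSpec, SimConfig, ObservableSeries, run
from .theory import lp_kuhn, mean_cos_continuous, theoretical_lp_curve

__all__ = ["ExperimentConfig", "run_experiment", "validate_counts",
           "default_schedule", "EXPERIMENTS"]

#: expected enumeration counts per model: (bond vectors, angle classes)
EXPECTED_COUNTS = {
    LatticeModel.BFM: (108, 87),
    LatticeModel.LBFM: (18, 6),
    LatticeModel.SCLM: (6, 2),
}


def default_schedule(k: float, profile: str = "full", seed: int = 0,
                     n_runs: "int | None" = None) -> SimConfig:
    """Equilibration and sampling schedule appropriate for a stiffness k.

    Stiffer chains relax more slowly under local moves, so the
    equilibration window grows with k.  The reduced profile divides all
    windows by ten and uses 10 runs instead of 100.
    """
    equil = 2_000_000 if k <= 10 else 10_000_000
    sample, interval, runs = 2_000_000, 10_000, 100
    if profile == "reduced":
        equil //= 10
        sample //= 10
        interval //= 10
        runs = 10
    elif profile != "full":
        raise ValueError(f"unknown profile {profile!r}")
    if n_runs is not None:
        runs = n_runs
    return SimConfig(equil, sample, interval, seed=seed, n_runs=runs)


@dataclass
class ExperimentConfig:
    """Parameters of one scripted experiment."""

    experiment: str
    out_dir: Path
    model: LatticeModel = LatticeModel.BFM
    potential_form: PotentialForm = PotentialForm.CA
    k_values: "list | None" = None
    n_bonds: "list | None" = None
    n_runs: "int | None" = None
    seed: int = 0
    box_length: "int | None" = None
    profile: str = "reduced"
    plots: bool = True

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        self.model = LatticeModel(self.model)
        self.potential_form = PotentialForm(self.potential_form)


def _box_for(k: float, config: ExperimentConfig) -> int:
    if config.box_length is not None:
        return config.box_length
    # stiff chains straighten out; give them room to stay below box/2
    return 512 if k > 10 else 256


def _n_bonds(config: ExperimentConfig) -> int:
    if config.n_bonds:
        return int(config.n_bonds[0])
    return 30 if config.profile == "reduced" else 50


def _k_grid(config: ExperimentConfig, default):
    if config.k_values:
        return list(config.k_values)
    ks = list(default)
    if config.profile == "reduced" and len(ks) > 8:
        ks = list(np.array(ks)[np.linspace(0, len(ks) - 1, 8).astype(int)])
    return ks


def _simulate_grid(config: ExperimentConfig, k_values, n_bonds, log=print):
    """One observable series per bending constant."""
    out = {}
    for k in k_values:
        spec = PotentialSpec(config.potential_form, float(k))
        model = ModelSpec(config.model, _box_for(k, config))
        sched = default_schedule(k, config.profile, seed=config.seed,
                                 n_runs=config.n_runs)
        out[k] = run(model, spec, n_bonds, sched, log=log)
    return out


def _size_table(series_by_k) -> pd.DataFrame:
    rows = []
    for k, series in series_by_k.items():
        per_run = series.per_run()
        re2 = per_run["re2"].mean()
        rg2 = per_run["rg2"].mean()
        rows.append(
            {
                "k": k,
                "re2": re2,
                "rg2": rg2,
                "ratio": re2 / rg2,
                "mean_cos_theta": per_run["mean_cos_theta"].mean(),
                "mean_bond_length": per_run["mean_bond_length"].mean(),
                "acceptance": series.acceptance_rate,
            }
        )
    return pd.DataFrame(rows)


def _estimator_table(series_by_k, n_bonds) -> pd.DataFrame:
    rows = []
    for k, series in series_by_k.items():
        est = estimate_all(series, n_bonds)
        rows.append(
            {
                "k": k,
                "lp_auto": est.lp_auto, "se_auto": est.se_auto,
                "lp_theta": est.lp_theta, "se_theta": est.se_theta,
                "lp_ee": est.lp_ee, "se_ee": est.se_ee,
                "lp_wlc": est.lp_wlc, "se_wlc": est.se_wlc,
                "mean_bond_length": est.mean_bond_length,
                "contour_length": est.contour_length,
            }
        )
    return pd.DataFrame(rows)


def _plot_lines(df, x, ys, path, logy=False, xlabel=None, ylabel=None):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for y in ys:
        if y in df:
            ax.plot(df[x], df[y], marker="o", ms=3, label=y)
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel(xlabel or x)
    ax.set_ylabel(ylabel or ", ".join(ys))
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# experiment bodies


def _exp_chain_size(config: ExperimentConfig, form: PotentialForm):
    config.potential_form = form
    ks = _k_grid(config, [0, 1, 2, 5, 10, 15, 20] if form is PotentialForm.CA
                 else [0, 5, 10, 20, 40, 80, 120])
    n = _n_bonds(config)
    series = _simulate_grid(config, ks, n)
    table = _size_table(series)
    table["mean_cos_theory"] = [
        mean_cos_continuous(PotentialSpec(form, float(k))) for k in table["k"]
    ]
    return {"chain_size.csv": table}, series


def _exp_correlation(config: ExperimentConfig):
    ks = _k_grid(config, [5, 10, 15, 20])
    n = _n_bonds(config)
    series = _simulate_grid(config, ks, n)
    frames = []
    for k, s in series.items():
        per_run = s.per_run()
        mean_l = per_run["mean_bond_length"].mean()
        corr = per_run[s.corr_columns].mean() / mean_l**2
        frames.append(pd.DataFrame({
            "k": k,
            "s": np.arange(1, len(corr) + 1),
            "corr": corr.to_numpy(),
        }))
    return {"orientation_correlation.csv": pd.concat(frames, ignore_index=True)}, series


def _exp_estimators(config: ExperimentConfig, form: PotentialForm):
    config.potential_form = form
    ks = _k_grid(config, [1, 2, 5, 7, 10, 13, 16, 20] if form is PotentialForm.CA
                 else [2, 5, 10, 20, 40, 60, 90, 120])
    n = _n_bonds(config)
    series = _simulate_grid(config, ks, n)
    table = _estimator_table(series, n)
    table["lp_th_over_l"] = [
        lp_kuhn(mean_cos_continuous(PotentialSpec(form, float(k)))) for k in table["k"]
    ]
    return {"persistence_lengths.csv": table}, series


def _exp_chain_length(config: ExperimentConfig):
    ks = _k_grid(config, [2, 5, 10, 15, 20])
    n_list = config.n_bonds or ([20, 30] if config.profile == "reduced" else [20, 50, 70])
    tables = {}
    for n in n_list:
        series = _simulate_grid(config, ks, int(n))
        tables[f"persistence_lengths_N{n}.csv"] = _estimator_table(series, int(n))
    return tables, None


def _exp_lattice_theory(config: ExperimentConfig, lattice: LatticeModel,
                        simulate: bool = True):
    """Discrete-lattice vs continuous theory, with simulated lp_theta overlay."""
    tables = {}
    for form, kmax in ((PotentialForm.CA, 100), (PotentialForm.CSA, 280)):
        grid = np.linspace(0.5, kmax, 60)
        cont = theoretical_lp_curve("continuous", form, grid)
        disc = theoretical_lp_curve(lattice, form, grid)
        tables[f"theory_{form.value.lower()}.csv"] = pd.DataFrame(
            {
                "k": grid,
                "lp_th_continuous": cont.lp_over_l,
                f"lp_{lattice.value}_discrete": disc.lp_over_l,
            }
        )
    if simulate:
        config.model = lattice
        ks = _k_grid(config, [2, 5, 10, 15, 20])
        n = _n_bonds(config)
        series = _simulate_grid(config, ks, n)
        table = _estimator_table(series, n)
        tables["lp_theta_sim.csv"] = table[
            ["k", "lp_theta", "se_theta", "mean_bond_length"]
        ].assign(lp_theta_over_l=lambda d: d.lp_theta / d.mean_bond_length)
    return tables, None


EXPERIMENTS = {
    "fig2": lambda c: _exp_chain_size(c, PotentialForm.CA),
    "fig3": _exp_correlation,
    "fig4": lambda c: _exp_estimators(c, PotentialForm.CA),
    "fig5": _exp_chain_length,
    "fig6": lambda c: _exp_chain_size(c, PotentialForm.CSA),
    "fig7": lambda c: _exp_estimators(c, PotentialForm.CSA),
    "fig9": lambda c: _exp_lattice_theory(c, LatticeModel.BFM),
    "fig10": lambda c: _exp_lattice_theory(c, LatticeModel.LBFM),
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one scripted experiment; returns {filename: DataFrame} written."""
    if config.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {config.experiment!r}; "
            f"choose from {sorted(EXPERIMENTS)}"
        )
    config.out_dir.mkdir(parents=True, exist_ok=True)
    tables, _series = EXPERIMENTS[config.experiment](config)
    for name, df in tables.items():
        df.to_csv(config.out_dir / name, index=False)
        if config.plots:
            ycols = [c for c in df.columns
                     if c not in ("k", "s") and not c.startswith("se_")
                     and df[c].dtype.kind == "f"]
            xcol = "k" if "k" in df else "s"
            _plot_lines(df, xcol, ycols[:6],
                        config.out_dir / (Path(name).stem + ".png"),
                        logy=config.experiment in ("fig3", "fig9", "fig10"))
    manifest = dataclasses.asdict(config)
    manifest["out_dir"] = str(config.out_dir)
    manifest["model"] = config.model.value
    manifest["potential_form"] = config.potential_form.value
    manifest["outputs"] = sorted(tables)
    (config.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tables


def validate_counts() -> pd.DataFrame:
    """Check the enumerated vector and angle-class counts of every model.

    Returns a table with observed and expected counts; raises ValueError on
    any mismatch (the CLI converts that into a nonzero exit status).
    """
    rows = []
    ok = True
    for model, (n_vec, n_ang) in EXPECTED_COUNTS.items():
        got_vec = len(enumerate_bond_vectors(model))
        dist = enumerate_angle_classes(model)
        got_ang = len(dist)
        f_sum = float(dist.probabilities.sum())
        rows.append(
            {
                "model": model.value,
                "vectors": got_vec, "vectors_expected": n_vec,
                "angle_classes": got_ang, "angle_classes_expected": n_ang,
                "f_sum": f_sum,
            }
        )
        ok &= got_vec == n_vec and got_ang == n_ang and abs(f_sum - 1) < 1e-12
    table = pd.DataFrame(rows)
    if not ok:
        raise ValueError(f"enumeration counts mismatch:\n{table}")
    return table
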