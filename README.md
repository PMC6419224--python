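# semiflex

Lattice Monte Carlo simulation of single semiflexible polymers and a
complete toolkit for measuring and predicting their persistence length.

Semiflexible polymers — DNA, filaments, polyelectrolytes, liquid-crystal
polymers — are characterised by the persistence length l_p, the decay
length of bond-orientation memory along the backbone. In simulations the
stiffness is imposed through a bending potential between successive bonds,
either the cosine-angle form E/k_BT = k (1 − cos θ) (the discretised
worm-like chain) or the cosine-squared form E/k_BT = k (1 − cos θ)², and a
recurring practical question is what l_p a given bending constant k
actually produces — especially on a lattice, where the bond angle θ is
discrete. This package is for simulators who need that mapping, and for
anyone comparing persistence-length estimators against each other and
against theory.

## What is inside

* **Lattice models** (`semiflex.lattice`): exact enumeration of the bond
  vectors and bond-angle classes of the bond fluctuation model (BFM: 108
  bond vectors, 87 angles), the Larson-type bond fluctuation model
  (L-BFM: 18 vectors, 6 angles) and the simple cubic lattice model
  (SCLM: 6 vectors, 2 angles), including each angle's a-priori probability
  f_i among excluded-volume-feasible bond pairs.
* **Theory** (`semiflex.theory`): the continuous Boltzmann average
  ⟨cos θ⟩ = ∫ cos θ sin θ e^(−E) dθ / ∫ sin θ e^(−E) dθ in closed form for
  both potentials (CA: coth k − 1/k; CSA:
  1 − (1 − e^(−4k)) / (√(πk) erf(2√k))), its discrete-lattice counterpart
  ⟨cos θ⟩ = Σ f_i cos θ_i e^(−E_i) / Σ f_i e^(−E_i), and the conversions
  l_p/l = (1 + ⟨cos θ⟩)/(2(1 − ⟨cos θ⟩)) (Kuhn) and
  l_p/l = −1/ln⟨cos θ⟩, plus power-law and exponential fitting of the
  resulting stiffness laws (BFM+CA: l_p ~ k^2.3 at 40 < k < 100;
  L-BFM: l_p ~ e^(0.29 k) for CA and ~ e^(0.086 k) for CSA;
  SCLM: l_p → e^k/4).
* **Simulator** (`semiflex.simulator`): Metropolis Monte Carlo of one
  self-avoiding chain on a periodic cubic lattice with a numba-compiled
  inner loop (~10⁷ attempted moves/s), L6 moves for the BFM, 18-direction
  moves for the L-BFM, seeded and bit-reproducible.
* **Estimators** (`semiflex.estimators`): the four standard routes from
  trajectories to l_p — bond-orientation correlation decay (lp_auto),
  mean bond angle (lp_theta), Flory projection of the end-to-end vector on
  the first bond (lp_ee), and inversion of the worm-like-chain
  ⟨Re²⟩ = 2 l_p L {1 − (l_p/L)[1 − e^(−L/l_p)]} (lp_wlc) — with
  run-to-run standard errors.
* **Synthetic ground truth** (`semiflex.synthetic`): ideal off-lattice
  chains with Boltzmann-distributed bond angles for validating the
  estimators.
* **CLI** (`semiflex`): `theory`, `simulate`, `estimate`, `reproduce`
  (scripted experiment sets at reduced or full scale) and
  `validate-counts`.

## Worked example

Simulate a BFM chain of 30 bonds at bending constant k = 5 (cosine-angle
potential), apply all four estimators and compare with theory:

```python
from semiflex import *

spec = PotentialSpec("CA", 5.0)
series = run(ModelSpec("BFM", 256), spec, 30,
             SimConfig(n_equil_mcs=200_000, n_sample_mcs=400_000,
                       sample_interval=1_000, seed=7, n_runs=4))
est = estimate_all(series)
print(f"mean bond length: {est.mean_bond_length:.4f}")
print(f"lp_theta = {est.lp_theta:.2f} +- {est.se_theta:.2f}")
print(f"lp_auto  = {est.lp_auto:.2f} +- {est.se_auto:.2f}")
print(f"lp_ee    = {est.lp_ee:.2f} +- {est.se_ee:.2f}")
print(f"lp_wlc   = {est.lp_wlc:.2f} +- {est.se_wlc:.2f}")

c = mean_cos_discrete("BFM", spec)
print(f"discrete-lattice theory: lp = {lp_log(c) * est.mean_bond_length:.2f}")
cc = mean_cos_continuous(spec)
print(f"continuous theory      : lp = {lp_log(cc) * est.mean_bond_length:.2f}")
```

Output:

```
mean bond length: 2.6908
lp_theta = 12.70 +- 0.19
lp_auto  = 14.33 +- 1.46
lp_ee    = 14.49 +- 1.48
lp_wlc   = 14.22 +- 1.57
discrete-lattice theory: lp = 12.36
continuous theory      : lp = 12.06
```

All lengths are in lattice units. The BFM bond length averages 2.69, so
k = 5 produces a persistence length of about 12–14 lattice units
(l_p/l ≈ 4.6); at this moderate stiffness the four estimators agree within
their error bars and sit close to both the continuous and the 87-angle
discrete-lattice prediction, which only separate at high k. The local
bond-angle estimator (lp_theta) is the sharpest, consistent with its use
of per-bond rather than chain-scale statistics.

From the command line, the same machinery:

```bash
semiflex validate-counts          # enumeration self-check (108/87, 18/6, 6/2)
semiflex theory --models continuous,BFM --potential CA --k-max 100 --out theory.csv
semiflex simulate --model BFM --k 5 -N 30 --runs 4 --seed 7 --out series.csv
semiflex estimate series.csv
semiflex reproduce fig9 --out-dir out/fig9 --profile reduced
```

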