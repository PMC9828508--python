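# atomgpr

Atomic Gaussian process regression (GPR) potentials trained by
expected-prediction-error active learning.

## The problem

Machine-learning force fields for molecular simulation predict a
molecule's energy as a sum of *atomic* energies, each regressed on
geometric descriptors of the atom's environment. The accuracy of such a
model is set almost entirely by its training set, and every training
label costs an expensive quantum-chemical calculation — so the practical
question is *which* configurations to label. `atomgpr` implements the
full desk-scale pipeline for answering that question:

* **Features** — each atom gets an *atomic local frame* (ALF: origin,
  x-axis atom, xy-plane atom) and a translation/rotation-invariant
  feature vector of length 3N−6: two ALF distances, the valence angle,
  then spherical polars (r, θ, φ) of every remaining atom. Azimuths are
  cyclic and compared on the circle.
* **Model** — ordinary kriging per atom with the cyclic squared-exponential
  kernel k(x, x\*) = exp(−Σ_d θ_d r_d(x_d, x\*_d)²), constant mean μ = ȳ,
  precomputed weights α = R⁻¹(y−μ), and the ordinary-kriging predictive
  variance s²(x\*) = σ²(1 − rᵀR⁻¹r + (1−**1**ᵀR⁻¹r)²/(**1**ᵀR⁻¹**1**)).
* **Hyperparameters** — θ is fit by maximizing the marginal log-likelihood
  with a particle swarm (ω = 0.729, φ_p = φ_g = 1.490, θ ∈ [0, 3],
  relative-difference stall rule σ_thresh = 10⁻⁷ over n_stall = 20).
* **Acquisition** — each sample point is scored by the expected prediction
  error EPE(x) = α·PE²_CV(x) + (1−α)·s²(x), where PE²_CV is a closed-form
  leave-one-out cross-validation error propagated through a Voronoi
  partition of the training set, and the balance factor α (0.5 initially,
  capped at 0.99) adapts each iteration from how well the previous batch's
  CV estimate anticipated the realized error. The batch with the largest
  EPE is labelled and absorbed; per-atom mode gives every atom its own
  independent training set, per-system mode shares one set and acquires
  on atom-summed scores.
* **Synthetic oracle** — a transparent harmonic + Lennard-Jones toy
  potential whose per-atom partition sums *exactly* to the total energy,
  plus a temperature-controlled distortion sampler with minimum-distance
  rejection, stand in for the AIMD/QM stages so the loop runs in seconds.

## Worked example

```sh
python examples/04_active_learning.py
```

runs per-atom active learning (batch 5) on a 400-frame synthetic water
trajectory and prints:

```
atom  iterations  ntrain  first RMSE  final RMSE  (kJ/mol, validation)
   0          7      39      0.9703      0.0285
   1          7      39      0.7807      0.0042
   2          7      39      0.3839      0.0039
```

Each row is one atomic model: starting from the min/max/mean feature seed
set (~9 frames), six acquisition rounds grow the training set to 39
points and push the held-out error per atom from ~1 kJ/mol to the
0.01 kJ/mol scale — comfortably below the 1 kJ/mol threshold usually
called chemical accuracy for atomic energies. The other examples cover
sampling/labelling, feature invariance, single-model fitting with PSO,
and S-curve/true-vs-predicted evaluation.

A thin CLI mirrors the scripts: `atomgpr sample`, `atomgpr init-sets`,
`atomgpr learn`, `atomgpr evaluate`, `atomgpr superpose`.

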