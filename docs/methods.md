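# Methods

This note records the model, the numerical choices, and what the
synthetic test-bed does and does not establish.

## Atomic local frames and features

Each atom is assigned a local frame from three atoms: itself (origin),
an x-axis partner and an xy-plane partner. Partners are chosen once, on
a reference geometry, from the covalent bonding graph (pair bonded when
the distance is below 1.2× the sum of Cordero covalent radii) by a
Cahn–Ingold–Prelog-like priority: candidates bonded to the origin are
ranked by atomic mass, ties broken by comparing breadth-first spheres of
substituent masses, final ties by lowest atom index. Atoms with fewer
than two bonded partners extend the candidate list by distance; a fully
disconnected atom triggers a logged warning and pure nearest-neighbour
selection. Freezing the ALF on the reference frame prevents frame
flipping across a trajectory.

Features of an atom in an N-atom molecule (3N−6 of them): distance to
the x-axis atom, distance to the xy-plane atom, the angle between those
two bonds, then (r, θ, φ) spherical polars of every non-ALF atom in
ascending atom index. Local axes: x̂ along origin→x-axis atom,
ẑ = x̂ × (origin→xy-plane) normalized, ŷ = ẑ × x̂; θ ∈ [0, π] from ẑ,
φ ∈ (−π, π] in the xy-plane. The representation is complete — the test
suite reconstructs Cartesian geometry from features and re-featurizes to
machine precision.

With 1-based dimension numbering, every dimension d with d mod 3 = 0 is
flagged cyclic: that marks every azimuth φ (d = 6, 9, …) and also the
ALF valence angle (d = 3), which is harmless since valence angles live
in [0, π] where the 2π wrap is the identity. Cyclic differences are
((Δ + π) mod 2π) − π, so their magnitude never exceeds π.

## Gaussian process regression

Per atom, ordinary kriging with kernel
k(x, x\*) = exp(−Σ_d θ_d r_d²), constant mean μ = ȳ, weights
α = R⁻¹(y − μ), and predictive variance
s² = σ²(1 − rᵀR⁻¹r + (1 − 1ᵀR⁻¹r)²/(1ᵀR⁻¹1)), clamped at zero. There
is no signal-amplitude hyperparameter in the kernel; the process
variance enters only through the plug-in estimate
σ̂² = (y−μ)ᵀR⁻¹(y−μ)/n (the maximum-likelihood value for a fixed
constant mean), which scales the variance but not the predictive mean.

All solves go through one Cholesky factorization of R + nugget·I. The
nugget is numerical conditioning only (the data are noise-free): default
10⁻¹⁰, escalated tenfold on factorization failure up to 10⁻⁴, beyond
which an ill-conditioned-model error is raised (the swarm treats such a
point as −∞ and continues). Prediction never refactorizes R, so its
cost is linear in the training-set size. Models serialize to JSON (one
file per atom: ALF triple, cyclic mask, θ, nugget, μ, σ², X, y, weights)
and reload bit-comparably.

## Hyperparameter optimization

θ is fit by maximizing the marginal log-likelihood with a plain global
PSO: inertia 0.729, cognitive and social rates 1.490, box [0, 3] per
dimension. Positions *and* velocities initialize uniformly on the box
(the all-positive initial velocities are deliberate); positions clamp at
the bounds with the velocity zeroed on the clamped dimension; r₁, r₂ are
drawn per particle per dimension; personal and global bests update once
per cycle. Stopping: the relative change of the global best stays below
10⁻⁷ for 20 consecutive iterations (absolute change when the reference
is zero), or an iteration cap (default 1000). Swarm size defaults to
max(4·ndim, 50); the desk-scale runs in tests and examples use 15–25
particles and 40–100 iterations, which recover optima of the separable
test objectives to 10⁻² and keep a full active-learning run in seconds.

## Leave-one-out cross-validation

The exploitation signal is the squared LOO error of each training point.
The literal computation (refit without the point, predict it) is O(n⁴)
per model, so acquisition uses the closed form

e_i = [R⁻¹(d + H[:,i] · d_i/(1 − H_ii))]_i / (R⁻¹)_ii,  PE²_CV = e_i²,

with the constant-basis hat matrix H = J/n, GLS constant
β̂ = (1ᵀR⁻¹y)/(1ᵀR⁻¹1) and d = y − β̂. Note the two mean conventions
coexist deliberately: prediction uses μ = ȳ while the CV closed form
uses β̂. Validated against the literal refit on random instances
(n ≤ 30): instance-level RMS LOO errors agree to ~0.6% at the median and
~10% at the 90th percentile with per-point ratios centred on one (no
systematic bias); isolated points in one-dimensional designs form a
heavy tail (worst observed ≈2× on an instance's RMS), driven by the
ȳ-vs-β̂ difference, not by the grouping of the closed form. Since
acquisition consumes only the *ranking* of errors, this accuracy is
ample; the acceptance suite pins the distributional bound.

If a diagonal element of R⁻¹ is non-positive (numerically broken), that
point falls back to the exact refit with a logged warning.

Sample points inherit the CV error of their nearest training point
(Voronoi assignment). The metric is unweighted Euclidean distance in
feature space with cyclic wrapping — unweighted rather than θ-weighted
so that assignments do not jump discontinuously when θ is refit.

## Acquisition and the balance factor

EPE(x) = α·PE²_CV(x) + (1−α)·s²(x). α = 0.5 at the first iteration;
afterwards α = 0.99·min(0.5·PE²_true/PE²_CV, 1) using the previous
batch's realized squared error (measured with the model that selected
it) against its CV estimate at selection time, so α ∈ [0, 0.99]; a zero
CV estimate is treated as an infinite ratio (α = 0.99). With batches,
each added point contributes its own α and the mean is used next
iteration. The batch is the `batch_size` sample points with the largest
EPE, ties to the lower frame index; selected frames move from the sample
set to the training set.

Runs are organized over *atom groups*: per-atom mode is one singleton
group per atom (independent training sets; each group queries the
oracle only for its own atom, and any execution order gives identical
results), per-system mode is one group of all atoms sharing a training
set, with CV error, variance and realized error summed over atoms. The
group-sum formulas reduce exactly to the single-model ones for one atom,
and group RNG streams are derived from (seed, atom indices), so a
one-atom per-system run is bit-identical to the per-atom run — asserted
in the tests. The per-system initial training set is the union of the
per-atom min/max/mean selections.

Set initialization: per feature dimension, the argmin frame, argmax
frame, and the frame nearest the dimension mean (lowest index on ties),
deduplicated — at most 3·ndim frames. The sample and validation sets
default to 10 000 and 500 frames drawn randomly from the remainder,
shrinking proportionally (with a warning) when fewer frames exist.
Stopping: training-set size cap (default 500 per atom), an optional
validation-RMSE target, or sample-set exhaustion. Hyperparameters are
refit every iteration by default (`refit_every` relaxes this).

## Synthetic oracle

The generator emulates the two upstream stages of a production pipeline.
*Sampling*: Gaussian displacements along randomized orthonormal
directions spanning the internal subspace of Cartesian space (net
translation and rotation projected out), with per-mode standard
deviation 0.002·√T Å — at the 300 K label this gives bond-length
fluctuations of a few hundredths of an Å, a realistic vibrational
scale — and rejection of candidates closer than `min_dist_cutoff` (in
all-atom feature space) to any accepted frame. The default cutoff is 0
(no rejection); `suggest_cutoff` implements the 1%-of-median-
nearest-neighbour heuristic for callers who want one. Temperature is a
monotone spread control, not thermodynamic Kelvin; tests assert only
monotonicity.

*Labels*: a toy PES of harmonic bonds and angles plus Lennard-Jones
nonbonded pairs, with each pair term split half/half and each angle term
a third per atom, so Σ_a e_a = E_total to machine precision — the exact
additivity that real topological energy partitions provide and that the
per-atom model architecture relies on. Built-in systems (water, ammonia,
a 12-atom carbon chain covering 3, 6 and 30 feature dimensions) place
every equilibrium parameter at the seed geometry, so each geometry is a
stationary point of its own PES (finite-difference gradient < 10⁻⁶).

What passing on this test-bed shows: the acquisition machinery, the
closed forms and the bookkeeping are correct, and EPE acquisition beats
random selection on a smooth low-dimensional surface. What it does not
show: performance on real ab initio surfaces with anharmonicity,
many-body couplings, label noise from SCF/partitioning convergence, or
feature dimensions in the tens — those claims require real data.

## Desk-scale study conditions

The end-to-end acceptance comparison uses synthetic water at the 300 K
distortion label: 500-frame trajectories, per-atom training sets grown
from the seed set to 40 points (batches of 1 and 5), swarms of 20
particles × 60 iterations, 5 seeds, with median final validation RMSE
compared between EPE and random acquisition at equal label budget.
These sizes keep the whole loop to a few seconds per run while leaving
a clear gap between the initial (~1 kJ/mol) and final (~0.01 kJ/mol)
error scales.

## Known limitations

* No force/gradient learning; outputs are scalar atomic energies.
* No sparse approximations: training is O(n³), appropriate for the
  few-hundred-point sets this method is designed to produce.
* The ALF partner-priority rule is a deterministic, chemistry-aware
  choice; other conventions produce equally valid (but different)
  feature spaces, so models are not transferable across conventions.
* Feature ordering enumerates non-ALF atoms by ascending index; this is
  a convention, fixed and documented rather than uniquely principled.
* The fast LOO closed form degrades for isolated points in very
  low-dimensional designs (see above); acquisition rankings are robust
  to this in practice, but absolute CV magnitudes from 1-D models
  should not be over-interpreted.
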