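"""Expected-prediction-error (EPE) active learning for atomic GPR models.

The acquisition rule scores every sample-set point by a convex
combination of two terms:

* exploitation — an approximated leave-one-out cross-validation (LOO-CV)
  error, propagated from training points to sample points through a
  Voronoi partition of feature space;
* exploration — the ordinary-kriging predictive variance.

``EPE(x) = alpha * PE_CV^2(x) + (1 - alpha) * s^2(x)``

The balance factor alpha starts at 0.5 and is re-estimated each iteration
from how well the previous iteration's CV approximation anticipated the
realized prediction error of the point(s) just added; it is capped at
0.99.  The ``batch_size`` points with the largest EPE are added per
iteration, and with batches the next alpha is the mean of the per-point
balance factors.

Runs are organized over *atom groups*: per-atom mode trains each atomic
model on its own training set (one singleton group per atom, fully
independent, any execution order), while per-system mode shares one
training set across all atoms and acquires on the atom-summed CV error,
variance and realized error.  A one-atom system makes the two modes
coincide exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gpr, pso
from .alf import ALFDefinition, compute_alf, cyclic_mask, featurize_trajectory
from .gpr import GPRModel, Hyperparameters
from .molio import Trajectory

__all__ = [
    "ALConfig",
    "ALState",
    "ALResult",
    "EPEReport",
    "init_training_set",
    "partition_sets",
    "loo_cv_error_exact",
    "loo_cv_error_fast",
    "assign_voronoi",
    "balance_factor",
    "batch_balance_factor",
    "expected_prediction_error",
    "aggregate_per_system",
    "select_points",
    "run_active_learning",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# set initialization

def init_training_set(features: np.ndarray) -> list[int]:
    """Initial training frames: per feature dimension, the argmin frame,
    the argmax frame, and the frame closest to the dimension mean.

    Duplicates collapse, so the set holds at most ``3 * ndim`` frames and
    scales linearly with dimensionality.  Ties go to the lowest frame
    index (argmin/argmax already do; nearest-to-mean does explicitly).
    """
    features = np.atleast_2d(np.asarray(features, float))
    if features.size == 0:
        raise ValueError("empty feature matrix")
    chosen: list[int] = []
    for d in range(features.shape[1]):
        col = features[:, d]
        chosen.append(int(np.argmin(col)))
        chosen.append(int(np.argmax(col)))
        chosen.append(int(np.argmin(np.abs(col - col.mean()))))
    return sorted(set(chosen))


def partition_sets(trajectory_size: int, train_idx: list[int],
                   sample_size: int = 10000, valid_size: int = 500,
                   rng: np.random.Generator | int = 0
                   ) -> tuple[list[int], list[int]]:
    """Randomly split the non-training frames into sample and validation
    sets (defaults 10000 / 500), shrinking proportionally when fewer
    frames remain."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    remaining = np.array(sorted(set(range(trajectory_size)) - set(train_idx)))
    if len(remaining) < 2:
        raise ValueError(
            f"cannot partition: only {len(remaining)} non-training frames")
    want = sample_size + valid_size
    if len(remaining) < want:
        frac = valid_size / want
        valid_size = max(1, int(round(frac * len(remaining))))
        sample_size = len(remaining) - valid_size
        logger.warning("shrinking sample/validation sets to %d/%d",
                       sample_size, valid_size)
    perm = rng.permutation(remaining)
    sample = sorted(int(i) for i in perm[:sample_size])
    valid = sorted(int(i) for i in perm[sample_size:sample_size + valid_size])
    return sample, valid


# ---------------------------------------------------------------------------
# leave-one-out cross-validation errors

def loo_cv_error_exact(X: np.ndarray, y: np.ndarray, theta: Hyperparameters,
                       mask: np.ndarray, i: int,
                       nugget: float = gpr.DEFAULT_NUGGET) -> float:
    """Squared LOO error of training point i by literal refit-and-predict."""
    y = np.asarray(y, float)
    if len(y) < 2:
        raise ValueError("need at least 2 training points for LOO")
    keep = [j for j in range(len(y)) if j != i]
    sub = gpr.fit(X[keep], y[keep], theta, mask, nugget)
    pred = gpr.predict(sub, X[i], with_variance=False)
    return float((y[i] - pred.mean) ** 2)


def loo_cv_error_fast(model: GPRModel) -> np.ndarray:
    """Closed-form approximation of all squared LOO errors at once.

    With a single constant basis function the hat matrix is ``H = J/n``
    (J all-ones) and the generalized-least-squares constant is
    ``beta = (1'R^-1 y)/(1'R^-1 1)``; the i-th LOO residual is
    approximated by

        e_i = [R^-1 (d + H[:, i] * d_i / (1 - H_ii))]_i / (R^-1)_ii

    with ``d = y - beta``.  Any point whose ``(R^-1)_ii`` is not strictly
    positive (numerically broken) falls back to the exact refit.
    """
    n = model.ntrain
    if n < 2:
        raise ValueError("need at least 2 training points for LOO")
    Rinv = model.factor.inverse()
    ones = np.ones(n)
    Rinv_1 = Rinv @ ones
    beta = float(ones @ (Rinv @ model.y)) / float(ones @ Rinv_1)
    d = model.y - beta
    # H[:, i] = (1/n) * ones and H_ii = 1/n, so the correction term
    # collapses to (R^-1 1)_i * d_i / (n - 1)
    Rinv_d = Rinv @ d
    diag = np.diag(Rinv).copy()
    e = np.empty(n)
    bad = diag <= 0
    good = ~bad
    e[good] = (Rinv_d[good] + Rinv_1[good] / n * d[good] / (1.0 - 1.0 / n)
               ) / diag[good]
    if np.any(bad):
        for i in np.flatnonzero(bad):
            logger.warning("fast LOO fell back to exact refit for point %d", i)
            e[i] = np.sqrt(loo_cv_error_exact(
                model.X, model.y, model.theta, model.cyclic_mask, int(i),
                model.nugget))
    return e ** 2


def assign_voronoi(sample_features: np.ndarray, train_features: np.ndarray,
                   train_cv2: np.ndarray, mask: np.ndarray | None = None
                   ) -> np.ndarray:
    """Propagate training-point CV errors to sample points: each sample
    point inherits the CV^2 of its nearest training point (unweighted
    Euclidean distance with the cyclic wrap on cyclic dims; ties to the
    lower training index)."""
    sample_features = np.atleast_2d(sample_features)
    train_features = np.atleast_2d(train_features)
    if mask is None:
        mask = np.zeros(train_features.shape[1], dtype=bool)
    d = sample_features[:, None, :] - train_features[None, :, :]
    wrapped = np.mod(d + np.pi, 2 * np.pi) - np.pi
    d = np.where(mask[None, None, :], wrapped, d)
    dist2 = np.einsum("ijd,ijd->ij", d, d)
    nearest = np.argmin(dist2, axis=1)  # argmin takes the first (lowest) index
    return np.asarray(train_cv2, float)[nearest]


# ---------------------------------------------------------------------------
# balance factor and acquisition

def balance_factor(pe_true2_prev: float, pe_cv2_prev: float, q: int) -> float:
    """Exploration/exploitation weight alpha.

    alpha = 0.5 on the first iteration; afterwards
    ``0.99 * min(0.5 * PE_true^2 / PE_CV^2, 1)`` using the previous
    iteration's realized and cross-validation errors, so alpha always
    lies in [0, 0.99].  A zero CV error makes the ratio infinite, hence
    the cap value 0.99.
    """
    if q < 1:
        raise ValueError("iteration counter q starts at 1")
    if q == 1:
        return 0.5
    if pe_true2_prev < 0 or pe_cv2_prev < 0:
        raise ValueError("squared errors must be non-negative")
    if pe_cv2_prev == 0:
        return 0.99
    return 0.99 * min(0.5 * pe_true2_prev / pe_cv2_prev, 1.0)


def batch_balance_factor(alphas: np.ndarray) -> float:
    """Mean of per-point balance factors from the previous batch."""
    alphas = np.asarray(alphas, float)
    if alphas.size == 0:
        raise ValueError("need at least one balance factor")
    return float(alphas.mean())


def expected_prediction_error(cv2, s2, alpha: float):
    """EPE = alpha * PE_CV^2 + (1 - alpha) * s^2 (elementwise)."""
    return alpha * np.asarray(cv2, float) + (1.0 - alpha) * np.asarray(s2, float)


def aggregate_per_system(per_atom_cv2: np.ndarray, per_atom_s2: np.ndarray,
                         per_atom_pe_true2: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum per-atom CV errors, variances and realized errors over atoms.

    Inputs are stacked per-atom arrays (first axis = atoms); outputs drop
    that axis.  A one-atom system returns its inputs unchanged.
    """
    cv2 = np.asarray(per_atom_cv2, float)
    s2 = np.asarray(per_atom_s2, float)
    pe = np.asarray(per_atom_pe_true2, float)
    if not (cv2.shape == s2.shape == pe.shape):
        raise ValueError("per-atom arrays must share a shape")
    return cv2.sum(axis=0), s2.sum(axis=0), pe.sum(axis=0)


def select_points(epe: np.ndarray, batch_size: int) -> list[int]:
    """Indices of the ``batch_size`` largest EPE values, ties broken by
    the lower sample index.  An empty sample set signals the loop to stop
    by returning an empty list."""
    epe = np.asarray(epe, float)
    if epe.size == 0:
        return []
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    batch_size = min(batch_size, epe.size)
    order = np.lexsort((np.arange(epe.size), -epe))
    return [int(i) for i in order[:batch_size]]


# ---------------------------------------------------------------------------
# state containers

@dataclass
class EPEReport:
    """Per-sample-point acquisition ingredients for one iteration."""

    cv2: np.ndarray
    s2: np.ndarray
    epe: np.ndarray
    alpha: float


@dataclass
class ALState:
    """Bookkeeping for one atom group's active-learning run."""

    atoms: tuple[int, ...]
    train_idx: list[int]
    sample_idx: list[int]
    valid_idx: list[int]
    q: int = 1
    alpha: float = 0.5
    last_added: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        sets = [set(self.train_idx), set(self.sample_idx), set(self.valid_idx)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("train/sample/validation sets must be disjoint")


@dataclass
class ALResult:
    """Final models plus the per-iteration history of each atom group."""

    models: dict[int, GPRModel]
    states: dict[tuple[int, ...], ALState]
    history: pd.DataFrame

    def history_csv(self, path) -> None:
        self.history.to_csv(path, index=False)


@dataclass
class ALConfig:
    mode: str = "per_atom"            # per_atom | per_system
    batch_size: int = 1
    sample_size: int = 10000
    valid_size: int = 500
    max_train: int = 500
    target_rmse: float | None = None
    seed: int = 0
    refit_every: int = 1
    acquisition: str = "mepe"         # mepe | random (baseline)
    nugget: float = gpr.DEFAULT_NUGGET
    atoms: list[int] | None = None
    swarm: pso.SwarmConfig = field(default_factory=pso.SwarmConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("per_atom", "per_system"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.acquisition not in ("mepe", "random"):
            raise ValueError(f"unknown acquisition {self.acquisition!r}")


# ---------------------------------------------------------------------------
# the outer loop

def _group_rng(seed: int, atoms: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng([seed, *atoms])


def _fit_atom(X: np.ndarray, y: np.ndarray, mask: np.ndarray,
              theta: Hyperparameters | None, refit: bool,
              config: ALConfig, rng: np.random.Generator
              ) -> tuple[GPRModel, Hyperparameters]:
    if refit or theta is None:
        objective = lambda th: gpr.log_marginal_likelihood(
            X, y, Hyperparameters(th), mask, config.nugget)
        child = np.random.default_rng(rng.integers(2 ** 31))
        best, _, _ = pso.optimize(objective, X.shape[1], config.swarm,
                                  rng=child)
        theta = Hyperparameters(best)
    return gpr.fit(X, y, theta, mask, config.nugget), theta


def _run_group(trajectory: Trajectory, oracle, atoms: tuple[int, ...],
               alf: ALFDefinition, config: ALConfig
               ) -> tuple[dict[int, GPRModel], ALState, list[dict]]:
    rng = _group_rng(config.seed, atoms)
    ndim = 3 * trajectory[0].natoms - 6
    mask = cyclic_mask(ndim)
    feats = {a: featurize_trajectory(trajectory, alf, a) for a in atoms}

    train: list[int] = sorted(set().union(
        *(init_training_set(feats[a]) for a in atoms)))
    sample, valid = partition_sets(len(trajectory), train,
                                   config.sample_size, config.valid_size, rng)
    state = ALState(atoms=atoms, train_idx=train, sample_idx=sample,
                    valid_idx=valid)

    y_true_valid = {a: np.array([oracle.atomic_energy(f, a) for f in valid])
                    for a in atoms}
    thetas: dict[int, Hyperparameters | None] = {a: None for a in atoms}
    models: dict[int, GPRModel] = {}
    history: list[dict] = []

    while True:
        refit = (state.q - 1) % config.refit_every == 0
        cv2_atoms, s2_atoms, mean_atoms = [], [], {}
        sample_arr = np.array(state.sample_idx, dtype=int)
        for a in atoms:
            X = feats[a][state.train_idx]
            y = np.array([oracle.atomic_energy(f, a) for f in state.train_idx])
            models[a], thetas[a] = _fit_atom(X, y, mask, thetas[a], refit,
                                             config, rng)
            if config.acquisition == "mepe" and len(sample_arr):
                cv2_train = loo_cv_error_fast(models[a])
                cv2_atoms.append(assign_voronoi(feats[a][sample_arr], X,
                                                cv2_train, mask))
                mu_s, s2_s = gpr.predict_many(models[a], feats[a][sample_arr])
                s2_atoms.append(s2_s)
                mean_atoms[a] = mu_s

        # validation tracking (per-atom absolute errors summed over the group)
        val_err = np.zeros(len(state.valid_idx))
        for a in atoms:
            mu_v, _ = gpr.predict_many(models[a], feats[a][state.valid_idx],
                                       with_variance=False)
            val_err += np.abs(y_true_valid[a] - mu_v)
        val_rmse = float(np.sqrt(np.mean(val_err ** 2)))
        record = {
            "atoms": "+".join(str(a) for a in atoms),
            "iteration": state.q,
            "ntrain": len(state.train_idx),
            "alpha": state.alpha,
            "val_rmse": val_rmse,
            "val_max": float(np.max(val_err)) if len(val_err) else np.nan,
        }

        stop = (len(state.train_idx) >= config.max_train
                or not state.sample_idx
                or (config.target_rmse is not None
                    and val_rmse <= config.target_rmse))
        if stop:
            record["selected_frames"] = ""
            history.append(record)
            break

        if config.acquisition == "mepe":
            cv2_sys, s2_sys, _ = aggregate_per_system(
                np.array(cv2_atoms), np.array(s2_atoms),
                np.zeros((len(atoms), len(sample_arr))))
            epe = expected_prediction_error(cv2_sys, s2_sys, state.alpha)
            picked = select_points(epe, config.batch_size)
        else:
            k = min(config.batch_size, len(sample_arr))
            picked = sorted(rng.choice(len(sample_arr), size=k,
                                       replace=False).tolist())
        frames = [int(sample_arr[i]) for i in picked]
        record["selected_frames"] = ";".join(str(f) for f in frames)
        history.append(record)

        # realized errors of this batch -> next iteration's balance factor
        if config.acquisition == "mepe":
            alphas = []
            for i, f in zip(picked, frames):
                pe_true2 = 0.0
                for a in atoms:
                    truth = oracle.atomic_energy(f, a)
                    pe_true2 += (truth - mean_atoms[a][i]) ** 2
                cv2_prev = float(cv2_sys[i])
                alphas.append(balance_factor(pe_true2, cv2_prev, state.q + 1))
            state.alpha = batch_balance_factor(np.array(alphas))

        state.train_idx = sorted(state.train_idx + frames)
        state.sample_idx = [f for f in state.sample_idx if f not in set(frames)]
        state.last_added = frames
        state.q += 1

    return models, state, history


def run_active_learning(trajectory: Trajectory, oracle,
                        config: ALConfig | None = None,
                        alf: ALFDefinition | None = None) -> ALResult:
    """Run the full acquisition loop and return final per-atom models.

    ``oracle`` must expose ``atomic_energy(frame_id, atom) -> float``; in
    per-atom mode each singleton group queries only its own atom's
    energies.  Atom groups are independent, so any execution order gives
    identical results under a fixed seed.
    """
    config = config or ALConfig()
    if alf is None:
        alf = compute_alf(trajectory[0])
    natoms = trajectory[0].natoms
    atom_list = config.atoms if config.atoms is not None else list(range(natoms))
    if config.mode == "per_atom":
        groups = [(a,) for a in atom_list]
    else:
        groups = [tuple(atom_list)]

    models: dict[int, GPRModel] = {}
    states: dict[tuple[int, ...], ALState] = {}
    rows: list[dict] = []
    for group in groups:
        g_models, g_state, g_history = _run_group(
            trajectory, oracle, group, alf, config)
        models.update(g_models)
        states[group] = g_state
        rows.extend(g_history)
    return ALResult(models=models, states=states, history=pd.DataFrame(rows))
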