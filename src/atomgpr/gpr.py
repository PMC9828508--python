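"""Gaussian process regression with a cyclic RBF kernel and constant mean.

The model is ordinary kriging: a squared-exponential kernel
``k(x, x*) = exp(-sum_d theta_d r_d^2)`` where ``r_d`` is the per-dimension
feature difference with a 2*pi wrap on cyclic (azimuthal) dimensions, a
constant mean ``mu = mean(y)``, and the ordinary-kriging predictive
variance that accounts for the estimated constant mean.

All linear algebra goes through one Cholesky factorization of
``R + nugget*I``; R is never inverted for prediction.  The nugget is purely
numerical conditioning (the model is noise-free) and escalates tenfold on
factorization failure up to a ceiling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "Hyperparameters",
    "GPRModel",
    "Prediction",
    "IllConditionedModelError",
    "kernel",
    "kernel_vector",
    "covariance_matrix",
    "log_marginal_likelihood",
    "fit",
    "predict",
]

THETA_MIN = 0.0
THETA_MAX = 3.0
DEFAULT_NUGGET = 1e-10
NUGGET_CEILING = 1e-4


class IllConditionedModelError(np.linalg.LinAlgError):
    """Covariance factorization failed even after nugget escalation."""


@dataclass(frozen=True)
class Hyperparameters:
    """Non-negative per-dimension kernel scales theta_d."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta must be finite")
        if np.any(self.theta < 0):
            raise ValueError("theta must be non-negative")


def _wrapped_diffs(X: np.ndarray, Y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    d = X[:, None, :] - Y[None, :, :]
    wrapped = np.mod(d + np.pi, 2 * np.pi) - np.pi
    return np.where(mask[None, None, :], wrapped, d)


def kernel_matrix(X: np.ndarray, Y: np.ndarray, theta: Hyperparameters,
                  mask: np.ndarray) -> np.ndarray:
    """Dense kernel block k(X, Y) with the cyclic correction."""
    r = _wrapped_diffs(np.atleast_2d(X), np.atleast_2d(Y), mask)
    return np.exp(-np.einsum("ijd,d->ij", r * r, theta.theta))


def kernel(x: np.ndarray, x_star: np.ndarray, theta: Hyperparameters,
           mask: np.ndarray) -> float:
    """Covariance of one feature pair; always in (0, 1]."""
    x = np.asarray(x, float)
    x_star = np.asarray(x_star, float)
    if x.shape != x_star.shape:
        raise ValueError("feature vectors must share a dimension")
    return float(kernel_matrix(x[None], x_star[None], theta, mask)[0, 0])


@dataclass
class _CholFactor:
    """SPD factorization of R + nugget*I supporting solve and log-det."""

    c_and_lower: tuple
    nugget: float

    def solve(self, b: np.ndarray) -> np.ndarray:
        return cho_solve(self.c_and_lower, b)

    def logdet(self) -> float:
        c = self.c_and_lower[0]
        return 2.0 * float(np.sum(np.log(np.diag(c))))

    def inverse(self) -> np.ndarray:
        n = self.c_and_lower[0].shape[0]
        return self.solve(np.eye(n))


def covariance_matrix(X: np.ndarray, theta: Hyperparameters, mask: np.ndarray,
                      nugget: float = DEFAULT_NUGGET) -> _CholFactor:
    """Build and factorize R + nugget*I, escalating the nugget on failure."""
    X = np.atleast_2d(X)
    R = kernel_matrix(X, X, theta, mask)
    R = 0.5 * (R + R.T)
    current = nugget
    while True:
        try:
            c = cho_factor(R + current * np.eye(len(R)), lower=True)
            return _CholFactor(c, current)
        except np.linalg.LinAlgError:
            current = max(current, DEFAULT_NUGGET) * 10.0
            if current > NUGGET_CEILING:
                raise IllConditionedModelError(
                    f"covariance factorization failed up to nugget {NUGGET_CEILING}"
                ) from None


def log_marginal_likelihood(X: np.ndarray, y: np.ndarray, theta: Hyperparameters,
                            mask: np.ndarray,
                            nugget: float = DEFAULT_NUGGET) -> float:
    """Constant-mean marginal log-likelihood.

    ``LL = -1/2 (y-mu)' R^-1 (y-mu) - 1/2 log|R| - n/2 log(2 pi)`` with
    ``mu = mean(y)`` and R understood as the nugget-regularized matrix.
    """
    y = np.asarray(y, float)
    n = len(y)
    fac = covariance_matrix(X, theta, mask, nugget)
    resid = y - y.mean()
    return float(
        -0.5 * resid @ fac.solve(resid) - 0.5 * fac.logdet()
        - 0.5 * n * np.log(2 * np.pi)
    )


@dataclass
class GPRModel:
    """A fitted per-atom model: training data, weights and variance."""

    X: np.ndarray
    y: np.ndarray
    mu: float
    theta: Hyperparameters
    cyclic_mask: np.ndarray
    factor: _CholFactor
    weights: np.ndarray
    sigma2: float
    atom_label: str = ""
    alf_triple: tuple[int, int, int] | None = None

    @property
    def ntrain(self) -> int:
        return len(self.y)

    @property
    def nugget(self) -> float:
        return self.factor.nugget

    def save(self, path: str | Path) -> None:
        doc = {
            "atom_label": self.atom_label,
            "alf_triple": list(self.alf_triple) if self.alf_triple else None,
            "cyclic_mask": self.cyclic_mask.astype(int).tolist(),
            "theta": self.theta.theta.tolist(),
            "nugget": self.nugget,
            "mu": self.mu,
            "sigma2": self.sigma2,
            "X": self.X.tolist(),
            "y": self.y.tolist(),
            "weights": self.weights.tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "GPRModel":
        doc = json.loads(Path(path).read_text())
        theta = Hyperparameters(np.array(doc["theta"]))
        mask = np.array(doc["cyclic_mask"], dtype=bool)
        X = np.array(doc["X"])
        fac = covariance_matrix(X, theta, mask, doc["nugget"])
        return cls(
            X=X, y=np.array(doc["y"]), mu=doc["mu"], theta=theta,
            cyclic_mask=mask, factor=fac, weights=np.array(doc["weights"]),
            sigma2=doc["sigma2"], atom_label=doc["atom_label"],
            alf_triple=tuple(doc["alf_triple"]) if doc["alf_triple"] else None,
        )


@dataclass(frozen=True)
class Prediction:
    mean: float
    variance: float


def fit(X: np.ndarray, y: np.ndarray, theta: Hyperparameters, mask: np.ndarray,
        nugget: float = DEFAULT_NUGGET, atom_label: str = "",
        alf_triple: tuple[int, int, int] | None = None) -> GPRModel:
    """Fit the constant-mean GPR: precompute weights alpha = R^-1 (y - mu).

    The process variance is the maximum-likelihood plug-in for a fixed
    constant mean, ``sigma2 = (1/n) (y-mu)' R^-1 (y-mu)``.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    fac = covariance_matrix(X, theta, mask, nugget)
    mu = float(np.mean(y))
    resid = y - mu
    weights = fac.solve(resid)
    sigma2 = float(resid @ weights) / len(y)
    return GPRModel(X=X, y=y, mu=mu, theta=theta, cyclic_mask=mask,
                    factor=fac, weights=weights, sigma2=max(sigma2, 0.0),
                    atom_label=atom_label, alf_triple=alf_triple)


def predict(model: GPRModel, x_star: np.ndarray,
            with_variance: bool = True) -> Prediction:
    """Predictive mean mu + r'alpha and ordinary-kriging variance.

    ``s2 = sigma2 * (1 - r'R^-1 r + (1 - 1'R^-1 r)^2 / (1'R^-1 1))``,
    clamped at zero.  The mean costs one kernel vector and a dot product;
    nothing here refactorizes R.
    """
    x_star = np.asarray(x_star, float)
    if x_star.shape != (model.X.shape[1],):
        raise ValueError(
            f"dimension mismatch: model has {model.X.shape[1]} features, "
            f"query has shape {x_star.shape}")
    r = kernel_matrix(x_star[None], model.X, model.theta, model.cyclic_mask)[0]
    mean = model.mu + float(r @ model.weights)
    if not with_variance:
        return Prediction(mean, 0.0)
    Rinv_r = model.factor.solve(r)
    ones = np.ones(model.ntrain)
    Rinv_1 = model.factor.solve(ones)
    denom = float(ones @ Rinv_1)
    var = model.sigma2 * (1.0 - float(r @ Rinv_r)
                          + (1.0 - float(ones @ Rinv_r)) ** 2 / denom)
    return Prediction(mean, max(var, 0.0))


def predict_many(model: GPRModel, X_star: np.ndarray,
                 with_variance: bool = True
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized predictions: returns (means, variances)."""
    X_star = np.atleast_2d(np.asarray(X_star, float))
    Rm = kernel_matrix(X_star, model.X, model.theta, model.cyclic_mask)
    means = model.mu + Rm @ model.weights
    if not with_variance:
        return means, np.zeros(len(means))
    Rinv_rT = model.factor.solve(Rm.T)  # (ntrain, nstar)
    ones = np.ones(model.ntrain)
    Rinv_1 = model.factor.solve(ones)
    denom = float(ones @ Rinv_1)
    quad = np.einsum("ij,ji->i", Rm, Rinv_rT)
    lagrange = (1.0 - Rm @ Rinv_1) ** 2 / denom
    var = model.sigma2 * (1.0 - quad + lagrange)
    return means, np.maximum(var, 0.0)
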