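"""Gaussian process regression with an isotropic RBF kernel.

The model is standard GP regression on standardized outputs:

    k(x_i, x_j) = theta1 * exp(-||x_i - x_j||^2 / (2 * theta2^2))

    mu(x*)     = k*^T (K + sigma_n^2 I)^-1 y
    sigma^2(x*)= k** - k*^T (K + sigma_n^2 I)^-1 k*

with a single shared length scale ``theta2`` across all descriptor
dimensions (inputs are feature-standardized upstream so isotropy is
meaningful).  Hyperparameters ``(theta1, theta2, sigma_n^2)`` are chosen by
type-II MAP: the log marginal likelihood plus a log gamma-prior density for
each hyperparameter is maximized by multi-start L-BFGS in log-hyperparameter
space, with analytic gradients.

Outputs are standardized to mean 0 and *population* standard deviation 1
(divide by n); the transform is stored on the state so predictions can be
mapped back to kJ/mol.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: Floor on the fitted noise variance (standardized scale); doubles as jitter.
NOISE_FLOOR = 1e-6


class GPError(ValueError):
    """Invalid GP input or configuration."""


class DegenerateStandardizationError(GPError):
    """Raised when the outputs to standardize are constant or too few."""


class FitError(RuntimeError):
    """Hyperparameter optimization failed on every restart."""


# ---------------------------------------------------------------------------
# kernel and standardization


def rbf_kernel(xi: Sequence[float], xj: Sequence[float], theta1: float, theta2: float) -> float:
    """RBF covariance ``theta1 * exp(-||xi - xj||^2 / (2 theta2^2))``."""
    if theta1 <= 0 or theta2 <= 0:
        raise GPError(f"hyperparameters must be positive, got theta1={theta1}, theta2={theta2}")
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise GPError(f"vector length mismatch: {xi.shape} vs {xj.shape}")
    if not (np.all(np.isfinite(xi)) and np.all(np.isfinite(xj))):
        raise GPError("non-finite input vector")
    d2 = float(np.sum((xi - xj) ** 2))
    return float(theta1 * np.exp(-d2 / (2.0 * theta2 ** 2)))


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, theta1: float, theta2: float) -> np.ndarray:
    """Cross-covariance matrix between two sets of row vectors."""
    if theta1 <= 0 or theta2 <= 0:
        raise GPError("hyperparameters must be positive")
    d2 = cdist(np.atleast_2d(X1), np.atleast_2d(X2), metric="sqeuclidean")
    return theta1 * np.exp(-d2 / (2.0 * theta2 ** 2))


@dataclass(frozen=True)
class StandardTransform:
    """Affine map raw -> (raw - mean) / sd and its inverse."""

    mean: float
    sd: float

    def apply(self, raw: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(raw, dtype=float) - self.mean) / self.sd

    def invert(self, std: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(std, dtype=float) * self.sd + self.mean


def standardize(raw: Sequence[float]) -> tuple[np.ndarray, StandardTransform]:
    """Center and scale to mean 0, population sd 1.

    Uses the population convention (divide by n), so two points map to
    exactly -1 and +1.  Raises on fewer than two values or a constant input.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise DegenerateStandardizationError("need at least two values to standardize")
    mean = float(arr.mean())
    sd = float(arr.std())  # population convention
    if sd == 0.0:
        raise DegenerateStandardizationError("constant outputs cannot be standardized")
    t = StandardTransform(mean, sd)
    return np.asarray(t.apply(arr)), t


# ---------------------------------------------------------------------------
# priors and configuration


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior over a positive hyperparameter."""

    shape: float
    rate: float

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        return (
            self.shape * np.log(self.rate)
            - gammaln(self.shape)
            + (self.shape - 1.0) * np.log(x)
            - self.rate * x
        )

    def dlogpdf(self, x: float) -> float:
        return (self.shape - 1.0) / x - self.rate


@dataclass(frozen=True)
class GPConfig:
    """Priors and optimizer settings for type-II MAP fitting.

    The gamma-prior defaults are weakly informative: they keep the output
    scale near the standardized unit scale, the length scale near the typical
    inter-point distance of standardized features, and the noise variance
    small, while letting the likelihood dominate with more than a handful of
    points.  They are deliberately broad and fully configurable.
    """

    theta1_prior: GammaPrior = GammaPrior(shape=2.0, rate=1.0)
    theta2_prior: GammaPrior = GammaPrior(shape=2.0, rate=0.2)
    noise_prior: GammaPrior = GammaPrior(shape=1.5, rate=5.0)
    n_restarts: int = 5
    maxiter: int = 60
    noise_floor: float = NOISE_FLOOR


@dataclass
class GPState:
    """A (fitted) GP: training data, hyperparameters and output transform."""

    X: np.ndarray
    y: np.ndarray  # standardized outputs
    theta1: float
    theta2: float
    noise_var: float
    transform: StandardTransform = StandardTransform(0.0, 1.0)
    objective: float | None = None  # attained log posterior (MAP objective)
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)
    _alpha: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if self.theta1 <= 0 or self.theta2 <= 0:
            raise GPError("theta1 and theta2 must be strictly positive")
        if self.noise_var < 0:
            raise GPError("noise_var must be non-negative")
        if self.transform.sd <= 0:
            raise GPError("transform sd must be strictly positive")
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] < 1:
            raise GPError("need matching, non-empty X and y")

    def _factor(self) -> tuple[np.ndarray, np.ndarray]:
        if self._chol is None:
            K = kernel_matrix(self.X, self.X, self.theta1, self.theta2)
            Kn = K + self.noise_var * np.eye(len(self.y))
            try:
                L = linalg.cholesky(Kn, lower=True)
            except linalg.LinAlgError:
                Kn = Kn + NOISE_FLOOR * np.eye(len(self.y))
                try:
                    L = linalg.cholesky(Kn, lower=True)
                except linalg.LinAlgError as e:
                    cond = np.linalg.cond(Kn)
                    raise GPError(
                        f"covariance matrix not positive definite even with "
                        f"jitter (condition estimate {cond:.3e})"
                    ) from e
            self._chol = L
            self._alpha = linalg.cho_solve((L, True), self.y)
        return self._chol, self._alpha

    def to_json(self, path: str | Path) -> None:
        payload = {
            "X": self.X.tolist(),
            "y": self.y.tolist(),
            "theta1": self.theta1,
            "theta2": self.theta2,
            "noise_var": self.noise_var,
            "transform": [self.transform.mean, self.transform.sd],
            "objective": self.objective,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GPState":
        d = json.loads(Path(path).read_text())
        return cls(
            X=np.array(d["X"]),
            y=np.array(d["y"]),
            theta1=d["theta1"],
            theta2=d["theta2"],
            noise_var=d["noise_var"],
            transform=StandardTransform(*d["transform"]),
            objective=d.get("objective"),
        )


@dataclass(frozen=True)
class PosteriorPrediction:
    """Posterior mean and variance at one query point (standardized units)."""

    mean: float
    variance: float


# ---------------------------------------------------------------------------
# posterior


def posterior_batch(
    state: GPState, X_star: np.ndarray, return_clip: bool = False
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, float]:
    """Posterior mean and variance at each row of ``X_star``.

    Variances are clipped at zero after numerical round-off; the clip
    magnitude (largest negative raw variance, 0 if none) is returned when
    ``return_clip`` is set.
    """
    L, alpha = state._factor()
    Ks = kernel_matrix(np.atleast_2d(X_star), state.X, state.theta1, state.theta2)
    mean = Ks @ alpha
    V = linalg.solve_triangular(L, Ks.T, lower=True, check_finite=False)
    var = state.theta1 - np.einsum("ij,ij->j", V, V)
    clip = float(max(0.0, -var.min())) if var.size else 0.0
    if clip > 0:
        logger.debug("clipped negative posterior variance of magnitude %.3e", clip)
    var = np.maximum(var, 0.0)
    if return_clip:
        return mean, var, clip
    return mean, var


def posterior(state: GPState, x_star: Sequence[float]) -> PosteriorPrediction:
    """Posterior mean/variance at a single query point."""
    mean, var = posterior_batch(state, np.atleast_2d(np.asarray(x_star, dtype=float)))
    return PosteriorPrediction(mean=float(mean[0]), variance=float(var[0]))


# ---------------------------------------------------------------------------
# type-II MAP fitting


def _map_objective_and_grad(
    u: np.ndarray, D2: np.ndarray, y: np.ndarray, cfg: GPConfig
) -> tuple[float, np.ndarray]:
    """Negative (log marginal likelihood + log priors) and its gradient.

    ``u = (log theta1, log theta2, log(noise_var - floor))``.
    """
    n = y.size
    theta1, theta2 = np.exp(u[0]), np.exp(u[1])
    noise = cfg.noise_floor + np.exp(u[2])
    M = np.exp(-D2 / (2.0 * theta2 ** 2))
    Kn = theta1 * M + noise * np.eye(n)
    L, info = linalg.lapack.dpotrf(Kn, lower=1)
    if info != 0:
        return 1e12, np.zeros(3)
    alpha = linalg.cho_solve((L, True), y)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    logml = -0.5 * float(y @ alpha) - 0.5 * logdet - 0.5 * n * np.log(2.0 * np.pi)
    logprior = (
        cfg.theta1_prior.logpdf(theta1)
        + cfg.theta2_prior.logpdf(theta2)
        + cfg.noise_prior.logpdf(noise)
    )

    # d logml/dp = 0.5 tr((alpha alpha^T - Kn^-1) dKn/dp); the traces are
    # assembled from quadratic forms and Frobenius products without
    # materializing alpha alpha^T.  dpotri fills the lower triangle only and
    # M, D2 are symmetric, so off-diagonal products are doubled.
    Kinv, info = linalg.lapack.dpotri(L, lower=1)
    if info != 0:
        return 1e12, np.zeros(3)
    MD = M * D2
    Klow = np.tril(Kinv, -1)
    diagK = np.diag(Kinv)
    tr_KinvM = 2.0 * float(np.einsum("ij,ij->", Klow, M)) + float(diagK @ np.diag(M))
    tr_KinvMD = 2.0 * float(np.einsum("ij,ij->", Klow, MD))  # MD diagonal is zero
    AM = float(alpha @ (M @ alpha)) - tr_KinvM
    AMD = float(alpha @ (MD @ alpha)) - tr_KinvMD
    trA = float(alpha @ alpha) - float(diagK.sum())

    d_theta1 = 0.5 * AM + cfg.theta1_prior.dlogpdf(theta1)
    d_theta2 = 0.5 * theta1 * AMD / theta2 ** 3 + cfg.theta2_prior.dlogpdf(theta2)
    d_noise = 0.5 * trA + cfg.noise_prior.dlogpdf(noise)
    grad = np.array(
        [
            d_theta1 * theta1,
            d_theta2 * theta2,
            d_noise * (noise - cfg.noise_floor),
        ]
    )
    return -(logml + logprior), -grad


_BOUNDS = [(np.log(1e-4), np.log(1e4)), (np.log(1e-3), np.log(1e4)), (np.log(1e-9), np.log(1e3))]


def fit_hyperparameters(
    X: np.ndarray,
    y_std: np.ndarray,
    config: GPConfig = GPConfig(),
    seed: int = 0,
    transform: StandardTransform = StandardTransform(0.0, 1.0),
    warm_start: tuple[float, float, float] | None = None,
    n_restarts: int | None = None,
) -> GPState:
    """Fit (theta1, theta2, noise_var) by multi-start MAP optimization.

    Starts from a median-distance heuristic (and ``warm_start`` if given) plus
    seeded log-normal perturbations; returns the best local optimum.  The
    attained objective is at least as good as every start's initial value.
    """
    from scipy.optimize import minimize

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y_std = np.asarray(y_std, dtype=float)
    if X.shape[0] != y_std.size or X.shape[0] < 2:
        raise GPError("need at least two observations to fit hyperparameters")
    restarts = config.n_restarts if n_restarts is None else n_restarts
    D2 = cdist(X, X, metric="sqeuclidean")

    med = np.median(D2[np.triu_indices_from(D2, k=1)]) if X.shape[0] > 1 else 1.0
    theta2_0 = float(np.sqrt(max(med, 1e-6) / 2.0))
    base = np.array([np.log(1.0), np.log(theta2_0), np.log(0.05)])

    starts = []
    if warm_start is not None:
        t1, t2, nv = warm_start
        starts.append(
            np.array([np.log(t1), np.log(t2), np.log(max(nv - config.noise_floor, 1e-9))])
        )
    starts.append(base)
    rng = np.random.default_rng(seed)
    while len(starts) < restarts:
        starts.append(base + rng.normal(scale=0.7, size=3))
    starts = starts[: max(restarts, 1)]

    best = None
    failures = []
    for u0 in starts:
        u0 = np.clip(u0, [b[0] for b in _BOUNDS], [b[1] for b in _BOUNDS])
        res = minimize(
            _map_objective_and_grad,
            u0,
            args=(D2, y_std, config),
            jac=True,
            method="L-BFGS-B",
            bounds=_BOUNDS,
            options={"maxiter": config.maxiter, "ftol": 1e-7, "gtol": 1e-4},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            failures.append(res.message)
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(f"all restarts failed: {failures}")

    theta1, theta2 = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    noise = float(config.noise_floor + np.exp(best.x[2]))
    return GPState(
        X=X,
        y=y_std,
        theta1=theta1,
        theta2=theta2,
        noise_var=noise,
        transform=transform,
        objective=-float(best.fun),
    )


def map_objective(state: GPState, config: GPConfig = GPConfig()) -> float:
    """The (positive) MAP objective of a state, for diagnostics and tests."""
    D2 = cdist(state.X, state.X, metric="sqeuclidean")
    u = np.array(
        [
            np.log(state.theta1),
            np.log(state.theta2),
            np.log(max(state.noise_var - config.noise_floor, 1e-12)),
        ]
    )
    f, _ = _map_objective_and_grad(u, D2, state.y, config)
    return -f


def feature_standardize(X: np.ndarray) -> np.ndarray:
    """Z-score each feature column; constant columns map to zero.

    Applied to the whole candidate pool once so the isotropic kernel sees
    comparably scaled descriptor dimensions.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd
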