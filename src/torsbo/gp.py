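"""Gaussian-process regression over periodic torsion space.

The surrogate potential energy surface is a GP with a product of
exp-sine-squared (periodic) kernels, one factor per dihedral, with the
period fixed at 360 degrees:

    k(x, y) = s2 * prod_j exp(-2 sin^2(pi (x_j - y_j) / 360) / u_j^2),
    u_j = pi * l_j / 360

with the lengthscales l_j expressed in degrees: in the small-distance limit
the factor reduces to exp(-2 (x_j - y_j)^2 / l_j^2), so l_j reads directly
as an angular correlation length.

Hyperparameters (per-dimension lengthscales l_j in degrees, signal variance
s2 in eV^2) are fitted by maximizing the log marginal likelihood with a
fixed multi-start L-BFGS-B schedule; the observation-noise variance is held
at a small numerical floor because the energies fed to the model are
deterministic.  The prior mean is the training-set mean.

Posterior mean, variance and the analytic gradient of both are exposed;
gradients are what make cheap multi-start minimization of the surrogate
(acquisition optimization, minima extraction) practical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .errors import ConditioningError, NotFittedError
from .geometry import wrap_angle

PERIOD = 360.0

#: numerical observation-noise floor, eV (standard deviation)
NOISE_FLOOR = 1e-4

_JITTERS = (1e-10, 1e-8, 1e-6)

_DEG = np.pi / PERIOD  # radians per degree of half-angle argument


def _sqdist_features(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """sin^2(pi * (x - y)/360) per dimension, shape (nx, ny, d)."""
    diff = X[:, None, :] - Y[None, :, :]
    return np.sin(_DEG * diff) ** 2


def kernel_eval(lengthscales: np.ndarray, signal_variance: float,
                X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Periodic product kernel matrix between row-stacked torsion vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    ell = np.asarray(lengthscales, dtype=float)
    if ell.shape != (X.shape[1],):
        raise ValueError("lengthscales must have one entry per dimension")
    u = _DEG * ell
    s2 = _sqdist_features(X, Y)
    return signal_variance * np.exp(-2.0 * np.sum(s2 / u**2, axis=-1))


@dataclass
class SurrogateModel:
    """Fitted GP posterior over the torsion box.

    Attributes are populated by :func:`fit`; query through
    :meth:`posterior` / :meth:`posterior_gradient`.
    """

    lengthscales: np.ndarray
    signal_variance: float
    noise_variance: float
    X: np.ndarray
    y: np.ndarray
    mean: float
    seed: int | None = None
    log_marginal_likelihood: float = float("nan")
    _chol: tuple = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def _require_fitted(self):
        if self._alpha is None:
            raise NotFittedError("surrogate model has not been fitted")

    def posterior(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean (eV) and variance (eV^2) at torsion vector(s) x."""
        self._require_fitted()
        Xq = np.atleast_2d(np.asarray(x, dtype=float))
        ks = kernel_eval(self.lengthscales, self.signal_variance, Xq, self.X)
        mu = self.mean + ks @ self._alpha
        v = cho_solve(self._chol, ks.T)
        var = np.clip(self.signal_variance - np.einsum("ij,ji->i", ks, v), 0.0, None)
        if np.asarray(x).ndim == 1:
            return float(mu[0]), float(var[0])
        return mu, var

    def posterior_gradient(self, x: np.ndarray) -> np.ndarray:
        """Analytic gradient of the posterior mean, eV/deg."""
        self._require_fitted()
        xq = np.asarray(x, dtype=float).reshape(1, -1)
        dk = self._kernel_grad(xq)          # (n, d)
        return dk.T @ self._alpha

    def posterior_mean_and_gradient(self, x) -> tuple[float, np.ndarray]:
        self._require_fitted()
        xq = np.asarray(x, dtype=float).reshape(1, -1)
        ks = kernel_eval(self.lengthscales, self.signal_variance, xq, self.X)[0]
        dk = self._kernel_grad(xq)
        return float(self.mean + ks @ self._alpha), dk.T @ self._alpha

    def posterior_with_gradients(self, x):
        """(mu, var, dmu/dx, dvar/dx) — used by acquisition optimization."""
        self._require_fitted()
        xq = np.asarray(x, dtype=float).reshape(1, -1)
        ks = kernel_eval(self.lengthscales, self.signal_variance, xq, self.X)[0]
        dk = self._kernel_grad(xq)          # (n, d)
        mu = float(self.mean + ks @ self._alpha)
        kinv_ks = cho_solve(self._chol, ks)
        var = max(self.signal_variance - float(ks @ kinv_ks), 0.0)
        dmu = dk.T @ self._alpha
        dvar = -2.0 * dk.T @ kinv_ks
        return mu, var, dmu, dvar

    def _kernel_grad(self, xq: np.ndarray) -> np.ndarray:
        """d k(x, X_i) / d x_j, shape (n_train, d)."""
        ks = kernel_eval(self.lengthscales, self.signal_variance, xq, self.X)[0]
        diff = xq[0][None, :] - self.X      # (n, d)
        u = _DEG * self.lengthscales
        # d/dx of -2 sin^2(pi diff/360)/u^2  =  -(2 pi/360) sin(2 pi diff/360)/u^2
        factor = -(2.0 * _DEG) * np.sin(2.0 * _DEG * diff) / u**2
        return ks[:, None] * factor

    # -- persistence ----------------------------------------------------------

    def save(self, path: str) -> None:
        """Checkpoint as JSON scalars + .npz arrays so a search can resume."""
        meta = {
            "lengthscales": self.lengthscales.tolist(),
            "signal_variance": self.signal_variance,
            "noise_variance": self.noise_variance,
            "mean": self.mean,
            "seed": self.seed,
            "log_marginal_likelihood": self.log_marginal_likelihood,
        }
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)
        np.savez(path + ".npz", X=self.X, y=self.y)

    @classmethod
    def load(cls, path: str) -> "SurrogateModel":
        with open(path + ".json") as fh:
            meta = json.load(fh)
        arrays = np.load(path + ".npz")
        model = cls(
            lengthscales=np.array(meta["lengthscales"]),
            signal_variance=meta["signal_variance"],
            noise_variance=meta["noise_variance"],
            X=arrays["X"], y=arrays["y"], mean=meta["mean"],
            seed=meta["seed"],
            log_marginal_likelihood=meta["log_marginal_likelihood"],
        )
        model._factorize()
        return model

    def _factorize(self):
        n = self.n_samples
        K = kernel_eval(self.lengthscales, self.signal_variance, self.X, self.X)
        last = None
        for jitter in _JITTERS:
            try:
                self._chol = cho_factor(
                    K + (self.noise_variance + jitter) * np.eye(n), lower=True)
                break
            except np.linalg.LinAlgError as exc:   # pragma: no cover
                last = exc
        else:
            raise ConditioningError(
                f"Gram matrix singular after jitter escalation: {last}")
        self._alpha = cho_solve(self._chol, self.y - self.mean)


def _neg_lml_and_grad(theta: np.ndarray, X: np.ndarray, yc: np.ndarray,
                      noise_variance: float) -> tuple[float, np.ndarray]:
    """Negative log marginal likelihood and its gradient in
    theta = (log l_1..log l_d, log s2)."""
    d = X.shape[1]
    n = len(yc)
    u = _DEG * np.exp(theta[:d])
    s2 = np.exp(theta[d])
    s2feat = _sqdist_features(X, X)                       # (n, n, d)
    expo = np.sum(s2feat / u**2, axis=-1)
    K = s2 * np.exp(-2.0 * expo)
    Ky = K + noise_variance * np.eye(n)
    try:
        c, low = cho_factor(Ky, lower=True)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros_like(theta)
    alpha = cho_solve((c, low), yc)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    nll = 0.5 * (yc @ alpha) + 0.5 * logdet + 0.5 * n * np.log(2 * np.pi)
    # gradient: dL/dtheta_m = -0.5 tr((alpha alpha^T - Ky^-1) dK/dtheta_m)
    Kinv = cho_solve((c, low), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv
    grad = np.empty_like(theta)
    for m in range(d):
        dK = K * (4.0 * s2feat[:, :, m] / u[m]**2)        # d/d log l_m
        grad[m] = -0.5 * np.sum(A * dK)
    grad[d] = -0.5 * np.sum(A * K)                        # d/d log s2 : dK = K
    return float(nll), grad


def fit(samples_X: np.ndarray, samples_y: np.ndarray, *, seed: int = 0,
        noise_variance: float = NOISE_FLOOR**2,
        n_random_starts: int = 2,
        warm_start: SurrogateModel | None = None) -> SurrogateModel:
    """Fit GP hyperparameters by multi-start marginal-likelihood maximization.

    The start schedule is fixed: lengthscales {30, 60, 120} degrees with the
    sample variance as signal variance, the previous optimum when
    `warm_start` is given, plus `n_random_starts` seeded log-uniform draws.
    Deterministic for a given seed.
    """
    X = np.atleast_2d(np.asarray(samples_X, dtype=float))
    y = np.asarray(samples_y, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 samples to fit")
    X = wrap_angle(X)
    d = X.shape[1]
    mean = float(np.mean(y))
    yc = y - mean
    yvar = max(float(np.var(yc)), 1e-8)

    starts = [np.concatenate([np.full(d, np.log(ls)), [np.log(yvar)]])
              for ls in (30.0, 60.0, 120.0)]
    if warm_start is not None and warm_start.dim == d:
        starts.append(np.concatenate([
            np.log(warm_start.lengthscales), [np.log(warm_start.signal_variance)]]))
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        ls = np.exp(rng.uniform(np.log(10.0), np.log(180.0), size=d))
        sv = yvar * np.exp(rng.uniform(-1.0, 1.0))
        starts.append(np.concatenate([np.log(ls), [np.log(sv)]]))

    bounds = [(np.log(5.0), np.log(720.0))] * d + [(np.log(1e-8), np.log(1e4))]
    best = None
    for x0 in starts:
        res = minimize(_neg_lml_and_grad, x0, args=(X, yc, noise_variance),
                       jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 80})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    model = SurrogateModel(
        lengthscales=np.exp(theta[:d]),
        signal_variance=float(np.exp(theta[d])),
        noise_variance=noise_variance,
        X=X, y=y, mean=mean, seed=seed,
        log_marginal_likelihood=-float(best.fun),
    )
    model._factorize()
    return model
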