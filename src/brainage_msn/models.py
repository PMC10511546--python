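"""Kernel-based age regression: Gaussian process and relevance vector models.

Both regressors operate on column-standardised feature matrices through one
of two radial basis kernels,

* ``laplacedot``: k(x, x') = exp(-sigma * ||x - x'||)
* ``rbfdot``:     k(x, x') = exp(-sigma * ||x - x'||^2)

with the bandwidth either given or set by the median heuristic on training
pairwise distances.  GPR solves the regularised dual system
alpha = (K + noise_var I)^-1 y; RVR is Tipping-style sparse Bayesian
regression over the kernel basis, iterating per-weight precisions until
convergence and pruning basis functions whose precision diverges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec",
    "eval_kernel",
    "gram_matrix",
    "median_heuristic_sigma",
    "GPRModel",
    "RVRModel",
    "fit_gpr",
    "fit_rvr",
    "predict_age",
]

KERNEL_NAMES = ("laplacedot", "rbfdot")


@dataclass
class KernelSpec:
    """A named radial kernel with bandwidth sigma > 0 (k(x, x) = 1)."""

    name: str
    sigma: float

    def __post_init__(self):
        if self.name not in KERNEL_NAMES:
            raise ValueError(f"unknown kernel {self.name!r}; expected one of {KERNEL_NAMES}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def eval_kernel(spec: KernelSpec, x: np.ndarray, x2: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x.shape != x2.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {x2.shape}")
    return float(gram_matrix(spec, x[None, :], x2[None, :])[0, 0])


def gram_matrix(spec: KernelSpec, X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("feature dimensions differ")
    if spec.name == "rbfdot":
        d = cdist(X, Y, metric="sqeuclidean")
    else:
        d = cdist(X, Y, metric="euclidean")
    return np.exp(-spec.sigma * d)


def median_heuristic_sigma(name: str, X: np.ndarray, max_points: int = 200, seed: int = 0) -> float:
    """Bandwidth from the median pairwise distance of (a subsample of) X.

    rbfdot uses sigma = 1 / median(||x - x'||^2); laplacedot the analogue
    with unsquared distances.  Zero distances (duplicate rows) are ignored.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=max_points, replace=False)]
    metric = "sqeuclidean" if name == "rbfdot" else "euclidean"
    d = cdist(X, X, metric=metric)[np.triu_indices(X.shape[0], k=1)]
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    med = float(np.median(d))
    return 1.0 / med


@dataclass
class _Standardiser:
    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Standardiser":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


def _resolve(X, y, kernel, sigma, standardise, seed):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y have different numbers of rows")
    std = _Standardiser.fit(X) if standardise else _Standardiser(
        mean=np.zeros(X.shape[1]), scale=np.ones(X.shape[1]))
    Xs = std.transform(X)
    if sigma == "auto" or sigma is None:
        sigma = median_heuristic_sigma(kernel, Xs, seed=seed)
    spec = KernelSpec(name=kernel, sigma=float(sigma))
    return Xs, y, std, spec


@dataclass
class GPRModel:
    """Fitted Gaussian-process age regressor (posterior-mean predictor)."""

    spec: KernelSpec
    noise_var: float
    X_train: np.ndarray
    y_mean: float
    dual_weights: np.ndarray
    standardiser: _Standardiser
    jitter: float = 1e-8
    _chol: tuple = field(default=None, repr=False)  # type: ignore[assignment]

    algorithm = "GPR"

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size == 0:
            return np.empty(0)
        if X.shape[1] != self.X_train.shape[1]:
            raise ValueError(
                f"feature count {X.shape[1]} does not match training layout {self.X_train.shape[1]}")
        Ks = gram_matrix(self.spec, self.standardiser.transform(X), self.X_train)
        return Ks @ self.dual_weights + self.y_mean

    def refit_targets(self, y: np.ndarray) -> "GPRModel":
        """Same inputs and kernel, new targets: reuses the Cholesky factor.

        The Gram matrix depends only on X, so permutation null models can
        resolve the dual system without recomputing or refactorising it.
        """
        y = np.asarray(y, dtype=float).ravel()
        yc = y - y.mean()
        alpha = cho_solve(self._chol, yc)
        return GPRModel(spec=self.spec, noise_var=self.noise_var, X_train=self.X_train,
                        y_mean=float(y.mean()), dual_weights=alpha,
                        standardiser=self.standardiser, jitter=self.jitter, _chol=self._chol)

    def save(self, path: str | Path) -> None:
        payload = {
            "algorithm": "GPR", "kernel": self.spec.name, "sigma": self.spec.sigma,
            "noise_var": self.noise_var, "jitter": self.jitter, "y_mean": self.y_mean,
            "X_train": self.X_train.tolist(), "dual_weights": self.dual_weights.tolist(),
            "std_mean": self.standardiser.mean.tolist(), "std_scale": self.standardiser.scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def fit_gpr(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "rbfdot",
    sigma: float | str = "auto",
    noise_var: float = 1e-3,
    standardise: bool = True,
    jitter: float = 1e-8,
    seed: int = 0,
) -> GPRModel:
    """Fit GPR with a centred-target, standardised-feature dual solve."""
    Xs, y, std, spec = _resolve(X, y, kernel, sigma, standardise, seed)
    if y.size < 1:
        raise ValueError("need at least one training subject")
    K = gram_matrix(spec, Xs)
    A = K + (noise_var + jitter) * np.eye(y.size)
    try:
        chol = cho_factor(A, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"Gram matrix not positive definite after jitter: {exc}") from exc
    yc = y - y.mean()
    alpha = cho_solve(chol, yc)
    return GPRModel(spec=spec, noise_var=noise_var, X_train=Xs, y_mean=float(y.mean()),
                    dual_weights=alpha, standardiser=std, jitter=jitter, _chol=chol)


@dataclass
class RVRModel:
    """Fitted relevance vector regressor.

    ``relevance_idx`` indexes the retained training subjects (the relevance
    vectors); ``weights`` is the posterior mean over the surviving kernel
    basis; ``alphas`` the final per-weight precisions.
    """

    spec: KernelSpec
    X_train: np.ndarray
    relevance_idx: np.ndarray
    weights: np.ndarray
    alphas: np.ndarray
    noise_var: float
    y_mean: float
    standardiser: _Standardiser
    n_iter: int

    algorithm = "RVR"

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size == 0:
            return np.empty(0)
        if X.shape[1] != self.X_train.shape[1]:
            raise ValueError(
                f"feature count {X.shape[1]} does not match training layout {self.X_train.shape[1]}")
        Phi = gram_matrix(self.spec, self.standardiser.transform(X),
                          self.X_train[self.relevance_idx])
        return Phi @ self.weights + self.y_mean

    def save(self, path: str | Path) -> None:
        payload = {
            "algorithm": "RVR", "kernel": self.spec.name, "sigma": self.spec.sigma,
            "noise_var": self.noise_var, "y_mean": self.y_mean,
            "X_train": self.X_train.tolist(), "relevance_idx": self.relevance_idx.tolist(),
            "weights": self.weights.tolist(), "alphas": self.alphas.tolist(),
            "std_mean": self.standardiser.mean.tolist(), "std_scale": self.standardiser.scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def fit_rvr(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "rbfdot",
    sigma: float | str = "auto",
    max_iter: int = 1000,
    tol: float = 1e-6,
    prune_threshold: float = 1e9,
    standardise: bool = True,
    seed: int = 0,
) -> RVRModel:
    """Sparse Bayesian regression over the kernel basis (Tipping updates).

    Iterates the closed-form precision updates
    gamma_i = 1 - alpha_i Sigma_ii, alpha_i <- gamma_i / mu_i^2 together
    with the noise update until the largest relative change in the
    precisions falls below ``tol``; basis functions with alpha above
    ``prune_threshold`` are removed as irrelevant.
    """
    Xs, y, std, spec = _resolve(X, y, kernel, sigma, standardise, seed)
    n = y.size
    if n < 2:
        raise ValueError("need at least two training subjects")
    yc = y - y.mean()
    Phi_full = gram_matrix(spec, Xs)
    active = np.arange(n)
    alphas = np.full(n, 1e-6)
    noise_var = max(np.var(yc) * 0.1, 1e-6)
    mu = np.zeros(n)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Phi = Phi_full[:, active]
        A = np.diag(alphas[active]) + (Phi.T @ Phi) / noise_var
        try:
            chol = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            A = A + 1e-10 * np.eye(A.shape[0])
            chol = cho_factor(A, lower=True)
        Sigma_diag = np.diag(cho_solve(chol, np.eye(A.shape[0])))
        mu = cho_solve(chol, Phi.T @ yc) / noise_var
        gamma = 1.0 - alphas[active] * Sigma_diag
        gamma = np.clip(gamma, 1e-12, None)
        new_alphas = gamma / np.maximum(mu**2, 1e-300)
        resid = yc - Phi @ mu
        denom = max(n - gamma.sum(), 1e-12)
        new_noise = max(float(resid @ resid) / denom, 1e-12)
        change = np.max(np.abs(new_alphas - alphas[active]) / np.maximum(alphas[active], 1e-300))
        noise_change = abs(new_noise - noise_var) / max(noise_var, 1e-300)
        alphas[active] = new_alphas
        noise_var = new_noise
        keep = alphas[active] < prune_threshold
        if not keep.all():
            active = active[keep]
            if active.size == 0:
                raise ValueError("all basis functions pruned; model degenerate")
            continue  # re-solve with the reduced basis before convergence check
        if max(change, noise_change) < tol:
            break
    # final posterior mean on the surviving basis
    Phi = Phi_full[:, active]
    A = np.diag(alphas[active]) + (Phi.T @ Phi) / noise_var
    chol = cho_factor(A + 1e-12 * np.eye(A.shape[0]), lower=True)
    mu = cho_solve(chol, Phi.T @ yc) / noise_var
    return RVRModel(spec=spec, X_train=Xs, relevance_idx=active, weights=mu,
                    alphas=alphas[active], noise_var=noise_var, y_mean=float(y.mean()),
                    standardiser=std, n_iter=n_iter)


def fit_model(algorithm: str, X, y, kernel: str, **kwargs):
    """Dispatch on algorithm name ('GPR' or 'RVR')."""
    if algorithm == "GPR":
        allowed = {k: v for k, v in kwargs.items()
                   if k in ("sigma", "noise_var", "standardise", "jitter", "seed")}
        return fit_gpr(X, y, kernel=kernel, **allowed)
    if algorithm == "RVR":
        allowed = {k: v for k, v in kwargs.items()
                   if k in ("sigma", "max_iter", "tol", "prune_threshold", "standardise", "seed")}
        return fit_rvr(X, y, kernel=kernel, **allowed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def predict_age(model, X: np.ndarray) -> np.ndarray:
    """Predict ages for new feature rows with a fitted model."""
    return model.predict(X)
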