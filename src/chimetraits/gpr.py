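"""Gaussian process regression with a squared-exponential ARD kernel.

The regression core of the retrieval: a zero-mean GP (targets centered by
the training mean, added back at prediction) with kernel

    k(x_i, x_j) = σ_s² · exp(−½ Σ_b [(x_i(b) − x_j(b)) / σ_b]²)

observation noise variance σ_n², hyperparameters θ = {σ_s², σ_n², σ_1..σ_D}
trained by maximizing the log marginal likelihood (analytic gradients,
L-BFGS in log-space, seeded random restarts).  Predictions return both a
mean and a variance; the coefficient of variation 100·σ/|mean| is the
per-pixel uncertainty used for map masking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, cho_solve, solve_triangular
from scipy.optimize import minimize
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "GPRHyperparams",
    "GPRModel",
    "se_kernel",
    "kernel_matrix",
    "log_marginal_likelihood",
    "fit",
    "refit_solve",
    "predict",
    "kfold_cv",
]

#: Jitter policy: start tiny, escalate ×10 until the Cholesky succeeds.
_JITTER_START = 1e-10
_JITTER_MAX = 1e-6


@dataclass(frozen=True)
class GPRHyperparams:
    """Kernel hyperparameters: output variance, noise variance, ARD lengthscales."""

    sigma_s2: float
    sigma_n2: float
    lengthscales: np.ndarray

    def __post_init__(self) -> None:
        ls = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        if self.sigma_s2 < 0 or self.sigma_n2 < 0:
            raise ValueError("variances must be non-negative")
        if np.any(ls <= 0):
            raise ValueError("lengthscales must be strictly positive")
        object.__setattr__(self, "lengthscales", ls)

    def to_log_vector(self) -> np.ndarray:
        return np.log(
            np.concatenate([[self.sigma_s2, self.sigma_n2], self.lengthscales])
        )

    @classmethod
    def from_log_vector(cls, v: np.ndarray) -> "GPRHyperparams":
        v = np.exp(np.asarray(v, dtype=float))
        return cls(sigma_s2=float(v[0]), sigma_n2=float(v[1]), lengthscales=v[2:])


def se_kernel(xi: np.ndarray, xj: np.ndarray, hp: GPRHyperparams) -> float:
    """Squared-exponential ARD kernel between two D-vectors."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape or xi.shape != hp.lengthscales.shape:
        raise ValueError("dimension mismatch between inputs and lengthscales")
    z = (xi - xj) / hp.lengthscales
    return float(hp.sigma_s2 * np.exp(-0.5 * np.dot(z, z)))


def kernel_matrix(
    X1: np.ndarray, X2: np.ndarray, hp: GPRHyperparams
) -> np.ndarray:
    """Cross-kernel matrix K[i, j] = k(X1[i], X2[j]) (vectorized)."""
    A = np.asarray(X1, dtype=float) / hp.lengthscales
    B = np.asarray(X2, dtype=float) / hp.lengthscales
    sq = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return hp.sigma_s2 * np.exp(-0.5 * np.maximum(sq, 0.0))


def _chol_with_jitter(Ky: np.ndarray) -> tuple[np.ndarray, float]:
    jitter = 0.0
    scale = float(np.mean(np.diag(Ky))) or 1.0
    level = _JITTER_START
    while True:
        try:
            L = cholesky(Ky + jitter * np.eye(len(Ky)), lower=True)
            return L, jitter
        except np.linalg.LinAlgError:
            if level > _JITTER_MAX:
                raise np.linalg.LinAlgError(
                    f"kernel matrix not positive-definite even with jitter "
                    f"{jitter:g} (diag scale {scale:g})"
                )
            jitter = level * scale
            level *= 10.0


def log_marginal_likelihood(
    X: np.ndarray, y: np.ndarray, hp: GPRHyperparams, center: bool = True
) -> float:
    """Gaussian evidence −½ yᵀK_y⁻¹y − ½ log|K_y| − (N/2) log 2π."""
    lml, _ = _lml_and_grad(np.asarray(X, float), np.asarray(y, float), hp, center, grad=False)
    return lml


def _lml_and_grad(X, y, hp: GPRHyperparams, center: bool, grad: bool = True):
    n = len(y)
    yc = y - y.mean() if center else y
    K = kernel_matrix(X, X, hp)
    Ky = K + hp.sigma_n2 * np.eye(n)
    L, jitter = _chol_with_jitter(Ky)
    alpha = cho_solve((L, True), yc)
    lml = (
        -0.5 * float(yc @ alpha)
        - float(np.sum(np.log(np.diag(L))))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    if not grad:
        return lml, None
    Kinv = cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv  # d(lml) = ½ tr(W dK)
    grads = np.empty(2 + hp.lengthscales.size)
    grads[0] = 0.5 * np.sum(W * K)  # d/d log σ_s²
    grads[1] = 0.5 * hp.sigma_n2 * np.trace(W)  # d/d log σ_n²
    Xs = np.asarray(X, dtype=float)
    WK = W * K
    for b in range(hp.lengthscales.size):
        diff = Xs[:, b][:, None] - Xs[:, b][None, :]
        grads[2 + b] = 0.5 * np.sum(WK * diff**2) / hp.lengthscales[b] ** 2
    return lml, grads


@dataclass
class GPRModel:
    """A trained GP: hyperparameters plus the precomputed training solve."""

    hyperparams: GPRHyperparams
    train_inputs: np.ndarray
    train_targets: np.ndarray
    y_mean: float
    chol_factor: np.ndarray
    alpha: np.ndarray
    log_evidence: float

    @property
    def n_train(self) -> int:
        return len(self.train_targets)

    def save(self, path) -> None:
        """Persist as a self-contained npz-free text archive (CSV blocks)."""
        import json

        payload = {
            "format_version": 1,
            "sigma_s2": self.hyperparams.sigma_s2,
            "sigma_n2": self.hyperparams.sigma_n2,
            "lengthscales": self.hyperparams.lengthscales.tolist(),
            "y_mean": self.y_mean,
            "train_inputs": self.train_inputs.tolist(),
            "train_targets": self.train_targets.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GPRModel":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != 1:
            raise ValueError("unsupported model archive version")
        hp = GPRHyperparams(
            payload["sigma_s2"], payload["sigma_n2"], np.array(payload["lengthscales"])
        )
        X = np.array(payload["train_inputs"])
        y = np.array(payload["train_targets"])
        return refit_solve(X, y, hp)


def refit_solve(X: np.ndarray, y: np.ndarray, hp: GPRHyperparams) -> GPRModel:
    """Build a GPRModel at fixed hyperparameters (Cholesky + solve only)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    y_mean = float(y.mean())
    yc = y - y_mean
    Ky = kernel_matrix(X, X, hp) + hp.sigma_n2 * np.eye(len(y))
    L, _ = _chol_with_jitter(Ky)
    alpha = cho_solve((L, True), yc)
    lml = (
        -0.5 * float(yc @ alpha)
        - float(np.sum(np.log(np.diag(L))))
        - 0.5 * len(y) * np.log(2.0 * np.pi)
    )
    return GPRModel(hp, X, y, y_mean, L, alpha, lml)


def _default_init(X: np.ndarray, y: np.ndarray) -> GPRHyperparams:
    var_y = float(np.var(y)) or 1.0
    ls = np.std(X, axis=0, ddof=0)
    ls = np.where(ls > 0, ls, 1.0)
    # conservative noise init: starting too close to interpolation drives
    # the optimizer into degenerate zero-lengthscale optima on noisy targets
    return GPRHyperparams(var_y, 0.1 * var_y, ls)


def fit(
    X: np.ndarray,
    y: np.ndarray,
    init: GPRHyperparams | None = None,
    restarts: int = 3,
    seed: int = 0,
    max_iter: int = 200,
) -> GPRModel:
    """Train hyperparameters by evidence maximization.

    Gradient-based search (L-BFGS-B) in log-hyperparameter space with
    ``restarts`` seeded random re-initializations; the best-evidence solution
    is kept.  Default initialization: σ_s² = var(y), σ_n² = 0.1·var(y),
    lengthscales = per-dimension input std.  Deterministic given the seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("GPR training requires at least 2 samples")
    if init is None:
        init = _default_init(X, y)
    yc_full = y - y.mean()
    rng = np.random.default_rng(seed)

    def objective(log_theta):
        hp = GPRHyperparams.from_log_vector(log_theta)
        try:
            lml, grads = _lml_and_grad(X, yc_full, hp, center=False)
        except np.linalg.LinAlgError:
            return 1e25, np.zeros_like(log_theta)
        return -lml, -grads

    best = None
    last_err = None
    theta0 = init.to_log_vector()
    bounds = [(-20.0, 20.0)] * len(theta0)
    starts = [theta0] + [
        theta0 + rng.normal(0.0, 1.0, size=theta0.shape) for _ in range(max(0, restarts - 1))
    ]
    for start in starts:
        try:
            res = minimize(
                objective,
                start,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": max_iter},
            )
        except Exception as exc:  # pragma: no cover - optimizer hard failure
            last_err = exc
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all GPR restarts failed; last error: {last_err}")
    hp = GPRHyperparams.from_log_vector(best.x)
    model = refit_solve(X, y, hp)
    # optimizer contract: never worse than the evidence at the initial θ
    init_lml = log_marginal_likelihood(X, y, init)
    if model.log_evidence < init_lml:
        model = refit_solve(X, y, init)
    return model


def predict(
    model: GPRModel, xstar: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and variance at one or many test points.

    mean = ȳ + k*ᵀ(K+σ_n²I)⁻¹(y−ȳ);
    variance = c* − k*ᵀ(K+σ_n²I)⁻¹k*, c* = k(x*,x*)+σ_n², floored at 0.
    """
    hp = model.hyperparams
    X_star = np.atleast_2d(np.asarray(xstar, dtype=float))
    if X_star.shape[1] != model.train_inputs.shape[1]:
        raise ValueError(
            f"test dimension {X_star.shape[1]} does not match training "
            f"dimension {model.train_inputs.shape[1]}"
        )
    Kstar = kernel_matrix(X_star, model.train_inputs, hp)
    mean = model.y_mean + Kstar @ model.alpha
    v = solve_triangular(model.chol_factor, Kstar.T, lower=True)
    cstar = hp.sigma_s2 + hp.sigma_n2
    var = np.maximum(cstar - np.sum(v**2, axis=0), 0.0)
    if np.ndim(xstar) == 1:
        return float(mean[0]), float(var[0])
    return mean, var


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    restarts: int = 1,
) -> dict:
    """k-fold cross-validation: every sample predicted exactly once.

    Returns pooled predictions plus per-fold and pooled metrics (computed by
    the evaluation module).  Default k = 10.
    """
    from .metrics import compute_metrics

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if k > len(y):
        raise ValueError(f"k={k} exceeds sample count {len(y)}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    pooled_pred = np.empty_like(y)
    pooled_var = np.empty_like(y)
    fold_metrics = []
    for fold, (tr, te) in enumerate(splitter.split(X)):
        model = fit(X[tr], y[tr], restarts=restarts, seed=seed + fold)
        mean, var = predict(model, X[te])
        pooled_pred[te] = mean
        pooled_var[te] = var
        if len(te) >= 2 and np.ptp(y[te]) > 0:
            fold_metrics.append(compute_metrics(y[te], mean))
    pooled = compute_metrics(y, pooled_pred)
    return {
        "pooled": pooled,
        "per_fold": fold_metrics,
        "predictions": pooled_pred,
        "variances": pooled_var,
    }
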