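"""Kriging (Gaussian-process regression) with per-dimension kernel exponents.

One model maps a single atomic energy output y (kJ/mol) to the atom's
internal-coordinate features x ∈ R^d through

    ŷ(x) = μ̂ + Σ_j a_j · exp(−Σ_h θ_h |x_h^j − x_h|^{p_h}),

with a = R⁻¹(y − 1μ̂) and the symmetric correlation matrix

    R_ij = exp(−Σ_h θ_h |x_h^i − x_h^j|^{p_h}) + λ·1{i=j}.

Each feature has its own scale θ_h > 0 and exponent p_h ∈ [1, 2]. μ̂ is the
generalized-least-squares (R-weighted) mean; λ is a small nugget added for
finite-precision positive definiteness, escalated ×10 (to at most 1e-6) if
the Cholesky factorization fails.

Hyperparameters are trained by maximizing the concentrated log-likelihood

    ℓ(θ, p) = −(n/2)·ln σ̂² − ½·ln det R,   σ̂² = (y−1μ̂)ᵀR⁻¹(y−1μ̂)/n,

with a global-best particle swarm over (log10 θ, p).

The analytic gradient of the predictor,

    ∂ŷ/∂x_k = Σ_j a_j δ_jk (−θ_k p_k |x_k^j − x_k|^{p_k−1})
              · exp(−Σ_h θ_h |x_h^j − x_h|^{p_h}),

uses the sign factor δ_jk = +1 if x_k^j − x_k ≤ 0 and −1 otherwise; for
p_k < 2 the absolute value has a cusp at x_k^j = x_k and the convention
returns the one-sided value there (the tie deliberately maps to +1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "Hyperparameters",
    "PSOConfig",
    "KrigingModel",
    "correlation_matrix",
    "fit_weights",
    "concentrated_log_likelihood",
    "train",
    "save_model",
    "load_model",
]

DEFAULT_NUGGET = 1e-10
_MAX_NUGGET = 1e-6


@dataclass(frozen=True)
class Hyperparameters:
    """Per-dimension kernel scales θ (feature-unit^(−p)) and exponents p."""

    theta: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        theta = np.atleast_1d(np.asarray(self.theta, float))
        p = np.atleast_1d(np.asarray(self.p, float))
        if theta.shape != p.shape:
            raise ValueError("theta and p must have the same length")
        if np.any(theta < 0):
            raise ValueError("theta must be ≥ 0")
        if np.any((p < 1.0) | (p > 2.0)):
            raise ValueError("p must lie in [1, 2]")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class PSOConfig:
    """Global-best particle swarm settings for hyperparameter training."""

    swarm_size: int = 40
    iterations: int = 200
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    log10_theta_bounds: tuple[float, float] = (-6.0, 3.0)
    p_bounds: tuple[float, float] = (1.0, 2.0)
    seed: int = 0


def _weighted_distances(X: np.ndarray, hyper: Hyperparameters) -> np.ndarray:
    """Σ_h θ_h |x_h^i − x_h^j|^{p_h} for all pairs → (n, n)."""
    diff = np.abs(X[:, None, :] - X[None, :, :])
    return np.einsum("h,ijh->ij", hyper.theta, diff**hyper.p)


def correlation_matrix(
    X: np.ndarray, hyper: Hyperparameters, nugget: float = DEFAULT_NUGGET
) -> np.ndarray:
    """Kernel matrix R with nugget on the diagonal."""
    X = np.atleast_2d(np.asarray(X, float))
    r = np.exp(-_weighted_distances(X, hyper))
    r[np.diag_indices_from(r)] += nugget
    return r


def _chol(X, hyper, nugget):
    """Cholesky of R with ×10 nugget escalation; raises past 1e-6."""
    lam = nugget
    base = np.exp(-_weighted_distances(np.atleast_2d(X), hyper))
    while True:
        r = base.copy()
        r[np.diag_indices_from(r)] += lam
        try:
            return cho_factor(r, lower=True), r, lam
        except np.linalg.LinAlgError:
            lam *= 10
            if lam > _MAX_NUGGET:
                cond = np.linalg.cond(base)
                raise np.linalg.LinAlgError(
                    "correlation matrix not positive definite even with "
                    f"nugget {lam:.1e} (condition number ≈ {cond:.2e})"
                ) from None


def _gls_mean(cf, y):
    ones = np.ones_like(y)
    r_inv_y = cho_solve(cf, y)
    r_inv_1 = cho_solve(cf, ones)
    return float(ones @ r_inv_y) / float(ones @ r_inv_1)


def fit_weights(
    X: np.ndarray,
    y: np.ndarray,
    hyper: Hyperparameters,
    nugget: float = DEFAULT_NUGGET,
) -> tuple[float, np.ndarray]:
    """GLS mean μ̂ = (1ᵀR⁻¹y)/(1ᵀR⁻¹1) and weights a = R⁻¹(y − 1μ̂).

    Solved through a Cholesky factorization, never an explicit inverse.
    """
    y = np.asarray(y, float)
    cf, _, _ = _chol(X, hyper, nugget)
    mu = _gls_mean(cf, y)
    a = cho_solve(cf, y - mu)
    return mu, a


def concentrated_log_likelihood(
    X: np.ndarray,
    y: np.ndarray,
    hyper: Hyperparameters,
    nugget: float = DEFAULT_NUGGET,
) -> float:
    """−(n/2)·ln σ̂² − ½·ln det R, the objective PSO maximizes."""
    y = np.asarray(y, float)
    n = y.size
    if n < 2:
        raise ValueError("need at least two training examples")
    cf, _, _ = _chol(X, hyper, nugget)
    mu = _gls_mean(cf, y)
    resid = y - mu
    sigma2 = float(resid @ cho_solve(cf, resid)) / n
    if sigma2 <= 0:
        warnings.warn("perfectly constant response: σ̂² = 0", stacklevel=2)
        return np.inf
    log_det = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * n * np.log(sigma2) - 0.5 * log_det


@dataclass(frozen=True)
class KrigingModel:
    """A trained predictor for one (atom, output) pair.

    Stores everything prediction needs: μ̂, the weight vector a, the
    training inputs/outputs, hyperparameters, the nugget actually used, and
    free-form metadata (ALF indices, units, output name…).
    """

    mu: float
    a: np.ndarray
    X: np.ndarray
    y: np.ndarray
    hyper: Hyperparameters
    nugget: float
    metadata: dict = field(default_factory=dict, compare=False)

    @property
    def n_train(self) -> int:
        return self.y.size

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def _check_dim(self, x):
        x = np.asarray(x, float)
        if x.shape[-1] != self.d:
            raise ValueError(
                f"query has {x.shape[-1]} features, model expects {self.d}"
            )
        return x

    def correlations(self, x: np.ndarray) -> np.ndarray:
        """Kernel correlations of query points with the training set.

        ``x`` may be (d,) or (M, d); returns (n,) or (n, M).
        """
        x = self._check_dim(x)
        single = x.ndim == 1
        xq = np.atleast_2d(x)
        diff = np.abs(self.X[:, None, :] - xq[None, :, :])  # (n, M, d)
        s = np.einsum("h,jmh->jm", self.hyper.theta, diff**self.hyper.p)
        r = np.exp(-s)
        return r[:, 0] if single else r

    def predict(self, x: np.ndarray) -> float:
        """ŷ(x) = μ̂ + Σ_j a_j r_j(x); reverts to μ̂ far from the data."""
        return float(self.mu + self.a @ self.correlations(x))

    def predict_batch(self, x: np.ndarray) -> np.ndarray:
        return self.mu + self.a @ self.correlations(x)

    def predict_gradient(self, x: np.ndarray) -> np.ndarray:
        """Analytic ∂ŷ/∂x (see module docs for the cusp sign rule)."""
        x = self._check_dim(np.asarray(x, float))
        return self.predict_gradient_batch(x[None, :])[0]

    def predict_gradient_batch(self, x: np.ndarray) -> np.ndarray:
        """(M, d) gradients for an (M, d) query block."""
        xq = np.atleast_2d(self._check_dim(x))
        theta, p = self.hyper.theta, self.hyper.p
        diff = self.X[:, None, :] - xq[None, :, :]  # (n, M, d)
        absd = np.abs(diff)
        r = np.exp(-np.einsum("h,jmh->jm", theta, absd**p))  # (n, M)
        delta = np.where(diff <= 0, 1.0, -1.0)  # +1 at the tie, as defined
        w = self.a[:, None] * r  # (n, M)
        inner = delta * (-(theta * p) * absd ** (p - 1.0))  # (n, M, d)
        return np.einsum("jm,jmh->mh", w, inner)


#: Reciprocal-condition floor for hyperparameters accepted during training.
#: Near-singular correlation matrices (the long-lengthscale limit) produce
#: weight vectors so large that predictions lose ~8 digits to cancellation,
#: which breaks finite-difference force validation; such hyperparameters
#: score −inf instead.
_MIN_RCOND = 1e-6


def _fast_objective_factory(X, y, nugget):
    """Concentrated log-likelihood with |Δ| precomputed in log space.

    Reuses log|x_h^i − x_h^j| across PSO evaluations so each one costs a
    couple of exps plus a Cholesky. Hyperparameters whose correlation matrix
    fails to factor at the base nugget, or whose estimated reciprocal
    condition number falls below ``_MIN_RCOND``, are rejected with −inf.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n = y.size
    diff = np.abs(X[:, None, :] - X[None, :, :])  # (n, n, d)
    with np.errstate(divide="ignore"):
        log_diff = np.log(diff)  # -inf where equal → exp(p·log) = 0

    def objective(theta, p):
        powed = np.exp(p * log_diff)  # |Δ|^p, exact zeros preserved
        base = np.exp(-np.einsum("h,ijh->ij", theta, powed))
        r = base
        r[np.diag_indices_from(r)] += nugget
        try:
            cf = cho_factor(r, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        diag_l = np.diag(cf[0])
        if (diag_l.min() / diag_l.max()) ** 2 < _MIN_RCOND:
            return -np.inf
        mu = _gls_mean(cf, y)
        resid = y - mu
        sigma2 = float(resid @ cho_solve(cf, resid)) / n
        if sigma2 <= 0:
            return np.inf
        log_det = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return -0.5 * n * np.log(sigma2) - 0.5 * log_det

    return objective


def train(
    X: np.ndarray,
    y: np.ndarray,
    pso_config: PSOConfig = PSOConfig(),
    nugget: float = DEFAULT_NUGGET,
    metadata: dict | None = None,
) -> KrigingModel:
    """PSO-maximize the concentrated log-likelihood and fit the weights.

    The search space is (log10 θ_h, p_h) per feature within the configured
    bounds; the best particle's hyperparameters are frozen into the model.
    Reproducible from ``pso_config.seed``.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training data must be finite")
    d = X.shape[1]
    rng = np.random.default_rng(pso_config.seed)
    lo = np.r_[np.full(d, pso_config.log10_theta_bounds[0]),
               np.full(d, pso_config.p_bounds[0])]
    hi = np.r_[np.full(d, pso_config.log10_theta_bounds[1]),
               np.full(d, pso_config.p_bounds[1])]
    objective = _fast_objective_factory(X, y, nugget)

    def value(z):
        return objective(10.0 ** z[:d], z[d:])

    ns = pso_config.swarm_size
    pos = rng.uniform(lo, hi, size=(ns, 2 * d))
    vel = np.zeros_like(pos)
    pbest = pos.copy()
    pbest_val = np.array([value(z) for z in pos])
    g_idx = int(np.argmax(pbest_val))
    gbest, gbest_val = pbest[g_idx].copy(), pbest_val[g_idx]

    span = hi - lo
    for _ in range(pso_config.iterations):
        r1 = rng.random((ns, 2 * d))
        r2 = rng.random((ns, 2 * d))
        vel = (
            pso_config.inertia * vel
            + pso_config.cognitive * r1 * (pbest - pos)
            + pso_config.social * r2 * (gbest - pos)
        )
        np.clip(vel, -span, span, out=vel)
        pos = np.clip(pos + vel, lo, hi)
        vals = np.array([value(z) for z in pos])
        improved = vals > pbest_val
        pbest[improved] = pos[improved]
        pbest_val[improved] = vals[improved]
        g_idx = int(np.argmax(pbest_val))
        if pbest_val[g_idx] > gbest_val:
            gbest, gbest_val = pbest[g_idx].copy(), pbest_val[g_idx]

    if not np.isfinite(gbest_val):
        raise RuntimeError(
            "log-likelihood non-finite (or correlation matrix degenerate) "
            "for every particle visited"
        )
    hyper = Hyperparameters(10.0 ** gbest[:d], gbest[d:])
    cf, _, lam = _chol(X, hyper, nugget)
    mu = _gls_mean(cf, y)
    a = cho_solve(cf, y - mu)
    resid = correlation_matrix(X, hyper, lam) @ a - (y - mu)
    if np.max(np.abs(resid)) > 1e-8 * max(1.0, np.max(np.abs(y - mu))):
        raise RuntimeError("weight-fitting residual exceeds tolerance")
    meta = dict(metadata or {})
    meta.setdefault("log_likelihood", float(gbest_val))
    meta.setdefault("feature_units", ["angstrom", "angstrom", "radian"][: d])
    return KrigingModel(mu, a, X.copy(), y.copy(), hyper, lam, meta)


# ---------------------------------------------------------------------------
# Model files: documented JSON containers, bit-exact round trips (floats are
# serialized via hex to avoid decimal rounding).
# ---------------------------------------------------------------------------


def _enc(arr: np.ndarray):
    return [float.hex(float(v)) for v in np.asarray(arr).ravel()]


def _dec(vals, shape=None):
    arr = np.array([float.fromhex(v) for v in vals])
    return arr.reshape(shape) if shape is not None else arr


def save_model(model: KrigingModel, path) -> None:
    payload = {
        "format": "krigforce-model-v1",
        "mu": float.hex(model.mu),
        "nugget": float.hex(model.nugget),
        "theta": _enc(model.hyper.theta),
        "p": _enc(model.hyper.p),
        "a": _enc(model.a),
        "y": _enc(model.y),
        "X": _enc(model.X),
        "n": model.n_train,
        "d": model.d,
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> KrigingModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "krigforce-model-v1":
        raise ValueError(f"{path} is not a krigforce model file")
    n, d = payload["n"], payload["d"]
    return KrigingModel(
        mu=float.fromhex(payload["mu"]),
        a=_dec(payload["a"]),
        X=_dec(payload["X"], (n, d)),
        y=_dec(payload["y"]),
        hyper=Hyperparameters(_dec(payload["theta"]), _dec(payload["p"])),
        nugget=float.fromhex(payload["nugget"]),
        metadata=payload["metadata"],
    )
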