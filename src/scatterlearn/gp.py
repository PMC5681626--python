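"""Gaussian-process regression with an adaptive nugget.

Model: ``Y(x) = β f(x) + Z(x)`` with a constant basis ``f(x) = 1`` and a
zero-mean GP ``Z`` whose covariance is ``s · R(x, w)``, where

    R(x, w) = exp(-Σ_i θ_i (x_i - w_i)²)  (+ δ on the diagonal).

The nugget δ is estimated jointly with the roughness parameters θ by
maximum likelihood, so the same fit near-interpolates noiseless data
(δ → 0) and smooths noisy data (δ grows with the noise-to-signal variance
ratio).

Two modes are provided for multi-column responses:

* ``single`` — one independent GP per response column (SRGP), each with its
  own θ, δ and scalar process variance;
* ``multi`` — a multi-response GP (MRGP) with a separable covariance
  ``s ⊗ R``: one correlation function shared by all responses and a u×u
  response covariance matrix ``s`` estimated in closed form by generalized
  least squares given R.

β and s are profiled out of the likelihood in closed form; the optimizer
only searches (log θ, log δ) with a deterministic Sobol multistart.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.stats import qmc

__all__ = ["GPModel", "Prediction", "correlation", "fit_gp", "scaled_rmse"]

_LOG10_THETA_BOUNDS = (-2.0, 3.0)
_LOG10_DELTA_BOUNDS = (-8.0, 0.0)
_PENALTY = 1e10


@dataclass
class Prediction:
    mean: np.ndarray      # (u,) or (m, u)
    variance: np.ndarray  # same shape, nonnegative


def correlation(
    x: np.ndarray,
    w: np.ndarray,
    roughness: np.ndarray,
    nugget: float = 0.0,
) -> np.ndarray:
    """Gaussian correlation between row sets ``x`` (m,d) and ``w`` (p,d).

    The nugget is added only where the points coincide exactly (the
    diagonal of a self-correlation matrix).
    """
    roughness = np.asarray(roughness, dtype=float)
    if np.any(roughness <= 0):
        raise ValueError("roughness parameters must be positive")
    if nugget < 0:
        raise ValueError("nugget must be nonnegative")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    w = np.atleast_2d(np.asarray(w, dtype=float))
    d2 = ((x[:, None, :] - w[None, :, :]) ** 2 * roughness).sum(axis=-1)
    R = np.exp(-d2)
    if nugget:
        same = np.all(x[:, None, :] == w[None, :, :], axis=-1)
        R = R + nugget * same
    return R


def _profiled_nll(
    log_params: np.ndarray, D2: np.ndarray, Y: np.ndarray
) -> float:
    """Concentrated negative log-likelihood at (log10 θ, log10 δ).

    β and the response covariance are replaced by their closed-form
    conditional MLEs; returns a large penalty instead of raising on
    numerically singular covariances.
    """
    n, u = Y.shape
    theta = 10.0 ** log_params[:-1]
    delta = 10.0 ** log_params[-1]
    R = np.exp(-(D2 * theta).sum(axis=-1))
    R[np.diag_indices_from(R)] += delta
    try:
        c, low = cho_factor(R, lower=True)
    except np.linalg.LinAlgError:
        return _PENALTY
    logdet_R = 2.0 * np.sum(np.log(np.diag(c)))
    F = np.ones((n, 1))
    RiY = cho_solve((c, low), Y)
    RiF = cho_solve((c, low), F)
    ftf = float((F.T @ RiF)[0, 0])
    beta = (F.T @ RiY) / ftf                    # (1, u)
    resid = Y - F @ beta
    S = resid.T @ cho_solve((c, low), resid) / n  # (u, u)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        return _PENALTY
    return 0.5 * n * logdet_S + 0.5 * u * logdet_R


@dataclass
class _CoreGP:
    """One fitted GP block (u=1 for SRGP columns, u=2 for the MRGP)."""

    X: np.ndarray          # (n, d), inputs normalized to the unit cube
    Y: np.ndarray          # (n, u), standardized responses
    theta: np.ndarray      # (d,)
    delta: float
    beta: np.ndarray       # (u,)
    S: np.ndarray          # (u, u) response covariance (standardized scale)
    nll: float
    _chol: tuple = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)
    _RiF: np.ndarray = field(default=None, repr=False)

    def _factor(self) -> None:
        n = self.X.shape[0]
        R = correlation(self.X, self.X, self.theta)
        R[np.diag_indices_from(R)] += self.delta
        jitter = 0.0
        for jitter in (0.0, 1e-10, 1e-8, 1e-6):
            try:
                c = cholesky(R + jitter * np.eye(n), lower=True)
                break
            except np.linalg.LinAlgError:
                continue
        else:  # pragma: no cover - last jitter retried above
            raise np.linalg.LinAlgError("correlation matrix not positive definite")
        if jitter:
            warnings.warn(f"covariance factorization needed jitter {jitter:g}")
        self._chol = (c, True)
        resid = self.Y - np.ones((n, 1)) * self.beta
        self._alpha = cho_solve(self._chol, resid)
        self._RiF = cho_solve(self._chol, np.ones((n, 1)))

    def predict(self, Xq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self._chol is None:
            self._factor()
        r = correlation(Xq, self.X, self.theta)      # (m, n)
        mean = self.beta + r @ self._alpha           # (m, u)
        ftf = float(np.sum(self._RiF))
        Rir = cho_solve(self._chol, r.T)             # (n, m)
        quad = np.sum(r.T * Rir, axis=0)             # r' R^-1 r
        one_m_fr = 1.0 - r @ self._RiF               # (m, 1)
        base = 1.0 + self.delta - quad + one_m_fr[:, 0] ** 2 / ftf
        base = np.maximum(base, 0.0)
        var = base[:, None] * np.diag(self.S)[None, :]
        return mean, var


def _fit_block(
    X: np.ndarray, Y: np.ndarray, n_starts: int, fixed_nugget: float | None
) -> _CoreGP:
    n, d = X.shape
    D2 = (X[:, None, :] - X[None, :, :]) ** 2        # cached pairwise sq. diffs

    lo = np.array([_LOG10_THETA_BOUNDS[0]] * d + [_LOG10_DELTA_BOUNDS[0]])
    hi = np.array([_LOG10_THETA_BOUNDS[1]] * d + [_LOG10_DELTA_BOUNDS[1]])
    if fixed_nugget is not None:
        fixed_log = np.log10(max(fixed_nugget, 1e-12))

        def obj(p):
            return _profiled_nll(np.append(p, fixed_log), D2, Y)

        lo, hi = lo[:-1], hi[:-1]
    else:

        def obj(p):
            return _profiled_nll(p, D2, Y)

    starts = qmc.Sobol(d=lo.size, scramble=False).random(n_starts)
    starts = lo + starts * (hi - lo)
    # include a mid-box start so n_starts=1 is sensible
    starts[0] = 0.5 * (lo + hi)

    best = None
    for s in starts:
        res = optimize.minimize(
            obj, s, method="L-BFGS-B", bounds=list(zip(lo, hi)),
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    p = (
        np.append(best.x, fixed_log) if fixed_nugget is not None else best.x
    )
    theta = 10.0 ** p[:-1]
    delta = 10.0 ** p[-1]

    # recover the profiled β and S at the optimum
    R = np.exp(-(D2 * theta).sum(axis=-1))
    R[np.diag_indices_from(R)] += delta
    c = cho_factor(R, lower=True)
    F = np.ones((n, 1))
    RiY = cho_solve(c, Y)
    RiF = cho_solve(c, F)
    beta = ((F.T @ RiY) / float((F.T @ RiF)[0, 0]))[0]
    resid = Y - np.ones((n, 1)) * beta
    S = resid.T @ cho_solve(c, resid) / n
    core = _CoreGP(X=X, Y=Y, theta=theta, delta=float(delta), beta=beta,
                   S=np.atleast_2d(S), nll=float(best.fun))
    core._factor()
    return core


@dataclass
class GPModel:
    """Fitted forward model mapping normalized inputs to responses.

    Inputs are affinely mapped to the unit cube by ``x_lo``/``x_hi`` and
    responses are standardized per column before fitting; predictions are
    returned on the original scales.
    """

    mode: str                       # "single" or "multi"
    x_lo: np.ndarray
    x_hi: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    response_names: tuple[str, ...]
    cores: list[_CoreGP]
    #: when True the GP was fitted to log-responses (appropriate for
    #: positive quantities spanning decades); predictions are mapped back
    #: with exp (posterior median) and a delta-method variance
    log_responses: bool = False

    @property
    def nugget(self) -> np.ndarray:
        return np.array([c.delta for c in self.cores])

    @property
    def response_covariance(self) -> np.ndarray:
        """Estimated response covariance on the original response scale."""
        if self.mode == "multi":
            return self.cores[0].S * np.outer(self.y_std, self.y_std)
        return np.diag([float(c.S[0, 0]) * sd**2
                        for c, sd in zip(self.cores, self.y_std)])

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_lo.size:
            raise ValueError(
                f"expected {self.x_lo.size} input columns, got {X.shape[1]}"
            )
        Z = (X - self.x_lo) / (self.x_hi - self.x_lo)
        if np.any(Z < -0.05) or np.any(Z > 1.05):
            warnings.warn("prediction input outside the trained range "
                          "(extrapolating)")
        return Z

    def predict(self, X: np.ndarray) -> Prediction:
        """Posterior mean and variance per response at query inputs."""
        single = np.asarray(X).ndim == 1
        Z = self._normalize(X)
        if self.mode == "multi":
            mean, var = self.cores[0].predict(Z)
        else:
            parts = [core.predict(Z) for core in self.cores]
            mean = np.column_stack([m[:, 0] for m, _ in parts])
            var = np.column_stack([v[:, 0] for _, v in parts])
        mean = mean * self.y_std + self.y_mean
        var = var * self.y_std**2
        if self.log_responses:
            mean = np.exp(mean)
            var = mean**2 * var
        if single:
            return Prediction(mean[0], var[0])
        return Prediction(mean, var)

    # ---------------------------------------------------------- persistence
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mode": self.mode,
            "x_lo": self.x_lo.tolist(),
            "x_hi": self.x_hi.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_std": self.y_std.tolist(),
            "response_names": list(self.response_names),
            "log_responses": self.log_responses,
            "cores": [
                {
                    "X": c.X.tolist(),
                    "Y": c.Y.tolist(),
                    "theta": c.theta.tolist(),
                    "delta": c.delta,
                    "beta": c.beta.tolist(),
                    "S": c.S.tolist(),
                    "nll": c.nll,
                }
                for c in self.cores
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GPModel":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        d = json.loads(source)
        cores = [
            _CoreGP(
                X=np.array(c["X"]), Y=np.array(c["Y"]),
                theta=np.array(c["theta"]), delta=c["delta"],
                beta=np.array(c["beta"]), S=np.array(c["S"]), nll=c["nll"],
            )
            for c in d["cores"]
        ]
        return cls(
            mode=d["mode"],
            x_lo=np.array(d["x_lo"]), x_hi=np.array(d["x_hi"]),
            y_mean=np.array(d["y_mean"]), y_std=np.array(d["y_std"]),
            response_names=tuple(d["response_names"]), cores=cores,
            log_responses=d.get("log_responses", False),
        )


def fit_gp(
    X: np.ndarray,
    Y: np.ndarray,
    mode: str = "multi",
    x_bounds: tuple[np.ndarray, np.ndarray] | None = None,
    response_names: tuple[str, ...] | None = None,
    n_starts: int = 8,
    fixed_nugget: float | None = None,
    log_responses: bool = False,
) -> GPModel:
    """Fit a GP forward model by maximum likelihood.

    Parameters
    ----------
    X, Y : arrays
        Training inputs (n, d) and responses (n,) or (n, u).
    mode : str
        ``"single"`` fits one independent GP per response column;
        ``"multi"`` fits a multi-response GP with a shared correlation
        function and a jointly estimated response covariance matrix.
    x_bounds : optional (lo, hi)
        Input box used to normalize to the unit cube; defaults to the data
        range.
    n_starts : int
        Deterministic Sobol multistart count for the (θ, δ) likelihood
        search (the likelihood surface is multimodal).
    fixed_nugget : optional float
        Fix δ instead of estimating it (e.g. 0 for noiseless data).
    log_responses : bool
        Fit the GP to log-responses and exponentiate predictions back;
        suited to strictly positive responses spanning orders of magnitude,
        where errors are naturally relative.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, d = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n < 5:
        raise ValueError(f"need at least 5 training points, got {n}")
    if mode not in ("single", "multi"):
        raise ValueError(f"mode must be 'single' or 'multi', got {mode!r}")
    u = Y.shape[1]
    if response_names is None:
        response_names = tuple(f"y{j}" for j in range(u))
    if log_responses:
        if np.any(Y <= 0):
            raise ValueError("log_responses requires strictly positive Y")
        Y = np.log(Y)

    if x_bounds is None:
        x_lo, x_hi = X.min(axis=0), X.max(axis=0)
    else:
        x_lo = np.asarray(x_bounds[0], dtype=float)
        x_hi = np.asarray(x_bounds[1], dtype=float)
    span = np.where(x_hi > x_lo, x_hi - x_lo, 1.0)
    x_hi = x_lo + span
    Z = (X - x_lo) / span

    y_mean = Y.mean(axis=0)
    y_std = Y.std(axis=0, ddof=1)
    y_std = np.where(y_std > 0, y_std, 1.0)
    Ys = (Y - y_mean) / y_std

    if mode == "multi":
        cores = [_fit_block(Z, Ys, n_starts, fixed_nugget)]
    else:
        cores = [
            _fit_block(Z, Ys[:, j: j + 1], n_starts, fixed_nugget)
            for j in range(u)
        ]
    return GPModel(
        mode=mode, x_lo=x_lo, x_hi=x_hi, y_mean=y_mean, y_std=y_std,
        response_names=response_names, cores=cores,
        log_responses=log_responses,
    )


def scaled_rmse(q: np.ndarray, q_hat: np.ndarray) -> float:
    """Root-mean-square relative error: sqrt(mean(((q - q̂)/q)²)).

    Dimensionless; invariant to a common rescaling of both arguments.
    """
    q = np.asarray(q, dtype=float)
    q_hat = np.asarray(q_hat, dtype=float)
    if q.shape != q_hat.shape:
        raise ValueError("q and q_hat must have equal shapes")
    if np.any(q == 0):
        raise ValueError("scaled RMSE undefined for zero true values")
    return float(np.sqrt(np.mean(((q - q_hat) / q) ** 2)))
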