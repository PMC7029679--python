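"""Fitting RAM models: covariance maximum likelihood and FIML for raw data.

Two estimation routes share one set of RAM internals:

* covariance input -- minimize the normal-theory discrepancy
  ``F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p``; ``chisq = (N-1) F_min``
  (Wishart convention);
* raw input with missingness -- maximize the casewise (full-information)
  log-likelihood with saturated means, grouped by missingness pattern;
  ``chisq = 2 (ll_sat - ll_model)`` with the saturated log-likelihood
  obtained by EM.

Gradients of both objectives are analytic (chain rule through
``Sigma = F (I-A)^-1 S (I-A)^-T F^T``), which keeps large models (~100 free
parameters) fast and makes the convergence check on the gradient max-norm
meaningful.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .model_spec import ModelSpec, RAMMatrices, build_ram, degrees_of_freedom

__all__ = [
    "DataInput",
    "FitResult",
    "EstimationError",
    "implied_covariance",
    "ml_discrepancy",
    "fiml_loglik",
    "saturated_mvn",
    "fit",
    "standardize_solution",
    "r_squared",
    "factor_scores",
]

_LOG_2PI = math.log(2.0 * math.pi)

# convergence defaults (objective change / gradient max-norm)
FTOL = 1e-11
GTOL = 1e-5


class EstimationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class DataInput:
    """Either a raw rectangular table (with NaN missingness) or (S, N)."""

    kind: str  # "raw" | "covariance"
    names: tuple[str, ...]
    raw: np.ndarray | None = None
    S: np.ndarray | None = None
    n: int | None = None
    n_dropped: int = 0

    @classmethod
    def from_raw(cls, table, names: Sequence[str] | None = None) -> "DataInput":
        if isinstance(table, pd.DataFrame):
            names = tuple(str(c) for c in table.columns)
            arr = table.to_numpy(dtype=float)
        else:
            arr = np.asarray(table, dtype=float)
            if names is None:
                raise ValueError("names required for array input")
            names = tuple(names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if arr.ndim != 2 or arr.shape[1] != len(names):
            raise ValueError("raw data must be N x p matching names")
        all_missing = np.isnan(arr).all(axis=1)
        n_dropped = int(all_missing.sum())
        arr = arr[~all_missing]
        return cls(kind="raw", names=names, raw=arr, n=arr.shape[0],
                   n_dropped=n_dropped)

    @classmethod
    def from_covariance(cls, S, n: int, names: Sequence[str]) -> "DataInput":
        S = np.asarray(S, dtype=float)
        names = tuple(names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if S.shape != (len(names), len(names)):
            raise ValueError("covariance matrix shape does not match names")
        asym = np.abs(S - S.T).max()
        if asym > 1e-8:
            raise ValueError(f"covariance matrix asymmetric (max |S-S'| = {asym:g})")
        if asym > 1e-12:
            warnings.warn("covariance matrix symmetrized", stacklevel=2)
        S = (S + S.T) / 2.0
        if np.any(np.diag(S) <= 0):
            raise ValueError("covariance matrix has non-positive diagonal")
        if n <= len(names):
            raise ValueError("sample size must exceed the number of variables")
        return cls(kind="covariance", names=names, S=S, n=int(n))

    def subset(self, names: Sequence[str]) -> "DataInput":
        """Restrict to (and reorder by) the given variable names."""
        names = tuple(names)
        missing = [v for v in names if v not in self.names]
        if missing:
            raise ValueError(f"data lacks variables {missing}")
        pos = [self.names.index(v) for v in names]
        if self.kind == "covariance":
            return DataInput(kind="covariance", names=names,
                             S=self.S[np.ix_(pos, pos)], n=self.n)
        return DataInput.from_raw(self.raw[:, pos], names)


# ---------------------------------------------------------------------------
# RAM algebra
# ---------------------------------------------------------------------------

def _ram_internals(ram: RAMMatrices, theta: np.ndarray):
    A, S = ram.materialize(theta)
    m = A.shape[0]
    ImA = np.eye(m) - A
    try:
        B = np.linalg.inv(ImA)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - acyclic A is invertible
        raise EstimationError(f"(I - A) singular: {exc}") from exc
    V = B @ S @ B.T
    p = ram.n_manifest
    Sigma = V[:p, :p]
    return A, S, B, V, Sigma


def implied_covariance(ram: RAMMatrices, theta: np.ndarray) -> np.ndarray:
    """Model-implied manifest covariance ``F (I-A)^-1 S (I-A)^-T F^T``."""
    *_, Sigma = _ram_internals(ram, np.asarray(theta, dtype=float))
    return (Sigma + Sigma.T) / 2.0


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory discrepancy; 0 iff Sigma == S."""
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = S.shape[0]
    if Sigma.shape != S.shape:
        raise ValueError("S and Sigma must have the same order")
    for name, M in (("S", S), ("Sigma", Sigma)):
        ev_min = linalg.eigvalsh(M)[0]
        if ev_min <= 0:
            raise EstimationError(
                f"{name} not positive definite (smallest eigenvalue {ev_min:g})"
            )
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    return float(logdet_m - logdet_s + np.trace(linalg.solve(Sigma, S, assume_a="pos")) - p)


def _grad_chain(ram: RAMMatrices, B: np.ndarray, S: np.ndarray, V: np.ndarray,
                D: np.ndarray) -> np.ndarray:
    """Chain d(obj)/dSigma = D (symmetric, manifest block) back to theta."""
    m = B.shape[0]
    p = ram.n_manifest
    T = np.zeros((m, m))
    T[:p, :p] = D
    M = B.T @ T @ B          # for S-cells
    VTB = V @ T @ B          # for A-cells
    grad = np.zeros(ram.n_free)
    sc = ram._s_cells
    if len(sc):
        w = np.where(sc[:, 1] == sc[:, 2], 1.0, 2.0)
        np.add.at(grad, sc[:, 0], w * M[sc[:, 1], sc[:, 2]])
    ac = ram._a_cells
    if len(ac):
        np.add.at(grad, ac[:, 0], 2.0 * VTB[ac[:, 2], ac[:, 1]])
    return grad


class _CovMLObjective:
    """F_ML(theta) with analytic gradient, for a fixed sample covariance."""

    PENALTY = 1e10

    def __init__(self, ram: RAMMatrices, S_sample: np.ndarray):
        self.ram = ram
        self.S = np.asarray(S_sample, dtype=float)
        self.p = ram.n_manifest
        sign, self.logdet_s = np.linalg.slogdet(self.S)
        if sign <= 0:
            raise EstimationError("sample covariance not positive definite")

    def value_and_grad(self, theta: np.ndarray):
        A, S, B, V, Sigma = _ram_internals(self.ram, theta)
        try:
            cho = linalg.cho_factor(Sigma, lower=True)
        except linalg.LinAlgError:
            return self.PENALTY, np.zeros(self.ram.n_free)
        logdet_m = 2.0 * np.log(np.diag(cho[0])).sum()
        iSig = linalg.cho_solve(cho, np.eye(self.p))
        F = logdet_m - self.logdet_s + float((iSig * self.S).sum()) - self.p
        G = iSig - iSig @ self.S @ iSig
        return F, _grad_chain(self.ram, B, S, V, G)


# ---------------------------------------------------------------------------
# FIML
# ---------------------------------------------------------------------------

@dataclass
class _Pattern:
    idx: np.ndarray      # observed-column indices
    n: int
    mean: np.ndarray
    scatter: np.ndarray  # centered cross-product
    row_idx: np.ndarray | None = None


def _patterns(raw: np.ndarray) -> list[_Pattern]:
    isnan = np.isnan(raw)
    if not isnan.any():  # complete data: one pattern, skip the row sort
        idx = np.arange(raw.shape[1])
        mean = raw.mean(axis=0)
        c = raw - mean
        return [_Pattern(idx=idx, n=raw.shape[0], mean=mean, scatter=c.T @ c,
                         row_idx=np.arange(raw.shape[0]))]
    obs = ~isnan
    keys, inverse = np.unique(obs, axis=0, return_inverse=True)
    out = []
    for k in range(keys.shape[0]):
        idx = np.flatnonzero(keys[k])
        row_idx = np.flatnonzero(inverse == k)
        rows = raw[row_idx][:, idx]
        n = rows.shape[0]
        mean = rows.mean(axis=0)
        c = rows - mean
        out.append(_Pattern(idx=idx, n=n, mean=mean, scatter=c.T @ c,
                            row_idx=row_idx))
    return out


class _FIMLObjective:
    """Negative FIML log-likelihood over (theta, mu) with analytic gradient.

    ``scale`` (typically 1/N) puts the objective on a per-observation scale
    so that optimizer and convergence tolerances are sample-size free.
    """

    PENALTY = 1e10

    def __init__(self, ram: RAMMatrices, raw: np.ndarray, scale: float = 1.0):
        self.ram = ram
        self.p = ram.n_manifest
        self.patterns = _patterns(raw)
        self.n = sum(pt.n for pt in self.patterns)
        self.scale = scale

    def loglik_at(self, Sigma: np.ndarray, mu: np.ndarray) -> float:
        ll = 0.0
        for pt in self.patterns:
            So = Sigma[np.ix_(pt.idx, pt.idx)]
            po = len(pt.idx)
            L = np.linalg.cholesky(So)
            logdet = 2.0 * np.log(np.diagonal(L)).sum()
            d = pt.mean - mu[pt.idx]
            iSo = np.linalg.inv(So)
            Co = pt.scatter + pt.n * np.outer(d, d)
            ll -= 0.5 * (pt.n * (logdet + po * _LOG_2PI) + float((iSo * Co).sum()))
        return ll

    def value_and_grad(self, x: np.ndarray):
        q = self.ram.n_free
        theta, mu = x[:q], x[q:]
        A, S, B, V, Sigma = _ram_internals(self.ram, theta)
        D = np.zeros((self.p, self.p))
        gmu = np.zeros(self.p)
        ll = 0.0
        for pt in self.patterns:
            ix = np.ix_(pt.idx, pt.idx)
            So = Sigma[ix]
            po = len(pt.idx)
            try:
                L = np.linalg.cholesky(So)
            except np.linalg.LinAlgError:
                return self.PENALTY, np.zeros(x.size)
            logdet = 2.0 * np.log(np.diagonal(L)).sum()
            iSo = np.linalg.inv(So)
            d = pt.mean - mu[pt.idx]
            Co = pt.scatter + pt.n * np.outer(d, d)
            ll -= 0.5 * (pt.n * (logdet + po * _LOG_2PI) + float((iSo * Co).sum()))
            D[ix] += -0.5 * (pt.n * iSo - iSo @ Co @ iSo)
            gmu[pt.idx] += iSo @ (pt.n * d)
        grad_theta = _grad_chain(self.ram, B, S, V, -self.scale * D)
        return -self.scale * ll, np.concatenate([grad_theta, -self.scale * gmu])


def fiml_loglik(raw, ram: RAMMatrices, theta: np.ndarray,
                mu: np.ndarray | None = None) -> float:
    """Casewise log-likelihood of raw data (NaN = missing) under the model.

    ``mu`` defaults to column-wise observed means (saturated/implicit means).
    Rows with every variable missing are excluded.
    """
    if isinstance(raw, DataInput):
        arr = raw.raw
    elif isinstance(raw, pd.DataFrame):
        arr = raw.to_numpy(dtype=float)
    else:
        arr = np.asarray(raw, dtype=float)
    arr = arr[~np.isnan(arr).all(axis=1)]
    obj = _FIMLObjective(ram, arr)
    Sigma = implied_covariance(ram, theta)
    if mu is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mu = np.nanmean(arr, axis=0)
    ev_min = linalg.eigvalsh(Sigma)[0]
    if ev_min <= 0:
        raise EstimationError(
            f"implied covariance not positive definite (smallest eigenvalue {ev_min:g})"
        )
    return obj.loglik_at(Sigma, np.asarray(mu, dtype=float))


def saturated_mvn(raw: np.ndarray, tol: float = 1e-10, maxiter: int = 2000):
    """EM for the unrestricted Gaussian (mu, Sigma) with missing data.

    Returns (mu, Sigma, loglik) with Sigma the ML (divide-by-N) estimate.
    Complete data converges in one step to the sample moments.
    """
    raw = np.asarray(raw, dtype=float)
    raw = raw[~np.isnan(raw).all(axis=1)]
    n, p = raw.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mu = np.nanmean(raw, axis=0)
        var = np.nanvar(raw, axis=0)
    var = np.where(var > 0, var, 1.0)
    Sigma = np.diag(var)
    pats = _patterns(raw)
    prev_ll = -np.inf
    for _ in range(maxiter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        for pt in pats:
            o = pt.idx
            mis = np.setdiff1d(np.arange(p), o)
            rows = raw[pt.row_idx][:, o]
            So = Sigma[np.ix_(o, o)]
            cho = linalg.cho_factor(So, lower=True)
            iSo = linalg.cho_solve(cho, np.eye(len(o)))
            d = rows - mu[o]
            logdet = 2.0 * np.log(np.diag(cho[0])).sum()
            ll -= 0.5 * (rows.shape[0] * (logdet + len(o) * _LOG_2PI)
                         + float(np.einsum("ij,jk,ik->", d, iSo, d)))
            ex = np.empty((rows.shape[0], p))
            ex[:, o] = rows
            if len(mis):
                W = Sigma[np.ix_(mis, o)] @ iSo
                ex[:, mis] = mu[mis] + d @ W.T
                cond = Sigma[np.ix_(mis, mis)] - W @ Sigma[np.ix_(o, mis)]
            sum_x += ex.sum(axis=0)
            sum_xx += ex.T @ ex
            if len(mis):
                sum_xx[np.ix_(mis, mis)] += rows.shape[0] * cond
        mu_new = sum_x / n
        Sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        Sigma_new = (Sigma_new + Sigma_new.T) / 2.0
        mu, Sigma = mu_new, Sigma_new
        if abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
            break
        prev_ll = ll
    # final log-likelihood at the converged parameters
    ll = 0.0
    for pt in pats:
        o = pt.idx
        So = Sigma[np.ix_(o, o)]
        cho = linalg.cho_factor(So, lower=True)
        logdet = 2.0 * np.log(np.diag(cho[0])).sum()
        iSo = linalg.cho_solve(cho, np.eye(len(o)))
        d = pt.mean - mu[o]
        Co = pt.scatter + pt.n * np.outer(d, d)
        ll -= 0.5 * (pt.n * (logdet + len(o) * _LOG_2PI) + float((iSo * Co).sum()))
    return mu, Sigma, float(ll)


# ---------------------------------------------------------------------------
# Fit driver
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Converged (or flagged) solution of one model on one data set."""

    spec: ModelSpec
    ram: RAMMatrices
    data: DataInput
    theta: np.ndarray
    param_names: tuple[str, ...]
    F_min: float | None
    loglik: float
    chisq: float
    df: int
    n: int
    converged: bool
    grad_norm: float
    warnings: tuple[str, ...] = ()
    mu: np.ndarray | None = None
    se: dict[str, float] | None = None
    sample_cov: np.ndarray | None = None  # S used (cov input) or EM-saturated
    loglik_sat: float | None = None

    @property
    def theta_hat(self) -> dict[str, float]:
        return self.ram.theta_dict(self.theta)

    @property
    def n_free(self) -> int:
        return self.ram.n_free

    @property
    def standardized(self) -> dict[str, float]:
        return standardize_solution(self)

    @property
    def r2(self) -> dict[str, float]:
        out = {}
        for v in sorted(self.spec.endogenous):
            try:
                out[v] = r_squared(self, v)
            except EstimationError:
                pass
        return out

    def implied(self) -> np.ndarray:
        return implied_covariance(self.ram, self.theta)


def _start_values(ram: RAMMatrices, S_obs: np.ndarray) -> np.ndarray:
    """Loadings/paths at 0.5; variances from observed moments; covariances of
    observed pairs at their sample value, latent covariances at 0."""
    names = ram.var_names
    p = ram.n_manifest
    obs_var = {names[i]: max(S_obs[i, i], 1e-3) for i in range(p)}
    x0 = np.empty(ram.n_free)
    for k, name in enumerate(ram.param_names):
        mat, i, j = ram.param_map[name][0]
        if mat == "A":
            x0[k] = 0.5
        elif i == j:
            v = names[i]
            if v in obs_var:
                x0[k] = 0.5 * obs_var[v]
            else:
                x0[k] = 0.5  # latent scale set by marker loading of 1
        else:
            if i < p and j < p:
                x0[k] = 0.5 * S_obs[i, j]
            else:
                x0[k] = 0.0
    return x0


def _numeric_hessian(fun, x: np.ndarray) -> np.ndarray:
    """Forward-difference Jacobian of the analytic gradient."""
    q = x.size
    _, g0 = fun(x)
    H = np.empty((q, q))
    h = 1e-6 * np.maximum(1.0, np.abs(x))
    for k in range(q):
        xp = x.copy()
        xp[k] += h[k]
        _, gp = fun(xp)
        H[:, k] = (gp - g0) / h[k]
    return (H + H.T) / 2.0


def newton_polish(fun, x: np.ndarray, gtol: float = 1e-9, iters: int = 5,
                  chord: bool = False):
    """Damped Newton refinement of a near-optimal point.

    Drives the gradient max-norm to (near) machine precision, which the
    quasi-Newton stage alone does not reliably achieve at its ftol stop.
    With ``chord`` the (finite-difference) Hessian is reused across
    iterations and only recomputed when progress stalls, saving most of the
    gradient evaluations for warm starts.
    """
    f, g = fun(x)
    H = None
    for _ in range(iters):
        gn = np.abs(g).max() if g.size else 0.0
        if gn <= gtol:
            break
        if H is None:
            H = _numeric_hessian(fun, x)
        lam = 0.0
        for attempt in range(8):
            try:
                step = linalg.solve(H + lam * np.eye(x.size), -g, assume_a="sym")
            except linalg.LinAlgError:
                lam = max(2 * lam, 1e-8)
                continue
            x_new = x + step
            f_new, g_new = fun(x_new)
            if np.isfinite(f_new) and (f_new <= f + 1e-12
                                       or np.abs(g_new).max() < gn):
                if chord and np.abs(g_new).max() > 0.25 * gn:
                    H = None  # slow contraction: refresh next iteration
                x, f, g = x_new, f_new, g_new
                break
            lam = max(2 * lam, 1e-8)
            if attempt == 3 and chord:
                H = _numeric_hessian(fun, x)
        else:
            break
        if not chord:
            H = None
    return x, f, g


def _observed_moments(data: DataInput) -> tuple[np.ndarray, np.ndarray]:
    if data.kind == "covariance":
        return data.S, np.zeros(len(data.names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mu = np.nanmean(data.raw, axis=0)
        df = pd.DataFrame(data.raw)
        S = df.cov(min_periods=2).to_numpy()
    S = np.where(np.isnan(S), 0.0, S)
    return S, mu


def fit(spec: ModelSpec, data: DataInput, *, compute_se: bool = False,
        start: np.ndarray | None = None, maxiter: int = 5000) -> FitResult:
    """Estimate free parameters by ML (covariance input) or FIML (raw input)."""
    data = data.subset(spec.manifests)
    ram = build_ram(spec)
    df = degrees_of_freedom(spec)
    S_obs, mu_obs = _observed_moments(data)
    x0_theta = _start_values(ram, S_obs) if start is None else np.asarray(start, float)

    if data.kind == "covariance":
        obj = _CovMLObjective(ram, data.S)
        fun = obj.value_and_grad
        x0 = x0_theta
    else:
        obj = _FIMLObjective(ram, data.raw, scale=1.0 / data.n)
        fun = obj.value_and_grad
        x0 = np.concatenate([x0_theta, mu_obs])

    res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                                     "ftol": FTOL, "gtol": 1e-7})
    xhat, fval, grad = newton_polish(fun, res.x)
    grad_norm = float(np.abs(grad).max()) if grad.size else 0.0
    converged = bool(np.isfinite(fval)) and fval < _CovMLObjective.PENALTY / 2 \
        and grad_norm <= GTOL

    warn: list[str] = []
    theta = xhat[:ram.n_free]
    # Heywood screen: negative variance estimates
    for name in ram.param_names:
        mat, i, j = ram.param_map[name][0]
        if mat == "S" and i == j:
            val = ram.theta_dict(theta)[name]
            if val < 0:
                warn.append(f"Heywood case: variance {name} = {val:.4g} < 0")

    n = data.n
    if data.kind == "covariance":
        F_min = float(fval)
        chisq = (n - 1) * F_min
        sign, logdet_s = np.linalg.slogdet(data.S)
        p = len(data.names)
        loglik = -0.5 * (n - 1) * (F_min + logdet_s + p + p * _LOG_2PI)
        loglik_sat = -0.5 * (n - 1) * (logdet_s + p + p * _LOG_2PI)
        mu_hat = None
        sample_cov = data.S
    else:
        loglik = -float(fval) * data.n
        mu_hat = xhat[ram.n_free:]
        _, Sigma_sat, loglik_sat = saturated_mvn(data.raw)
        chisq = max(0.0, 2.0 * (loglik_sat - loglik))
        try:
            F_min = ml_discrepancy((Sigma_sat + Sigma_sat.T) / 2,
                                   implied_covariance(ram, theta))
        except EstimationError:
            F_min = None
        sample_cov = Sigma_sat

    result = FitResult(
        spec=spec, ram=ram, data=data, theta=theta,
        param_names=ram.param_names, F_min=F_min, loglik=float(loglik),
        chisq=float(chisq), df=df, n=n, converged=converged,
        grad_norm=grad_norm, warnings=tuple(warn), mu=mu_hat,
        sample_cov=sample_cov, loglik_sat=float(loglik_sat),
    )
    if compute_se:
        result.se = _standard_errors(result, fun, xhat)
    return result


def _standard_errors(result: FitResult, fun, xhat: np.ndarray) -> dict[str, float]:
    """Observed-information SEs from a central-difference Hessian of the
    objective gradient."""
    q = xhat.size
    H = np.zeros((q, q))
    h = 1e-5 * np.maximum(1.0, np.abs(xhat))
    for k in range(q):
        xp = xhat.copy(); xp[k] += h[k]
        xm = xhat.copy(); xm[k] -= h[k]
        _, gp = fun(xp)
        _, gm = fun(xm)
        H[:, k] = (gp - gm) / (2 * h[k])
    H = (H + H.T) / 2.0
    if result.data.kind == "covariance":
        info = 0.5 * (result.n - 1) * H  # -2 ll ~ (N-1) F
    else:
        info = result.n * H  # objective is -ll / N
    try:
        cov = linalg.inv(info)
        se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except linalg.LinAlgError:
        se_vec = np.full(q, np.nan)
    return {name: float(se_vec[k]) for k, name in enumerate(result.param_names)}


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def _full_covariance(result: FitResult) -> np.ndarray:
    _, _, _, V, _ = _ram_internals(result.ram, result.theta)
    return V


def standardize_solution(result: FitResult) -> dict[str, float]:
    """Rescale estimates by model-implied standard deviations.

    Loadings and regression paths become ``a * sd(from) / sd(to)`` (and may
    exceed 1 in magnitude under suppression); covariances become
    correlations; variances become proportions of total implied variance.
    """
    V = _full_covariance(result)
    sd = np.sqrt(np.diag(V))
    if np.any(sd <= 0):
        bad = [result.ram.var_names[i] for i in np.flatnonzero(sd <= 0)]
        raise EstimationError(f"zero implied variance for {bad}")
    out: dict[str, float] = {}
    theta = result.theta_hat
    for name in result.param_names:
        mat, i, j = result.ram.param_map[name][0]
        val = theta[name]
        if mat == "A":
            out[name] = val * sd[j] / sd[i]
        elif i == j:
            out[name] = val / V[i, i]
        else:
            out[name] = val / (sd[i] * sd[j])
    return out


def r_squared(result: FitResult, variable: str) -> float:
    """1 - residual variance / implied total variance for an endogenous variable."""
    if variable not in result.spec.endogenous:
        raise EstimationError(f"{variable!r} is not endogenous")
    names = result.ram.var_names
    i = names.index(variable)
    V = _full_covariance(result)
    _, S = result.ram.materialize(result.theta)
    if V[i, i] <= 0:
        raise EstimationError(f"zero implied variance for {variable!r}")
    return float(1.0 - S[i, i] / V[i, i])


def factor_scores(result: FitResult, raw: pd.DataFrame | np.ndarray | None = None
                  ) -> pd.DataFrame:
    """Regression-method factor scores for complete-data rows."""
    if raw is None:
        if result.data.kind != "raw":
            raise EstimationError("factor scores require raw data")
        arr = result.data.raw
    elif isinstance(raw, pd.DataFrame):
        arr = raw.loc[:, list(result.spec.manifests)].to_numpy(dtype=float)
    else:
        arr = np.asarray(raw, dtype=float)
    p = result.ram.n_manifest
    m = len(result.ram.var_names)
    complete = ~np.isnan(arr).any(axis=1)
    X = arr[complete]
    V = _full_covariance(result)
    Sigma_mm = V[:p, :p]
    Sigma_ml = V[:p, p:]
    W = linalg.solve((Sigma_mm + Sigma_mm.T) / 2, Sigma_ml, assume_a="pos")
    center = result.mu if result.mu is not None else X.mean(axis=0)
    scores = (X - center) @ W
    return pd.DataFrame(scores, columns=list(result.ram.latents),
                        index=np.flatnonzero(complete))
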