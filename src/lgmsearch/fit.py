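"""Normal-theory maximum-likelihood fitting of growth-model specs.

The discrepancy minimized is the standard ML fit function for structured
mean and covariance,

    F_ML = ln|Sigma| + tr(S Sigma^-1) + (ybar - mu)' Sigma^-1 (ybar - mu)
           - ln|S| - t,

with ``S`` the divisor-``n`` sample covariance.  The log-likelihood keeps
the ``-(n t / 2) ln(2 pi)`` constant so AIC/BIC are comparable across
implementations, and ``chi_square = n * F_ML`` at the optimum.

Optimization runs a quasi-Newton method (L-BFGS-B) with analytic
gradients on unconstrained transforms: log variances, atanh
autocorrelation, and Cholesky factors with log diagonals for Psi and an
unstructured Theta.  Starting values are moment-based (OLS growth
coefficients, residual moments); non-convergence triggers up to three
jittered restarts and is reported via a flag, never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .model import (
    ModelSpec,
    ParamVector,
    build_theta,
    count_free_parameters,
    polynomial_loadings,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "sample_moments",
    "saturated_loglik",
    "fit_ml",
    "fit_ml_moments",
    "baseline_fit",
    "fit_indices",
    "lrt",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FitOptions:
    """Optimizer controls (defaults follow the package conventions)."""

    gtol: float = 1e-5
    ftol: float = 1e-9
    maxiter: int = 2000
    restarts: int = 3
    jitter_scale: float = 0.2
    jitter_seed: int = 0
    srmr_include_means: bool = True


@dataclass
class FitResult:
    """A fitted model: estimates, likelihood, and selection criteria.

    ``cfi``, ``rmsea`` and ``srmr`` are filled by :func:`fit_indices`
    (they require the independence baseline); everything else is set by
    the fitting routine itself.
    """

    spec: ModelSpec | None
    estimates: ParamVector | None
    loglik: float
    k: int
    df: int
    n: int
    converged: bool
    chi_square: float
    aic: float
    bic: float
    mu_hat: np.ndarray
    sigma_hat: np.ndarray
    sample_mean: np.ndarray
    sample_cov: np.ndarray
    cfi: float | None = None
    rmsea: float | None = None
    srmr: float | None = None
    grad_norm: float = float("nan")
    n_restarts: int = 0

    def to_record(self) -> dict:
        """Flat record with the fields a results table needs."""
        rec = {
            "k": self.k,
            "df": self.df,
            "n": self.n,
            "converged": self.converged,
            "loglik": self.loglik,
            "chi_square": self.chi_square,
            "cfi": self.cfi,
            "rmsea": self.rmsea,
            "srmr": self.srmr,
            "aic": self.aic,
            "bic": self.bic,
        }
        if self.spec is not None:
            rec.update(self.spec.to_config())
        return rec


def sample_moments(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """ML sample mean and divisor-n covariance of a wide outcome matrix."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("y must be 2-d (subjects x waves)")
    n = y.shape[0]
    ybar = y.mean(axis=0)
    centered = y - ybar
    S = centered.T @ centered / n
    return ybar, S, n


def saturated_loglik(S: np.ndarray, n: int) -> float:
    """Closed-form MVN maximum at (ybar, S): the saturated log-likelihood."""
    t = S.shape[0]
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance matrix is singular")
    return -0.5 * n * (t * _LOG2PI + logdet + t)


# --------------------------------------------------------------------------
# unconstrained parametrization


class _Parametrization:
    """Maps a flat unconstrained vector to (alpha, Psi, Theta) and back."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        t, q = spec.n_waves, spec.mean_order
        self.t = t
        self.p = q + 1
        self.r = spec.n_random_effects
        # optimize in an orthonormalized polynomial basis (QR of Lambda):
        # high-order raw time codes (up to (t-1)^q) condition the problem
        # terribly; estimates are mapped back to the raw basis at the end.
        lam_raw = polynomial_loadings(t, q)
        Q, R = np.linalg.qr(lam_raw)
        signs = np.sign(np.diag(R))
        signs[signs == 0] = 1.0
        self.lam_raw = lam_raw
        self.Rmat = R * signs[:, None]
        self.lam = Q * signs[None, :]
        self.lam_r = self.lam[:, : self.r]
        self.R_r = self.Rmat[: self.r, : self.r]
        self.structure = spec.residual_structure
        self.n_psi = self.r * (self.r + 1) // 2
        self.n_theta = spec.n_theta_params
        self.n_params = self.p + self.n_psi + self.n_theta
        self.tril_psi = np.tril_indices(self.r)
        self.tril_theta = np.tril_indices(t)
        self.lags = np.abs(np.subtract.outer(np.arange(t), np.arange(t)))

    # slices
    @property
    def s_alpha(self):
        return slice(0, self.p)

    @property
    def s_psi(self):
        return slice(self.p, self.p + self.n_psi)

    @property
    def s_theta(self):
        return slice(self.p + self.n_psi, self.n_params)

    def bounds(self) -> list[tuple[float, float]]:
        b: list[tuple[float, float]] = [(-1e6, 1e6)] * self.p
        if self.r:
            diag = set(zip(*np.diag_indices(self.r)))
            for i, j in zip(*self.tril_psi):
                b.append((-14.0, 14.0) if (i, j) in diag else (-1e3, 1e3))
        if self.structure == "ID":
            b.append((-14.0, 14.0))
        elif self.structure == "AR1":
            b.extend([(-14.0, 14.0), (-6.0, 6.0)])
        elif self.structure == "UN1":
            b.extend([(-14.0, 14.0)] * self.t)
        else:  # UN
            for i, j in zip(*self.tril_theta):
                b.append((-14.0, 14.0) if i == j else (-1e3, 1e3))
        return b

    # ---- pack / unpack ----------------------------------------------------

    def pack(self, alpha, psi, theta) -> np.ndarray:
        x = np.empty(self.n_params)
        x[self.s_alpha] = np.asarray(alpha, dtype=float)
        if self.r:
            C = np.linalg.cholesky(
                np.asarray(psi) + 1e-10 * np.eye(self.r)
            )
            vals = C[self.tril_psi]
            diag_mask = self.tril_psi[0] == self.tril_psi[1]
            vals = vals.copy()
            vals[diag_mask] = np.log(vals[diag_mask])
            x[self.s_psi] = vals
        st = self.structure
        if st == "ID":
            x[self.s_theta] = np.log(float(theta))
        elif st == "AR1":
            v, rho = theta
            x[self.s_theta] = [np.log(v), np.arctanh(rho)]
        elif st == "UN1":
            x[self.s_theta] = np.log(np.asarray(theta, dtype=float))
        else:  # UN
            mat = build_theta("UN", self.t, theta)
            L = np.linalg.cholesky(mat + 1e-10 * np.eye(self.t))
            vals = L[self.tril_theta]
            diag_mask = self.tril_theta[0] == self.tril_theta[1]
            vals = vals.copy()
            vals[diag_mask] = np.log(vals[diag_mask])
            x[self.s_theta] = vals
        return x

    def unpack(self, x: np.ndarray):
        """Return (alpha, C_psi, theta-pieces) in natural scale."""
        alpha = x[self.s_alpha]
        C = None
        if self.r:
            C = np.zeros((self.r, self.r))
            C[self.tril_psi] = x[self.s_psi]
            np.fill_diagonal(C, np.exp(np.diag(C)))
        xt = x[self.s_theta]
        st = self.structure
        if st == "ID":
            theta = float(np.exp(xt[0]))
        elif st == "AR1":
            theta = (float(np.exp(xt[0])), float(np.tanh(xt[1])))
        elif st == "UN1":
            theta = np.exp(xt)
        else:
            L = np.zeros((self.t, self.t))
            L[self.tril_theta] = xt
            np.fill_diagonal(L, np.exp(np.diag(L)))
            theta = L
        return alpha, C, theta

    def moments(self, x: np.ndarray):
        alpha, C, theta = self.unpack(x)
        mu = self.lam @ alpha
        st = self.structure
        if st == "ID":
            Theta = theta * np.eye(self.t)
        elif st == "AR1":
            v, rho = theta
            Theta = v * rho ** self.lags
        elif st == "UN1":
            Theta = np.diag(theta)
        else:
            Theta = theta @ theta.T
        if self.r:
            sigma = self.lam_r @ (C @ C.T) @ self.lam_r.T + Theta
        else:
            sigma = Theta
        return mu, sigma, (alpha, C, theta)

    def param_vector(self, x: np.ndarray) -> ParamVector:
        """Estimates mapped back to the raw time-code basis."""
        alpha, C, theta = self.unpack(x)
        alpha_raw = np.linalg.solve(self.Rmat, alpha)
        psi = None
        if C is not None:
            Ci = np.linalg.solve(self.R_r, C)
            psi = Ci @ Ci.T
        if self.structure == "UN":
            theta = theta @ theta.T
        return ParamVector(alpha=np.array(alpha_raw), psi=psi, theta=theta)

    # ---- objective and gradient -------------------------------------------

    def fml_and_grad(self, x, ybar, S, logdet_S):
        mu, sigma, (alpha, C, theta) = self.moments(x)
        t = self.t
        try:
            cho = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(x)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cho))))
        sigma_inv = _chol_inv(cho)
        d = ybar - mu
        sid = sigma_inv @ d
        M = S + np.outer(d, d)
        F = (
            logdet
            + float(np.sum(sigma_inv * M))
            - logdet_S
            - t
        )
        # dF/dSigma and dF/dmu
        G = sigma_inv - sigma_inv @ M @ sigma_inv
        g = np.empty_like(x)
        g[self.s_alpha] = self.lam.T @ (-2.0 * sid)
        if self.r:
            A = self.lam_r.T @ G @ self.lam_r
            dC = 2.0 * (A @ C)
            vals = dC[self.tril_psi]
            diag_mask = self.tril_psi[0] == self.tril_psi[1]
            vals = vals.copy()
            vals[diag_mask] *= np.diag(C)
            g[self.s_psi] = vals
        st = self.structure
        if st == "ID":
            g[self.s_theta] = float(np.trace(G)) * theta
        elif st == "AR1":
            v, rho = theta
            R = rho ** self.lags
            dR = np.where(
                self.lags > 0,
                self.lags * rho ** np.maximum(self.lags - 1, 0),
                0.0,
            )
            g_v = float(np.sum(G * R)) * v  # log transform
            g_rho = v * float(np.sum(G * dR)) * (1.0 - rho**2)  # atanh
            g[self.s_theta] = [g_v, g_rho]
        elif st == "UN1":
            g[self.s_theta] = np.diag(G) * theta
        else:
            dL = 2.0 * (G @ theta)
            vals = dL[self.tril_theta]
            diag_mask = self.tril_theta[0] == self.tril_theta[1]
            vals = vals.copy()
            vals[diag_mask] *= np.diag(theta)
            g[self.s_theta] = vals
        return F, g

    # ---- moment-based starting values --------------------------------------

    def start(self, ybar, S) -> np.ndarray:
        alpha0, *_ = np.linalg.lstsq(self.lam, ybar, rcond=None)
        d0 = ybar - self.lam @ alpha0
        R0 = S + np.outer(d0, d0)
        share = 0.5 if self.r else 1.0
        mean_var = float(np.mean(np.diag(R0)))
        st = self.structure
        if st == "ID":
            theta0 = share * mean_var
        elif st == "AR1":
            lag1 = float(np.mean(np.diag(R0, 1)))
            rho0 = float(np.clip(lag1 / mean_var, -0.8, 0.8))
            theta0 = (share * mean_var, rho0)
        elif st == "UN1":
            theta0 = np.clip(share * np.diag(R0), 1e-3, None)
        else:
            theta0 = R0 + 1e-6 * np.eye(self.t)
        psi0 = None
        if self.r:
            B = np.linalg.pinv(self.lam_r)
            resid = R0 - share * mean_var * np.eye(self.t)
            psi_raw = B @ resid @ B.T
            psi0 = _nearest_pd(0.5 * (psi_raw + psi_raw.T), floor=1e-3)
        return self.pack(alpha0, psi0, theta0)


def _projected_grad_norm(x, g, bounds) -> float:
    """Gradient norm with components blocked by an active bound zeroed.

    A variance pinned at its (log-scale) lower bound is a legitimate
    boundary ML solution; the raw gradient there need not vanish.
    """
    pg = np.array(g, dtype=float)
    for i, (lo, hi) in enumerate(bounds):
        if x[i] <= lo + 1e-8 and pg[i] > 0:
            pg[i] = 0.0
        elif x[i] >= hi - 1e-8 and pg[i] < 0:
            pg[i] = 0.0
    return float(np.max(np.abs(pg))) if pg.size else 0.0


def _chol_inv(cho: np.ndarray) -> np.ndarray:
    inv_l = np.linalg.solve(cho, np.eye(cho.shape[0]))
    return inv_l.T @ inv_l


def _nearest_pd(mat: np.ndarray, floor: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T


# --------------------------------------------------------------------------
# fitting


def fit_ml(dataset, spec: ModelSpec, options: FitOptions | None = None) -> FitResult:
    """Fit ``spec`` to a dataset (a :class:`~lgmsearch.population.Dataset`
    or a plain ``n x t`` array) by maximum likelihood."""
    y = np.asarray(getattr(dataset, "y", dataset), dtype=float)
    ybar, S, n = sample_moments(y)
    return fit_ml_moments(ybar, S, n, spec, options)


def fit_ml_moments(
    ybar: np.ndarray,
    S: np.ndarray,
    n: int,
    spec: ModelSpec,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit from sufficient statistics (sample mean, ML covariance, n)."""
    opts = options or FitOptions()
    t = spec.n_waves
    if ybar.shape != (t,) or S.shape != (t, t):
        raise ValueError(
            f"data has {ybar.shape[0]} waves but the spec expects {t}"
        )
    count = count_free_parameters(spec)
    if n <= count.k:
        raise ValueError(
            f"sample size {n} must exceed the free-parameter count {count.k}"
        )
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance matrix is singular")

    par = _Parametrization(spec)
    fun = lambda x: par.fml_and_grad(x, ybar, S, logdet_S)
    x0 = par.start(ybar, S)
    bounds = par.bounds()

    best_x, best_f, best_g = None, np.inf, np.inf
    rng = np.random.default_rng(opts.jitter_seed)
    n_restarts = 0
    for attempt in range(opts.restarts + 1):
        xa = x0 if attempt == 0 else x0 + opts.jitter_scale * rng.standard_normal(x0.shape)
        try:
            res = optimize.minimize(
                fun,
                xa,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": opts.maxiter,
                    # run the line search well past the reporting thresholds;
                    # convergence is judged on the projected gradient norm
                    "ftol": 1e-14,
                    "gtol": opts.gtol * 0.3,
                },
            )
        except (np.linalg.LinAlgError, FloatingPointError):
            continue
        g_norm = _projected_grad_norm(res.x, res.jac, bounds)
        if res.fun < best_f:
            best_x, best_f, best_g = res.x, float(res.fun), g_norm
        if g_norm < opts.gtol:
            break
        n_restarts = attempt + 1

    converged = best_x is not None and best_g < opts.gtol
    if best_x is None:  # every attempt blew up; report the start
        best_x = x0
        best_f, _ = fun(x0)
        best_g = float("nan")

    mu_hat, sigma_hat, _ = par.moments(best_x)
    chi_square = max(float(n) * best_f, 0.0)
    loglik = saturated_loglik(S, n) - 0.5 * float(n) * best_f
    return FitResult(
        spec=spec,
        estimates=par.param_vector(best_x),
        loglik=loglik,
        k=count.k,
        df=count.df,
        n=n,
        converged=bool(converged),
        chi_square=chi_square,
        aic=-2.0 * loglik + 2.0 * count.k,
        bic=-2.0 * loglik + count.k * np.log(n),
        mu_hat=mu_hat,
        sigma_hat=sigma_hat,
        sample_mean=ybar,
        sample_cov=S,
        grad_norm=best_g,
        n_restarts=n_restarts,
    )


def baseline_fit(dataset) -> FitResult:
    """Independence baseline for the CFI: free means and variances,
    zero covariances.  Closed form: mu = ybar, Sigma = diag(S)."""
    y = np.asarray(getattr(dataset, "y", dataset), dtype=float)
    ybar, S, n = sample_moments(y)
    t = ybar.shape[0]
    variances = np.diag(S)
    if np.any(variances <= 0):
        raise ValueError("sample covariance matrix is singular")
    loglik = -0.5 * n * (t * _LOG2PI + float(np.sum(np.log(variances))) + t)
    k = 2 * t
    df = t * (t + 1) // 2 - t
    chi_square = max(2.0 * (saturated_loglik(S, n) - loglik), 0.0)
    return FitResult(
        spec=None,
        estimates=None,
        loglik=loglik,
        k=k,
        df=df,
        n=n,
        converged=True,
        chi_square=chi_square,
        aic=-2.0 * loglik + 2.0 * k,
        bic=-2.0 * loglik + k * np.log(n),
        mu_hat=ybar.copy(),
        sigma_hat=np.diag(variances),
        sample_mean=ybar,
        sample_cov=S,
    )


def fit_indices(
    fit: FitResult,
    baseline: FitResult,
    n: int | None = None,
    include_means: bool = True,
) -> FitResult:
    """Fill CFI, RMSEA and SRMR on ``fit`` (returns the same object).

    CFI uses the independence baseline of :func:`baseline_fit`; RMSEA is
    ``sqrt(max(chi2 - df, 0) / (df * n))`` (0 when df = 0 by convention);
    SRMR averages squared standardized residuals over the unique
    covariance elements and, when ``include_means``, the means.
    """
    n = fit.n if n is None else n
    num = max(fit.chi_square - fit.df, 0.0)
    den = max(baseline.chi_square - baseline.df, num, 0.0)
    fit.cfi = 1.0 if den == 0.0 else 1.0 - num / den
    fit.rmsea = 0.0 if fit.df <= 0 else float(np.sqrt(num / (fit.df * n)))

    S, ybar = fit.sample_cov, fit.sample_mean
    sd = np.sqrt(np.diag(S))
    resid = (S - fit.sigma_hat) / np.outer(sd, sd)
    iu = np.triu_indices(S.shape[0])
    sq = list(resid[iu] ** 2)
    if include_means:
        sq.extend(((ybar - fit.mu_hat) / sd) ** 2)
    fit.srmr = float(np.sqrt(np.mean(sq)))
    return fit


def lrt(simple: FitResult, complex: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested pair of fits on the same data.

    Returns ``(delta_chi2, delta_df, p_value)`` with the statistic
    clipped at zero.
    """
    delta_df = simple.df - complex.df
    if delta_df <= 0:
        raise ValueError(
            f"LRT needs the simple model nested in the complex one "
            f"(delta_df = {delta_df} <= 0)"
        )
    delta_chi2 = max(2.0 * (complex.loglik - simple.loglik), 0.0)
    p = float(stats.chi2.sf(delta_chi2, delta_df))
    return delta_chi2, delta_df, p
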