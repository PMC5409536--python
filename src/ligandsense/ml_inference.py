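"""Exact maximum-likelihood inference of ligand concentrations.

Given a trace of bound/unbound intervals and known per-species binding and
unbinding rates, the log-likelihood of the concentration vector c is (up to
an additive constant independent of c)

    log P = -Tu * sum_i k_i c_i + sum_events log D(c, tau_b),
    D(c, tau) = sum_i k_i c_i r_i exp(-r_i tau),

where Tu is the total unbound time.  Stationarity of log P implies the exact
identity  sum_i k_i c_i* = n / Tu  at any interior optimum, so for two
species the 2-d problem reduces to a concave 1-d maximization along that
constraint line, parameterized by the cognate on-rate fraction
f = k_c c_c / (n/Tu) in [0, 1].  The per-estimate covariance is the inverse
negative Hessian of log P at the optimum (the Cramer-Rao scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .trace_sim import BindingTrace, LigandMixture

__all__ = [
    "MLResult",
    "ErrorMetrics",
    "log_likelihood",
    "gradient",
    "hessian",
    "solve_ml",
    "error_metrics",
]


def _log_w(trace: BindingTrace, rates: LigandMixture) -> np.ndarray:
    """(n, m) matrix log(k_a r_a) - tau_b r_a; D = sum_a c_a exp(log_w)."""
    k = rates.k
    r = rates.r
    return np.log(k * r)[None, :] - trace.tau_b[:, None] * r[None, :]


def _log_D(log_w: np.ndarray, c: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        log_c = np.where(c > 0, np.log(np.where(c > 0, c, 1.0)), -np.inf)
    return logsumexp(log_w + log_c[None, :], axis=1)


def log_likelihood(
    trace: BindingTrace, c: Sequence[float], rates: LigandMixture
) -> float:
    """Log-likelihood of concentrations ``c`` up to a c-independent constant.

    Evaluated in log space (log-sum-exp) so that bound intervals with
    tau * r of several hundred stay finite.  All-zero ``c`` returns -inf.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if not np.any(c > 0):
        return -np.inf
    lw = _log_w(trace, rates)
    return float(-trace.Tu * np.sum(rates.k * c) + np.sum(_log_D(lw, c)))


def gradient(
    trace: BindingTrace, c: Sequence[float], rates: LigandMixture
) -> np.ndarray:
    """Gradient of the log-likelihood w.r.t. the concentration vector."""
    c = np.asarray(c, dtype=float)
    lw = _log_w(trace, rates)
    lD = _log_D(lw, c)
    return -trace.Tu * rates.k + np.exp(
        logsumexp(lw - lD[:, None], axis=0)
    )


def _hessian_at(
    trace: BindingTrace, c: np.ndarray, rates: LigandMixture
) -> np.ndarray:
    lw = _log_w(trace, rates)
    lD = _log_D(lw, c)
    if not np.all(np.isfinite(lD)):
        raise ValueError("D vanishes for some event; Hessian undefined")
    m = lw.shape[1]
    H = np.empty((m, m))
    for a in range(m):
        for b in range(a, m):
            H[a, b] = H[b, a] = -np.exp(
                logsumexp(lw[:, a] + lw[:, b] - 2.0 * lD)
            )
    return H


def hessian(
    trace: BindingTrace, c: Sequence[float], rates: LigandMixture
) -> np.ndarray:
    """Hessian of log P at interior ``c``.

    Because D is linear in c, the Hessian is minus a sum of rank-one terms
    (outer products of k_i r_i exp(-r_i tau) over D^2), hence every entry is
    negative and the matrix is negative semidefinite.  Raises on boundary
    ``c`` (a zero component): there the inverse-Hessian error bars are not
    the asymptotic covariance and a profile-likelihood treatment is needed
    (``solve_ml`` reports the curvature at the constrained optimum instead).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError(
            "Hessian requires interior c (all components > 0); "
            "use profile curvature at boundary optima"
        )
    return _hessian_at(trace, c, rates)


@dataclass
class MLResult:
    """Outcome of a maximum-likelihood fit of two concentrations."""

    c_hat: np.ndarray
    covariance: np.ndarray
    E: np.ndarray
    rho: float
    converged: bool
    boundary: bool
    n: int
    f: float  # cognate on-rate fraction at the optimum

    def scaled_errors(self, c_true: Sequence[float]) -> np.ndarray:
        """E = n sigma^2 / c^2 against supplied true concentrations."""
        c_true = np.asarray(c_true, dtype=float)
        return self.n * np.diag(self.covariance) / c_true**2


def solve_ml(
    trace: BindingTrace,
    rates: LigandMixture,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> MLResult:
    """Maximum-likelihood concentrations for a two-species mixture.

    The optimum is found by a bracketed root-find of the (monotone) likelihood
    derivative along the constraint line k_c c_c + k_nc c_nc = n/Tu, which the
    interior optimum satisfies exactly.  If the derivative does not change
    sign the likelihood is monotone along the line and the better endpoint
    (one concentration exactly zero) is returned with ``boundary`` set; its
    single-species estimate k c = n/Tu is the boundary maximizer.
    """
    if len(rates.species) != 2:
        raise ValueError("solve_ml supports exactly two species")
    if trace.n < 2:
        raise ValueError("need at least 2 binding events")
    n = trace.n
    s = n / trace.Tu  # total on-rate fixed by Eq-(5)-type identity
    lw = _log_w(trace, rates)
    # u_i = w_nc / w_c is bounded above by (k_nc r_nc)/(k_c r_c) since
    # r_nc > r_c, and may underflow to 0 for very long bound intervals.
    u = np.exp(lw[:, 1] - lw[:, 0])

    def dldf(f: float) -> float:
        return float(np.sum((1.0 - u) / (f + (1.0 - f) * u)))

    converged = True
    boundary = False
    f_lo = 1e-12
    if dldf(1.0) >= 0.0:
        f_opt, boundary = 1.0, True
    elif dldf(f_lo) <= 0.0:
        f_opt, boundary = 0.0, True
    else:
        try:
            f_opt = brentq(
                dldf, f_lo, 1.0, xtol=1e-15, rtol=max(tol, 1e-14),
                maxiter=max_iter,
            )
        except RuntimeError:
            warnings.warn("ML root-find did not converge within iteration cap")
            converged = False
            f_opt = 0.5
    c_hat = np.array([f_opt * s / rates.k[0], (1.0 - f_opt) * s / rates.k[1]])
    # Curvature-based covariance at the optimum.  At a boundary point one
    # concentration is exactly zero but D > 0 for every event, so the local
    # curvature is still defined; it is reported as a one-sided approximation
    # with the boundary flag set.
    H = _hessian_at(trace, c_hat, rates)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-H)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        E = n * np.diag(cov) / np.where(c_hat > 0, c_hat, np.nan) ** 2
    rho = float(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))
    return MLResult(
        c_hat=c_hat,
        covariance=cov,
        E=E,
        rho=rho,
        converged=converged,
        boundary=boundary,
        n=n,
        f=f_opt,
    )


@dataclass
class ErrorMetrics:
    """Ensemble error summary over replicate ML fits.

    ``E_hessian`` is the posterior-variance definition (mean inverse-Hessian
    variance scaled by n/c^2); ``E_ensemble`` is the sampling-variance
    cross-check (n times the ensemble variance of the estimates over c^2).
    ``rho`` comes from the averaged inverse-Hessian covariance.
    """

    E_hessian: np.ndarray
    E_hessian_se: np.ndarray
    E_ensemble: np.ndarray | None
    E_ensemble_se: np.ndarray | None
    rho: float
    rho_ensemble: float | None
    mean_variance: np.ndarray  # mean inverse-Hessian variances (unscaled)
    n_replicates: int
    n_excluded: int


def error_metrics(
    results: Sequence[MLResult], truth: LigandMixture
) -> ErrorMetrics:
    """Aggregate scaled errors E_c, E_nc and correlation rho over replicates.

    Non-converged fits are excluded.  The ensemble-variance definition needs
    at least two replicates; with fewer it is omitted with a warning.
    """
    used = [r for r in results if r.converged]
    n_excluded = len(results) - len(used)
    if not used:
        raise ValueError("no converged fits to aggregate")
    c2 = truth.c**2
    nvars = np.array([r.n * np.diag(r.covariance) for r in used])
    ncovs = np.array([r.n * r.covariance[0, 1] for r in used])
    R = len(used)
    E_h = nvars.mean(axis=0) / c2
    E_h_se = nvars.std(axis=0, ddof=1) / np.sqrt(R) / c2 if R > 1 else np.full(2, np.nan)
    mean_var = np.array([np.diag(r.covariance) for r in used]).mean(axis=0)
    rho = float(ncovs.mean() / np.sqrt(np.prod(nvars.mean(axis=0))))
    if R >= 2:
        c_hats = np.array([r.c_hat for r in used])
        n_arr = np.array([r.n for r in used], dtype=float)
        E_e = n_arr.mean() * c_hats.var(axis=0, ddof=1) / c2
        E_e_se = E_e * np.sqrt(2.0 / (R - 1))
        rho_e = float(np.corrcoef(c_hats[:, 0], c_hats[:, 1])[0, 1])
    else:
        warnings.warn("fewer than 2 replicates: ensemble variant omitted")
        E_e = E_e_se = None
        rho_e = None
    return ErrorMetrics(
        E_hessian=E_h,
        E_hessian_se=E_h_se,
        E_ensemble=E_e,
        E_ensemble_se=E_e_se,
        rho=rho,
        rho_ensemble=rho_e,
        mean_variance=mean_var,
        n_replicates=R,
        n_excluded=n_excluded,
    )
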