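"""Maximum-likelihood estimation of the skew-t mixture LST model.

Estimation maximizes the observed-data mixture log-likelihood directly with
a quasi-Newton method on the packed (transformed) parameter scale; the
free-parameter count is small (21 in the two-class design), which makes EM
unnecessary.  Standard errors come from the observed information — a
central-difference Hessian of the log-likelihood at the optimum — mapped to
the reporting scale by the delta method.

Replication-level diagnostics mimic the warning taxonomy of mainstream SEM
software: variance estimates collapsing toward zero, non-positive-definite
information, saddle points, very low degrees-of-freedom estimates, and
standard-error failures are flagged rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from . import lst_spec
from .lst_spec import LSTModelSpec, MixtureParams
from .rmst_core import NU_MIN, NU_NORMAL_LIMIT

__all__ = [
    "FitResult",
    "compute_standard_errors",
    "fit_mixture",
    "mixture_loglik",
]

# Convergence tolerances on the packed scale (documented stand-ins for the
# reference software's defaults) and the iteration cap.
DEFAULT_MAX_ITER = 500
DEFAULT_FTOL = 1e-6
DEFAULT_GTOL = 1e-4

BOUNDARY_VARIANCE_RATIO = 1e-4
LOW_NU_THRESHOLD = 2.5

WARNING_KINDS = frozenset(
    {"boundary_variance", "nonpd_information", "low_nu", "se_failure", "saddle_point"}
)


@dataclass(eq=False)
class FitResult:
    """Outcome of one replication fit."""

    estimates: MixtureParams
    standard_errors: np.ndarray | None
    loglik: float
    converged: bool
    n_iterations: int
    warnings: frozenset[str]
    estimated_class1_proportion: float
    theta: np.ndarray = field(repr=False, default=None)
    spec: LSTModelSpec = field(repr=False, default=None)

    def __post_init__(self) -> None:
        bad = set(self.warnings) - WARNING_KINDS
        if bad:
            raise ValueError(f"unknown warning kinds: {sorted(bad)}")
        self.warnings = frozenset(self.warnings)


def mixture_loglik(
    theta: np.ndarray, spec: LSTModelSpec, data: np.ndarray
) -> float:
    """Observed-data log-likelihood sum_i log sum_c pi_c f_c(y_i)."""
    from .rmst_core import _logpdf_raw

    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != spec.p:
        raise ValueError(f"data has {data.shape[1]} columns, expected {spec.p}")
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_free_parameters,):
        raise ValueError(
            f"theta has shape {theta.shape}, expected ({spec.n_free_parameters},)"
        )
    names = spec.free_class_param_names
    k = len(names)
    j = spec.n_occasions
    scored = np.empty((spec.n_classes, data.shape[0]))
    for c in range(spec.n_classes):
        vals = {
            name: lst_spec._from_packed(name, theta[c * k + i])
            for i, name in enumerate(names)
        }
        vals.update(spec.fixed)
        mu, sigma, delta = lst_spec._moment_arrays(j, vals)
        try:
            scored[c] = _logpdf_raw(mu, delta, vals["nu"], data, sigma=sigma)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError("non-PD class covariance") from exc
    if spec.n_classes == 2:
        logit = theta[-1]
        # log pi_1 = -log(1+e^-l), log pi_2 = -log(1+e^l), stably
        log_pi = np.array([-np.logaddexp(0.0, -logit), -np.logaddexp(0.0, logit)])
    else:
        log_pi = np.zeros(1)
    scored += log_pi[:, None]
    top = scored.max(axis=0)
    row_ll = top + np.log(np.exp(scored - top).sum(axis=0))
    if not np.all(np.isfinite(row_ll)):
        bad = int(np.flatnonzero(~np.isfinite(row_ll))[0])
        raise FloatingPointError(f"non-finite mixture density at row {bad}")
    return float(np.sum(row_ll))


def _packed_bounds(spec: LSTModelSpec) -> list[tuple[float | None, float | None]]:
    """Box constraints on the packed scale: keep nu in [NU_MIN+, limit] and
    log-variances away from overflow; everything else unconstrained."""
    bounds: list[tuple[float | None, float | None]] = []
    for _ in range(spec.n_classes):
        for name in spec.free_class_param_names:
            if name == "nu":
                bounds.append((-12.0, float(np.log(NU_NORMAL_LIMIT - NU_MIN))))
            elif name in lst_spec.LOG_SCALE_PARAMS:
                bounds.append((-25.0, 25.0))
            else:
                bounds.append((None, None))
    if spec.n_classes == 2:
        bounds.append((None, None))
    return bounds


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    hess = np.empty((k, k))
    f0 = f(x)
    for a in range(k):
        ea = np.zeros(k)
        ea[a] = h[a]
        fpp = f(x + 2 * ea)
        fmm = f(x - 2 * ea)
        hess[a, a] = (fpp - 2.0 * f0 + fmm) / (4.0 * h[a] * h[a])
        for b in range(a + 1, k):
            eb = np.zeros(k)
            eb[b] = h[b]
            hess[a, b] = hess[b, a] = (
                f(x + ea + eb) - f(x + ea - eb) - f(x - ea + eb) + f(x - ea - eb)
            ) / (4.0 * h[a] * h[b])
    return hess


def compute_standard_errors(
    theta: np.ndarray, spec: LSTModelSpec, data: np.ndarray
) -> tuple[np.ndarray | None, frozenset[str]]:
    """Observed-information SEs on the reporting scale, plus warning flags.

    Returns ``(None, flags)`` when the information matrix is not positive
    definite or inversion fails; a negative eigenvalue additionally flags a
    saddle point.
    """
    warnings: set[str] = set()

    def neg_ll(t: np.ndarray) -> float:
        try:
            return -mixture_loglik(t, spec, data)
        except FloatingPointError:
            return np.inf

    try:
        hess = _numeric_hessian(neg_ll, np.asarray(theta, dtype=float))
    except Exception:
        return None, frozenset({"se_failure"})
    if not np.all(np.isfinite(hess)):
        return None, frozenset({"se_failure"})
    eigvals = linalg.eigvalsh(hess)
    if eigvals.min() <= 0:
        warnings.add("nonpd_information")
        if eigvals.min() < -1e-6 * max(1.0, abs(eigvals.max())):
            warnings.add("saddle_point")
        return None, frozenset(warnings)
    try:
        cov_packed = linalg.inv(hess)
    except linalg.LinAlgError:
        return None, frozenset({"se_failure"})
    se_packed = np.sqrt(np.maximum(np.diag(cov_packed), 0.0))
    se = se_packed * lst_spec.reporting_scale_jacobian(theta, spec)
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        warnings.add("se_failure")
        return None, frozenset(warnings)
    return se, frozenset(warnings)


def _se_with_polish(theta_hat, best_fun, spec, data, neg_ll):
    """Standard errors with one bounded polish retry.

    The default tolerances can stop the quasi-Newton search slightly short
    along nearly flat directions (typically nu), leaving the numerical
    information matrix indefinite even though the solution is interior.  In
    that case a short, tight re-optimization from the current point is
    attempted once before the non-PD flags are accepted.
    """
    se, se_warnings = compute_standard_errors(theta_hat, spec, data)
    if "nonpd_information" in se_warnings:
        try:
            res = optimize.minimize(
                neg_ll,
                theta_hat,
                method="L-BFGS-B",
                bounds=_packed_bounds(spec),
                options=dict(maxiter=80, ftol=1e-12, gtol=1e-7),
            )
        except Exception:
            res = None
        if res is not None and np.isfinite(res.fun) and res.fun <= best_fun:
            theta_hat, best_fun = res.x, float(res.fun)
            se, se_warnings = compute_standard_errors(theta_hat, spec, data)
    return theta_hat, best_fun, se, se_warnings


def add_standard_errors(fit: FitResult, data: np.ndarray) -> FitResult:
    """Return a copy of a converged fit with standard errors attached.

    Applies the same polish retry as :func:`fit_mixture`; the estimates and
    log-likelihood are updated if the polish improves the optimum.
    """
    from dataclasses import replace

    data = np.atleast_2d(np.asarray(data, dtype=float))
    spec = fit.spec

    def neg_ll(t: np.ndarray) -> float:
        try:
            return -mixture_loglik(t, spec, data)
        except FloatingPointError:
            return np.inf

    theta, best_fun, se, se_warnings = _se_with_polish(
        fit.theta, -fit.loglik, spec, data, neg_ll
    )
    estimates = lst_spec.unpack_params(theta, spec)
    return replace(
        fit,
        theta=np.asarray(theta, dtype=float),
        loglik=float(-best_fun),
        estimates=estimates,
        estimated_class1_proportion=float(estimates.pi[0]),
        standard_errors=se,
        warnings=fit.warnings | se_warnings,
    )


def fit_mixture(
    data: np.ndarray,
    spec: LSTModelSpec,
    start: MixtureParams,
    max_iter: int = DEFAULT_MAX_ITER,
    ftol: float = DEFAULT_FTOL,
    gtol: float = DEFAULT_GTOL,
    n_extra_starts: int = 0,
    rng: np.random.Generator | None = None,
    compute_se: bool = True,
) -> FitResult:
    """Maximize the mixture log-likelihood from the given starting values.

    Optimizer exceptions never propagate; they yield a non-converged
    :class:`FitResult`.  ``n_extra_starts`` adds that many perturbed starting
    points (population starts are the default, as in the study design).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    theta0 = lst_spec.pack_params(start, spec)
    bounds = _packed_bounds(spec)

    def neg_ll(t: np.ndarray) -> float:
        try:
            return -mixture_loglik(t, spec, data)
        except FloatingPointError:
            return np.inf

    starts = [theta0]
    if n_extra_starts:
        rng = rng or np.random.default_rng(0)
        starts += [
            theta0 + 0.25 * rng.standard_normal(theta0.size)
            for _ in range(n_extra_starts)
        ]

    best = None
    n_iter_total = 0
    for t0 in starts:
        try:
            res = optimize.minimize(
                neg_ll,
                t0,
                method="L-BFGS-B",
                bounds=bounds,
                options=dict(maxiter=max_iter, ftol=ftol, gtol=gtol),
            )
        except Exception:
            continue
        n_iter_total += int(res.nit)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res

    ll_start = -neg_ll(theta0)
    if best is None or not np.isfinite(best.fun):
        return FitResult(
            estimates=start,
            standard_errors=None,
            loglik=ll_start,
            converged=False,
            n_iterations=n_iter_total,
            warnings=frozenset({"se_failure"}),
            estimated_class1_proportion=float(start.pi[0]),
            theta=theta0,
            spec=spec,
        )

    theta_hat = best.x
    # guard against optimizer steps that ended worse than the start
    if -best.fun < ll_start:
        theta_hat = theta0
        best_fun = -ll_start
        converged = False
    else:
        best_fun = best.fun
        converged = bool(best.success)
    estimates = lst_spec.unpack_params(theta_hat, spec)

    warnings: set[str] = set()
    for cp, cp0 in zip(estimates.class_params, start.class_params):
        for name in lst_spec.LOG_SCALE_PARAMS & set(spec.free_class_param_names):
            if getattr(cp, name) < BOUNDARY_VARIANCE_RATIO * getattr(cp0, name):
                warnings.add("boundary_variance")
        if "nu" in spec.free_class_param_names and cp.nu < LOW_NU_THRESHOLD:
            warnings.add("low_nu")

    se = None
    if compute_se and converged:
        theta_hat, best_fun, se, se_warnings = _se_with_polish(
            theta_hat, best_fun, spec, data, neg_ll
        )
        estimates = lst_spec.unpack_params(theta_hat, spec)
        warnings |= se_warnings

    return FitResult(
        estimates=estimates,
        standard_errors=se,
        loglik=float(-best_fun),
        converged=converged,
        n_iterations=n_iter_total,
        warnings=frozenset(warnings),
        estimated_class1_proportion=float(estimates.pi[0]),
        theta=np.asarray(theta_hat, dtype=float),
        spec=spec,
    )
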