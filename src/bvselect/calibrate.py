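"""Penalized maximum-likelihood calibration of a BV model to one subject.

The likelihood treats the measurement errors as iid Gaussian, so for a
parameter vector Θ the log-likelihood is

    L*(Θ, σ) = −(K/2)·ln 2π − (K/2)·ln σ² − RSS(Θ)/(2σ²)

with RSS the residual sum of squares between the measurements and the
simulated ΔBV at the measurement times.  σ is profiled analytically
(σ*² = RSS/K at the optimum), leaving a bounded search over the model
parameters of the objective

    −L*(Θ, σ*(Θ)) + 2γ·‖Θ‖₂

where γ ≥ 0 penalizes the (raw-scale) L2 *norm* of the parameter vector.
The penalty level is chosen per subject and model from the candidate set
{1, 3, 5} by an inner validation split: fit on the first 120 min, score
the held-out last 60 min by AIC, keep the γ with the least value (ties go
to the smallest γ).

The optimizer is multi-start: bounded trust-region least squares on the
residual vector from Latin-hypercube starts (the profiled −L* is a
monotone transform of RSS, so for γ = 0 the least-squares optimum is the
MLE), with a bounded quasi-Newton (L-BFGS-B) polish of the penalized
objective when γ > 0.  The positive gains Kp, Ki are handled on a log
scale internally; bounds and penalty apply to the raw values and default
to the pooled cohort statistics (mean ± 4 sd over both fluid groups)
intersected with the parameter invariants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .cohort import PARAMETER_PRIORS
from .dataio import BVMeasurementSeries, SubjectRecord, register_serializable
from .models import (BVModelError, ModelParameters, PARAM_NAMES,
                     TrajectoryEvaluator, ValidationError, delta_bv_at)

__all__ = [
    "CalibrationResult",
    "FitOptions",
    "default_bounds",
    "negative_log_likelihood",
    "fit_mle",
    "select_penalty",
    "GAMMA_CANDIDATES",
    "REPLICATE_OPTIONS",
]

GAMMA_CANDIDATES = (1.0, 3.0, 5.0)
_LOG_2PI = float(np.log(2.0 * np.pi))
_MIN_VAR = 1e-12  # floor on the profiled variance (perfect-fit guard)


@register_serializable
@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of one penalized-MLE fit."""

    params: ModelParameters        # includes the profiled sigma*
    gamma: float
    loglik: float                  # L* at the optimum (unpenalized)
    residuals: np.ndarray          # measured − predicted, ml
    rmse: float                    # ml
    aic: float                     # −2 L* + 2 P
    n_obs: int
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for :func:`fit_mle`."""

    n_starts: int = 10
    bounds: dict[str, tuple[float, float]] | None = None
    x0: np.ndarray | None = None   # extra warm start, prepended to the LHS starts
    ftol: float = 1e-10            # L-BFGS-B relative f tolerance
    gtol: float = 1e-7
    maxiter: int = 500
    penalty: str = "norm"          # "norm" (2γ‖Θ‖₂) or "squared"


#: Cheaper settings for the bootstrap replicate fits of the prediction
#: scenarios: warm-started (x0 is set by the caller), single start, looser
#: convergence.  The envelope statistics are insensitive to the last digits
#: of each replicate optimum.
REPLICATE_OPTIONS = FitOptions(n_starts=1, ftol=1e-7, gtol=1e-5, maxiter=120)


def default_bounds(variant: str, spread: float = 4.0) -> dict[str, tuple[float, float]]:
    """Per-parameter box bounds: pooled-fluid mean ± ``spread``·sd, clipped to invariants."""
    lo_inv = {"alpha_u": -0.99, "alpha_v": -0.99, "Kp": 1e-4, "Ki": 1e-6,
              "A_u": -np.inf, "A_v": -np.inf}
    hi_inv = {"alpha_u": np.inf, "alpha_v": np.inf, "Kp": np.inf, "Ki": np.inf,
              "A_u": 0.0, "A_v": 0.0}
    bounds = {}
    for name in PARAM_NAMES[variant]:
        los, his = [], []
        for fluid in ("LR", "HEX"):
            mean, sd = PARAMETER_PRIORS[(variant, fluid)][name]
            los.append(mean - spread * sd)
            his.append(mean + spread * sd)
        bounds[name] = (max(min(los), lo_inv[name]), min(max(his), hi_inv[name]))
    return bounds


def _rss(free: np.ndarray, variant: str, subject: SubjectRecord,
         measurements: BVMeasurementSeries,
         evaluator: TrajectoryEvaluator | None = None) -> tuple[float, np.ndarray]:
    params = ModelParameters.from_free_values(variant, free)
    if evaluator is None:
        pred = delta_bv_at(params, subject.protocol, measurements.times)
    else:
        pred = evaluator(params)
    resid = measurements.delta_bv - pred
    return float(resid @ resid), resid


def negative_log_likelihood(params: ModelParameters, subject: SubjectRecord,
                            measurements: BVMeasurementSeries | None = None) -> float:
    """−L*(Θ, σ) for explicit σ (must be set on ``params``)."""
    if params.sigma is None:
        raise ValidationError("negative_log_likelihood requires params.sigma")
    meas = subject.measurements if measurements is None else measurements
    k = meas.K
    rss, _ = _rss(params.free_values(), params.variant, subject, meas)
    s2 = params.sigma ** 2
    return 0.5 * k * _LOG_2PI + 0.5 * k * np.log(s2) + rss / (2.0 * s2)


def _profiled_nll(rss: float, k: int) -> tuple[float, float]:
    """(−L*, σ*²) with σ profiled analytically at σ*² = RSS/K."""
    s2 = max(rss / k, _MIN_VAR)
    return 0.5 * k * (_LOG_2PI + np.log(s2) + rss / (k * s2)), s2


def fit_mle(subject: SubjectRecord, variant: str, gamma: float = 0.0,
            options: FitOptions = FitOptions(), seed: int | None = None,
            measurements: BVMeasurementSeries | None = None) -> CalibrationResult:
    """Fit one model to one subject by penalized maximum likelihood.

    ``measurements`` restricts the fit to a subset of the subject's series
    (used by the penalty-selection split and the bootstrap scenarios).
    Deterministic for a fixed ``seed``.
    """
    meas = subject.measurements if measurements is None else measurements
    names = PARAM_NAMES[variant]
    p = len(names)
    if meas.K <= p:
        raise ValidationError(
            f"need more observations than parameters (K={meas.K}, P={p})")
    if np.all(subject.protocol.infusion_rate == 0) and \
            np.all(subject.protocol.hemorrhage_rate == 0):
        raise ValidationError("uninformative data: protocol has zero input throughout")

    bounds_map = options.bounds or default_bounds(variant)
    lo = np.array([bounds_map[n][0] for n in names])
    hi = np.array([bounds_map[n][1] for n in names])
    is_log = np.array([n in ("Kp", "Ki") for n in names])

    def to_internal(x: np.ndarray) -> np.ndarray:
        z = np.array(x, dtype=float)
        z[is_log] = np.log(z[is_log])
        return z

    def to_raw(z: np.ndarray) -> np.ndarray:
        x = np.array(z, dtype=float)
        x[is_log] = np.exp(x[is_log])
        return x

    zlo, zhi = to_internal(lo), to_internal(hi)
    evaluator = TrajectoryEvaluator(subject.protocol, meas.times)

    def objective(z: np.ndarray) -> float:
        free = to_raw(z)
        try:
            rss, _ = _rss(free, variant, subject, meas, evaluator)
        except (ValidationError, FloatingPointError):
            return 1e12
        nll, _ = _profiled_nll(rss, meas.K)
        if gamma > 0:
            norm = float(np.linalg.norm(free))
            nll += 2.0 * gamma * (norm if options.penalty == "norm" else norm ** 2)
        return nll

    starts = []
    if options.x0 is not None:
        starts.append(to_internal(np.clip(np.asarray(options.x0, dtype=float),
                                          lo, hi)))
    n_lhs = max(options.n_starts - len(starts), 0)
    if n_lhs:
        sampler = qmc.LatinHypercube(d=p, seed=seed)
        unit = sampler.random(n_lhs)
        starts.extend(zlo + unit * (zhi - zlo))

    def residuals(z: np.ndarray) -> np.ndarray:
        try:
            _, resid = _rss(to_raw(z), variant, subject, meas, evaluator)
        except (ValidationError, FloatingPointError):
            return np.full(meas.K, 1e6)
        return resid

    # The profiled −L* is a monotone transform of RSS, so for γ = 0 the MLE
    # is the least-squares optimum; a trust-region least-squares stage has a
    # far better-behaved landscape than the log-likelihood itself (which is
    # near-singular as RSS → 0).  For γ > 0 the penalized objective is then
    # polished by a bounded quasi-Newton pass from the least-squares point.
    best_z, best_f = None, np.inf
    n_converged = 0
    nfev = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        for z0 in starts:
            ls = optimize.least_squares(
                residuals, z0, bounds=(zlo, zhi), method="trf",
                ftol=options.ftol, xtol=options.ftol, gtol=options.gtol,
                max_nfev=options.maxiter * (p + 1))
            nfev += ls.nfev
            z, f = ls.x, objective(ls.x)
            if ls.status > 0:
                n_converged += 1
            if np.isfinite(f) and f < best_f:
                best_z, best_f = z, f
        if gamma > 0 and best_z is not None:
            res = optimize.minimize(
                objective, best_z, method="L-BFGS-B", bounds=list(zip(zlo, zhi)),
                options={"ftol": options.ftol, "gtol": options.gtol,
                         "maxiter": options.maxiter})
            nfev += res.nfev
            if np.isfinite(res.fun) and res.fun < best_f:
                best_z, best_f = res.x, res.fun
    if best_z is None or best_f >= 1e12:
        raise BVModelError(
            f"all {len(starts)} optimizer starts failed for subject "
            f"{subject.subject_id} ({variant}, gamma={gamma})")

    free = np.clip(to_raw(best_z), lo, hi)
    rss, resid = _rss(free, variant, subject, meas)
    nll, s2 = _profiled_nll(rss, meas.K)
    loglik = -nll
    params = ModelParameters.from_free_values(variant, free, sigma=np.sqrt(s2))
    return CalibrationResult(
        params=params, gamma=gamma, loglik=loglik, residuals=resid,
        rmse=float(np.sqrt(rss / meas.K)), aic=-2.0 * loglik + 2.0 * p,
        n_obs=meas.K,
        diagnostics={"n_starts": len(starts), "n_converged": n_converged,
                     "best_objective": float(best_f),
                     "n_function_evals": int(nfev), "seed": seed})


def _holdout_aic(subject: SubjectRecord, fit: CalibrationResult,
                 holdout: BVMeasurementSeries) -> float:
    """AIC of the fitted model evaluated on held-out points (σ profiled there)."""
    rss, _ = _rss(fit.params.free_values(), fit.params.variant, subject, holdout)
    nll, _ = _profiled_nll(rss, holdout.K)
    return 2.0 * nll + 2.0 * fit.params.n_params


def select_penalty(subject: SubjectRecord, variant: str,
                   gammas: tuple[float, ...] = GAMMA_CANDIDATES,
                   split_time: float = 120.0,
                   options: FitOptions = FitOptions(),
                   seed: int | None = None,
                   aic_on: str = "holdout") -> tuple[float, dict[float, float]]:
    """Choose the penalty level by the inner validation split.

    Fits each candidate γ to the measurements at t ≤ ``split_time`` and
    scores the remaining points by AIC (on the held-out residuals by
    default, on the full series with ``aic_on="full"``).  Returns the
    selected γ and the per-candidate scores; ties go to the smallest γ.
    """
    meas = subject.measurements
    cal_mask = meas.times <= split_time
    if not cal_mask.any() or cal_mask.all():
        raise ValidationError(
            f"penalty selection needs measurements on both sides of "
            f"t = {split_time} min")
    cal = meas.subset(cal_mask)
    holdout = meas.subset(~cal_mask) if aic_on == "holdout" else meas
    scores: dict[float, float] = {}
    best_gamma, best_score = None, np.inf
    opts = options
    for g in sorted(gammas):
        fit = fit_mle(subject, variant, gamma=g, options=opts, seed=seed,
                      measurements=cal)
        # neighbouring penalty levels have nearby optima: chain warm starts
        opts = dc_replace(options, x0=fit.params.free_values())
        score = _holdout_aic(subject, fit, holdout)
        scores[g] = score
        if score < best_score:
            best_gamma, best_score = g, score
    return best_gamma, scores
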