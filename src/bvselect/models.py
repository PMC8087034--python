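"""Lumped-parameter blood-volume (BV) response models.

Two candidate models of the intravascular volume response ΔBV(t) to fluid
infusion U(t) and hemorrhage V(t):

* **original** — the desired steady-state BV change is a static split of the
  cumulative fluid balance, ``r_BV = ∫U/(1+α_u) − ∫V/(1+α_v)``, and an
  internal proportional–integral (PI) "controller" with gains ``K_p, K_i``
  drives ΔBV toward it via the inter-compartmental fluid shift ``q``.
* **refined** — the two components of ``r_BV`` acquire first-order dynamics
  ``ṙ_u = A_u·r_u + U/(1+α_u)`` and ``ṙ_v = A_v·r_v − V/(1+α_v)`` with
  non-positive state parameters ``A_u, A_v``, so the target itself relaxes
  over time even without fluid input.  ``A_u = A_v = 0`` recovers the
  original model exactly.

Both are linear time-invariant (LTI) systems.  The implementation realizes
the structural form as a four-state system (ΔBV, ∫e_BV, r_u, r_v) plus an
auxiliary ∫q state, and integrates it *exactly* for piecewise-constant
inputs by zero-order-hold (matrix-exponential) discretization.  Equivalence
to the third/fourth-order single-equation forms is exposed through
:func:`transfer_function`, which serves as an independent frequency-domain
oracle in the test-suite.

Units: volumes in ml, time in minutes, rates in ml/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
from numba import njit
from scipy.linalg import expm

__all__ = [
    "BVModelError",
    "ValidationError",
    "ConsistencyError",
    "ModelParameters",
    "FluidProtocol",
    "SimulationResult",
    "RegressorCoefficients",
    "TransferFunction",
    "simulate",
    "delta_bv_at",
    "TrajectoryEvaluator",
    "steady_state_response",
    "params_to_theta",
    "theta_to_params",
    "transfer_function",
    "PARAM_NAMES",
]

VARIANTS = ("original", "refined")

#: Ordered free-parameter names per variant (the penalized vector Θ).
PARAM_NAMES = {
    "original": ("alpha_u", "alpha_v", "Kp", "Ki"),
    "refined": ("alpha_u", "alpha_v", "Kp", "Ki", "A_u", "A_v"),
}


class BVModelError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(BVModelError, ValueError):
    """An input violated a documented invariant."""


class ConsistencyError(BVModelError):
    """A regressor-coefficient vector is inconsistent with the model structure."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Parameters of one BV-response model.

    ``alpha_u``/``alpha_v`` are the fluid distribution ratios between the
    interstitial and intravascular compartments under infusion/loss (the
    intravascular compartment retains a 1/(1+α) fraction at steady state);
    ``Kp`` [1/min] and ``Ki`` [1/min²] are the PI gains of the fluid-shift
    controller; ``A_u``/``A_v`` [1/min] are the refined model's state
    parameters (fixed at 0 for the original variant); ``sigma`` [ml] is the
    residual standard deviation, present only after a fit.
    """

    variant: str
    alpha_u: float
    alpha_v: float
    Kp: float
    Ki: float
    A_u: float = 0.0
    A_v: float = 0.0
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        for name in ("alpha_u", "alpha_v", "Kp", "Ki", "A_u", "A_v"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")
        if 1.0 + self.alpha_u <= 0.0:
            raise ValidationError(f"1 + alpha_u must be > 0 (alpha_u={self.alpha_u})")
        if 1.0 + self.alpha_v <= 0.0:
            raise ValidationError(f"1 + alpha_v must be > 0 (alpha_v={self.alpha_v})")
        if self.Kp <= 0.0:
            raise ValidationError(f"Kp must be > 0 (got {self.Kp})")
        if self.Ki <= 0.0:
            raise ValidationError(f"Ki must be > 0 (got {self.Ki})")
        if self.variant == "original":
            if self.A_u != 0.0 or self.A_v != 0.0:
                raise ValidationError("original variant requires A_u = A_v = 0")
        else:
            if self.A_u > 0.0 or self.A_v > 0.0:
                raise ValidationError(
                    f"refined variant requires A_u <= 0 and A_v <= 0 "
                    f"(got A_u={self.A_u}, A_v={self.A_v})")
        if self.sigma is not None and not self.sigma > 0.0:
            raise ValidationError(f"sigma must be > 0 when present (got {self.sigma})")

    @property
    def n_params(self) -> int:
        """Number of free model parameters P (4 original, 6 refined)."""
        return 4 if self.variant == "original" else 6

    def free_values(self) -> np.ndarray:
        """The free-parameter vector in the order of ``PARAM_NAMES[variant]``."""
        return np.array([getattr(self, n) for n in PARAM_NAMES[self.variant]])

    @classmethod
    def from_free_values(cls, variant: str, values: Sequence[float],
                         sigma: float | None = None) -> "ModelParameters":
        names = PARAM_NAMES[variant]
        if len(values) != len(names):
            raise ValidationError(
                f"{variant} variant expects {len(names)} parameters, got {len(values)}")
        return cls(variant=variant, sigma=sigma,
                   **dict(zip(names, (float(v) for v in values))))

    def with_sigma(self, sigma: float) -> "ModelParameters":
        return replace(self, sigma=float(sigma))


@dataclass(frozen=True)
class FluidProtocol:
    """Fluid perturbation protocol on a uniform time grid.

    Rates are piecewise constant and left-continuous: the value at grid
    point ``i`` holds over ``[time[i], time[i+1])``.
    """

    time: np.ndarray            # minutes
    infusion_rate: np.ndarray   # ml/min, U(t) >= 0
    hemorrhage_rate: np.ndarray  # ml/min, V(t) >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        u = np.asarray(self.infusion_rate, dtype=float)
        v = np.asarray(self.hemorrhage_rate, dtype=float)
        if not (t.ndim == u.ndim == v.ndim == 1 and len(t) == len(u) == len(v) >= 2):
            raise ValidationError("time, infusion_rate, hemorrhage_rate must be "
                                  "1-d arrays of equal length >= 2")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValidationError("time grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValidationError("time grid must be uniform (constant dt)")
        if np.any(u < 0) or np.any(v < 0):
            raise ValidationError("infusion and hemorrhage rates must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "infusion_rate", u)
        object.__setattr__(self, "hemorrhage_rate", v)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def cumulative_infused(self) -> np.ndarray:
        """Exact ∫U on the grid (ZOH: left value held over each step)."""
        return np.concatenate(([0.0], np.cumsum(self.infusion_rate[:-1]) * self.dt))

    def cumulative_lost(self) -> np.ndarray:
        """Exact ∫V on the grid."""
        return np.concatenate(([0.0], np.cumsum(self.hemorrhage_rate[:-1]) * self.dt))


@dataclass(frozen=True)
class SimulationResult:
    """Trajectories of one model run, all on the protocol grid (ml)."""

    time: np.ndarray
    delta_bv: np.ndarray
    r_bv: np.ndarray
    r_bv_u: np.ndarray
    r_bv_v: np.ndarray
    e_bv: np.ndarray
    q: np.ndarray                  # ml/min, inter-compartmental shift
    interstitial_change: np.ndarray  # cumulative ∫q


@dataclass(frozen=True)
class RegressorCoefficients:
    """The ordered identifiability coefficient vector Θ.

    Seven entries for the original model, eleven for the refined model, in
    the order the frequency-domain regression prints them.  The entry
    multiplying the ``s⁻¹(U−V)`` regressor is exactly 1 in both variants
    (3rd entry original, 5th refined).
    """

    variant: str
    theta: np.ndarray

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        expected = 7 if self.variant == "original" else 11
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")
        if th.shape != (expected,):
            raise ValidationError(
                f"{self.variant} variant requires {expected} theta entries, "
                f"got shape {th.shape}")
        object.__setattr__(self, "theta", th)


@dataclass(frozen=True)
class TransferFunction:
    """Rational transfer functions of the two input channels.

    ``ΔBV(s) = num_u(s)/den(s) · U(s) − num_v(s)/den(s) · V(s)`` with a
    shared monic denominator: degree 3, ``s³ + Kp·s² + Ki·s``, for the
    original model (pure integrator at s = 0) and the degree-4 analogue
    ``(s² + Kp·s + Ki)(s − A_u)(s − A_v)`` for the refined model.
    Coefficients are stored highest power first.
    """

    num_u: np.ndarray
    num_v: np.ndarray
    den: np.ndarray


# ---------------------------------------------------------------------------
# state-space realization and simulation
# ---------------------------------------------------------------------------
# State vector x = [ΔBV, ∫e_BV, r_u, r_v, ∫q]; inputs w = [U, V].
# e_BV = r_u + r_v − ΔBV,  q = −Kp·e_BV − Ki·∫e_BV,  ΔBV̇ = U − V − q.

def state_matrices(params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Continuous-time (A, B) of the 5-state augmented realization."""
    Kp, Ki = params.Kp, params.Ki
    cu = 1.0 / (1.0 + params.alpha_u)
    cv = 1.0 / (1.0 + params.alpha_v)
    A = np.array([
        [-Kp, Ki, Kp, Kp, 0.0],
        [-1.0, 0.0, 1.0, 1.0, 0.0],
        [0.0, 0.0, params.A_u, 0.0, 0.0],
        [0.0, 0.0, 0.0, params.A_v, 0.0],
        [Kp, -Ki, -Kp, -Kp, 0.0],
    ])
    B = np.array([
        [1.0, -1.0],
        [0.0, 0.0],
        [cu, 0.0],
        [0.0, -cv],
        [0.0, 0.0],
    ])
    return A, B


def _zoh(A: np.ndarray, B: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact zero-order-hold discretization via the augmented matrix exponential."""
    n, m = B.shape
    M = np.zeros((n + m, n + m))
    M[:n, :n] = A
    M[:n, n:] = B
    E = expm(M * dt)
    return E[:n, :n], E[:n, n:]


def simulate(params: ModelParameters, protocol: FluidProtocol) -> SimulationResult:
    """Integrate the model over the full protocol grid.

    The inputs are held constant over each grid step (zero-order hold), for
    which the matrix-exponential update is exact, so the only error source
    is floating point.  All states start at zero.
    """
    A, B = state_matrices(params)
    Ad, Bd = _zoh(A, B, protocol.dt)
    n = len(protocol.time)
    X = np.zeros((n, 5))
    w = np.column_stack([protocol.infusion_rate, protocol.hemorrhage_rate])
    x = np.zeros(5)
    for k in range(n - 1):
        x = Ad @ x + Bd @ w[k]
        X[k + 1] = x
    dbv, eint, ru, rv, qint = X.T
    r = ru + rv
    e = r - dbv
    q = -params.Kp * e - params.Ki * eint
    return SimulationResult(time=protocol.time, delta_bv=dbv, r_bv=r,
                            r_bv_u=ru, r_bv_v=rv, e_bv=e, q=q,
                            interstitial_change=qint)


def _segments(protocol: FluidProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Break the protocol into maximal constant-input runs.

    Returns (boundary grid indices including 0 and n-1, per-segment inputs).
    """
    w = np.column_stack([protocol.infusion_rate[:-1], protocol.hemorrhage_rate[:-1]])
    change = np.nonzero(np.any(w[1:] != w[:-1], axis=1))[0] + 1
    bounds = np.concatenate(([0], change, [len(protocol.time) - 1]))
    return bounds, w[bounds[:-1]]


@njit(cache=False)
def _hop_recursion(Ads: np.ndarray, bws: np.ndarray) -> np.ndarray:
    """x_{j+1} = Ads[j] @ x_j + bws[j]; returns ΔBV (= x[0]) at every stop."""
    n = Ads.shape[0]
    dbv = np.empty(n + 1)
    dbv[0] = 0.0
    x = np.zeros(4)
    for j in range(n):
        x = Ads[j] @ x + bws[j]
        dbv[j + 1] = x[0]
    return dbv


class TrajectoryEvaluator:
    """Prepared ΔBV evaluator for one protocol and a fixed set of times.

    Precomputes the constant-input segment structure once so that repeated
    evaluation inside an optimizer loop only pays one matrix exponential
    (hops are composed from the base hop by the zero-order-hold chain rule)
    plus a compiled recursion.  Results are identical to sampling
    :func:`simulate` at the requested times.
    """

    def __init__(self, protocol: FluidProtocol, times: np.ndarray) -> None:
        times = np.asarray(times, dtype=float)
        dt = protocol.dt
        idx_f = (times - protocol.time[0]) / dt
        idx = np.rint(idx_f).astype(int)
        if np.any(np.abs(idx_f - idx) > 1e-6) or np.any(idx < 0) or \
                np.any(idx > len(protocol.time) - 1):
            raise ValidationError("requested times must lie on the protocol grid")
        bounds, seg_w = _segments(protocol)
        stops = np.unique(np.concatenate([bounds[:-1], idx]))
        stops = stops[stops <= idx.max()] if len(idx) else stops[:1]
        hop_len: list[int] = []
        hop_w: list[np.ndarray] = []
        seg = 0
        for j in range(1, len(stops)):
            prev, cur = int(stops[j - 1]), int(stops[j])
            while seg + 1 < len(seg_w) and prev >= bounds[seg + 1]:
                seg += 1
            hop_len.append(cur - prev)
            hop_w.append(seg_w[seg])
        self._dt = dt
        self._base = int(np.gcd.reduce(hop_len)) if hop_len else 1
        self._multiples = np.array([m // self._base for m in hop_len], dtype=int)
        self._distinct = sorted(set(self._multiples.tolist()))
        self._W = np.array(hop_w) if hop_w else np.zeros((0, 2))
        record = {int(s): j for j, s in enumerate(stops)}
        self._out_pos = np.array([record[int(i)] for i in idx], dtype=int)
        self.times = times

    def __call__(self, params: ModelParameters) -> np.ndarray:
        A, B = state_matrices(params)
        A4, B4 = A[:4, :4], B[:4, :]  # ∫q state not needed for ΔBV
        n_hops = len(self._multiples)
        if n_hops == 0:
            return np.zeros(len(self.times))
        Ad, Bd = _zoh(A4, B4, self._base * self._dt)
        # compose larger hops from the base hop: Ad(k) = Ad^k,
        # Bd(k) = (Ad^{k-1} + ... + I) Bd
        mats = {1: (Ad, Bd)}
        for k in self._distinct:
            if k not in mats:
                kk = max(m for m in mats if m <= k)
                Adk, Bdk = mats[kk]
                while kk < k:
                    Adk, Bdk = Ad @ Adk, Ad @ Bdk + Bd
                    kk += 1
                mats[k] = (Adk, Bdk)
        Ads = np.empty((n_hops, 4, 4))
        bws = np.empty((n_hops, 4))
        for k in self._distinct:
            sel = self._multiples == k
            Adk, Bdk = mats[k]
            Ads[sel] = Adk
            bws[sel] = self._W[sel] @ Bdk.T
        dbv = _hop_recursion(Ads, bws)
        return dbv[self._out_pos]


def delta_bv_at(params: ModelParameters, protocol: FluidProtocol,
                times: np.ndarray) -> np.ndarray:
    """ΔBV at the requested times, exactly as :func:`simulate` would give.

    The propagation is compressed over maximal constant-input segments (one
    matrix-exponential per distinct hop length); ``times`` must lie on the
    protocol grid.  For repeated evaluation with the same protocol and
    times, build a :class:`TrajectoryEvaluator` once instead.
    """
    return TrajectoryEvaluator(protocol, times)(params)


def steady_state_response(params: ModelParameters, total_infused: float,
                          total_lost: float) -> float:
    """The t→∞ limit of ΔBV after all fluid input and loss has ceased.

    Each channel with a zero state parameter contributes its steady-state
    retained fraction, ``total/(1+α)``; a channel with A < 0 has a decaying
    target component, so its contribution vanishes.
    """
    if not (np.isfinite(total_infused) and np.isfinite(total_lost)):
        raise ValidationError("totals must be finite")
    gain = total_infused / (1.0 + params.alpha_u) if params.A_u == 0.0 else 0.0
    loss = total_lost / (1.0 + params.alpha_v) if params.A_v == 0.0 else 0.0
    return gain - loss


# ---------------------------------------------------------------------------
# structural identifiability: Θ coefficient maps
# ---------------------------------------------------------------------------

def params_to_theta(params: ModelParameters) -> RegressorCoefficients:
    """Map model parameters to the frequency-domain coefficient vector Θ."""
    Kp, Ki = params.Kp, params.Ki
    cu = 1.0 / (1.0 + params.alpha_u)
    cv = 1.0 / (1.0 + params.alpha_v)
    if params.variant == "original":
        theta = np.array([-Kp, -Ki, 1.0,
                          Kp * cu, -Kp * cv,
                          Ki * cu, -Ki * cv])
    else:
        Au, Av = params.A_u, params.A_v
        p, pr = Au + Av, Au * Av
        theta = np.array([
            p - Kp,
            Kp * p - pr - Ki,
            -Kp * pr + Ki * p,
            -Ki * pr,
            1.0,
            -p + Kp * cu,
            p - Kp * cv,
            pr + (Ki - Kp * Av) * cu,
            -pr + (Kp * Au - Ki) * cv,
            -Ki * Av * cu,
            Ki * Au * cv,
        ])
    return RegressorCoefficients(variant=params.variant, theta=theta)


def _theta_residual(coeffs: RegressorCoefficients, params: ModelParameters) -> np.ndarray:
    """Per-entry relative mismatch between Θ and the Θ implied by ``params``."""
    target = coeffs.theta
    implied = params_to_theta(params).theta
    scale = np.maximum(np.abs(target), 1e-3)
    return np.abs(implied - target) / scale


def theta_to_params(coeffs: RegressorCoefficients, rtol: float = 1e-5,
                    sigma: float | None = None) -> ModelParameters:
    """Invert :func:`params_to_theta`; the map is one-to-one for valid Θ.

    For the original model the inversion reads directly off the printed
    entries.  For the refined model the first four entries are, up to sign,
    the coefficients of the characteristic polynomial
    ``(s² + Kp·s + Ki)(s − A_u)(s − A_v)``; the quartic is factored by root
    pairing, candidate pairings are scored by the consistency residual on
    the remaining entries, and the α's come from entries 6–7.

    Raises :class:`ConsistencyError` when no parameter set reproduces every
    entry within ``rtol`` (reporting which entries disagree) and when the
    implied (A_u, A_v) are complex.
    """
    th = coeffs.theta
    if coeffs.variant == "original":
        Kp, Ki = -th[0], -th[1]
        if Kp <= 0 or Ki <= 0:
            raise ConsistencyError(
                f"entries 1-2 imply non-positive gains Kp={Kp}, Ki={Ki}")
        cu, cv = th[3] / Kp, -th[4] / Kp
        if cu <= 0 or cv <= 0:
            raise ConsistencyError("entries 4-5 imply non-positive 1/(1+alpha)")
        cand = ModelParameters("original", alpha_u=1.0 / cu - 1.0,
                               alpha_v=1.0 / cv - 1.0, Kp=Kp, Ki=Ki, sigma=sigma)
        res = _theta_residual(coeffs, cand)
        bad = np.nonzero(res > rtol)[0]
        if len(bad):
            raise ConsistencyError(
                f"theta inconsistent with original-model structure at entries "
                f"{(bad + 1).tolist()} (relative residuals {res[bad].round(6).tolist()})")
        return cand

    # refined: factor s^4 - t1 s^3 - t2 s^2 - t3 s - t4
    roots = np.roots([1.0, -th[0], -th[1], -th[2], -th[3]])
    best: tuple[float, ModelParameters] | None = None
    for pair in combinations(range(4), 2):
        a_roots = roots[list(pair)]
        k_roots = roots[[i for i in range(4) if i not in pair]]
        if np.max(np.abs(a_roots.imag)) > 1e-8 * (1 + np.max(np.abs(a_roots))):
            continue  # A_u, A_v must be real
        Au, Av = np.sort(a_roots.real)[::-1]  # assignment refined below by residual
        Kp = float(-(k_roots[0] + k_roots[1]).real)
        Ki = float((k_roots[0] * k_roots[1]).real)
        if Kp <= 0 or Ki <= 0:
            continue
        for Au_c, Av_c in ((Au, Av), (Av, Au)):
            if Au_c > 1e-10 or Av_c > 1e-10:
                continue
            p = Au_c + Av_c
            cu = (th[5] + p) / Kp
            cv = (p - th[6]) / Kp
            if cu <= 0 or cv <= 0:
                continue
            try:
                cand = ModelParameters(
                    "refined", alpha_u=1.0 / cu - 1.0, alpha_v=1.0 / cv - 1.0,
                    Kp=Kp, Ki=Ki, A_u=min(Au_c, 0.0), A_v=min(Av_c, 0.0),
                    sigma=sigma)
            except ValidationError:
                continue
            score = float(np.max(_theta_residual(coeffs, cand)))
            if best is None or score < best[0]:
                best = (score, cand)
    if best is None:
        raise ConsistencyError(
            "no real, stability-consistent factorization of entries 1-4 exists "
            "(complex or positive A_u/A_v implied)")
    score, cand = best
    res = _theta_residual(coeffs, cand)
    bad = np.nonzero(res > rtol)[0]
    if len(bad):
        raise ConsistencyError(
            f"theta inconsistent with refined-model structure at entries "
            f"{(bad + 1).tolist()} (relative residuals {res[bad].round(6).tolist()})")
    return cand


# ---------------------------------------------------------------------------
# frequency-domain oracle
# ---------------------------------------------------------------------------

def transfer_function(params: ModelParameters) -> TransferFunction:
    """Collect the single-equation form into per-channel rational functions."""
    Kp, Ki = params.Kp, params.Ki
    cu = 1.0 / (1.0 + params.alpha_u)
    cv = 1.0 / (1.0 + params.alpha_v)
    if params.variant == "original":
        den = np.array([1.0, Kp, Ki, 0.0])
        num_u = np.array([1.0, Kp * cu, Ki * cu])
        num_v = np.array([1.0, Kp * cv, Ki * cv])
    else:
        Au, Av = params.A_u, params.A_v
        p, pr = Au + Av, Au * Av
        den = np.polymul([1.0, Kp, Ki], np.polymul([1.0, -Au], [1.0, -Av]))
        num_u = np.array([1.0, Kp * cu - p, pr + (Ki - Kp * Av) * cu, -Ki * Av * cu])
        num_v = np.array([1.0, Kp * cv - p, pr + (Ki - Kp * Au) * cv, -Ki * Au * cv])
    return TransferFunction(num_u=num_u, num_v=num_v, den=den)
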