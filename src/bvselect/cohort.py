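"""Synthetic cohort generator emulating the sheep hemorrhage/resuscitation study.

Protocol template (per subject, scaled by body weight): a 25 ml/kg primary
hemorrhage over 0–15 min; closed-loop crystalloid/colloid infusion active
from 30 to 180 min; two additional 5 ml/kg hemorrhages over 50–55 and
70–75 min; ΔBV sampled every 5 min up to 80 min and every 10 min
thereafter.  The infusion controller of the physical experiments is not
reproduced; a simple discrete proportional law stands in for it (see
:class:`ProportionalController`).

Generating parameters are drawn per fluid type (LR crystalloid vs HEX
colloid) from normal priors whose means and spreads follow the fitted
cohort statistics of the emulated experiment, truncated to the model
invariants.  Measurement noise is iid Gaussian, matching the likelihood
the calibration stage assumes, so fitting synthetic subjects is a
well-specified parameter-recovery experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataio import BVMeasurementSeries, HctSeries, SubjectRecord
from .models import (FluidProtocol, ModelParameters, PARAM_NAMES,
                     ValidationError, delta_bv_at, simulate, state_matrices,
                     _zoh)

__all__ = [
    "ProtocolSpec",
    "ProportionalController",
    "CohortSpec",
    "PARAMETER_PRIORS",
    "standard_protocol",
    "sample_parameters",
    "simulate_subject",
    "hct_from_bv",
    "generate_cohort",
    "default_measurement_times",
]

#: Per-(variant, fluid) normal priors {parameter: (mean, sd)}.  Units: α and
#: A per ModelParameters; these are the cohort-level parameter statistics of
#: the two fluid groups.
PARAMETER_PRIORS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("original", "LR"): {"alpha_u": (1.72, 0.66), "alpha_v": (1.06, 0.78),
                         "Kp": (0.08, 0.04), "Ki": (0.003, 0.001)},
    ("original", "HEX"): {"alpha_u": (-0.18, 0.31), "alpha_v": (0.91, 0.46),
                          "Kp": (0.13, 0.08), "Ki": (0.007, 0.004)},
    ("refined", "LR"): {"alpha_u": (0.20, 0.69), "alpha_v": (0.60, 0.47),
                        "Kp": (0.28, 0.36), "Ki": (0.01, 0.01),
                        "A_u": (-0.16, 0.23), "A_v": (-0.007, 0.006)},
    ("refined", "HEX"): {"alpha_u": (-0.06, 0.27), "alpha_v": (0.64, 0.30),
                         "Kp": (0.19, 0.14), "Ki": (0.01, 0.003),
                         "A_u": (-0.004, 0.006), "A_v": (-0.006, 0.005)},
}


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing/volume template of the fluid-perturbation experiment."""

    duration: float = 180.0                       # min
    primary_hemorrhage_ml_per_kg: float = 25.0    # over primary_window
    primary_window: tuple[float, float] = (0.0, 15.0)
    infusion_window: tuple[float, float] = (30.0, 180.0)
    extra_hemorrhage_ml_per_kg: float = 5.0
    extra_windows: tuple[tuple[float, float], ...] = ((50.0, 55.0), (70.0, 75.0))
    dt: float = 1.0                               # grid step, min

    def __post_init__(self) -> None:
        windows = (self.primary_window,) + self.extra_windows
        for (a, b) in windows:
            if b <= a:
                raise ValidationError(f"degenerate event window {(a, b)}")
        for (a0, b0), (a1, b1) in zip(windows, windows[1:]):
            if a1 < b0:
                raise ValidationError("hemorrhage windows must not overlap")
        if self.primary_hemorrhage_ml_per_kg < 0 or self.extra_hemorrhage_ml_per_kg < 0:
            raise ValidationError("hemorrhage volumes must be >= 0")
        edges = [t for w in windows for t in w] + list(self.infusion_window) + [self.duration]
        for e in edges:
            if abs(e / self.dt - round(e / self.dt)) > 1e-9:
                raise ValidationError(f"dt={self.dt} does not divide event boundary {e}")


@dataclass(frozen=True)
class ProportionalController:
    """Discrete proportional resuscitation law.

    Every ``update_interval`` minutes inside the infusion window the rate is
    set to ``clip(−gain · ΔBV, 0, u_max)``: infuse in proportion to the
    current volume deficit, never withdraw.  This produces the decaying
    resuscitation profile the experiments describe while staying simple and
    seedable; it is not the controller used in the physical study.
    """

    gain: float = 0.1            # (ml/min) per ml of deficit
    u_max: float = 100.0         # ml/min
    update_interval: float = 5.0  # min


def default_measurement_times(spec: ProtocolSpec) -> np.ndarray:
    """Every 5 min through 80 min, then every 10 min to the end."""
    early = np.arange(0.0, min(80.0, spec.duration) + 1e-9, 5.0)
    late = np.arange(90.0, spec.duration + 1e-9, 10.0)
    return np.concatenate([early, late[late > early[-1]]])


def _hemorrhage_profile(weight: float, spec: ProtocolSpec, time: np.ndarray) -> np.ndarray:
    v = np.zeros_like(time)
    events = [(spec.primary_window, spec.primary_hemorrhage_ml_per_kg)] + \
             [(w, spec.extra_hemorrhage_ml_per_kg) for w in spec.extra_windows]
    for (a, b), ml_per_kg in events:
        rate = ml_per_kg * weight / (b - a)
        v[(time >= a - 1e-9) & (time < b - 1e-9)] = rate
    return v


def standard_protocol(weight: float, spec: ProtocolSpec = ProtocolSpec(),
                      controller: ProportionalController | None = None,
                      params: ModelParameters | None = None,
                      infusion_profile: np.ndarray | None = None) -> FluidProtocol:
    """Build one subject's fluid protocol.

    Hemorrhage rates are constant within each event window (volume/duration).
    The infusion is either a caller-supplied piecewise-constant table
    (``infusion_profile``, one value per grid point) or the closed-loop
    :class:`ProportionalController` response, which requires the subject's
    generating ``params`` to simulate the feedback loop.
    """
    if weight <= 0:
        raise ValidationError(f"weight must be > 0 (got {weight})")
    time = np.round(np.arange(0.0, spec.duration + spec.dt / 2, spec.dt), 9)
    hem = _hemorrhage_profile(weight, spec, time)

    if infusion_profile is not None:
        u = np.asarray(infusion_profile, dtype=float)
        if u.shape != time.shape:
            raise ValidationError("infusion_profile must have one value per grid point")
        return FluidProtocol(time, u, hem)

    if controller is None:
        controller = ProportionalController()
    if params is None:
        raise ValidationError(
            "closed-loop infusion requires the subject's model parameters")
    if abs(controller.update_interval / spec.dt
           - round(controller.update_interval / spec.dt)) > 1e-9:
        raise ValidationError("controller update interval must be a multiple of dt")

    # simulate the feedback loop block by block, holding u over each interval
    A, B = state_matrices(params)
    Ad, Bd = _zoh(A[:4, :4], B[:4, :], spec.dt)
    t_on, t_off = spec.infusion_window
    block = int(round(controller.update_interval / spec.dt))
    u = np.zeros_like(time)
    x = np.zeros(4)
    rate = 0.0
    for k in range(len(time) - 1):
        t = time[k]
        if t_on - 1e-9 <= t < t_off - 1e-9:
            if (k - int(round(t_on / spec.dt))) % block == 0:
                rate = float(np.clip(-controller.gain * x[0], 0.0, controller.u_max))
        else:
            rate = 0.0
        u[k] = rate
        x = Ad @ x + Bd @ np.array([u[k], hem[k]])
    return FluidProtocol(time, u, hem)


def sample_parameters(fluid_type: str, variant: str, rng: np.random.Generator,
                      priors: dict[str, tuple[float, float]] | None = None,
                      max_rejections: int = 10_000) -> ModelParameters:
    """Draw one parameter set from the per-fluid normal prior.

    Each parameter is drawn independently and rejection-truncated to the
    model invariants (1+α > 0, Kp > 0, Ki > 0, A ≤ 0).
    """
    if priors is None:
        priors = PARAMETER_PRIORS[(variant, fluid_type)]
    lo = {"alpha_u": -1.0, "alpha_v": -1.0, "Kp": 0.0, "Ki": 0.0,
          "A_u": -np.inf, "A_v": -np.inf}
    hi = {"alpha_u": np.inf, "alpha_v": np.inf, "Kp": np.inf, "Ki": np.inf,
          "A_u": 0.0, "A_v": 0.0}
    values = {}
    for name in PARAM_NAMES[variant]:
        mean, sd = priors[name]
        if not sd > 0:
            raise ValidationError(f"prior sd for {name} must be > 0")
        for trial in range(max_rejections):
            v = rng.normal(mean, sd)
            if lo[name] < v <= hi[name]:
                values[name] = v
                break
        else:
            raise ValidationError(
                f"prior for {name} (mean={mean}, sd={sd}) is infeasible: "
                f"{max_rejections} consecutive rejections")
    return ModelParameters(variant=variant, **values)


def hct_from_bv(delta_bv: np.ndarray, times: np.ndarray, baseline_bv: float,
                baseline_hct: float, withdrawn: np.ndarray) -> HctSeries:
    """Emit the hematocrit series a given ΔBV trajectory implies.

    Inverts the red-cell accounting of :func:`bvselect.dataio.bv_from_hct`
    in closed form: with total volume ``BV_k = BV(0) + ΔBV(t_k)`` and
    residual red-cell mass ``R_{k−1}`` before the withdrawal at ``t_k``,
    ``H(t_k) = R_{k−1} / (BV_k + V_H(t_k))``.
    """
    delta_bv = np.asarray(delta_bv, dtype=float)
    times = np.asarray(times, dtype=float)
    withdrawn = np.asarray(withdrawn, dtype=float)
    h = np.empty_like(delta_bv)
    r_prev = baseline_bv * baseline_hct
    for k in range(len(delta_bv)):
        bv_k = baseline_bv + delta_bv[k]
        h_k = r_prev / (bv_k + withdrawn[k])
        if not 0.0 < h_k < 1.0:
            raise ValidationError(
                f"implied hematocrit {h_k:.4f} at t = {times[k]:g} min is "
                f"outside (0, 1)")
        h[k] = h_k
        r_prev = r_prev - withdrawn[k] * h_k
    return HctSeries(times=times, hct=h, withdrawn=withdrawn,
                     baseline_bv=baseline_bv, baseline_hct=baseline_hct)


def simulate_subject(params: ModelParameters, protocol: FluidProtocol,
                     measurement_times: np.ndarray, noise_sd: float,
                     baseline_bv: float, rng: np.random.Generator,
                     subject_id: str = "S00", fluid_type: str = "LR",
                     weight: float = 40.0, baseline_hct: float | None = None,
                     emit_hct: bool = False) -> SubjectRecord:
    """Simulate one subject and attach noisy ΔBV measurements.

    With ``emit_hct`` the noisy ΔBV series is additionally expressed as a
    hematocrit series (withdrawals = the protocol's programmed hemorrhage
    accumulated since the previous measurement), stored as ``source_hct``.
    """
    measurement_times = np.asarray(measurement_times, dtype=float)
    if measurement_times[0] < protocol.time[0] - 1e-9 or \
            measurement_times[-1] > protocol.time[-1] + 1e-9:
        raise ValidationError("measurement schedule outside protocol horizon")
    truth = delta_bv_at(params, protocol, measurement_times)
    noisy = truth + rng.normal(0.0, noise_sd, size=len(truth)) if noise_sd > 0 \
        else truth.copy()
    source_hct = None
    if emit_hct:
        if baseline_hct is None:
            baseline_hct = 0.33
        lost = np.interp(measurement_times, protocol.time, protocol.cumulative_lost())
        withdrawn = np.diff(np.concatenate(([0.0], lost)))
        pos = measurement_times > 0
        source_hct = hct_from_bv(noisy[pos], measurement_times[pos], baseline_bv,
                                 baseline_hct, withdrawn[pos])
        measurements = BVMeasurementSeries(measurement_times[pos], noisy[pos])
    else:
        measurements = BVMeasurementSeries(measurement_times, noisy)
    return SubjectRecord(subject_id=subject_id, fluid_type=fluid_type,
                         weight=weight, baseline_bv=baseline_bv,
                         protocol=protocol, measurements=measurements,
                         source_hct=source_hct, true_params=params)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort."""

    n_lr: int = 11
    n_hex: int = 5
    variant: str = "refined"       # generating model
    noise_sd: float = 50.0         # ml
    weight_range: tuple[float, float] = (30.0, 45.0)   # kg, uniform
    baseline_bv_per_kg: float = 60.0                   # ml/kg
    baseline_hct: float = 0.33
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    controller: ProportionalController = field(default_factory=ProportionalController)
    priors: dict | None = None     # override PARAMETER_PRIORS entries
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lr < 1 or self.n_hex < 0:
            raise ValidationError("cohort needs n_lr >= 1 and n_hex >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], dict]:
    """Generate the cohort and a manifest of seeds and hidden ground truths.

    Per-subject RNG streams are spawned deterministically from the master
    seed, so the same spec always yields an identical cohort.
    """
    labels = ["LR"] * spec.n_lr + ["HEX"] * spec.n_hex
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(labels))
    subjects: list[SubjectRecord] = []
    manifest = {"seed": spec.seed, "variant": spec.variant, "subjects": []}
    for i, (fluid, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        weight = rng.uniform(*spec.weight_range)
        priors = None
        if spec.priors is not None:
            priors = spec.priors.get((spec.variant, fluid))
        params = sample_parameters(fluid, spec.variant, rng, priors=priors)
        protocol = standard_protocol(weight, spec.protocol,
                                     controller=spec.controller, params=params)
        sid = f"{fluid}{i + 1:02d}"
        record = simulate_subject(
            params, protocol, default_measurement_times(spec.protocol),
            spec.noise_sd, baseline_bv=spec.baseline_bv_per_kg * weight,
            rng=rng, subject_id=sid, fluid_type=fluid, weight=weight,
            baseline_hct=spec.baseline_hct)
        subjects.append(record)
        manifest["subjects"].append({
            "subject_id": sid, "fluid_type": fluid, "weight": weight,
            "baseline_bv": record.baseline_bv,
            "true_params": {n: getattr(params, n) for n in PARAM_NAMES[spec.variant]},
            "seed_entropy": child.entropy, "spawn_key": list(child.spawn_key),
        })
    return subjects, manifest
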