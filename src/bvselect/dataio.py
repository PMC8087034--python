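"""Subject data files, hematocrit conversion, and result (de)serialization.

File layout per subject (all plain text, minutes/ml units in column names):

* ``<id>_protocol.csv`` — ``time_min, infusion_ml_per_min, hemorrhage_ml_per_min``
* ``<id>_measurements.csv`` — either ``time_min, delta_bv_ml`` (direct BV
  change) or ``time_min, hct, withdrawn_ml`` (hematocrit series, converted
  on read via :func:`bv_from_hct`)
* ``<id>_meta.txt`` — flat ``key=value`` sidecar with ``id``, ``fluid_type``
  (LR or HEX), ``weight_kg``, ``baseline_bv_ml``, ``baseline_hct``

Results are written as JSON with provenance (seed, config hash, package
version) and round-trip losslessly through :func:`read_results`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (BVModelError, FluidProtocol, ModelParameters,
                     ValidationError)

__all__ = [
    "HctSeries",
    "BVMeasurementSeries",
    "SubjectRecord",
    "bv_from_hct",
    "read_subject",
    "write_subject",
    "write_results",
    "read_results",
    "register_serializable",
    "config_hash",
]

FLUID_TYPES = ("LR", "HEX")


@dataclass(frozen=True)
class HctSeries:
    """Hematocrit measurements with blood-withdrawal bookkeeping.

    ``withdrawn[i]`` is the blood volume (ml) withdrawn in the interval
    ending at ``times[i]`` (0 when none); the hematocrit reading at the same
    timestamp is used in the red-cell accounting.
    """

    times: np.ndarray       # minutes, strictly increasing
    hct: np.ndarray         # fraction in (0, 1)
    withdrawn: np.ndarray   # ml, >= 0
    baseline_bv: float      # BV(0), ml
    baseline_hct: float     # H(0), fraction

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.hct, dtype=float)
        w = np.asarray(self.withdrawn, dtype=float)
        if not (t.ndim == h.ndim == w.ndim == 1 and len(t) == len(h) == len(w) >= 1):
            raise ValidationError("times, hct, withdrawn must be 1-d arrays of equal length >= 1")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("hct times must be strictly increasing")
        if np.any(h <= 0) or np.any(h >= 1):
            raise ValidationError("hct values must lie strictly in (0, 1)")
        if np.any(w < 0):
            raise ValidationError("withdrawn volumes must be >= 0")
        if not self.baseline_bv > 0:
            raise ValidationError(f"baseline BV must be > 0 (got {self.baseline_bv})")
        if not 0 < self.baseline_hct < 1:
            raise ValidationError(f"baseline hct must be in (0, 1) (got {self.baseline_hct})")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "hct", h)
        object.__setattr__(self, "withdrawn", w)


@dataclass(frozen=True)
class BVMeasurementSeries:
    """Sparse ΔBV observations at strictly increasing times."""

    times: np.ndarray     # minutes
    delta_bv: np.ndarray  # ml

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.delta_bv, dtype=float)
        if not (t.ndim == y.ndim == 1 and len(t) == len(y) >= 1):
            raise ValidationError("times and delta_bv must be 1-d arrays of equal length >= 1")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("measurement times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "delta_bv", y)

    @property
    def K(self) -> int:
        return len(self.times)

    def subset(self, mask: np.ndarray) -> "BVMeasurementSeries":
        return BVMeasurementSeries(self.times[mask], self.delta_bv[mask])


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: protocol, measurements, metadata, optional provenance."""

    subject_id: str
    fluid_type: str
    weight: float          # kg
    baseline_bv: float     # ml
    protocol: FluidProtocol
    measurements: BVMeasurementSeries
    source_hct: HctSeries | None = None
    true_params: ModelParameters | None = None  # hidden ground truth (synthetic only)

    def __post_init__(self) -> None:
        if self.fluid_type not in FLUID_TYPES:
            raise ValidationError(
                f"fluid_type must be one of {list(FLUID_TYPES)}, got {self.fluid_type!r}")
        if not self.weight > 0:
            raise ValidationError(f"weight must be > 0 (got {self.weight})")
        if not self.baseline_bv > 0:
            raise ValidationError(f"baseline_bv must be > 0 (got {self.baseline_bv})")
        t0, t1 = self.protocol.time[0], self.protocol.time[-1]
        mt = self.measurements.times
        if mt[0] < t0 - 1e-9 or mt[-1] > t1 + 1e-9:
            raise ValidationError("measurement times must lie within the protocol horizon")


# ---------------------------------------------------------------------------
# hematocrit -> blood volume change
# ---------------------------------------------------------------------------

def bv_from_hct(hct: HctSeries) -> BVMeasurementSeries:
    """Convert a hematocrit series to ΔBV via red-cell mass accounting.

    The red-cell volume is depleted only by withdrawal,
    ``RBC(t_k) = BV(0)·H(0) − Σ_{i≤k} V_H(t_i)·H(t_i)``; plasma volume
    follows from the current hematocrit, ``PV = (1−H)·RBC/H``; and
    ``ΔBV = RBC + PV − BV(0)``.
    """
    rbc0 = hct.baseline_bv * hct.baseline_hct
    rbc = rbc0 - np.cumsum(hct.withdrawn * hct.hct)
    bad = np.nonzero(rbc <= 0)[0]
    if len(bad):
        raise ValidationError(
            f"red-cell volume depleted to {rbc[bad[0]]:.1f} ml at "
            f"t = {hct.times[bad[0]]:g} min (over-withdrawal)")
    pv = (1.0 - hct.hct) * rbc / hct.hct
    delta = rbc + pv - hct.baseline_bv
    return BVMeasurementSeries(times=hct.times.copy(), delta_bv=delta)


# ---------------------------------------------------------------------------
# subject file round trip
# ---------------------------------------------------------------------------

_META_KEYS = ("id", "fluid_type", "weight_kg", "baseline_bv_ml", "baseline_hct")


def _read_csv(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def read_subject(directory: str | Path, subject_id: str) -> SubjectRecord:
    """Load one subject from the CSV/sidecar layout described in the module docstring."""
    d = Path(directory)
    meta_path = d / f"{subject_id}_meta.txt"
    meta: dict[str, str] = {}
    for ln, line in enumerate(meta_path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"{meta_path}:{ln}: expected key=value, got {line!r}")
        k, v = line.split("=", 1)
        meta[k.strip()] = v.strip()
    missing = [k for k in _META_KEYS[:4] if k not in meta]
    if missing:
        raise ValidationError(f"{meta_path}: missing keys {missing}")

    prot_df = _read_csv(d / f"{subject_id}_protocol.csv",
                        ("time_min", "infusion_ml_per_min", "hemorrhage_ml_per_min"))
    neg = np.nonzero((prot_df["infusion_ml_per_min"] < 0)
                     | (prot_df["hemorrhage_ml_per_min"] < 0))[0]
    if len(neg):
        raise ValidationError(
            f"{subject_id}_protocol.csv: negative rate at data row {neg[0] + 1}")
    protocol = FluidProtocol(prot_df["time_min"].to_numpy(float),
                             prot_df["infusion_ml_per_min"].to_numpy(float),
                             prot_df["hemorrhage_ml_per_min"].to_numpy(float))

    meas_path = d / f"{subject_id}_measurements.csv"
    meas_df = pd.read_csv(meas_path)
    source_hct = None
    if "delta_bv_ml" in meas_df.columns:
        measurements = BVMeasurementSeries(meas_df["time_min"].to_numpy(float),
                                           meas_df["delta_bv_ml"].to_numpy(float))
    elif "hct" in meas_df.columns:
        if "baseline_hct" not in meta:
            raise ValidationError(f"{meta_path}: baseline_hct required for hct-format measurements")
        if "withdrawn_ml" not in meas_df.columns:
            raise ValidationError(f"{meas_path}: missing columns ['withdrawn_ml']")
        source_hct = HctSeries(meas_df["time_min"].to_numpy(float),
                               meas_df["hct"].to_numpy(float),
                               meas_df["withdrawn_ml"].to_numpy(float),
                               baseline_bv=float(meta["baseline_bv_ml"]),
                               baseline_hct=float(meta["baseline_hct"]))
        measurements = bv_from_hct(source_hct)
    else:
        raise ValidationError(
            f"{meas_path}: expected either delta_bv_ml or (hct, withdrawn_ml) columns")

    return SubjectRecord(subject_id=meta["id"], fluid_type=meta["fluid_type"],
                         weight=float(meta["weight_kg"]),
                         baseline_bv=float(meta["baseline_bv_ml"]),
                         protocol=protocol, measurements=measurements,
                         source_hct=source_hct)


def write_subject(record: SubjectRecord, directory: str | Path,
                  emit_hct: bool = False) -> None:
    """Write a subject in the layout :func:`read_subject` expects."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sid = record.subject_id
    pd.DataFrame({
        "time_min": record.protocol.time,
        "infusion_ml_per_min": record.protocol.infusion_rate,
        "hemorrhage_ml_per_min": record.protocol.hemorrhage_rate,
    }).to_csv(d / f"{sid}_protocol.csv", index=False)
    if emit_hct:
        if record.source_hct is None:
            raise ValidationError(f"subject {sid} has no hct series to emit")
        h = record.source_hct
        pd.DataFrame({"time_min": h.times, "hct": h.hct,
                      "withdrawn_ml": h.withdrawn}).to_csv(
            d / f"{sid}_measurements.csv", index=False)
        baseline_hct = h.baseline_hct
    else:
        pd.DataFrame({"time_min": record.measurements.times,
                      "delta_bv_ml": record.measurements.delta_bv}).to_csv(
            d / f"{sid}_measurements.csv", index=False)
        baseline_hct = (record.source_hct.baseline_hct
                        if record.source_hct is not None else "")
    lines = [f"id={sid}", f"fluid_type={record.fluid_type}",
             f"weight_kg={record.weight}", f"baseline_bv_ml={record.baseline_bv}"]
    if baseline_hct != "":
        lines.append(f"baseline_hct={baseline_hct}")
    (d / f"{sid}_meta.txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# result serialization (JSON with a dataclass registry)
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, type] = {}


def register_serializable(cls):
    """Class decorator making a dataclass JSON round-trippable by type name."""
    _REGISTRY[cls.__name__] = cls
    return cls


for _cls in (ModelParameters, FluidProtocol, BVMeasurementSeries, HctSeries,
             SubjectRecord):
    register_serializable(_cls)


def _encode(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        registered = type(obj).__name__ in _REGISTRY
        out = {"__type__": type(obj).__name__} if registered else {}
        for f in dataclasses.fields(obj):
            out[f.name] = _encode(getattr(obj, f.name))
        return out
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


def _decode(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"])
        if "__type__" in obj:
            cls = _REGISTRY[obj["__type__"]]
            kwargs = {k: _decode(v) for k, v in obj.items() if k != "__type__"}
            return cls(**kwargs)
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def config_hash(config) -> str:
    """Stable short hash of any JSON-encodable configuration object."""
    payload = json.dumps(_encode(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_results(results, path: str | Path, seed: int | None = None,
                  config=None) -> None:
    """Write result objects (a list or a single object) with provenance."""
    from . import __version__
    payload = {
        "provenance": {
            "package": "bvselect",
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash(config) if config is not None else None,
        },
        "records": _encode(list(results) if isinstance(results, (list, tuple))
                           else [results]),
    }
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(payload, indent=1))


def read_results(path: str | Path):
    """Read back a results file; returns (records, provenance)."""
    payload = json.loads(Path(path).read_text())
    return _decode(payload["records"]), payload["provenance"]
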