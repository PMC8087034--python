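"""End-to-end study orchestration: generate → fit → assess → sensitivity → predict.

One seeded configuration drives the whole model-selection pathway on a
synthetic cohort: both candidate models are calibrated to every subject
(with per-subject penalty selection), calibration quality is compared by
RMSE / AIC / the multi-dimensional measure, practical identifiability is
screened by first-order Sobol indices, and the three predictive-capability
scenarios are scored by interval score and envelope coverage.  Every
random draw descends deterministically from the master seed, so a re-run
with the same configuration reproduces every number bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import assess
from .calibrate import CalibrationResult, FitOptions, fit_mle, select_penalty
from .cohort import CohortSpec, generate_cohort
from .dataio import config_hash, write_results, write_subject
from .models import PARAM_NAMES, ValidationError
from .predict import (PredictionEnvelope, scenario_loo, scenario_steady_state,
                      scenario_transient, within_mask)
from .sensitivity import DEFAULT_REPORT_TIMES, sobol_first_order

__all__ = ["StudyConfig", "run_study"]

log = logging.getLogger("bvselect")

VARIANT_ORDER = ("original", "refined")


@dataclass(frozen=True)
class StudyConfig:
    """Flat configuration of a full study run (master seed mandatory)."""

    seed: int
    cohort: CohortSpec = field(default_factory=CohortSpec)
    variants: tuple[str, ...] = VARIANT_ORDER
    gamma: str | float = "auto"
    n_boot: int = 100
    n_draws: int = 1000
    alpha: float = 0.05
    n_sobol: int = 1000
    report_times: tuple[float, ...] = DEFAULT_REPORT_TIMES
    n_starts: int = 10
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValidationError("config must set a master seed")
        raw = dict(raw)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            cohort_raw = dict(raw["cohort"])
            cohort_known = {f.name for f in CohortSpec.__dataclass_fields__.values()}
            bad = set(cohort_raw) - cohort_known
            if bad:
                raise ValidationError(f"unknown cohort keys: {sorted(bad)}")
            raw["cohort"] = CohortSpec(**cohort_raw)
        if "variants" in raw:
            raw["variants"] = tuple(raw["variants"])
        return cls(**raw)


def _stage_seed(master: int, *tags) -> int:
    """Deterministic child seed below 2^31 from the master seed and a path."""
    key = tuple(zlib.crc32(str(t).encode()) for t in tags)
    return int(np.random.SeedSequence((master,) + key).generate_state(1)[0] % (2 ** 31))


def _fit_all(subjects, variants, cfg: StudyConfig) -> dict:
    """Per-(variant, subject) penalty selection and full-data fit."""
    fits: dict[str, list[CalibrationResult]] = {v: [] for v in variants}
    gammas: dict[str, list[float]] = {v: [] for v in variants}
    opts = FitOptions(n_starts=cfg.n_starts)
    sel_opts = FitOptions(n_starts=min(3, cfg.n_starts))
    for v in variants:
        for i, s in enumerate(subjects):
            t0 = time.perf_counter()
            seed = _stage_seed(cfg.seed, "fit", v, s.subject_id)
            if cfg.gamma == "auto":
                g, _ = select_penalty(s, v, options=sel_opts, seed=seed)
            else:
                g = float(cfg.gamma)
            fit = fit_mle(s, v, gamma=g, options=opts, seed=seed)
            fits[v].append(fit)
            gammas[v].append(g)
            log.info("fit %s %s gamma=%g rmse=%.1f aic=%.1f (%.2fs, seed=%d)",
                     v, s.subject_id, g, fit.rmse, fit.aic,
                     time.perf_counter() - t0, seed)
    return {"fits": fits, "gammas": gammas}


def _assess_all(subjects, fits: dict, variants) -> dict:
    """Calibration-quality table and model/fluid comparisons."""
    per_variant = {}
    features = {v: [] for v in variants}
    for v in variants:
        for s, fit in zip(subjects, fits[v]):
            pred = s.measurements.delta_bv - fit.residuals
            features[v].append(assess.error_features(
                s.measurements.delta_bv, pred, s.measurements.times))
    # joint normalization pool: all subjects x all fitted variants
    pool = [fv for v in variants for fv in features[v]]
    normalized = assess.normalize_features(pool)
    n_subj = len(subjects)
    for j, v in enumerate(variants):
        chunk = normalized[j * n_subj:(j + 1) * n_subj]
        ud = np.array([assess.euclidean_distance(fv) for fv in chunk])
        per_variant[v] = {
            "rmse": np.array([f.rmse for f in fits[v]]),
            "aic": np.array([f.aic for f in fits[v]]),
            "features": np.stack([fv.normalized for fv in chunk]),
            "ud": ud,
        }
    out = {"per_variant": per_variant}
    if set(("original", "refined")) <= set(variants):
        a, b = per_variant["original"], per_variant["refined"]
        min_aic_refined = (b["aic"] < a["aic"]).sum()
        out["min_aic_frequency"] = {"original": int(n_subj - min_aic_refined),
                                    "refined": int(min_aic_refined)}
        out["tests"] = {
            "rmse": assess.compare_models(a["rmse"], b["rmse"], "rmse"),
            "aic": assess.compare_models(a["aic"], b["aic"], "aic"),
            "ud": assess.compare_models(a["ud"], b["ud"], "ud"),
            **{f"feature_{name}": assess.compare_models(
                a["features"][:, k], b["features"][:, k], name)
               for k, name in enumerate(assess.FEATURE_NAMES)},
        }
    return out


def _fluid_comparisons(subjects, fits: dict, variants) -> dict:
    """Welch tests of each fitted parameter between the LR and HEX groups."""
    out = {}
    lr = np.array([s.fluid_type == "LR" for s in subjects])
    if lr.sum() < 2 or (~lr).sum() < 2:
        return out
    for v in variants:
        vals = np.array([f.params.free_values() for f in fits[v]])
        out[v] = {name: assess.compare_fluids(vals[lr, j], vals[~lr, j], name)
                  for j, name in enumerate(PARAM_NAMES[v])}
    return out


def _sensitivity_all(subjects, fits: dict, variants, cfg: StudyConfig) -> dict:
    """Cohort-averaged first-order indices per variant.

    Ranges span the fitted values across the cohort; indices are computed
    per subject protocol and averaged, and classification is applied to the
    cohort-mean index matrix.
    """
    out = {}
    for v in variants:
        vals = np.array([f.params.free_values() for f in fits[v]])
        ranges = {}
        for j, name in enumerate(PARAM_NAMES[v]):
            lo, hi = float(vals[:, j].min()), float(vals[:, j].max())
            if hi - lo < 1e-9:  # degenerate cohort range
                pad = max(abs(lo) * 0.05, 1e-6)
                lo, hi = lo - pad, min(hi + pad, 0.0) if name.startswith("A_") \
                    else hi + pad
            ranges[name] = (lo, hi)
        reports = []
        for s in subjects:
            seed = _stage_seed(cfg.seed, "sobol", v, s.subject_id)
            reports.append(sobol_first_order(
                v, ranges, s.protocol, report_times=cfg.report_times,
                n_base=cfg.n_sobol, seed=seed))
        g_mean = np.mean([r.G for r in reports], axis=0)
        out[v] = {"ranges": ranges, "per_subject": reports, "G_mean": g_mean,
                  "param_names": PARAM_NAMES[v],
                  "report_times": list(cfg.report_times)}
        log.info("sensitivity %s: mean G computed over %d subjects", v,
                 len(subjects))
    return out


def _predict_all(subjects, fits: dict, gammas: dict, variants,
                 cfg: StudyConfig) -> dict:
    """All three scenarios for every subject and variant."""
    envelopes: dict[str, dict[str, list[PredictionEnvelope]]] = {
        sc: {v: [] for v in variants}
        for sc in ("steady_state", "transient", "loo")}
    for v in variants:
        for i, s in enumerate(subjects):
            t0 = time.perf_counter()
            g = gammas[v][i]
            # the scenario anchor fit starts from the full-data optimum
            opts = FitOptions(n_starts=min(3, cfg.n_starts),
                              x0=fits[v][i].params.free_values())
            env_a = scenario_steady_state(
                s, v, n_boot=cfg.n_boot, gamma=g, alpha=cfg.alpha,
                seed=_stage_seed(cfg.seed, "steady", v, s.subject_id),
                fit_options=opts)
            env_b = scenario_transient(
                s, v, n_boot=cfg.n_boot, gamma=g, alpha=cfg.alpha,
                seed=_stage_seed(cfg.seed, "transient", v, s.subject_id),
                fit_options=opts)
            donors = [f for j, f in enumerate(fits[v]) if j != i]
            donor_fluids = [x.fluid_type for j, x in enumerate(subjects) if j != i]
            env_c = scenario_loo(
                s, donors, donor_fluids, v, n_draws=cfg.n_draws,
                alpha=cfg.alpha,
                seed=_stage_seed(cfg.seed, "loo", v, s.subject_id))
            envelopes["steady_state"][v].append(env_a)
            envelopes["transient"][v].append(env_b)
            envelopes["loo"][v].append(env_c)
            log.info("predict %s %s PM(ss)=%.2f PM(tr)=%.2f PM(loo)=%.2f (%.1fs)",
                     v, s.subject_id, env_a.pm, env_b.pm, env_c.pm,
                     time.perf_counter() - t0)
    summary = {}
    for sc, per_v in envelopes.items():
        summary[sc] = {}
        pooled = {}
        for v in variants:
            scores = np.concatenate([e.scores for e in per_v[v]])
            inside = np.concatenate([
                within_mask(e.lower, e.upper, e.measured) for e in per_v[v]])
            pooled[v] = (scores, inside)
            summary[sc][v] = {"mean_score": float(scores.mean()),
                              "pm": float(inside.mean()),
                              "n_points": int(len(scores))}
        if set(("original", "refined")) <= set(variants):
            s_o, in_o = pooled["original"]
            s_r, in_r = pooled["refined"]
            summary[sc]["tests"] = {
                "score": assess.compare_models(s_o, s_r, f"{sc}_score"),
                "pm": assess.compare_proportions(
                    int(in_o.sum()), len(in_o), int(in_r.sum()), len(in_r),
                    f"{sc}_pm"),
            }
    return {"envelopes": envelopes, "summary": summary}


def _write_outputs(out_dir: str, cfg, subjects, manifest, fitted, assessment,
                   fluid_tests, sens, pred) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_dir = out / "cohort"
    for s in subjects:
        write_subject(s, cohort_dir)
    (cohort_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for v, fit_list in fitted["fits"].items():
        write_results(fit_list, out / f"fits_{v}.json", seed=cfg.seed, config=cfg)
    rows = []
    for v, d in assessment["per_variant"].items():
        for i, s in enumerate(subjects):
            rows.append({"variant": v, "subject_id": s.subject_id,
                         "rmse_ml": d["rmse"][i], "aic": d["aic"][i],
                         **{f"f_{n}": d["features"][i, k]
                            for k, n in enumerate(assess.FEATURE_NAMES)},
                         "ud": d["ud"][i]})
    pd.DataFrame(rows).to_csv(out / "calibration_table.csv", index=False)
    for sc, per_v in pred["envelopes"].items():
        for v, envs in per_v.items():
            frames = []
            for s, e in zip(subjects, envs):
                frames.append(pd.DataFrame({
                    "subject_id": s.subject_id, "time_min": e.times,
                    "lower_ml": e.lower, "upper_ml": e.upper,
                    "measured_ml": e.measured, "score": e.scores,
                    "within": within_mask(e.lower, e.upper, e.measured),
                }))
            pd.concat(frames).to_csv(out / f"envelopes_{sc}_{v}.csv", index=False)
    summary = build_summary(cfg, fitted, assessment, fluid_tests, sens, pred)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))


def _tests_to_plain(tests: dict) -> dict:
    return {k: {"test": t.test, "statistic": t.statistic, "p_value": t.p_value,
                "n": t.n, "group_means": t.group_means}
            for k, t in tests.items()}


def build_summary(cfg, fitted, assessment, fluid_tests, sens, pred) -> dict:
    """Plain-JSON study summary (the shape of the printed study tables)."""
    pred_plain = {}
    for sc, d in pred["summary"].items():
        pred_plain[sc] = {k: dict(v) for k, v in d.items() if k != "tests"}
        if "tests" in d:
            pred_plain[sc]["tests"] = _tests_to_plain(d["tests"])
    out = {"config_hash": config_hash(cfg), "seed": cfg.seed,
           "calibration": {}, "prediction": pred_plain,
           "sensitivity": {}}
    for v, d in assessment["per_variant"].items():
        out["calibration"][v] = {
            "rmse_mean": float(d["rmse"].mean()),
            "rmse_sd": float(d["rmse"].std(ddof=1)),
            "aic_mean": float(d["aic"].mean()),
            "features_mean": d["features"].mean(axis=0).tolist(),
            "ud_mean": float(d["ud"].mean()),
        }
    if "min_aic_frequency" in assessment:
        out["calibration"]["min_aic_frequency"] = assessment["min_aic_frequency"]
    if "tests" in assessment:
        out["calibration"]["tests"] = _tests_to_plain(assessment["tests"])
    for v, d in sens.items():
        out["sensitivity"][v] = {
            "param_names": list(d["param_names"]),
            "report_times": d["report_times"],
            "G_mean": np.asarray(d["G_mean"]).tolist(),
        }
    for v, tests in fluid_tests.items():
        out.setdefault("fluid_comparisons", {})[v] = _tests_to_plain(tests)
    return out


def run_study(config: StudyConfig) -> dict:
    """Run the full model-selection pathway; returns the assembled results.

    The returned dict holds the raw per-stage objects under ``subjects``,
    ``fits``, ``assessment``, ``sensitivity``, ``prediction`` and a
    plain-JSON ``summary``.  With ``config.out_dir`` set, all artifacts are
    also written to disk.
    """
    t0 = time.perf_counter()
    cohort_spec = dc_replace(config.cohort, seed=_stage_seed(config.seed, "cohort"))
    subjects, manifest = generate_cohort(cohort_spec)
    log.info("cohort: %d subjects (%d LR, %d HEX), generator=%s",
             len(subjects), cohort_spec.n_lr, cohort_spec.n_hex,
             cohort_spec.variant)
    fitted = _fit_all(subjects, config.variants, config)
    assessment = _assess_all(subjects, fitted["fits"], config.variants)
    fluid_tests = _fluid_comparisons(subjects, fitted["fits"], config.variants)
    sens = _sensitivity_all(subjects, fitted["fits"], config.variants, config)
    pred = _predict_all(subjects, fitted["fits"], fitted["gammas"],
                        config.variants, config)
    summary = build_summary(config, fitted, assessment, fluid_tests, sens, pred)
    if config.out_dir:
        _write_outputs(config.out_dir, config, subjects, manifest, fitted,
                       assessment, fluid_tests, sens, pred)
    log.info("study complete in %.1fs", time.perf_counter() - t0)
    return {"subjects": subjects, "manifest": manifest, "fits": fitted["fits"],
            "gammas": fitted["gammas"], "assessment": assessment,
            "fluid_comparisons": fluid_tests, "sensitivity": sens,
            "prediction": pred, "summary": summary}
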