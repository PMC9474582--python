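"""End-to-end orchestration: generate -> exposures -> fit -> reduce -> evaluate.

``run_all`` executes the full analysis from one configuration mapping with
named seeds per stochastic stage, writing every artifact as CSV or JSON plus
a manifest with the configuration hash, seeds and per-file checksums.  A
rerun with an identical configuration reproduces every output byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    generate_cohort,
    regimens_for_cohort,
    simulate_outcomes,
)
from .config import (
    config_hash,
    covariate_specs_from_config,
    load_config,
    poppk_model_from_config,
    true_models_from_config,
    validate_config,
)
from .dose_eval import (
    BleedingEvent,
    _reference_patients,
    management_action,
    regimen_probability_table,
    target_attainment_table,
)
from .errors import ConfigError
from .exposure_safety import (
    ModelSpec,
    Term,
    backward_eliminate,
    fit_logistic,
    fit_model,
    likelihood_ratio_test,
    odds_ratio,
    predict_probability,
    quartile_incidence,
)
from .poppk import simulate_population
from .regimens import parse_regimen

__all__ = ["run_all"]

logger = logging.getLogger("bleedrisk.pipeline")

_CSV_FLOAT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FLOAT)


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_report(fit, or_unit: float, exposure: str = "cavg_sd") -> dict[str, Any]:
    report: dict[str, Any] = {"n": fit.n, "n_events": fit.n_events,
                              "log_likelihood": fit.log_likelihood, "terms": {}}
    for term in fit.terms:
        entry = {"coefficient": float(fit.coefficients[term]), "se": fit.se(term),
                 "p_wald": fit.wald_p(term)}
        if term != "const":
            scale = or_unit if term == exposure else 1.0
            summary = odds_ratio(fit, term, unit_scale=scale)
            entry.update(odds_ratio=summary.odds_ratio, ci_low=summary.ci_low,
                         ci_high=summary.ci_high, unit_scale=scale)
        report["terms"][term] = entry
    return report


def run_all(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> dict[str, Any]:
    """Run every stage of the analysis and write the artifact bundle.

    Returns the manifest (also written to ``manifest.json``).  Any stage
    failure raises with the stage name; artifacts written before the failure
    are listed in ``partial_manifest.json``.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    violations = validate_config(config)
    if violations:
        raise ConfigError("invalid configuration:\n" + "\n".join(f"- {v}" for v in violations))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    seeds = config["seeds"]
    stage = "setup"

    def emit(name: str) -> Path:
        artifacts.append(name)
        return out / name

    try:
        # ------------------------------------------------------------------
        stage = "cohort"
        t0 = time.time()
        specs = covariate_specs_from_config(config)
        cohort = generate_cohort(specs, config["population"]["allocation"],
                                 seed=seeds["cohort"])
        _write_csv(cohort, emit("cohort.csv"))
        logger.info("stage %s done in %.1fs (n=%d)", stage, time.time() - t0, len(cohort))

        # ------------------------------------------------------------------
        stage = "exposures"
        t0 = time.time()
        pk_model = poppk_model_from_config(config)
        regimens = regimens_for_cohort(cohort, infusion_duration=pk_model.infusion_duration)
        metrics = simulate_population(pk_model, cohort, regimens, seed=seeds["poppk"])
        cohort = pd.concat([cohort, metrics], axis=1)
        _write_csv(cohort[["patient_id", "cavg_sd", "ctrough_sd", "ctrough_ss"]],
                   emit("exposures.csv"))
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

        # ------------------------------------------------------------------
        stage = "outcomes"
        true_models = true_models_from_config(config)
        cohort = simulate_outcomes(cohort, true_models, seed=seeds["outcomes"])
        _write_csv(cohort, emit("cohort_with_outcomes.csv"))

        # ------------------------------------------------------------------
        stage = "exposure-safety"
        t0 = time.time()
        analysis = config.get("analysis", {})
        alpha = float(analysis.get("alpha", 0.05))
        or_unit = float(analysis.get("or_unit", 100.0))
        terms = tuple(
            Term(e["name"], e.get("kind", "continuous"), e.get("reference"),
                 e.get("standardize", False))
            for e in analysis.get("covariates", [])
        )
        fits: dict[str, dict[str, Any]] = {}
        univariable_fits = {}
        for endpoint in analysis.get("endpoints", []):
            uni_spec = ModelSpec(endpoint)
            uni_fit, _ = fit_model(cohort, uni_spec)
            null_design = pd.DataFrame({"const": np.ones(len(cohort))}, index=cohort.index)
            null_fit = fit_logistic(null_design, cohort[endpoint].to_numpy())
            p_exposure, _, _ = likelihood_ratio_test(uni_fit, null_fit)
            report = {"univariable": _fit_report(uni_fit, or_unit),
                      "exposure_lrt_p": p_exposure}
            univariable_fits[endpoint] = uni_fit
            if p_exposure < alpha:  # covariate modeling only on a significant base
                full_spec = ModelSpec(endpoint, covariates=terms)
                full_fit, _ = fit_model(cohort, full_spec)
                reduced = backward_eliminate(full_spec, cohort, alpha=alpha)
                report["full"] = _fit_report(full_fit, or_unit)
                report["reduced"] = _fit_report(reduced.fit, or_unit)
                report["elimination_trace"] = [
                    {"round": s.round, "term": s.term, "p": s.p_value, "removed": s.removed}
                    for s in reduced.trace
                ]
            fits[endpoint] = report
            quart = quartile_incidence(cohort["cavg_sd"], cohort[endpoint])
            _write_csv(quart, emit(f"quartiles_{endpoint}.csv"))
        _write_json(fits, emit("fit_reports.json"))
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

        # ------------------------------------------------------------------
        stage = "dose-evaluation"
        t0 = time.time()
        evaluation = config.get("evaluation", {})
        eval_regimens = {label: parse_regimen(label)
                         for label in evaluation.get("regimens", [])}
        gi_fit = univariable_fits.get("bleed_gi")
        prob_table = regimen_probability_table(
            gi_fit, eval_regimens, pk_model,
            n_sim=int(evaluation.get("n_sim", 0)), seed=seeds["fitting"],
        )
        _write_csv(prob_table, emit("probability_table.csv"))

        grid = np.linspace(0.0, 400.0, 81)
        _write_csv(predict_probability(gi_fit, grid), emit("prediction_curve.csv"))

        n_sim = max(int(evaluation.get("n_sim", 0)), 100)
        frames = []
        for label, regimen in eval_regimens.items():
            sim = simulate_population(
                pk_model, _reference_patients(n_sim, pk_model), regimen,
                seed=seeds["fitting"],
            )
            sim.insert(0, "regimen", label)
            frames.append(sim)
        attainment = target_attainment_table(
            pd.concat(frames, ignore_index=True),
            thresholds=[float(t) for t in evaluation.get("thresholds", [11.0, 50.0])],
        )
        _write_csv(attainment, emit("attainment_table.csv"))
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

        # ------------------------------------------------------------------
        stage = "decision-audit"
        audit = []
        for grade in (1, 2, 3, 4):
            for tumoral in (False, True):
                for resolved in (False, True):
                    event = BleedingEvent(grade, tumoral=tumoral,
                                          resolved_to_grade_le1_by_cycle_end=resolved)
                    action = management_action(event)
                    audit.append({
                        "grade": grade, "tumoral": tumoral, "resolved": resolved,
                        "action": action.action, "rule": action.rationale,
                    })
        _write_json(audit, emit("decision_audit.json"))

        # ------------------------------------------------------------------
        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config_hash": config_hash(config),
            "seeds": dict(seeds),
            "n_patients": int(len(cohort)),
            "artifacts": {name: _sha256(out / name) for name in sorted(artifacts)},
        }
        _write_json(manifest, out / "manifest.json")
        return manifest
    except Exception:
        partial = {"failed_stage": stage, "artifacts": sorted(artifacts)}
        try:
            _write_json(partial, out / "partial_manifest.json")
        except OSError:
            pass
        logger.error("pipeline aborted in stage %r", stage)
        raise
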