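"""Regimen-level decision outputs.

Translates the fitted (or table-anchored) exposure-safety model and the
population PK model into the quantities that drive dose-modification
decisions: predicted bleeding probability per regimen, trough-concentration
target attainment against the pharmacologic thresholds (>= 11 ug/mL for PD-L1
occupancy plus TGF-beta1/-beta3 neutralization, >= 50 ug/mL for TGF-beta2
neutralization), the effect of a dose reduction on the predicted probability,
and a configurable decision table mapping an observed bleeding event (grade,
tumoral origin, resolution, rapid hemoglobin drop, investigator risk
assessment) to a management action.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .exposure_safety import LogisticFit, UnivariableModel, predict_probability
from .poppk import PopPKModel, compute_cavg_sd, simulate_population
from .regimens import DoseRegimen

__all__ = [
    "PDL1_THRESHOLD",
    "TGFB2_THRESHOLD",
    "BleedingEvent",
    "ManagementAction",
    "PolicyRule",
    "ACTIONS",
    "default_policy",
    "reference_patients",
    "regimen_probability_table",
    "target_attainment_table",
    "fraction_above_at_time",
    "dose_reduction_effect",
    "management_action",
]

PDL1_THRESHOLD = 11.0   # ug/mL: PD-L1 occupancy + TGF-beta1/-beta3 neutralization
TGFB2_THRESHOLD = 50.0  # ug/mL: TGF-beta2 neutralization

ACTIONS = (
    "continue_rp2d",
    "interrupt_then_restart_rp2d",
    "interrupt_then_restart_50pct",
    "consult_monitor",
    "permanent_discontinuation",
)


# ---------------------------------------------------------------------------
# probability and attainment tables
# ---------------------------------------------------------------------------

def _reference_patients(n: int, pk: PopPKModel) -> pd.DataFrame:
    """n typical patients: every model covariate at its reference value
    (power effects) or unset (proportional effects), so only random effects vary."""
    columns: dict[str, float] = {}
    for eff in pk.covariate_effects:
        columns.setdefault(eff.covariate, eff.reference if eff.form == "power" else 0.0)
    return pd.DataFrame(columns, index=pd.RangeIndex(n)) if columns else pd.DataFrame(
        index=pd.RangeIndex(n))


#: public alias: a covariate table of n typical (reference) patients
reference_patients = _reference_patients


def regimen_probability_table(
    model: UnivariableModel | LogisticFit,
    regimens: Mapping[str, DoseRegimen],
    pk: PopPKModel,
    n_sim: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted event probability per regimen at its geometric-mean Cavg,SD.

    With ``n_sim == 0`` the typical-value exposure is used (the geometric mean
    of a median-preserving lognormal population); otherwise ``n_sim`` patients
    per regimen are simulated with between-subject variability and the
    geometric mean exp(mean(log Cavg)) is used.  95% CIs come from the fit's
    coefficient covariance via the delta method and are omitted (NaN) for a
    bare calibrated (intercept, slope) model.
    """
    rows = []
    for label, regimen in regimens.items():
        if n_sim > 0:
            metrics = simulate_population(
                pk, _reference_patients(n_sim, pk), regimen, seed=seed,
                metrics=("cavg_sd",),
            )
            gm = float(np.exp(np.mean(np.log(metrics["cavg_sd"]))))
        else:
            gm = compute_cavg_sd(pk.typical, regimen, rtol=1e-8)
        pred = predict_probability(model, [gm]).iloc[0]
        rows.append({
            "regimen": label,
            "geomean_cavg_sd": gm,
            "probability": float(pred["probability"]),
            "ci_low": float(pred["ci_low"]),
            "ci_high": float(pred["ci_high"]),
        })
    return pd.DataFrame(rows)


def target_attainment_table(
    exposures: pd.DataFrame,
    thresholds: Sequence[float] = (PDL1_THRESHOLD, TGFB2_THRESHOLD),
    states: Sequence[str] = ("sd", "ss"),
    min_patients: int = 100,
) -> pd.DataFrame:
    """Percentage of simulated patients meeting trough targets per regimen.

    ``exposures`` needs a ``regimen`` column plus ``ctrough_sd`` /
    ``ctrough_ss`` columns for the requested states.  Cells are percentages in
    [0, 100].
    """
    if "regimen" not in exposures.columns:
        raise InvalidParameterError("exposures must carry a 'regimen' column")
    rows = []
    for label, group in exposures.groupby("regimen", sort=False):
        if len(group) == 0:
            raise InvalidParameterError(f"empty regimen group {label!r}")
        if len(group) < min_patients:
            raise InvalidParameterError(
                f"regimen {label!r} has {len(group)} simulated patients; "
                f"need >= {min_patients}"
            )
        row = {"regimen": label, "n": len(group)}
        for state in states:
            col = f"ctrough_{state}"
            values = group[col].to_numpy(dtype=float)
            for thr in thresholds:
                row[f"pct_{state}_ge_{thr:g}"] = 100.0 * float(np.mean(values >= thr))
        rows.append(row)
    return pd.DataFrame(rows)


def fraction_above_at_time(
    profiles: np.ndarray,
    times: Sequence[float],
    threshold: float,
    t: float,
) -> float:
    """Fraction of patients with C(t) >= threshold at within-cycle time ``t``.

    ``profiles`` is an (n_patients, n_times) concentration matrix on the
    common grid ``times``; concentrations at ``t`` are linearly interpolated.
    """
    times = np.asarray(times, dtype=float)
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] != times.size:
        raise InvalidParameterError("profiles must be (n_patients, n_times)")
    if not (times.min() <= t <= times.max()):
        raise InvalidParameterError(
            f"t = {t} outside the profile window [{times.min()}, {times.max()}]"
        )
    at_t = np.array([np.interp(t, times, row) for row in profiles])
    return float(np.mean(at_t >= threshold))


def dose_reduction_effect(
    model: UnivariableModel | LogisticFit,
    from_regimen: DoseRegimen,
    to_regimen: DoseRegimen,
    pk: PopPKModel,
    n_sim: int = 0,
    seed: int = 0,
) -> dict[str, float]:
    """Absolute and relative reduction in predicted probability for a dose change."""
    table = regimen_probability_table(
        model, {"from": from_regimen, "to": to_regimen}, pk, n_sim=n_sim, seed=seed
    ).set_index("regimen")
    p_from = float(table.loc["from", "probability"])
    p_to = float(table.loc["to", "probability"])
    delta = p_from - p_to
    return {
        "p_from": p_from,
        "p_to": p_to,
        "absolute_reduction": delta,
        "relative_reduction": delta / p_from if p_from > 0 else float("nan"),
    }


# ---------------------------------------------------------------------------
# bleeding-management decision table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BleedingEvent:
    """An observed bleeding adverse event and its clinical context.

    ``rapid_hemoglobin_drop`` flags a decrease > 3 g/dL in 3 weeks or
    > 2 g/dL in 2 weeks; ``resolved_to_grade_le1_by_cycle_end`` applies the
    general grade 2 adverse-drug-reaction rule.
    """

    grade: int
    tumoral: bool = False
    resolved_to_grade_le1_by_cycle_end: bool = False
    rapid_hemoglobin_drop: bool = False
    investigator_high_risk: bool = False
    alternative_explanation: bool = False

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 4):
            raise InvalidParameterError(f"grade must be 1-4, got {self.grade}")


@dataclass(frozen=True)
class ManagementAction:
    action: str
    rationale: str

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise InvalidParameterError(f"unknown action {self.action!r}")


@dataclass(frozen=True)
class PolicyRule:
    """First-match decision rule: ``conditions`` maps BleedingEvent field
    names to required values; an empty mapping matches everything."""

    conditions: Mapping[str, object]
    action: str
    rationale: str
    extrapolated: bool = False

    def matches(self, event: BleedingEvent) -> bool:
        return all(getattr(event, name) == value for name, value in self.conditions.items())


def default_policy() -> tuple[PolicyRule, ...]:
    """Default management rules for bleeding events.

    Core rules: grade >= 3 events interrupt treatment with restart at 50% of
    the initial dose after resolution; a grade 2 event resolving to grade <= 1
    by cycle end continues at the RP2D; an unresolved but manageable grade 2
    event goes to the medical monitor.  Branches that combine tumoral origin
    or high investigator-assessed risk with severe events escalate to
    permanent discontinuation.  Rules whose rationale is marked
    "[extrapolated]" fill combinations the core guidance does not pin down and
    are deliberately conservative; they are configurable.
    """
    return (
        PolicyRule({"grade": 4}, "permanent_discontinuation",
                   "grade 4 bleeding: permanent discontinuation [extrapolated]", True),
        PolicyRule({"grade": 3, "tumoral": True}, "permanent_discontinuation",
                   "grade 3 tumoral bleeding: high recurrence risk, permanent discontinuation"),
        PolicyRule({"grade": 3, "investigator_high_risk": True}, "permanent_discontinuation",
                   "grade 3 with investigator-assessed high risk of additional bleeding: "
                   "permanent discontinuation"),
        PolicyRule({"grade": 3}, "interrupt_then_restart_50pct",
                   "grade 3 bleeding: interrupt; restart at 50% of the initial dose "
                   "after resolution"),
        PolicyRule({"rapid_hemoglobin_drop": True, "tumoral": True},
                   "interrupt_then_restart_50pct",
                   "rapid hemoglobin drop with tumoral bleeding: interrupt, thorough "
                   "assessment, restart at 50% dose [extrapolated]", True),
        PolicyRule({"rapid_hemoglobin_drop": True, "alternative_explanation": True},
                   "interrupt_then_restart_rp2d",
                   "rapid hemoglobin drop with an alternative explanation (antithrombotics, "
                   "trauma): interrupt, restart at RP2D once stable [extrapolated]", True),
        PolicyRule({"rapid_hemoglobin_drop": True}, "interrupt_then_restart_50pct",
                   "rapid hemoglobin drop without alternative explanation: treat as severe; "
                   "interrupt and restart at 50% dose [extrapolated]", True),
        PolicyRule({"grade": 2, "resolved_to_grade_le1_by_cycle_end": True}, "continue_rp2d",
                   "grade 2 resolved to grade <= 1 by the last day of the cycle: "
                   "treatment may continue at RP2D"),
        PolicyRule({"grade": 2}, "consult_monitor",
                   "grade 2 not resolved by cycle end but manageable: consult the medical "
                   "monitor before the next infusion at RP2D"),
        PolicyRule({"grade": 1, "tumoral": True, "investigator_high_risk": True},
                   "consult_monitor",
                   "grade 1 tumoral bleeding with high assessed risk: consult the medical "
                   "monitor [extrapolated]", True),
        PolicyRule({}, "continue_rp2d",
                   "grade 1 bleeding without risk modifiers: continue at RP2D"),
    )


def management_action(
    event: BleedingEvent, policy: Sequence[PolicyRule] | None = None
) -> ManagementAction:
    """Deterministic lookup of the management action for a bleeding event.

    Rules are evaluated in order; the first match decides.  The shipped
    default policy ends in a catch-all, so every valid event maps to exactly
    one action.
    """
    rules = default_policy() if policy is None else tuple(policy)
    for rule in rules:
        if rule.matches(event):
            return ManagementAction(rule.action, rule.rationale)
    raise InvalidParameterError("policy is not total: no rule matched the event")
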