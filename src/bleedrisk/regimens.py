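"""Dosing regimens for an intravenously infused biologic.

Doses are administered as zero-order infusions repeated every ``tau`` hours.
The two clinically used schedules are every-2-weeks (Q2W, tau = 336 h) and
every-3-weeks (Q3W, tau = 504 h).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace

from .errors import InvalidParameterError

TAU_Q2W = 336.0  # h
TAU_Q3W = 504.0  # h

__all__ = [
    "DoseRegimen",
    "TAU_Q2W",
    "TAU_Q3W",
    "q2w",
    "q3w",
    "standard_regimens",
    "parse_regimen",
]


@dataclass(frozen=True)
class DoseRegimen:
    """An administration schedule: repeated zero-order infusions.

    Parameters
    ----------
    dose_amount : float
        Dose per administration (mg). Zero is allowed (null input).
    tau : float
        Dosing interval (h).
    infusion_duration : float
        Duration of each infusion (h); must lie in (0, tau).
    n_doses : int
        Number of administrations.
    """

    dose_amount: float
    tau: float
    infusion_duration: float = 1.0
    n_doses: int = 1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dose_amount) and self.dose_amount >= 0):
            raise InvalidParameterError(f"dose_amount must be >= 0, got {self.dose_amount}")
        if not (math.isfinite(self.tau) and self.tau > 0):
            raise InvalidParameterError(f"tau must be > 0, got {self.tau}")
        if not (0 < self.infusion_duration < self.tau):
            raise InvalidParameterError(
                f"infusion_duration must lie in (0, tau), got {self.infusion_duration}"
            )
        if self.n_doses < 1:
            raise InvalidParameterError(f"n_doses must be >= 1, got {self.n_doses}")

    @property
    def infusion_rate(self) -> float:
        """Zero-order input rate during an infusion (mg/h)."""
        return self.dose_amount / self.infusion_duration

    @property
    def horizon(self) -> float:
        """End of the last dosing interval (h from first-dose start)."""
        return self.n_doses * self.tau

    def with_doses(self, n_doses: int) -> "DoseRegimen":
        return replace(self, n_doses=n_doses)

    def scaled(self, factor: float) -> "DoseRegimen":
        """Same schedule with the dose amount multiplied by ``factor``."""
        return replace(self, dose_amount=self.dose_amount * factor)


def q2w(dose_amount: float, n_doses: int = 1, infusion_duration: float = 1.0) -> DoseRegimen:
    return DoseRegimen(dose_amount, TAU_Q2W, infusion_duration, n_doses)


def q3w(dose_amount: float, n_doses: int = 1, infusion_duration: float = 1.0) -> DoseRegimen:
    return DoseRegimen(dose_amount, TAU_Q3W, infusion_duration, n_doses)


_LABEL_RE = re.compile(r"^(\d+(?:\.\d+)?)(?:\s*mg)?\s*(Q2W|Q3W)$", re.IGNORECASE)
_MGKG_RE = re.compile(r"^(\d+(?:\.\d+)?)\s*(?:mpk|mg/kg)[ _]?(Q2W|Q3W)$", re.IGNORECASE)


def parse_regimen(label: str, body_weight: float | None = None, n_doses: int = 1) -> DoseRegimen:
    """Build a :class:`DoseRegimen` from a label like ``"1200Q2W"`` or ``"3mpk_Q2W"``.

    Weight-based labels (mg/kg escalation arms) need ``body_weight`` in kg to
    resolve the absolute dose.
    """
    m = _LABEL_RE.match(label.strip())
    if m:
        dose = float(m.group(1))
    else:
        m = _MGKG_RE.match(label.strip())
        if not m:
            raise InvalidParameterError(f"unrecognized regimen label: {label!r}")
        if body_weight is None:
            raise InvalidParameterError(
                f"regimen {label!r} is weight-based; body_weight is required"
            )
        dose = float(m.group(1)) * body_weight
    tau = TAU_Q2W if m.group(2).upper() == "Q2W" else TAU_Q3W
    return DoseRegimen(dose, tau, n_doses=n_doses)


def standard_regimens(n_doses: int = 1) -> dict[str, DoseRegimen]:
    """The four absolute-dose regimens compared in the dose-modification analysis."""
    return {
        "600Q2W": q2w(600.0, n_doses),
        "1200Q2W": q2w(1200.0, n_doses),
        "1200Q3W": q3w(1200.0, n_doses),
        "2400Q3W": q3w(2400.0, n_doses),
    }
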