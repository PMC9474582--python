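"""Independent closed-form oracles used by the test suite.

These are derived and coded independently of the package's numerical paths:
the bi-exponential two-compartment infusion solution (macro-constant form),
the one-compartment infusion trough, and the 2x2 contingency log-odds.
"""

from __future__ import annotations

import math

import numpy as np


def two_compartment_infusion(cl, v1, v2, q, dose, t_inf, t):
    """Concentration after a single zero-order infusion, constant clearance.

    Standard bi-exponential superposition: during the infusion
    C(t) = (R/V1) * sum_i c_i (1 - e^{-l_i t}), afterwards each term decays
    as e^{-l_i (t - T_inf)} from its end-of-infusion value.
    """
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    root = math.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    c_alpha = (alpha - k21) / (alpha * (alpha - beta))
    c_beta = (k21 - beta) / (beta * (alpha - beta))
    rate = dose / t_inf
    t = np.asarray(t, dtype=float)
    during = rate / v1 * (
        c_alpha * (1.0 - np.exp(-alpha * t)) + c_beta * (1.0 - np.exp(-beta * t))
    )
    after = rate / v1 * (
        c_alpha * (1.0 - math.exp(-alpha * t_inf)) * np.exp(-alpha * (t - t_inf))
        + c_beta * (1.0 - math.exp(-beta * t_inf)) * np.exp(-beta * (t - t_inf))
    )
    return np.where(t <= t_inf, during, after)


def multi_dose_two_compartment(cl, v1, v2, q, dose, t_inf, tau, n_doses, t):
    """Superposition of time-shifted single-dose solutions (constant CL)."""
    t = np.asarray(t, dtype=float)
    total = np.zeros_like(t)
    for k in range(n_doses):
        shifted = t - k * tau
        mask = shifted > 0
        total[mask] += two_compartment_infusion(cl, v1, v2, q, dose, t_inf, shifted[mask])
    return total


def one_compartment_infusion_trough(cl, v, dose, t_inf, tau):
    """Single-dose trough C(tau) for a one-compartment infusion model."""
    k = cl / v
    rate = dose / t_inf
    c_end = rate / cl * (1.0 - math.exp(-k * t_inf))
    return c_end * math.exp(-k * (tau - t_inf))


def log_odds_2x2(events_exposed, n_exposed, events_unexposed, n_unexposed):
    """Logistic slope and intercept for a single binary covariate equal the
    contingency-table log-odds."""
    odds1 = events_exposed / (n_exposed - events_exposed)
    odds0 = events_unexposed / (n_unexposed - events_unexposed)
    return math.log(odds0), math.log(odds1 / odds0)  # intercept, slope
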