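"""Logistic exposure-safety modeling.

Fits maximum-likelihood logistic regressions of binary bleeding endpoints on
the single-dose average concentration (Cavg,SD), summarizes the exposure
effect as an odds ratio per 100 ug/mL (Wald CI), reduces full covariate models
by backward elimination with the likelihood-ratio test at p < 0.05
(categorical factors tested as whole blocks; the exposure term is never a
candidate for removal), and produces quartile-binned observed-incidence
summaries with exact Clopper-Pearson intervals.

The likelihood maximization itself is delegated to statsmodels (Newton
scoring, relative log-likelihood tolerance 1e-10); everything above the raw
fit -- design coding, inference summaries, model reduction, calibration --
lives here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import beta as beta_dist
from scipy.stats import chi2, norm

from .errors import InvalidParameterError, RankDeficiencyError, SeparationError

__all__ = [
    "Term",
    "ModelSpec",
    "LogisticFit",
    "ORSummary",
    "UnivariableModel",
    "EliminationResult",
    "build_design",
    "fit_logistic",
    "fit_model",
    "odds_ratio",
    "likelihood_ratio_test",
    "backward_eliminate",
    "quartile_incidence",
    "predict_probability",
    "calibrate_univariable",
]

Z95 = norm.ppf(0.975)


def _logit(p: float) -> float:
    if not 0.0 < p < 1.0:
        raise InvalidParameterError(f"probability must lie in (0, 1), got {p}")
    return math.log(p / (1.0 - p))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# model specification and design coding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """One covariate term: continuous/binary column or categorical factor."""

    name: str
    kind: str = "continuous"  # continuous | binary | categorical
    reference: str | None = None  # reference level for categorical terms
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise InvalidParameterError(f"unknown term kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise InvalidParameterError(f"categorical term {self.name!r} needs a reference level")


@dataclass(frozen=True)
class ModelSpec:
    """Endpoint + exposure + candidate covariate terms for one logistic model."""

    endpoint: str
    exposure: str = "cavg_sd"
    covariates: tuple[Term, ...] = ()

    def __post_init__(self) -> None:
        names = [self.exposure] + [t.name for t in self.covariates]
        if len(set(names)) != len(names):
            raise InvalidParameterError("duplicate terms in model specification")

    def without(self, term_name: str) -> "ModelSpec":
        return ModelSpec(
            self.endpoint, self.exposure,
            tuple(t for t in self.covariates if t.name != term_name),
        )


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Code the design matrix (with intercept) for a model specification.

    Returns the design and a mapping term name -> design columns (categorical
    factors expand to one indicator per non-reference level).
    """
    if spec.exposure not in data.columns:
        raise InvalidParameterError(f"exposure column {spec.exposure!r} missing from data")
    cols: dict[str, np.ndarray] = {"const": np.ones(len(data))}
    groups: dict[str, list[str]] = {spec.exposure: [spec.exposure]}
    cols[spec.exposure] = data[spec.exposure].to_numpy(dtype=float)
    for term in spec.covariates:
        if term.name not in data.columns:
            raise InvalidParameterError(f"covariate column {term.name!r} missing from data")
        if term.kind == "categorical":
            levels = [
                lv for lv in pd.unique(data[term.name].astype(str))
                if lv != term.reference
            ]
            names = []
            for lv in sorted(levels):
                cname = f"{term.name}[{lv}]"
                cols[cname] = (data[term.name].astype(str) == lv).to_numpy(dtype=float)
                names.append(cname)
            groups[term.name] = names
        else:
            x = data[term.name].to_numpy(dtype=float)
            if term.standardize:
                sd = x.std(ddof=1)
                if sd == 0:
                    raise InvalidParameterError(f"covariate {term.name!r} is constant")
                x = (x - x.mean()) / sd
            cols[term.name] = x
            groups[term.name] = [term.name]
    return pd.DataFrame(cols, index=data.index), groups


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """A converged maximum-likelihood logistic regression."""

    terms: tuple[str, ...]            # design column names, "const" first
    coefficients: pd.Series           # log-odds scale
    covariance: pd.DataFrame          # observed-information covariance
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    score_norm: float                 # gradient norm at the optimum
    outcome_checksum: int             # guards LRT comparisons across outcomes

    def se(self, term: str) -> float:
        return float(np.sqrt(self.covariance.loc[term, term]))

    def wald_p(self, term: str) -> float:
        z = self.coefficients[term] / self.se(term)
        return float(2.0 * norm.sf(abs(z)))


def fit_logistic(design: pd.DataFrame, outcomes: Sequence[int]) -> LogisticFit:
    """Maximum-likelihood logistic fit of a coded design matrix.

    Raises :class:`SeparationError` on (quasi-)complete separation, detected
    either by statsmodels or by a standardized coefficient exceeding 15, and
    :class:`RankDeficiencyError` (naming the collinear columns) when the
    design is rank deficient.
    """
    y = np.asarray(outcomes, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise InvalidParameterError("outcomes must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise InvalidParameterError("outcomes are constant; a logistic model is not estimable")
    X = np.asarray(design, dtype=float)
    if X.shape[0] < X.shape[1]:
        raise InvalidParameterError("fewer observations than coefficients")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns beyond the numerical rank via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        tol = abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = sorted(design.columns[piv[i]] for i in range(X.shape[1])
                     if abs(r[i, i]) < tol)
        raise RankDeficiencyError(f"design matrix is rank deficient; collinear terms: {bad}")

    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            result = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10, maxiter=200)
        except Exception as exc:  # PerfectSeparationError, singular Hessian, ...
            separated = (
                "eparation" in type(exc).__name__
                or "eparation" in str(exc)
                or any("eparation" in str(w.message) for w in caught)
            )
            if separated:
                raise SeparationError(
                    "complete or quasi-complete separation detected"
                ) from exc
            raise
    params = np.asarray(result.params, dtype=float)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0  # intercept column
    if np.any(np.abs(params * scale) > 15.0):
        worst = design.columns[int(np.argmax(np.abs(params * scale)))]
        raise SeparationError(
            f"separation suspected: standardized coefficient for {worst!r} exceeds 15"
        )
    score = result.model.score(params)
    coef = pd.Series(params, index=design.columns)
    cov = pd.DataFrame(np.asarray(result.cov_params()), index=design.columns,
                       columns=design.columns)
    return LogisticFit(
        terms=tuple(design.columns),
        coefficients=coef,
        covariance=cov,
        log_likelihood=float(result.llf),
        n=int(y.size),
        n_events=int(y.sum()),
        converged=bool(result.mle_retvals.get("converged", True)),
        score_norm=float(np.linalg.norm(score)),
        outcome_checksum=int(np.dot(y, np.arange(1, y.size + 1))),
    )


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> tuple[LogisticFit, dict[str, list[str]]]:
    """Code the design for ``spec`` and fit it against ``spec.endpoint``."""
    if spec.endpoint not in data.columns:
        raise InvalidParameterError(f"endpoint column {spec.endpoint!r} missing from data")
    design, groups = build_design(data, spec)
    fit = fit_logistic(design, data[spec.endpoint].to_numpy())
    return fit, groups


# ---------------------------------------------------------------------------
# inference summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ORSummary:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    unit_scale: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise InvalidParameterError("CI must contain the odds-ratio point estimate")


def odds_ratio(fit: LogisticFit, term: str, unit_scale: float = 100.0) -> ORSummary:
    """Odds ratio per ``unit_scale`` units of ``term`` with Wald 95% CI."""
    if term not in fit.coefficients.index:
        raise InvalidParameterError(f"term {term!r} not in fit")
    b = float(fit.coefficients[term])
    se = fit.se(term)
    return ORSummary(
        term=term,
        odds_ratio=math.exp(unit_scale * b),
        ci_low=math.exp(unit_scale * (b - Z95 * se)),
        ci_high=math.exp(unit_scale * (b + Z95 * se)),
        p_value=fit.wald_p(term),
        unit_scale=unit_scale,
    )


def likelihood_ratio_test(full: LogisticFit, reduced: LogisticFit) -> tuple[float, float, int]:
    """LRT of nested logistic fits: returns (p_value, statistic, df)."""
    if not set(reduced.terms) <= set(full.terms):
        raise InvalidParameterError("models are not nested (reduced terms not a subset)")
    if reduced.n != full.n or reduced.outcome_checksum != full.outcome_checksum:
        raise InvalidParameterError("models were fitted to different outcome vectors")
    df = len(full.terms) - len(reduced.terms)
    stat = max(2.0 * (full.log_likelihood - reduced.log_likelihood), 0.0)
    if df == 0:
        return 1.0, stat, 0
    return float(chi2.sf(stat, df)), stat, df


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EliminationStep:
    round: int
    term: str
    p_value: float
    removed: bool


@dataclass(frozen=True)
class EliminationResult:
    fit: LogisticFit
    spec: ModelSpec
    trace: tuple[EliminationStep, ...]


def backward_eliminate(
    spec: ModelSpec, data: pd.DataFrame, alpha: float = 0.05
) -> EliminationResult:
    """Stepwise backward elimination by likelihood-ratio test.

    In each round the covariate (categorical factors as whole blocks) with the
    largest LRT p-value >= ``alpha`` is removed; the exposure term is never a
    candidate.  Stops when every remaining covariate is significant at
    ``alpha``.
    """
    current = spec
    fit, _ = fit_model(data, current)
    trace: list[EliminationStep] = []
    round_no = 0
    while current.covariates:
        round_no += 1
        p_values: dict[str, float] = {}
        for term in current.covariates:
            reduced_fit, _ = fit_model(data, current.without(term.name))
            p, _, _ = likelihood_ratio_test(fit, reduced_fit)
            p_values[term.name] = p
        worst = max(p_values, key=lambda name: p_values[name])
        for name, p in sorted(p_values.items()):
            trace.append(EliminationStep(round_no, name, p, removed=(
                name == worst and p_values[worst] >= alpha)))
        if p_values[worst] < alpha:
            break
        current = current.without(worst)
        fit, _ = fit_model(data, current)
    return EliminationResult(fit=fit, spec=current, trace=tuple(trace))


# ---------------------------------------------------------------------------
# quartile summaries
# ---------------------------------------------------------------------------

def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def quartile_incidence(
    exposures: Sequence[float], outcomes: Sequence[int]
) -> pd.DataFrame:
    """Observed incidence by exposure quartile with exact 95% CIs.

    Quartile boundaries sit at the 25/50/75th percentiles (boundary values go
    to the lower bin); the plotting abscissa of each bin is the
    12.5/37.5/62.5/87.5th percentile of the full exposure distribution.
    """
    x = np.asarray(exposures, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.size != y.size:
        raise InvalidParameterError("exposures and outcomes must align")
    if x.size < 8:
        raise InvalidParameterError("need at least 8 observations for quartile summaries")
    edges = np.percentile(x, [25, 50, 75])
    bins = np.searchsorted(edges, x, side="left")  # boundary values -> lower bin
    placement = np.percentile(x, [12.5, 37.5, 62.5, 87.5])
    lo_edges = [float(x.min()), *edges]
    hi_edges = [*edges, float(x.max())]
    rows = []
    for b in range(4):
        mask = bins == b
        n = int(mask.sum())
        k = int(y[mask].sum())
        ci_lo, ci_hi = (_clopper_pearson(k, n) if n else (float("nan"),) * 2)
        rows.append({
            "quartile": b + 1,
            "exposure_low": lo_edges[b],
            "exposure_high": hi_edges[b],
            "placement": float(placement[b]),
            "n": n,
            "events": k,
            "incidence": k / n if n else float("nan"),
            "ci_low": ci_lo,
            "ci_high": ci_hi,
        })
    out = pd.DataFrame(rows)
    assert out["n"].sum() == x.size  # bins partition the sample
    return out


# ---------------------------------------------------------------------------
# prediction and table-anchored calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnivariableModel:
    """A univariable logistic model in Cavg,SD given by (intercept, slope)."""

    intercept: float
    slope: float  # log-odds per ug/mL

    def predict(self, exposure):
        return _invlogit(self.intercept + self.slope * np.asarray(exposure, dtype=float))

    def odds_ratio_per(self, unit_scale: float = 100.0) -> float:
        return math.exp(self.slope * unit_scale)


def predict_probability(
    model: UnivariableModel | LogisticFit | tuple[float, float],
    exposures: Sequence[float],
    exposure_term: str = "cavg_sd",
) -> pd.DataFrame:
    """Predicted event probability along an exposure grid.

    For a :class:`LogisticFit` (univariable: intercept + exposure only) a 95%
    CI band is computed by the delta method on the linear predictor and then
    transformed; for a bare (intercept, slope) model the band is omitted.
    """
    grid = np.asarray(exposures, dtype=float)
    if np.any(grid < 0):
        raise InvalidParameterError("exposures must be >= 0")
    if isinstance(model, LogisticFit):
        extra = [t for t in model.terms if t not in ("const", exposure_term)]
        if extra:
            raise InvalidParameterError(
                f"CI bands require a univariable fit; extra terms present: {extra}"
            )
        b0 = float(model.coefficients["const"])
        b1 = float(model.coefficients[exposure_term])
        lp = b0 + b1 * grid
        cov = model.covariance.loc[["const", exposure_term], ["const", exposure_term]].to_numpy()
        var = cov[0, 0] + 2.0 * grid * cov[0, 1] + grid**2 * cov[1, 1]
        half = Z95 * np.sqrt(var)
        return pd.DataFrame({
            "exposure": grid,
            "probability": _invlogit(lp),
            "ci_low": _invlogit(lp - half),
            "ci_high": _invlogit(lp + half),
        })
    if isinstance(model, tuple):
        model = UnivariableModel(*model)
    return pd.DataFrame({
        "exposure": grid,
        "probability": model.predict(grid),
        "ci_low": np.nan,
        "ci_high": np.nan,
    })


def calibrate_univariable(
    anchor1: tuple[float, float], anchor2: tuple[float, float]
) -> UnivariableModel:
    """Recover (intercept, slope) from two (exposure, probability) anchors.

    slope = [logit(p2) - logit(p1)] / (c2 - c1); intercept through anchor1.
    """
    c1, p1 = anchor1
    c2, p2 = anchor2
    if c1 == c2:
        raise InvalidParameterError("anchors must have distinct exposures")
    l1, l2 = _logit(p1), _logit(p2)
    slope = (l2 - l1) / (c2 - c1)
    return UnivariableModel(intercept=l1 - slope * c1, slope=slope)
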