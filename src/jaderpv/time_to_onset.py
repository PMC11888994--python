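"""Time-to-onset analysis: quartiles, Weibull MLE and hazard typing.

Time to onset is the number of whole days from the first administration of
the suspect drug to the adverse event.  Reports without complete (year, month,
day) dates on both ends are excluded rather than imputed, and same-day events
are excluded because the lifetime model's support is strictly positive.

Every extracted report is an observed event — spontaneous reports are events
by construction — so the two-parameter Weibull is fitted without censoring.
The shape parameter beta types the hazard: an upper 95% confidence limit
below 1 indicates a decreasing hazard (initial-failure type), a lower limit
above 1 an increasing hazard (wear-out type), and a CI spanning 1 a constant
hazard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .case_extraction import SMQDefinition
from .errors import DegenerateSampleError, DomainError
from .records import CaseReport, HazardClass, Involvement, normalize_name

__all__ = [
    "OnsetSample",
    "QuartileSummary",
    "WeibullFit",
    "WeibullTimeToOnset",
    "compute_onset_days",
    "annotate_onset",
    "collect_onset_samples",
    "quartile_summary",
    "fit_weibull_mle",
    "classify_hazard",
    "tto_summary_table",
]

_Z975 = stats.norm.ppf(0.975)
_CHI2_95 = stats.chi2.ppf(0.95, df=1)


@dataclass(frozen=True)
class OnsetSample:
    """Onset days for one stratum (an indication category or ``all``)."""

    stratum: str
    days: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.days, dtype=float)
        object.__setattr__(self, "days", arr)
        if arr.size and arr.min() < 1:
            raise DomainError("onset days must all be >= 1")

    @property
    def n(self) -> int:
        return int(self.days.size)


@dataclass(frozen=True)
class QuartileSummary:
    n: int
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class WeibullFit:
    """Weibull scale/shape MLE with Wald (or profile) 95% CIs."""

    alpha: float
    beta: float
    alpha_ci95: tuple[float, float]
    beta_ci95: tuple[float, float]
    n: int
    hazard_class: HazardClass
    loglik: float


def compute_onset_days(
    case: CaseReport, drug_name: str, smq: SMQDefinition
) -> Optional[int]:
    """Days from first target-drug administration to the first SMQ event.

    Uses the earliest *complete* start date among suspect records of
    ``drug_name`` and the earliest complete event date among SMQ-matching
    reactions.  Returns None (exclusion) when either side lacks a complete
    date or the difference is < 1 day.
    """
    target = normalize_name(drug_name)
    starts = [
        d.start_date.to_date()
        for d in case.drugs
        if d.involvement is Involvement.SUSPECT
        and normalize_name(d.generic_name) == target
        and d.start_date is not None
        and d.start_date.is_complete
    ]
    reactions = case.smq_reactions or [r for r in case.reactions if r.pt_code in smq.pt_codes]
    events = [
        r.event_date.to_date()
        for r in reactions
        if r.event_date is not None and r.event_date.is_complete
    ]
    if not starts or not events:
        return None
    delta = (min(events) - min(starts)).days
    return delta if delta >= 1 else None


def annotate_onset(
    cases: Iterable[CaseReport], drug_name: str, smq: SMQDefinition
) -> list[CaseReport]:
    return [c.annotated(onset_days=compute_onset_days(c, drug_name, smq)) for c in cases]


def collect_onset_samples(cases: Iterable[CaseReport]) -> dict[str, OnsetSample]:
    """Group annotated onset days into per-indication strata plus ``all``.

    Multi-indication cases contribute their onset to every matching stratum.
    Cases without an onset (incomplete dates) are excluded everywhere.
    """
    days_by: dict[str, list[int]] = {"all": []}
    for c in cases:
        if c.onset_days is None:
            continue
        days_by["all"].append(c.onset_days)
        for cat in c.indications:
            days_by.setdefault(cat.value, []).append(c.onset_days)
    return {k: OnsetSample(k, np.asarray(v, dtype=float)) for k, v in days_by.items()}


def quartile_summary(sample: OnsetSample, method: str = "linear") -> QuartileSummary:
    """Median and quartiles by the configured quantile rule.

    ``method`` is passed to :func:`numpy.quantile`; the default linear
    interpolation of order statistics is the common convention, but the rule
    is configurable because different statistics products disagree on it.
    """
    if sample.n < 1:
        raise DomainError("quartile summary needs at least one observation")
    q1, med, q3 = np.quantile(sample.days, [0.25, 0.5, 0.75], method=method)
    return QuartileSummary(n=sample.n, median=float(med), q1=float(q1), q3=float(q3))


def _score_beta(beta: float, x: np.ndarray, logx: np.ndarray) -> float:
    # Profile score for beta after maximising over alpha analytically.
    xb = np.power(x, beta)
    return 1.0 / beta + logx.mean() - float((xb * logx).sum() / xb.sum())


def _loglik(alpha: float, beta: float, x: np.ndarray) -> float:
    z = (x / alpha) ** beta
    return float(
        x.size * (math.log(beta) - beta * math.log(alpha))
        + (beta - 1.0) * np.log(x).sum()
        - z.sum()
    )


class WeibullTimeToOnset(BaseEstimator):
    """Maximum-likelihood Weibull fit for uncensored onset-day samples.

    Parameters
    ----------
    ci_method : ``"wald"`` (default) or ``"profile"``.
        Wald intervals are computed on the log-parameter scale from the
        observed information and back-transformed; profile intervals invert
        the likelihood-ratio statistic at the 95% level.
    conf_level : confidence level for the parameter intervals.
    score_tol : convergence tolerance on the profile score at the optimum.

    Attributes (after :meth:`fit`)
    ------------------------------
    alpha_, beta_ : scale (days) and shape (dimensionless) MLEs.
    alpha_ci95_, beta_ci95_ : the confidence intervals.
    hazard_class_ : hazard type implied by the shape CI.
    n_, loglik_ : sample size and maximized log-likelihood.
    """

    def __init__(self, ci_method: str = "wald", conf_level: float = 0.95, score_tol: float = 1e-8):
        self.ci_method = ci_method
        self.conf_level = conf_level
        self.score_tol = score_tol

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None) -> "WeibullTimeToOnset":
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 3:
            raise DomainError("Weibull fit needs at least 3 observations")
        if np.any(x <= 0) or not np.all(np.isfinite(x)):
            raise DomainError("onset days must be positive and finite")
        if np.ptp(x) == 0:
            raise DegenerateSampleError(
                "all onset days identical: the shape parameter is unbounded"
            )
        logx = np.log(x)
        beta = self._solve_beta(x, logx)
        alpha = float((np.power(x, beta).mean()) ** (1.0 / beta))
        if abs(_score_beta(beta, x, logx)) > self.score_tol:
            raise RuntimeError("profile score did not converge to tolerance")
        self.alpha_, self.beta_ = alpha, float(beta)
        self.n_ = int(x.size)
        self.loglik_ = _loglik(alpha, beta, x)
        if self.ci_method == "profile":
            self.alpha_ci95_, self.beta_ci95_ = self._profile_ci(x, logx)
        else:
            self.alpha_ci95_, self.beta_ci95_ = self._wald_ci(x)
        self.hazard_class_ = classify_hazard(self.beta_ci95_)
        return self

    @staticmethod
    def _solve_beta(x: np.ndarray, logx: np.ndarray) -> float:
        lo, hi = 1e-3, 1.0
        while _score_beta(hi, x, logx) > 0:
            hi *= 2.0
            if hi > 1e6:  # pragma: no cover - guarded by the ptp check
                raise DegenerateSampleError("shape parameter diverges")
        while _score_beta(lo, x, logx) < 0:
            lo /= 2.0
        return float(optimize.brentq(_score_beta, lo, hi, args=(x, logx), xtol=1e-13))

    def _observed_information(self, x: np.ndarray) -> np.ndarray:
        """Observed information for (log alpha, log beta), analytic."""
        a, b = self.alpha_, self.beta_
        z = b * (np.log(x) - math.log(a))
        u = np.exp(z)
        n = x.size
        h_aa = -(b**2) * u.sum()
        h_ab = b * (u.sum() - n) + b * (u * z).sum()
        h_bb = z.sum() - (u * z * (1.0 + z)).sum()
        return -np.array([[h_aa, h_ab], [h_ab, h_bb]])

    def _wald_ci(self, x: np.ndarray):
        info = self._observed_information(x)
        cov = np.linalg.inv(info)
        z = stats.norm.ppf(0.5 + self.conf_level / 2.0)
        se_la, se_lb = np.sqrt(np.diag(cov))
        a, b = self.alpha_, self.beta_
        return (
            (a * math.exp(-z * se_la), a * math.exp(z * se_la)),
            (b * math.exp(-z * se_lb), b * math.exp(z * se_lb)),
        )

    # -- profile-likelihood intervals ------------------------------------
    def _profile_ci(self, x: np.ndarray, logx: np.ndarray):
        crit = stats.chi2.ppf(self.conf_level, df=1)

        def dev_beta(beta: float) -> float:
            alpha = float((np.power(x, beta).mean()) ** (1.0 / beta))
            return 2.0 * (self.loglik_ - _loglik(alpha, beta, x)) - crit

        def dev_alpha(alpha: float) -> float:
            def score_b(beta: float) -> float:
                z = (x / alpha) ** beta
                return x.size / beta - x.size * math.log(alpha) + logx.sum() - float(
                    (z * (logx - math.log(alpha))).sum()
                )

            lo, hi = 1e-3, 1.0
            while score_b(hi) > 0:
                hi *= 2.0
            while score_b(lo) < 0:
                lo /= 2.0
            beta = optimize.brentq(score_b, lo, hi, xtol=1e-12)
            return 2.0 * (self.loglik_ - _loglik(alpha, beta, x)) - crit

        def invert(dev, center: float) -> tuple[float, float]:
            lo = center
            while dev(lo) < 0:
                lo /= 1.5
            hi = center
            while dev(hi) < 0:
                hi *= 1.5
            left = optimize.brentq(dev, lo, center * (1 - 1e-12))
            right = optimize.brentq(dev, center * (1 + 1e-12), hi)
            return float(left), float(right)

        return invert(dev_alpha, self.alpha_), invert(dev_beta, self.beta_)

    def to_fit(self) -> WeibullFit:
        return WeibullFit(
            alpha=self.alpha_,
            beta=self.beta_,
            alpha_ci95=self.alpha_ci95_,
            beta_ci95=self.beta_ci95_,
            n=self.n_,
            hazard_class=self.hazard_class_,
            loglik=self.loglik_,
        )


def fit_weibull_mle(sample: OnsetSample, **kwargs) -> WeibullFit:
    """Thin functional wrapper around :class:`WeibullTimeToOnset`."""
    return WeibullTimeToOnset(**kwargs).fit(sample.days).to_fit()


def classify_hazard(fit) -> HazardClass:
    """Type the hazard from the shape parameter's 95% CI.

    Lower limit > 1 -> wear-out (increasing hazard); upper limit < 1 ->
    initial-failure (decreasing hazard); otherwise constant.  Accepts a
    :class:`WeibullFit` or a ``(lo, hi)`` interval.
    """
    lo, hi = fit.beta_ci95 if isinstance(fit, WeibullFit) else fit
    if lo <= 0 or hi <= 0 or lo > hi:
        raise DomainError("shape CI must be a positive interval")
    if lo > 1.0:
        return HazardClass.WEAR_OUT
    if hi < 1.0:
        return HazardClass.INITIAL_FAILURE
    return HazardClass.CONSTANT


def tto_summary_table(
    samples: Mapping[str, OnsetSample],
    *,
    quantile_method: str = "linear",
    min_n_weibull: int = 3,
    **fit_kwargs,
) -> pd.DataFrame:
    """Per-stratum summary: n, quartiles and Weibull parameters with CIs.

    Strata too small (or too degenerate) for a Weibull fit keep their
    quartile columns and carry NaNs in the parameter columns.
    """
    rows = []
    order = ["all"] + sorted(k for k in samples if k != "all")
    for name in order:
        s = samples[name]
        if s.n == 0:
            continue
        q = quartile_summary(s, method=quantile_method)
        row = {
            "stratum": name,
            "n": s.n,
            "median": q.median,
            "q1": q.q1,
            "q3": q.q3,
            "alpha": np.nan,
            "alpha_lo": np.nan,
            "alpha_hi": np.nan,
            "beta": np.nan,
            "beta_lo": np.nan,
            "beta_hi": np.nan,
            "hazard_class": "",
        }
        if s.n >= min_n_weibull and np.ptp(s.days) > 0:
            fit = fit_weibull_mle(s, **fit_kwargs)
            row.update(
                alpha=fit.alpha,
                alpha_lo=fit.alpha_ci95[0],
                alpha_hi=fit.alpha_ci95[1],
                beta=fit.beta,
                beta_lo=fit.beta_ci95[0],
                beta_hi=fit.beta_ci95[1],
                hazard_class=fit.hazard_class.value,
            )
        rows.append(row)
    return pd.DataFrame(rows)
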