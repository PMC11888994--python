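"""Kaplan-Meier onset curves and pairwise log-rank comparisons.

Spontaneous reports contribute an event by construction, so every onset day
is an observed event and the product-limit estimate reduces to 1 minus the
empirical CDF; the estimator and the two-sample log-rank test are delegated
to lifelines behind this module's surface.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import DomainError
from .time_to_onset import OnsetSample

__all__ = ["KMCurve", "LogRankResult", "km_estimate", "km_to_frame", "log_rank", "pairwise_logrank"]


@dataclass(frozen=True)
class KMCurve:
    stratum: str
    times: np.ndarray  # sorted unique event days
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray


@dataclass(frozen=True)
class LogRankResult:
    stratum_a: str
    stratum_b: str
    chi2: float
    p_value: float


def km_estimate(sample: OnsetSample) -> KMCurve:
    """Product-limit estimate treating every observation as an event.

    With no censoring the final survival probability is exactly 0 and the
    curve equals the empirical proportion of onset days beyond each time.
    Ties are handled by the standard aggregated-increment formula.
    """
    if sample.n < 1:
        raise DomainError("Kaplan-Meier estimate needs at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(sample.days, event_observed=np.ones(sample.n))
    table = kmf.event_table
    table = table[table["observed"] > 0]
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy(dtype=float)
    return KMCurve(
        stratum=sample.stratum,
        times=times,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        survival=surv,
    )


def km_to_frame(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stratum": curve.stratum,
            "time": curve.times,
            "at_risk": curve.at_risk,
            "events": curve.events,
            "survival": curve.survival,
        }
    )


def log_rank(a: OnsetSample, b: OnsetSample) -> LogRankResult:
    """Two-sample log-rank test (hypergeometric variance at each event time).

    The statistic is chi-squared with 1 df.  The degenerate case of two
    identical constant samples — zero variance everywhere — is reported as
    chi2 = 0, p = 1.
    """
    if a.n < 1 or b.n < 1:
        raise DomainError("log-rank needs at least one observation per group")
    res = logrank_test(
        a.days, b.days, event_observed_A=np.ones(a.n), event_observed_B=np.ones(b.n)
    )
    chi2, p = float(res.test_statistic), float(res.p_value)
    if not (math.isfinite(chi2) and math.isfinite(p)):
        chi2, p = 0.0, 1.0
    return LogRankResult(stratum_a=a.stratum, stratum_b=b.stratum, chi2=chi2, p_value=p)


def pairwise_logrank(
    samples: Mapping[str, OnsetSample],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    *,
    bonferroni: bool = False,
    min_n: int = 1,
) -> pd.DataFrame:
    """All pairwise log-rank tests between the given strata.

    Comparisons are reported unadjusted by default (raw P, as is conventional
    for a small number of planned contrasts); ``bonferroni=True`` multiplies
    each p-value by the number of comparisons, capped at 1.
    """
    strata = [k for k in samples if k != "all" and samples[k].n >= min_n]
    todo = pairs if pairs is not None else list(itertools.combinations(sorted(strata), 2))
    rows = []
    for sa, sb in todo:
        r = log_rank(samples[sa], samples[sb])
        rows.append({"stratum_a": sa, "stratum_b": sb, "chi2": r.chi2, "p": r.p_value})
    frame = pd.DataFrame(rows, columns=["stratum_a", "stratum_b", "chi2", "p"])
    if bonferroni and len(frame):
        frame["p_adjusted"] = np.minimum(frame["p"] * len(frame), 1.0)
    return frame
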