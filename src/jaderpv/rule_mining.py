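"""Association-rule mining over case transactions with time-binned consequents.

Each eligible case becomes one transaction whose items are its suspect-drug
generic names plus its indication-category labels, and whose consequent is
the 100-day bin containing its onset day (events beyond day 1095 are outside
the last bin and drop the case).  Frequent itemsets are mined with a
level-wise apriori using the downward-closure prune, and rules
``lhs => time-bin`` are scored with support, confidence, coverage, lift and
count, plus a chi-squared statistic computed from those measures alone:

    chi2 = D (lift - 1)^2 (support * confidence)
           / ((confidence - support) (lift - confidence))

which for a 2x2 contingency table with D transactions equals the classical
Pearson chi-squared (1 df); 3.84 is therefore the conventional 5% threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, DegenerateRuleError, DomainError
from .records import CaseReport, IndicationCategory, Involvement

__all__ = [
    "TimeBinning",
    "DEFAULT_BINNING",
    "Transaction",
    "MiningConfig",
    "INDICATION_LABELS",
    "bin_onset_days",
    "build_transactions",
    "mine_frequent_itemsets",
    "derive_rules",
    "chi_squared_eq5",
    "filter_rules",
    "AssociationRule",
    "AssociationRuleMiner",
    "rules_to_frame",
]

logger = logging.getLogger(__name__)

#: Transaction item labels for the indication categories.
INDICATION_LABELS: dict[IndicationCategory, str] = {
    IndicationCategory.COLORECTAL: "colon and rectal cancer",
    IndicationCategory.NSCLC: "non-small cell lung cancer",
    IndicationCategory.BREAST: "breast cancer",
    IndicationCategory.MALIGNANT_GLIOMA: "malignant glioma",
    IndicationCategory.OVARIAN: "ovarian cancer",
    IndicationCategory.CERVICAL: "cervical cancer",
    IndicationCategory.HEPATOCELLULAR: "hepatocellular carcinoma",
    IndicationCategory.OTHER: "others",
    IndicationCategory.NO_ENTRY: "no entry",
}

CHI2_5PCT = 3.84


@dataclass(frozen=True)
class TimeBinning:
    """Disjoint, contiguous onset-day bins covering [1, last edge]."""

    edges: tuple[tuple[int, int], ...] = (
        (1, 100),
        (101, 200),
        (201, 300),
        (301, 400),
        (401, 500),
        (501, 600),
        (601, 700),
        (701, 800),
        (801, 900),
        (901, 1000),
        (1001, 1095),
    )

    def __post_init__(self) -> None:
        if not self.edges or self.edges[0][0] != 1:
            raise ConfigurationError("bins must start at day 1")
        prev_hi = 0
        for lo, hi in self.edges:
            if lo != prev_hi + 1 or hi < lo:
                raise ConfigurationError("bins must be disjoint and contiguous")
            prev_hi = hi

    @property
    def labels(self) -> list[str]:
        return [f"{lo}-{hi}" for lo, hi in self.edges]

    @property
    def max_day(self) -> int:
        return self.edges[-1][1]


DEFAULT_BINNING = TimeBinning()


def bin_onset_days(days: int, binning: TimeBinning = DEFAULT_BINNING) -> Optional[str]:
    """Label of the bin containing ``days``; None beyond the last edge."""
    if days < 1:
        raise DomainError("onset days must be >= 1")
    for lo, hi in binning.edges:
        if lo <= days <= hi:
            return f"{lo}-{hi}"
    return None


@dataclass(frozen=True)
class Transaction:
    case_id: str
    items: frozenset[str]
    rhs_bin: str

    def __post_init__(self) -> None:
        if not self.items:
            raise DomainError("a transaction needs at least one item")
        if self.rhs_bin in self.items:
            raise DomainError("the consequent bin may not appear among the items")


def build_transactions(
    cases: Iterable[CaseReport],
    binning: TimeBinning = DEFAULT_BINNING,
    *,
    with_stats: bool = False,
):
    """Assemble one transaction per case with a binnable onset day.

    Items are all suspect-drug generic names (the target drug included as its
    own item) plus the labels of every indication category the case belongs
    to.  Cases without an onset day, or with one beyond the last bin edge,
    are dropped and counted.
    """
    transactions, dropped = [], 0
    for c in cases:
        if c.onset_days is None:
            dropped += 1
            continue
        label = bin_onset_days(int(c.onset_days), binning)
        if label is None:
            dropped += 1
            continue
        items = {d.generic_name for d in c.drugs if d.involvement is Involvement.SUSPECT}
        items |= {INDICATION_LABELS[cat] for cat in c.indications}
        transactions.append(Transaction(case_id=c.case_id, items=frozenset(items), rhs_bin=label))
    if dropped:
        logger.info("build_transactions dropped %d cases without a binnable onset", dropped)
    if with_stats:
        return transactions, {"n_transactions": len(transactions), "dropped": dropped}
    return transactions


@dataclass(frozen=True)
class MiningConfig:
    """Apriori thresholds.

    ``maxlen`` bounds the *total* itemset size (|lhs| + 1 for the consequent),
    with None meaning unbounded; ``max_lhs`` optionally bounds the antecedent
    alone.  ``chi2_d`` is the D used in the chi-squared formula: ``"auto"``
    uses the mined transaction count, while an integer supports reproducing
    reports whose D was fixed externally.
    """

    min_support: float = 5e-9
    min_confidence: float = 5e-9
    maxlen: Optional[int] = 3
    max_lhs: Optional[int] = None
    chi2_threshold: float = CHI2_5PCT
    lift_min: float = 1.0
    chi2_d: Union[int, str] = "auto"

    def __post_init__(self) -> None:
        if self.min_support < 0 or self.min_confidence < 0 or self.chi2_threshold < 0:
            raise ConfigurationError("mining thresholds must be >= 0")
        if self.maxlen is not None and self.maxlen < 2:
            raise ConfigurationError("maxlen must be >= 2 (one antecedent item plus the bin)")
        if isinstance(self.chi2_d, str) and self.chi2_d != "auto":
            raise ConfigurationError("chi2_d must be an integer or 'auto'")


@dataclass(frozen=True)
class AssociationRule:
    lhs: frozenset[str]
    rhs: str
    support: float
    confidence: float
    coverage: float
    lift: float
    count: int
    chi2: float
    significant: bool
    degenerate: bool = False


def _transaction_itemsets(transactions: Sequence[Transaction]) -> list[frozenset[str]]:
    return [t.items | {t.rhs_bin} for t in transactions]


def mine_frequent_itemsets(
    transactions: Sequence[Transaction], config: MiningConfig = MiningConfig()
) -> dict[frozenset, int]:
    """Level-wise apriori over items plus consequent labels.

    Returns every itemset meeting ``min_support`` (and ``maxlen``) with its
    absolute transaction count.  Candidate (k+1)-itemsets are generated from
    frequent k-itemsets sharing a (k-1)-prefix and pruned by downward closure
    before counting.
    """
    if not transactions:
        raise DomainError("mining needs at least one transaction")
    baskets = _transaction_itemsets(transactions)
    d = len(baskets)
    min_count = max(1, math.ceil(config.min_support * d - 1e-9))

    counts: dict[frozenset, int] = {}
    item_counts: dict[str, int] = {}
    for basket in baskets:
        for item in basket:
            item_counts[item] = item_counts.get(item, 0) + 1
    frequent = {
        frozenset([i]): c for i, c in item_counts.items() if c >= min_count
    }
    counts.update(frequent)
    current = sorted(tuple(sorted(s)) for s in frequent)
    k = 1
    while current and (config.maxlen is None or k < config.maxlen):
        current_set = {frozenset(t) for t in current}
        candidates = set()
        for i, a in enumerate(current):
            for b in current[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break  # sorted order: no later b shares the prefix
                cand = a + (b[-1],)
                fs = frozenset(cand)
                # downward closure: every k-subset must be frequent
                if all(fs - {item} in current_set for item in cand):
                    candidates.add(cand)
        if not candidates:
            break
        cand_counts = {c: 0 for c in candidates}
        for basket in baskets:
            for c in candidates:
                if all(item in basket for item in c):
                    cand_counts[c] += 1
        next_level = sorted(c for c, n in cand_counts.items() if n >= min_count)
        for c in next_level:
            counts[frozenset(c)] = cand_counts[c]
        current = next_level
        k += 1
    return counts


def chi_squared_eq5(support: float, confidence: float, lift: float, D: int) -> float:
    """Chi-squared of a rule from its support, confidence and lift alone.

    ``chi2 = D (lift-1)^2 (support*confidence) / ((confidence-support)(lift-confidence))``

    Equals the Pearson chi-squared (1 df) of the rule's 2x2 contingency table
    when ``D`` is the transaction count.  Independence (lift = 1) gives 0
    exactly.  Degenerate contingencies — confidence equal to support
    (antecedent covers everything) or lift equal to confidence (consequent
    covers everything) — are rejected, as is any negative denominator.
    """
    if D < 1:
        raise DomainError("D must be >= 1")
    if not 0 < support <= confidence:
        raise DomainError("requires 0 < support <= confidence")
    if lift == 1.0:
        return 0.0
    denom = (confidence - support) * (lift - confidence)
    if denom == 0:
        raise DegenerateRuleError(
            "chi-squared undefined: confidence equals support or lift equals confidence"
        )
    if denom < 0:
        raise DegenerateRuleError("negative denominator: inconsistent rule measures")
    return D * (lift - 1.0) ** 2 * (support * confidence) / denom


def derive_rules(
    itemsets: Mapping[frozenset, int],
    transactions: Sequence[Transaction],
    config: MiningConfig = MiningConfig(),
) -> list[AssociationRule]:
    """Turn frequent itemsets into rules ``lhs => time-bin``.

    The consequent is always a single bin label; the antecedent is the rest
    of the itemset and must be non-empty.  Measures are the standard ones
    (support = joint frequency, coverage = antecedent frequency, confidence =
    support/coverage, lift = confidence over the consequent's base rate);
    rules below ``min_confidence`` are dropped.  Rules whose contingency
    makes the chi-squared statistic undefined are kept with ``chi2 = nan``
    and flagged degenerate.
    """
    d = len(transactions)
    bin_labels = {t.rhs_bin for t in transactions}
    d_chi = d if config.chi2_d == "auto" else int(config.chi2_d)
    rules = []
    for itemset, cnt in itemsets.items():
        bins = itemset & bin_labels
        if len(bins) != 1 or len(itemset) < 2:
            continue
        rhs = next(iter(bins))
        lhs = itemset - {rhs}
        if config.max_lhs is not None and len(lhs) > config.max_lhs:
            continue
        coverage_cnt = itemsets[lhs]
        rhs_cnt = itemsets.get(frozenset([rhs]), 0)
        support = cnt / d
        coverage = coverage_cnt / d
        confidence = cnt / coverage_cnt
        lift = confidence * d / rhs_cnt
        if confidence < config.min_confidence:
            continue
        degenerate = False
        try:
            chi2 = chi_squared_eq5(support, confidence, lift, d_chi)
        except DegenerateRuleError:
            chi2, degenerate = float("nan"), True
            logger.warning("degenerate rule %s => %s flagged (chi2 undefined)", sorted(lhs), rhs)
        rules.append(
            AssociationRule(
                lhs=lhs,
                rhs=rhs,
                support=support,
                confidence=confidence,
                coverage=coverage,
                lift=lift,
                count=cnt,
                chi2=chi2,
                significant=bool(chi2 > config.chi2_threshold),
                degenerate=degenerate,
            )
        )
    bin_order = {label: i for i, label in enumerate(sorted(bin_labels, key=_bin_sort_key))}
    rules.sort(
        key=lambda r: (bin_order[r.rhs], -r.confidence, -r.support, tuple(sorted(r.lhs)))
    )
    return rules


def _bin_sort_key(label: str):
    try:
        return (int(label.split("-")[0]), label)
    except ValueError:
        return (1 << 30, label)


def filter_rules(
    rules: Iterable[AssociationRule], config: MiningConfig = MiningConfig()
) -> list[AssociationRule]:
    """Retain rules with lift above ``lift_min`` (default: lift > 1).

    The chi-squared significance flag annotates rather than drops: reports
    conventionally list rules on both sides of the 3.84 threshold.
    """
    return [r for r in rules if r.lift > config.lift_min]


class AssociationRuleMiner(BaseEstimator):
    """Apriori rule miner with time-bin consequents and chi-squared scoring.

    Parameters mirror :class:`MiningConfig`.  After :meth:`fit` on a sequence
    of :class:`Transaction`:

    Attributes
    ----------
    itemsets_ : dict mapping frequent itemsets to absolute counts.
    rules_ : lift-filtered rules, deterministically ordered.
    n_transactions_ : the D underlying support and count.
    """

    def __init__(
        self,
        min_support: float = 5e-9,
        min_confidence: float = 5e-9,
        maxlen: Optional[int] = 3,
        max_lhs: Optional[int] = None,
        chi2_threshold: float = CHI2_5PCT,
        lift_min: float = 1.0,
        chi2_d: Union[int, str] = "auto",
    ):
        self.min_support = min_support
        self.min_confidence = min_confidence
        self.maxlen = maxlen
        self.max_lhs = max_lhs
        self.chi2_threshold = chi2_threshold
        self.lift_min = lift_min
        self.chi2_d = chi2_d

    def _config(self) -> MiningConfig:
        return MiningConfig(
            min_support=self.min_support,
            min_confidence=self.min_confidence,
            maxlen=self.maxlen,
            max_lhs=self.max_lhs,
            chi2_threshold=self.chi2_threshold,
            lift_min=self.lift_min,
            chi2_d=self.chi2_d,
        )

    def fit(self, X: Sequence[Transaction], y=None) -> "AssociationRuleMiner":
        config = self._config()
        self.n_transactions_ = len(X)
        self.itemsets_ = mine_frequent_itemsets(X, config)
        self.rules_ = filter_rules(derive_rules(self.itemsets_, X, config), config)
        return self

    def rules_frame(self, decimals: Optional[int] = 7) -> pd.DataFrame:
        return rules_to_frame(self.rules_, decimals=decimals)


def rules_to_frame(rules: Sequence[AssociationRule], decimals: Optional[int] = 7) -> pd.DataFrame:
    """Render rules as a report table (measures rounded to 7 decimals by
    default, mirroring the conventional arules print format)."""
    rows = []
    for r in rules:
        row = {
            "lhs": "{" + ", ".join(sorted(r.lhs)) + "}",
            "rhs": r.rhs,
            "support": r.support,
            "confidence": r.confidence,
            "coverage": r.coverage,
            "lift": r.lift,
            "count": r.count,
            "chi_squared": r.chi2,
            "significant_3p84": r.significant,
        }
        if decimals is not None:
            for k in ("support", "confidence", "coverage", "lift", "chi_squared"):
                row[k] = round(row[k], decimals) if not math.isnan(row[k]) else row[k]
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "lhs",
            "rhs",
            "support",
            "confidence",
            "coverage",
            "lift",
            "count",
            "chi_squared",
            "significant_3p84",
        ],
    )
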