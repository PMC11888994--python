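"""Apriori mining, rule measures and the measure-based chi-squared."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from jaderpv.errors import DegenerateRuleError, DomainError
from jaderpv.records import IndicationCategory as IC, Involvement, Outcome
from jaderpv.rule_mining import (
    AssociationRuleMiner,
    DEFAULT_BINNING,
    MiningConfig,
    TimeBinning,
    Transaction,
    bin_onset_days,
    build_transactions,
    chi_squared_eq5,
    derive_rules,
    filter_rules,
    mine_frequent_itemsets,
)

from conftest import BEVA, make_case


def _tx(i, items, rhs):
    return Transaction(case_id=f"T{i}", items=frozenset(items), rhs_bin=rhs)


class TestBinning:
    @pytest.mark.parametrize(
        "days,label",
        [(1, "1-100"), (100, "1-100"), (101, "101-200"), (1000, "901-1000"), (1095, "1001-1095")],
    )
    def test_edges(self, days, label):
        assert bin_onset_days(days) == label

    def test_beyond_last_edge_absent(self):
        assert bin_onset_days(1096) is None

    def test_below_one_is_domain_error(self):
        with pytest.raises(DomainError):
            bin_onset_days(0)

    def test_bins_cover_contiguously(self):
        labels = [bin_onset_days(d) for d in range(1, DEFAULT_BINNING.max_day + 1)]
        assert None not in labels
        assert len(set(labels)) == len(DEFAULT_BINNING.edges)


class TestBuildTransactions:
    def _case(self, onset, indications, extra_drugs=()):
        drugs = [(BEVA, Involvement.SUSPECT, "", "")] + [
            (d, Involvement.SUSPECT, "", "") for d in extra_drugs
        ]
        c = make_case("A", drugs=drugs, reactions=[("10018001", Outcome.RECOVERED, "")])
        return c.annotated(indications=frozenset(indications), onset_days=onset)

    def test_assembly(self):
        (t,) = build_transactions([self._case(46, {IC.NSCLC}, ["paclitaxel"])])
        assert t.items == frozenset({BEVA, "paclitaxel", "non-small cell lung cancer"})
        assert t.rhs_bin == "1-100"

    def test_out_of_range_onset_dropped(self):
        txs, stats = build_transactions([self._case(1200, {IC.NSCLC})], with_stats=True)
        assert txs == [] and stats["dropped"] == 1

    def test_concomitant_drugs_not_items(self):
        c = make_case(
            "A",
            drugs=[
                (BEVA, Involvement.SUSPECT, "", ""),
                ("loxoprofen", Involvement.CONCOMITANT, "", ""),
            ],
        ).annotated(indications=frozenset({IC.OTHER}), onset_days=10)
        (t,) = build_transactions([c])
        assert "loxoprofen" not in t.items

    def test_two_indications_both_labelled(self):
        (t,) = build_transactions([self._case(250, {IC.COLORECTAL, IC.OVARIAN})])
        assert {"colon and rectal cancer", "ovarian cancer"} <= t.items


def _brute_force_itemsets(transactions, min_support, maxlen):
    """Oracle: exhaustive enumeration of every itemset over the universe."""
    baskets = [t.items | {t.rhs_bin} for t in transactions]
    universe = sorted(set().union(*baskets))
    d = len(baskets)
    out = {}
    top = maxlen if maxlen is not None else len(universe)
    for k in range(1, top + 1):
        for combo in itertools.combinations(universe, k):
            s = frozenset(combo)
            cnt = sum(1 for b in baskets if s <= b)
            if cnt >= 1 and cnt / d >= min_support - 1e-12:
                out[s] = cnt
    return out


class TestApriori:
    def test_toy_example_matches_enumeration(self):
        txs = [
            _tx(0, {"a", "b"}, "1-100"),
            _tx(1, {"a"}, "1-100"),
            _tx(2, {"a", "b"}, "101-200"),
            _tx(3, {"b", "c"}, "101-200"),
        ]
        cfg = MiningConfig(min_support=0.5, maxlen=None)
        assert mine_frequent_itemsets(txs, cfg) == _brute_force_itemsets(txs, 0.5, None)

    def test_min_support_zero_yields_all_observed_itemsets(self):
        txs = [_tx(0, {"a", "b"}, "1-100"), _tx(1, {"c"}, "101-200")]
        cfg = MiningConfig(min_support=0.0, maxlen=None)
        mined = mine_frequent_itemsets(txs, cfg)
        assert frozenset({"a", "b", "1-100"}) in mined
        assert all(cnt >= 1 for cnt in mined.values())

    def test_support_monotonicity(self):
        rng = np.random.default_rng(6)
        items = list("abcdef")
        txs = [
            _tx(
                i,
                set(rng.choice(items, size=rng.integers(1, 5), replace=False)),
                ["1-100", "101-200", "201-300"][rng.integers(3)],
            )
            for i in range(40)
        ]
        mined = mine_frequent_itemsets(txs, MiningConfig(min_support=0.0, maxlen=4))
        for s, cnt in mined.items():
            if len(s) < 2:
                continue
            for item in s:
                assert cnt <= mined[s - {item}]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.sets(st.sampled_from("abcdefghij"), min_size=1, max_size=5),
                st.sampled_from(["1-100", "101-200"]),
            ),
            min_size=1,
            max_size=12,
        ),
        min_support=st.sampled_from([0.0, 0.1, 0.25, 0.5]),
        maxlen=st.sampled_from([2, 3, None]),
    )
    def test_equals_exhaustive_enumeration(self, data, min_support, maxlen):
        txs = [_tx(i, items, rhs) for i, (items, rhs) in enumerate(data)]
        cfg = MiningConfig(min_support=min_support, maxlen=maxlen)
        assert mine_frequent_itemsets(txs, cfg) == _brute_force_itemsets(
            txs, min_support, maxlen
        )


class TestDeriveRules:
    def _engineered(self):
        """Transactions realising a known 2x2 contingency: D = 1519, 64 with
        the antecedent, 881 with the 1-100 consequent, 55 joint."""
        lhs_items = {"paclitaxel", "non-small cell lung cancer"}
        txs = []
        i = 0
        for _ in range(55):
            txs.append(_tx(i := i + 1, lhs_items, "1-100"))
        for _ in range(9):
            txs.append(_tx(i := i + 1, lhs_items, "201-300"))
        for _ in range(826):
            txs.append(_tx(i := i + 1, {"filler"}, "1-100"))
        for _ in range(629):
            txs.append(_tx(i := i + 1, {"filler"}, "201-300"))
        return txs, frozenset(lhs_items)

    def test_measures_via_full_mining_path(self):
        txs, lhs = self._engineered()
        miner = AssociationRuleMiner(maxlen=3).fit(txs)
        assert miner.n_transactions_ == 1519
        rule = next(r for r in miner.rules_ if r.lhs == lhs and r.rhs == "1-100")
        assert round(rule.support, 7) == 0.0362080
        assert round(rule.confidence, 7) == 0.8593750
        assert round(rule.coverage, 7) == 0.0421330
        assert round(rule.lift, 7) == 1.4817147
        assert rule.count == 55

    def test_identities_hold_exactly(self):
        txs, _ = self._engineered()
        rules = derive_rules(
            mine_frequent_itemsets(txs, MiningConfig()), txs, MiningConfig()
        )
        for r in rules:
            assert r.confidence * r.coverage == pytest.approx(r.support, abs=1e-9)
            p_rhs = sum(1 for t in txs if t.rhs_bin == r.rhs) / len(txs)
            assert r.lift * p_rhs == pytest.approx(r.confidence, abs=1e-9)
            assert r.count == round(r.support * len(txs))

    def test_count_over_support_is_constant_d(self):
        txs, _ = self._engineered()
        miner = AssociationRuleMiner().fit(txs)
        ds = {round(r.count / r.support) for r in miner.rules_}
        assert ds == {1519}

    def test_measures_match_direct_counting(self):
        rng = np.random.default_rng(17)
        items = list("pqrs")
        txs = [
            _tx(i, set(rng.choice(items, rng.integers(1, 4), replace=False)),
                ["1-100", "101-200"][rng.integers(2)])
            for i in range(60)
        ]
        rules = derive_rules(
            mine_frequent_itemsets(txs, MiningConfig(maxlen=None)), txs, MiningConfig(maxlen=None)
        )
        baskets = [t.items | {t.rhs_bin} for t in txs]
        for r in rules:
            joint = sum(1 for b in baskets if r.lhs | {r.rhs} <= b)
            cover = sum(1 for b in baskets if r.lhs <= b)
            assert r.count == joint
            assert r.support == pytest.approx(joint / 60)
            assert r.confidence == pytest.approx(joint / cover)

    def test_rhs_alone_not_emitted(self):
        txs = [_tx(0, {"a"}, "1-100"), _tx(1, {"a"}, "1-100")]
        rules = derive_rules(mine_frequent_itemsets(txs, MiningConfig()), txs, MiningConfig())
        assert all(len(r.lhs) >= 1 for r in rules)
        assert all(r.rhs not in r.lhs for r in rules)

    def test_max_lhs_option(self):
        txs = [_tx(i, {"a", "b", "c", "d"}, "1-100") for i in range(4)] + [
            _tx(9, {"z"}, "101-200")
        ]
        rules = derive_rules(
            mine_frequent_itemsets(txs, MiningConfig(maxlen=None)),
            txs,
            MiningConfig(maxlen=None, max_lhs=2),
        )
        assert rules and all(len(r.lhs) <= 2 for r in rules)


class TestChiSquaredEq5:
    def test_independence_gives_zero(self):
        assert chi_squared_eq5(0.2, 0.5, 1.0, 100) == 0.0

    def test_pearson_equivalence_on_random_tables(self):
        """With D the transaction count, the measure-based statistic equals
        the classical Pearson chi-squared of the 2x2 table (1,000 tables)."""
        rng = np.random.default_rng(12345)
        checked = 0
        while checked < 1000:
            n11 = int(rng.integers(1, 50))
            n10 = int(rng.integers(1, 200))
            n01 = int(rng.integers(1, 200))
            n00 = int(rng.integers(1, 2000))
            d = n11 + n10 + n01 + n00
            support = n11 / d
            coverage = (n11 + n10) / d
            confidence = n11 / (n11 + n10)
            p_rhs = (n11 + n01) / d
            lift = confidence / p_rhs
            if confidence <= support or lift == confidence or lift == 1.0:
                continue
            ours = chi_squared_eq5(support, confidence, lift, d)
            pearson = chi2_contingency(
                [[n11, n10], [n01, n00]], correction=False
            ).statistic
            assert ours == pytest.approx(pearson, rel=1e-9)
            checked += 1

    def test_linear_in_d(self):
        one = chi_squared_eq5(0.03, 0.8, 1.5, 1000)
        two = chi_squared_eq5(0.03, 0.8, 1.5, 2000)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_degenerate_guards(self):
        with pytest.raises(DegenerateRuleError):
            chi_squared_eq5(0.5, 0.5, 1.2, 100)  # coverage = 1
        with pytest.raises(DegenerateRuleError):
            chi_squared_eq5(0.3, 0.5, 0.5, 100)  # consequent covers everything
        with pytest.raises(DomainError):
            chi_squared_eq5(0.0, 0.5, 1.2, 100)


class TestFilterRules:
    def _rule(self, lift, chi2):
        from jaderpv.rule_mining import AssociationRule

        return AssociationRule(
            lhs=frozenset({"a"}),
            rhs="1-100",
            support=0.1,
            confidence=0.5,
            coverage=0.2,
            lift=lift,
            count=10,
            chi2=chi2,
            significant=chi2 > 3.84,
        )

    def test_lift_below_one_removed(self):
        kept = filter_rules([self._rule(0.98, 5.0), self._rule(1.2, 5.0)])
        assert len(kept) == 1 and kept[0].lift == 1.2

    def test_chi2_flag_annotates_not_drops(self):
        kept = filter_rules([self._rule(1.2, 3.9), self._rule(1.3, 2.53)])
        assert len(kept) == 2
        assert kept[0].significant and not kept[1].significant


def test_custom_binning_must_be_contiguous():
    from jaderpv.errors import ConfigurationError

    with pytest.raises(ConfigurationError):
        TimeBinning(edges=((1, 100), (102, 200)))
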