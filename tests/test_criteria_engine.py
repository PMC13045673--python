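"""Criteria engine: Kleene connectives, rule trees, and the completion
semantics they must agree with."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import completion_oracle, make_record
from crseligible.criteria_engine import (AllOf, AnyOf, AtLeast, Flag,
                                         RuleSetSchemaError, Threshold,
                                         at_least_k, bundled_rulesets,
                                         epos_2023, euforea_2021,
                                         eval_epos2023, eval_euforea2021,
                                         eval_type2, evaluate,
                                         ruleset_from_json, ruleset_to_json,
                                         threshold_test)
from crseligible.tristate import (FALSE, TRUE, UNKNOWN, TriState, kleene_and,
                                  kleene_or, lift_bool)

T, F, U = TRUE, FALSE, UNKNOWN
tristates = st.sampled_from([T, F, U])


class TestConnectives:
    @pytest.mark.parametrize("a,b,expected", [
        (F, U, F), (U, F, F), (T, U, U), (U, T, U),
        (T, T, T), (T, F, F), (U, U, U),
    ])
    def test_kleene_and(self, a, b, expected):
        assert kleene_and(a, b) is expected

    @pytest.mark.parametrize("a,b,expected", [
        (T, U, T), (U, T, T), (F, U, U), (U, F, U),
        (F, F, F), (T, F, T), (U, U, U),
    ])
    def test_kleene_or(self, a, b, expected):
        assert kleene_or(a, b) is expected

    @given(a=tristates, b=tristates)
    def test_de_morgan_duality_via_commutativity(self, a, b):
        assert kleene_and(a, b) is kleene_and(b, a)
        assert kleene_or(a, b) is kleene_or(b, a)

    def test_tristate_not_boolean_coercible(self):
        with pytest.raises(TypeError):
            bool(TRUE)


class TestThresholdTest:
    def test_published_median_meets_snot22_cutoff(self):
        # cohort median SNOT-22 of 37 clears the 2021 cutoff of 35
        assert threshold_test(37, 35) is T

    @pytest.mark.parametrize("value,cutoff,expected", [
        (None, 35, U), (34, 35, F), (35, 35, T), (52.0, 52.0, T),
        (51.9, 52.0, F),
    ])
    def test_boundary_and_missing(self, value, cutoff, expected):
        assert threshold_test(value, cutoff) is expected

    def test_non_finite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            threshold_test(10, float("nan"))


class TestAtLeastK:
    @pytest.mark.parametrize("states,k,expected", [
        ([T, T, T, U, U], 3, T),          # quota already reached
        ([T, F, F, F, F], 3, F),          # at most 1 achievable
        ([T, U, U, F, F], 3, U),          # completions disagree (see below)
        ([U] * 5, 3, U),
        ([T, T, F, F, F], 2, T),
        ([F, F, F], 1, F),
    ])
    def test_contract(self, states, k, expected):
        assert at_least_k(states, k) is expected

    def test_unknown_case_matches_completion_enumeration(self):
        # [T, U, U, F, F] with k=3: completions of the two UNKNOWNs give
        # counts {1, 2, 2, 3} -> some reach 3, some do not.
        counts = {1 + u1 + u2 for u1 in (0, 1) for u2 in (0, 1)}
        assert any(c >= 3 for c in counts) and any(c < 3 for c in counts)
        assert at_least_k([T, U, U, F, F], 3) is U

    @pytest.mark.parametrize("k", [0, 6])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError):
            at_least_k([T, F, T, U, U], k)

    @given(states=st.lists(tristates, min_size=1, max_size=8),
           k=st.integers(1, 8))
    def test_equivalent_to_completion_contract(self, states, k):
        if k > len(states):
            return
        n_true = states.count(T)
        n_unknown = states.count(U)
        outcomes = {
            (n_true + flipped) >= k for flipped in range(n_unknown + 1)
        }
        expected = (T if outcomes == {True}
                    else F if outcomes == {False} else U)
        assert at_least_k(states, k) is expected


class TestType2:
    @pytest.mark.parametrize("bec,ige,expected", [
        (200, None, T),    # eosinophils alone settle it
        (100, None, U),    # low eosinophils, missing IgE
        (100, 50, F),
        (None, 150, T),
        (150, 0, T),       # inclusive cutoff
    ])
    def test_disjunction(self, bec, ige, expected):
        assert eval_type2(bec, ige) is expected


class TestEuforea2021:
    def test_history_and_severe_and_one_uncontrolled(self):
        rec = make_record(n_ess=1, n_scs_past_year=0, nps=5, snot22=40)
        assert eval_euforea2021(rec).overall is T

    def test_severe_gate_failure_is_decisive(self):
        rec = make_record(nps=3, n_ess=2, snot22=60, vas_los=90.0)
        assert eval_euforea2021(rec).overall is F

    def test_missing_nps_leaves_verdict_open(self):
        rec = make_record(nps=None, n_ess=1, snot22=60)
        assert eval_euforea2021(rec).overall is U

    def test_component_order_matches_documented_table(self):
        verdict = eval_euforea2021(make_record())
        assert tuple(verdict.components) == (
            "ess", "scs", "history", "nps", "snot22", "vas_tss", "vas_nb",
            "vas_los", "uncontrolled", "uncontrolled_severe", "overall")

    def test_evaluable_iff_determinate(self):
        for rec in [make_record(), make_record(nps=0),
                    make_record(n_ess=1, nps=5, snot22=50)]:
            v = eval_euforea2021(rec)
            assert v.evaluable == (v.overall is not U)


class TestEpos2023:
    def test_surgery_gate_failure_is_decisive(self):
        rec = make_record(n_ess=0, bec=400.0, ige=300.0, n_scs_past_year=3,
                          snot22=80, vas_los=90.0, asthma=True)
        assert eval_epos2023(rec).overall is F

    def test_three_true_leaves_suffice(self):
        rec = make_record(n_ess=2, bec=400.0, n_scs_past_year=2, snot22=45,
                          vas_los=None, asthma=False)
        assert eval_epos2023(rec).overall is T

    def test_two_true_two_unknown_is_open(self):
        # 2 TRUE (type2, asthma), 1 FALSE (scs), 2 UNKNOWN -> completions
        # reach 2, 3 or 4 TRUEs, straddling the quota of 3
        rec = make_record(n_ess=1, bec=400.0, asthma=True, n_scs_past_year=0,
                          snot22=None, vas_los=None)
        assert eval_epos2023(rec).overall is U

    def test_component_order_matches_documented_table(self):
        verdict = eval_epos2023(make_record())
        assert tuple(verdict.components) == (
            "ess", "bec", "ige", "type2", "scs", "snot22", "vas_los",
            "asthma", "uncontrolled_severe", "overall")

    def test_scs_strictness_2023_implies_2021(self):
        # any count meeting the 2023 leaf (>= 2) also meets the 2021 (>= 1)
        for n in range(0, 6):
            if threshold_test(n, 2) is T:
                assert threshold_test(n, 1) is T


# --- record strategies over the rule-relevant fields ----------------------

def _maybe(strategy):
    return st.one_of(st.none(), strategy)


record_strategy = st.builds(
    make_record,
    n_ess=_maybe(st.integers(0, 4)),
    n_scs_past_year=_maybe(st.integers(0, 4)),
    nps=_maybe(st.integers(0, 8)),
    snot22=_maybe(st.integers(0, 110)),
    vas_tss=_maybe(st.floats(0, 100)),
    vas_nb=_maybe(st.floats(0, 100)),
    vas_los=_maybe(st.floats(0, 100)),
    bec=_maybe(st.floats(0, 1500)),
    ige=_maybe(st.floats(0, 2000)),
    asthma=_maybe(st.booleans()),
)

# boundary-heavy records: values pinned at the cutoffs
boundary_strategy = st.builds(
    make_record,
    n_ess=_maybe(st.sampled_from([0, 1])),
    n_scs_past_year=_maybe(st.sampled_from([0, 1, 2])),
    nps=_maybe(st.sampled_from([3, 4])),
    snot22=_maybe(st.sampled_from([34, 35, 39, 40])),
    vas_tss=_maybe(st.sampled_from([49.9, 50.0])),
    vas_nb=_maybe(st.sampled_from([49.9, 50.0])),
    vas_los=_maybe(st.sampled_from([51.9, 52.0])),
    bec=_maybe(st.sampled_from([149.9, 150.0])),
    ige=_maybe(st.sampled_from([99.9, 100.0])),
    asthma=_maybe(st.booleans()),
)


# a deeper custom tree exercising all node types with 10 leaves
_DEEP_TREE = AllOf("root", (
    AnyOf("x1", (Threshold("l1", "snot22", 40), Threshold("l2", "nps", 4),
                 Flag("l3", "asthma"))),
    AtLeast("x2", 2, (
        Threshold("l4", "bec", 150), Threshold("l5", "ige", 100),
        Threshold("l6", "vas_los", 52),
        AllOf("x3", (Threshold("l7", "n_ess", 1),
                     Threshold("l8", "n_scs_past_year", 2))),
    )),
    AnyOf("x4", (Threshold("l9", "vas_tss", 50),
                 Threshold("l10", "vas_nb", 50))),
))


class TestCompletionOracleEquivalence:
    """Engine verdict == brute-force enumeration over all 2^u completions."""

    @given(record=st.one_of(record_strategy, boundary_strategy))
    def test_bundled_rulesets(self, record):
        for ruleset in bundled_rulesets().values():
            engine = evaluate(ruleset, record).overall
            assert engine is completion_oracle(ruleset.tree, record)

    @given(record=st.one_of(record_strategy, boundary_strategy))
    def test_deep_custom_tree_ten_leaves(self, record):
        engine = _DEEP_TREE.evaluate(record)
        assert engine is completion_oracle(_DEEP_TREE, record)

    def test_all_leaves_missing_both_rulesets(self):
        rec = make_record()
        for ruleset in bundled_rulesets().values():
            assert evaluate(ruleset, rec).overall is U


_RULE_FIELDS = ("n_ess", "n_scs_past_year", "nps", "snot22", "vas_tss",
                "vas_nb", "vas_los", "bec", "ige", "asthma")

_FILL_VALUES = {"n_ess": 2, "n_scs_past_year": 0, "nps": 6, "snot22": 10,
                "vas_tss": 80.0, "vas_nb": 20.0, "vas_los": 52.0,
                "bec": 149.0, "ige": 400.0, "asthma": True}


class TestInformationMonotonicity:
    """Filling in a missing field never flips a determinate verdict."""

    @given(record=record_strategy, data=st.data())
    def test_fill_one_missing_field(self, record, data):
        missing = [f for f in _RULE_FIELDS if getattr(record, f) is None]
        if not missing:
            return
        field = data.draw(st.sampled_from(missing))
        for ruleset in bundled_rulesets().values():
            before = evaluate(ruleset, record).overall
            filled = make_record(**{
                f: getattr(record, f) for f in _RULE_FIELDS})
            setattr(filled, field, _FILL_VALUES[field])
            after = evaluate(ruleset, filled).overall
            assert after.refines(before)

    @given(record=st.builds(
        make_record,
        n_ess=st.integers(0, 4), n_scs_past_year=st.integers(0, 4),
        nps=st.integers(0, 8), snot22=st.integers(0, 110),
        vas_tss=st.floats(0, 100), vas_nb=st.floats(0, 100),
        vas_los=st.floats(0, 100), bec=st.floats(0, 1500),
        ige=st.floats(0, 2000), asthma=st.booleans()))
    def test_total_on_complete_records(self, record):
        for ruleset in bundled_rulesets().values():
            verdict = evaluate(ruleset, record)
            assert verdict.overall is not U
            assert all(s is not U for s in verdict.components.values())


class TestRuleSetSerialization:
    def test_json_round_trip_preserves_tree(self):
        for ruleset in bundled_rulesets().values():
            restored = ruleset_from_json(ruleset_to_json(ruleset))
            assert restored.name == ruleset.name
            assert restored.tree == ruleset.tree

    def test_thresholds_reproduce_published_constants(self):
        t21 = euforea_2021().thresholds
        t23 = epos_2023().thresholds
        assert (t21["nps_min"], t21["snot22_min_2021"]) == (4, 35)
        assert (t21["vas_tss_min"], t21["vas_nb_min"]) == (50.0, 50.0)
        assert t21["vas_los_min"] == 52.0
        assert (t23["bec_min"], t23["ige_min"]) == (150.0, 100.0)
        assert (t23["scs_min_2021"], t23["scs_min_2023"]) == (1, 2)
        assert t23["snot22_min_2023"] == 40
        assert t23["k_of_n"] == (3, 5)

    def test_thresholds_read_only(self):
        with pytest.raises(TypeError):
            euforea_2021().thresholds["nps_min"] = 5

    @pytest.mark.parametrize("doc", [
        '{"name": "x"}',                                    # no tree
        '{"name": "x", "tree": {"type": "nope", "id": "a"}}',
        '{"name": "x", "tree": {"type": "threshold", "id": "a", '
        '"field": "asthma", "cutoff": 1}}',                 # bool field
        '{"name": "x", "tree": {"type": "at_least", "id": "a", "k": 3, '
        '"children": [{"type": "flag", "id": "b", "field": "asthma"}]}}',
        'not json',
    ])
    def test_schema_violations_rejected(self, doc):
        with pytest.raises(RuleSetSchemaError):
            ruleset_from_json(doc)

    def test_national_variant_expressible(self):
        # stricter national rule: NPS >= 5 and SNOT-22 >= 50
        doc = """{"name": "national", "tree": {"type": "all_of",
            "id": "overall", "children": [
            {"type": "threshold", "id": "nps", "field": "nps", "cutoff": 5},
            {"type": "threshold", "id": "snot22", "field": "snot22",
             "cutoff": 50}]}}"""
        ruleset = ruleset_from_json(doc)
        assert evaluate(ruleset, make_record(nps=4, snot22=60)).overall is F
        assert evaluate(ruleset, make_record(nps=6, snot22=60)).overall is T


class TestLiftBool:
    @pytest.mark.parametrize("value,expected", [
        (True, T), (False, F), (None, U),
    ])
    def test_lift(self, value, expected):
        assert lift_bool(value) is expected
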