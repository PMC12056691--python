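"""Actual-cause search: AC1, contingency matching, PC2 modes, ranking."""

from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coronacause import (
    Assignment,
    CausalTable,
    VariableSchema,
    brute_force_causes,
    candidate_assignments,
    conditional_probability,
    contingency_split,
    find_causes,
    pc2_holds,
)
from coronacause.causal_core import SchemaError
from coronacause.cause_search import UndefinedProbabilityError, ac1_holds
from coronacause.synthetic_data import confounded_effect

from conftest import T1_SCHEMA, binary_effect, random_binary_table, t1_effect


class TestToyT1:
    def test_candidate_assignments_sorted(self, toy_t1):
        assert candidate_assignments(toy_t1, "M") == [
            Assignment("M", "a"),
            Assignment("M", "b"),
        ]
        with pytest.raises(SchemaError):
            candidate_assignments(toy_t1, "C")

    def test_ac1(self, toy_t1):
        assert ac1_holds(toy_t1, Assignment("M", "a"), t1_effect)
        assert ac1_holds(toy_t1, Assignment("M", "b"), t1_effect)
        nothing = lambda r: False
        assert not ac1_holds(toy_t1, Assignment("M", "a"), nothing)

    def test_contingency_split(self, toy_t1):
        actual, by_ctx = contingency_split(toy_t1, Assignment("M", "a"))
        assert len(actual) == 2
        assert set(actual["M"]) == {"a"}
        assert set(by_ctx) == {(1,), (2,)}
        for ctx, cf in by_ctx.items():
            assert set(cf["M"]) == {"b"}
            assert set(cf["C"]) == {ctx[0]}

    @pytest.mark.parametrize("mode", ["pooled", "standardized"])
    def test_pc2_both_modes(self, toy_t1, mode):
        ok, p_act, p_cf = pc2_holds(toy_t1, Assignment("M", "a"), t1_effect, mode)
        assert (ok, p_act, p_cf) == (True, Fraction(1), Fraction(1, 2))
        ok, p_act, p_cf = pc2_holds(toy_t1, Assignment("M", "b"), t1_effect, mode)
        assert (ok, p_act, p_cf) == (False, Fraction(1, 2), Fraction(1))

    def test_conditional_probability(self, toy_t1):
        assert conditional_probability(toy_t1, Assignment("M", "a"), t1_effect) == 1
        assert conditional_probability(
            toy_t1, Assignment("M", "b"), t1_effect
        ) == Fraction(1, 2)

    def test_unique_cause(self, toy_t1):
        results = find_causes(toy_t1, t1_effect)
        causes = [r for r in results if r.is_cause]
        assert len(causes) == 1
        assert causes[0].assignment == Assignment("M", "a")
        assert causes[0].rank == 1
        assert causes[0].conditional_probability == 1
        assert causes[0].ac3 is True

    def test_effect_nowhere_means_no_cause(self, toy_t1):
        results = find_causes(toy_t1, lambda r: False)
        assert not any(r.is_cause for r in results)
        assert all(not r.ac1 for r in results)


class TestConfounder:
    """The season/ice-cream confound separates the two PC2 aggregations."""

    def test_pooled_is_fooled(self, toy_t2):
        ok, p_act, p_cf = pc2_holds(
            toy_t2, Assignment("IceCream", "hi"), confounded_effect, "pooled"
        )
        assert (ok, p_act, p_cf) == (True, Fraction(2, 3), Fraction(1, 3))

    def test_standardized_rejects(self, toy_t2):
        ok, p_act, p_cf = pc2_holds(
            toy_t2, Assignment("IceCream", "hi"), confounded_effect, "standardized"
        )
        assert (ok, p_act, p_cf) == (False, Fraction(2, 3), Fraction(2, 3))

    @pytest.mark.parametrize("mode", ["pooled", "standardized"])
    def test_season_is_cause_in_both_modes(self, toy_t2, mode):
        ok, p_act, p_cf = pc2_holds(
            toy_t2, Assignment("Season", "summer"), confounded_effect, mode
        )
        assert (ok, p_act, p_cf) == (True, Fraction(1), Fraction(0))

    def test_confounder_rejection_invariant(self, toy_t2):
        """If phi is conditionally independent of X given the context in the
        empirical table, standardized PC2 never certifies X as a cause."""
        results = find_causes(toy_t2, confounded_effect, variables=["IceCream"],
                              mode="standardized")
        assert not any(r.is_cause for r in results)


class TestDegenerateAndLocality:
    def test_single_valued_variable_has_no_counterfactual(self):
        df = pd.DataFrame({"C": [1, 2], "M": ["a", "a"], "y": [1.0, 1.0]})
        table = CausalTable(T1_SCHEMA, df)
        ok, p_act, p_cf = pc2_holds(table, Assignment("M", "a"), t1_effect)
        assert (ok, p_act, p_cf) == (False, Fraction(1), None)
        [res] = find_causes(table, t1_effect)
        assert res.p_counterfactual is None and not res.is_cause

    def test_zero_occurrence_probability_undefined(self, toy_t1):
        with pytest.raises((UndefinedProbabilityError, SchemaError)):
            conditional_probability(toy_t1, Assignment("M", "zzz"), t1_effect)

    def test_new_context_under_other_value_is_inert(self, toy_t1):
        """A record whose context never occurs in the actual world of M<-a
        changes nothing about M<-a's verdict (locality)."""
        before = [r for r in find_causes(toy_t1, t1_effect)
                  if r.assignment.value == "a"][0]
        df = pd.concat(
            [toy_t1.data,
             pd.DataFrame({"C": [99], "M": ["b"], "y": [0.0]})],
            ignore_index=True,
        )
        bigger = CausalTable(T1_SCHEMA, df)
        after = [r for r in find_causes(bigger, t1_effect)
                 if r.assignment.value == "a"][0]
        assert (before.p_actual, before.p_counterfactual, before.pc2) == (
            after.p_actual, after.p_counterfactual, after.pc2
        )
        # ... and it does not enter either side of the contingency split
        _, by_ctx = contingency_split(bigger, Assignment("M", "a"))
        assert (99,) not in by_ctx


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["pooled", "standardized"])
    def test_random_tables_match_oracle(self, mode):
        for seed in range(30):
            table = random_binary_table(seed)
            fast = find_causes(table, binary_effect, mode=mode)
            slow = brute_force_causes(table, binary_effect, mode=mode)
            assert fast == slow, f"seed {seed} diverged in mode {mode}"

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), mode=st.sampled_from(["pooled", "standardized"]))
    def test_property_oracle_equivalence(self, seed, mode):
        table = random_binary_table(seed)
        assert find_causes(table, binary_effect, mode=mode) == brute_force_causes(
            table, binary_effect, mode=mode
        )

    def test_balanced_design_modes_agree(self):
        """One record per (context, candidate value): pooled p_cf equals the
        standardized mixture for every assignment."""
        for seed in range(10):
            table = random_binary_table(seed)  # full factorial -> balanced
            pooled = find_causes(table, binary_effect, mode="pooled")
            standard = find_causes(table, binary_effect, mode="standardized")
            by_val = lambda rs: {r.assignment.value: r for r in rs}
            p, s = by_val(pooled), by_val(standard)
            for v in p:
                assert p[v].p_counterfactual == s[v].p_counterfactual
                assert p[v].pc2 == s[v].pc2


class TestRankingDeterminism:
    def test_tie_break_is_lexicographic(self):
        """Identical probabilities and support: values order alphabetically."""
        df = pd.DataFrame(
            {
                "C": [1, 1, 2, 2, 1, 2],
                "M": ["b", "a", "b", "a", "c", "c"],
                "y": [1.0, 1.0, 1.0, 1.0, 0.0, 0.0],
            }
        )
        table = CausalTable(T1_SCHEMA, df)
        results = find_causes(table, t1_effect, mode="standardized")
        causes = [r for r in results if r.is_cause]
        assert [r.assignment.value for r in causes] == ["a", "b"]
        assert [r.rank for r in causes] == [1, 2]

    def test_repeated_runs_identical(self, toy_t1):
        assert find_causes(toy_t1, t1_effect) == find_causes(toy_t1, t1_effect)
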