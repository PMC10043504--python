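import itertools

import pytest
from hypothesis import given, settings, strategies as st

from progmetrics.decision import Status
from progmetrics.rules import (
    And,
    MetricLeaf,
    Or,
    RuleParseError,
    builtin_rules,
    evaluate_rule,
    load_rules_file,
    parse_rule,
    rule_leaves,
    serialize_rule,
)

P, S, U = Status.PROGRESSING, Status.STABLE, Status.INELIGIBLE


class TestParse:
    def test_inferior_ss_expression(self):
        tree = parse_rule("TI_small AND (TI_GCL OR I_GCL)")
        assert tree == And(
            (MetricLeaf("TI_small"), Or((MetricLeaf("TI_GCL"), MetricLeaf("I_GCL"))))
        )

    def test_single_leaf(self):
        assert parse_rule("G_small") == MetricLeaf("G_small")

    def test_operators_case_insensitive_and_precedence(self):
        # AND binds tighter than OR
        tree = parse_rule("G_small or TI_small and TI_GCL")
        assert tree == Or(
            (MetricLeaf("G_small"), And((MetricLeaf("TI_small"), MetricLeaf("TI_GCL"))))
        )

    def test_unknown_metric_token_with_position(self):
        with pytest.raises(RuleParseError, match="BOGUS"):
            parse_rule("G_small AND BOGUS")

    def test_unbalanced_parentheses(self):
        with pytest.raises(RuleParseError, match="parenthes"):
            parse_rule("(G_small AND TI_small")
        with pytest.raises(RuleParseError):
            parse_rule("G_small) OR TI_small")

    def test_empty_expression(self):
        with pytest.raises(RuleParseError):
            parse_rule("   ")


class TestSerialize:
    def test_ss_canonical_form(self):
        ss = builtin_rules()["SS"]
        assert serialize_rule(ss) == (
            "(TI_small AND (TI_GCL OR I_GCL)) OR (TS_small AND (TS_GCL OR S_GCL))"
        )

    def test_round_trip_builtins(self):
        for name, rule in builtin_rules().items():
            assert parse_rule(serialize_rule(rule)) == rule


_leaf = st.sampled_from(["G_small", "TI_small", "TI_GCL", "I_GCL", "MD_24"]).map(MetricLeaf)


def _tree_strategy():
    return st.recursive(
        _leaf,
        lambda children: st.tuples(
            st.sampled_from([And, Or]), st.lists(children, min_size=2, max_size=3)
        ).map(lambda t: t[0](tuple(t[1]))),
        max_leaves=8,
    )


class TestRoundTripProperty:
    @settings(max_examples=100, derandomize=True)
    @given(_tree_strategy())
    def test_parse_serialize_round_trip(self, tree):
        assert parse_rule(serialize_rule(tree)) == tree


def _kleene_oracle(rule, assignment):
    """Independent three-valued evaluator: False < Unknown < True as 0 < 0.5 < 1."""
    order = {S: 0.0, U: 0.5, P: 1.0}

    def val(node):
        if isinstance(node, MetricLeaf):
            return order[assignment[node.metric]]
        vals = [val(c) for c in node.children]
        return min(vals) if isinstance(node, And) else max(vals)

    v = val(rule)
    return {0.0: Status.STABLE, 0.5: Status.UNDETERMINED, 1.0: Status.PROGRESSING}[v]


class TestEvaluate:
    def test_inferior_ss_fires_on_partial_gcl_agreement(self):
        rule = builtin_rules()["InferiorSS"]
        statuses = {"TI_small": P, "I_GCL": P, "TI_GCL": S}
        assert evaluate_rule(rule, statuses) == Status.PROGRESSING

    def test_all_stable_is_stable(self):
        rule = builtin_rules()["SS"]
        statuses = {m: S for m in rule_leaves(rule)}
        assert evaluate_rule(rule, statuses) == Status.STABLE

    def test_unknown_propagation(self):
        rule = builtin_rules()["InferiorSS"]
        statuses = {"TI_small": P, "I_GCL": U, "TI_GCL": U}
        assert evaluate_rule(rule, statuses) == Status.UNDETERMINED

    def test_missing_as_stable_forces_binary(self):
        rule = builtin_rules()["InferiorSS"]
        statuses = {"TI_small": P, "I_GCL": U, "TI_GCL": U}
        assert evaluate_rule(rule, statuses, missing_as_stable=True) == Status.STABLE

    def test_and_false_dominates_unknown(self):
        rule = parse_rule("G_small AND TI_small")
        assert evaluate_rule(rule, {"G_small": S, "TI_small": U}) == Status.STABLE

    def test_or_true_dominates_unknown(self):
        rule = parse_rule("G_small OR TI_small")
        assert evaluate_rule(rule, {"G_small": P, "TI_small": U}) == Status.PROGRESSING

    @pytest.mark.parametrize("name", sorted(builtin_rules()))
    def test_truth_table_agreement_with_kleene_oracle(self, name):
        """Exhaustive 3^k agreement with an independent min/max evaluator."""
        rule = builtin_rules()[name]
        leaves = rule_leaves(rule)
        assert len(leaves) <= 10
        for combo in itertools.product((P, S, U), repeat=len(leaves)):
            assignment = dict(zip(leaves, combo))
            assert evaluate_rule(rule, assignment) == _kleene_oracle(rule, assignment)

    @settings(max_examples=150, derandomize=True)
    @given(
        _tree_strategy(),
        st.dictionaries(
            st.sampled_from(["G_small", "TI_small", "TI_GCL", "I_GCL", "MD_24"]),
            st.sampled_from([P, S, U]),
        ),
    )
    def test_monotone_in_components(self, tree, partial):
        """Flipping any component stable -> progressing never unflags the rule."""
        statuses = {m: S for m in rule_leaves(tree)} | partial
        before = evaluate_rule(tree, statuses)
        for m in rule_leaves(tree):
            if statuses[m] == S:
                bumped = dict(statuses) | {m: P}
                after = evaluate_rule(tree, bumped)
                if before == Status.PROGRESSING:
                    assert after == Status.PROGRESSING


class TestBuiltinRegistry:
    def test_named_rules_present(self):
        rules = builtin_rules()
        for name in ("InferiorSS", "SuperiorSS", "SS", "SF_global", "SF_sec"):
            assert name in rules

    def test_sf_sectoral_is_hemifield_matched(self):
        assert serialize_rule(builtin_rules()["SF_sec"]) == (
            "((TI_small AND (TI_GCL OR I_GCL)) AND (infMD_24 OR infMD_10))"
            " OR ((TS_small AND (TS_GCL OR S_GCL)) AND (supMD_24 OR supMD_10))"
        )

    def test_sf_global_combines_ss_with_global_mds(self):
        assert serialize_rule(builtin_rules()["SF_global"]) == (
            "((TI_small AND (TI_GCL OR I_GCL)) OR (TS_small AND (TS_GCL OR S_GCL)))"
            " AND (MD_24 OR MD_10)"
        )

    def test_all_leaves_resolve(self):
        from progmetrics.metrics import builtin_metrics

        reg = builtin_metrics()
        for rule in builtin_rules().values():
            for leaf in rule_leaves(rule):
                assert leaf in reg

    def test_table_pairings_present(self):
        rules = builtin_rules()
        for key in (
            "G_small OR G_MRW", "G_small AND G_MRW", "TI_small AND TI_MRW",
            "TS_small AND TS_MRW", "G_small AND G_GCL", "G_small OR G_GCL",
            "G_small AND MD_24", "G_GCL AND MD_10",
            "(G_small OR G_GCL) AND (MD_24 OR MD_10)",
            "(G_small AND G_GCL) AND (MD_24 AND MD_10)",
        ):
            assert key in rules


def test_load_rules_file(tmp_path):
    p = tmp_path / "rules.txt"
    p.write_text(
        "# custom combinations\n"
        "my_rule = G_small AND (TI_GCL OR I_GCL)\n"
        "other = MD_24 OR MD_10\n"
    )
    rules = load_rules_file(p)
    assert set(rules) == {"my_rule", "other"}
    assert rules["other"] == Or((MetricLeaf("MD_24"), MetricLeaf("MD_10")))
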