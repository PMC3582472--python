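"""Filter rules, chain combination semantics, actions, and the rule dialect."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ltrfam.filtering import (
    Action,
    Combinator,
    FilterRule,
    RuleChain,
    Scope,
    apply_chain,
    full_domain_set,
    load_rule_file,
    low_reference_coverage,
    make_rule,
    no_protein_domain,
)
from ltrfam.model import (
    Candidate,
    FeatureNode,
    LtrfamError,
    ParseError,
    Project,
    UNCLASSIFIED,
)


def _candidate(cid="c1", length=1000, domain_names=(), match_len=None):
    root = FeatureNode("LTR_retrotransposon", "seq0", 1, length, "+")
    root.add_child(FeatureNode("long_terminal_repeat", "seq0", 1, 100, "+"))
    root.add_child(
        FeatureNode("long_terminal_repeat", "seq0", length - 99, length, "+")
    )
    for i, name in enumerate(domain_names):
        root.add_child(
            FeatureNode(
                "protein_match",
                "seq0",
                150 + i * 120,
                150 + i * 120 + 99,
                "+",
                attributes={"name": name},
            )
        )
    if match_len is not None:
        root.add_child(
            FeatureNode(
                "nucleotide_match",
                "seq0",
                1,
                match_len,
                "+",
                attributes={"Target": "ref 1 %d +" % match_len},
            )
        )
    return Candidate(id=cid, root=root)


class TestBuiltinRules:
    def test_no_protein_domain_false_on_domain_carrier(self):
        assert no_protein_domain(_candidate(domain_names=("RVT_1",))) is False

    def test_no_protein_domain_true_without_domains(self):
        assert no_protein_domain(_candidate()) is True

    def test_no_protein_domain_agrees_with_count_oracle(self):
        rng = np.random.default_rng(3)
        for i in range(50):
            names = tuple(
                rng.choice(["RVT_1", "rve", "RNase_H"], size=rng.integers(0, 3))
            )
            cand = _candidate(cid=f"c{i}", domain_names=names)
            n_domains = sum(
                1 for n in cand.root.traverse() if n.so_type == "protein_match"
            )
            assert no_protein_domain(cand) == (n_domains == 0)

    @pytest.mark.parametrize(
        "match_len,expected",
        [(799, True), (800, False), (801, False)],
        ids=["just_below", "exactly_at", "just_above"],
    )
    def test_low_reference_coverage_boundary_inclusive(self, match_len, expected):
        cand = _candidate(length=1000, match_len=match_len)
        assert low_reference_coverage(cand, min_frac=0.8) is expected

    def test_low_reference_coverage_true_without_matches(self):
        assert low_reference_coverage(_candidate()) is True

    def test_full_domain_set_canonical_names(self):
        cand = _candidate(domain_names=("RVP", "RVT_1", "rve", "RNase_H"))
        assert full_domain_set(cand) is True

    def test_full_domain_set_missing_integrase(self):
        cand = _candidate(domain_names=("RVP", "RVT_1", "RNase_H"))
        assert full_domain_set(cand) is False

    def test_full_domain_set_no_domains(self):
        assert full_domain_set(_candidate()) is False


class TestChainSemantics:
    @given(
        truths=st.lists(st.booleans(), min_size=1, max_size=4),
        negs=st.lists(st.booleans(), min_size=4, max_size=4),
        use_all=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_chain_verdict_equals_truth_table(self, truths, negs, use_all):
        cand = _candidate()
        rules = [
            FilterRule(name=f"r{i}", predicate=(lambda c, v=v: v), negated=neg)
            for i, (v, neg) in enumerate(zip(truths, negs))
        ]
        chain = RuleChain(
            rules=rules,
            combinator=Combinator.ALL if use_all else Combinator.ANY,
        )
        effective = [v ^ n for v, n in zip(truths, negs)]
        expected = all(effective) if use_all else any(effective)
        assert chain.verdict(cand) == expected

    def test_double_negation_is_identity(self):
        cand = _candidate(domain_names=("RVT_1",))
        rule = make_rule("no_protein_domain")
        base = rule.verdict(cand)
        rule.negated = True
        negated = rule.verdict(cand)
        rule.negated = False
        assert rule.verdict(cand) == base
        assert negated != base

    def test_all_with_one_false_keeps_candidate(self):
        cand = _candidate(domain_names=("RVT_1",))
        chain = RuleChain(
            rules=[
                FilterRule(name="t", predicate=lambda c: True),
                make_rule("no_protein_domain"),  # False here
            ],
            combinator=Combinator.ALL,
        )
        assert chain.verdict(cand) is False


class TestApplyChain:
    def _project(self):
        project = Project()
        with_domain = _candidate("with_dom", domain_names=("RVT_1",))
        without = _candidate("no_dom")
        floating = _candidate("floating")
        for cand in (with_domain, without, floating):
            project.candidates[cand.id] = cand
        project.families = {"famA": ["with_dom", "no_dom"]}
        project.unclassified = ["floating"]
        return project

    def test_unclassify_or_delete_semantics(self):
        project = self._project()
        chain = RuleChain(rules=[make_rule("no_protein_domain")])
        result = apply_chain(project, chain)
        # family member without domains -> unclassified
        assert "no_dom" in project.unclassified
        # unclassified candidate without domains -> deleted from the project
        assert "floating" not in project.candidates
        assert result["deleted"] == ["floating"]
        # domain carrier untouched
        assert "with_dom" in project.families["famA"]

    def test_false_verdict_candidates_untouched(self):
        project = self._project()
        snapshot = copy.deepcopy(project.candidates["with_dom"].root)
        apply_chain(project, RuleChain(rules=[make_rule("no_protein_domain")]))
        assert project.candidates["with_dom"].root.equal_tree(snapshot)

    def test_move_to_new_family(self):
        project = self._project()
        chain = RuleChain(
            rules=[make_rule("no_protein_domain")],
            action=Action.MOVE_TO_NEW_FAMILY,
        )
        result = apply_chain(project, chain)
        assert result["new_family"] is not None
        assert sorted(project.families[result["new_family"]]) == [
            "floating",
            "no_dom",
        ]

    def test_family_scope(self):
        project = self._project()
        chain = RuleChain(
            rules=[make_rule("no_protein_domain")],
            scope=Scope.of_family("famA"),
        )
        apply_chain(project, chain)
        assert "floating" in project.candidates  # out of scope, untouched

    def test_empty_chain_errors(self):
        with pytest.raises(LtrfamError):
            apply_chain(self._project(), RuleChain(rules=[]))

    def test_unknown_family_scope_errors(self):
        chain = RuleChain(
            rules=[make_rule("no_protein_domain")], scope=Scope.of_family("nope")
        )
        with pytest.raises(LtrfamError):
            apply_chain(self._project(), chain)


class TestRuleFiles:
    def test_exists_negated_equals_builtin(self, tmp_path):
        path = tmp_path / "has_domain.rule"
        path.write_text(
            "# author: a@b.c\n# description: domain presence\n# version: 1.0\n"
            'exists(type == "protein_match")\n'
        )
        rule, warnings = load_rule_file(str(path))
        assert warnings == []
        assert rule.metadata["version"] == "1.0"
        rule.negated = True
        rng = np.random.default_rng(7)
        for i in range(100):
            names = tuple(
                rng.choice(["RVT_1", "rve"], size=rng.integers(0, 3))
            )
            cand = _candidate(cid=f"c{i}", domain_names=names)
            assert rule.verdict(cand) == no_protein_domain(cand)

    def test_malformed_expression_errors(self, tmp_path):
        path = tmp_path / "bad.rule"
        path.write_text("# version: 1\nexists(type ==\n")
        with pytest.raises(ParseError, match="syntax"):
            load_rule_file(str(path))

    def test_disallowed_construct_rejected(self, tmp_path):
        path = tmp_path / "evil.rule"
        path.write_text("__import__('os').system('true')\n")
        with pytest.raises(ParseError):
            load_rule_file(str(path))

    def test_missing_metadata_warns_with_defaults(self, tmp_path):
        path = tmp_path / "plain.rule"
        path.write_text("element_length > 500\n")
        rule, warnings = load_rule_file(str(path))
        assert len(warnings) == 3
        assert rule.metadata["author_contact"] == ""
        assert rule.verdict(_candidate(length=1000)) is True
        assert rule.verdict(_candidate(length=400)) is False

    def test_count_and_attr_accessors(self, tmp_path):
        path = tmp_path / "rt.rule"
        path.write_text(
            "# version: 1\n# author: x\n# description: two RT hits\n"
            'count(type == "protein_match" and attr("name") == "RVT_1") >= 2\n'
        )
        rule, _ = load_rule_file(str(path))
        assert rule.verdict(_candidate(domain_names=("RVT_1", "RVT_1"))) is True
        assert rule.verdict(_candidate(domain_names=("RVT_1", "rve"))) is False

    def test_match_coverage_expression(self, tmp_path):
        path = tmp_path / "cov.rule"
        path.write_text(
            "# version: 1\n# author: x\n# description: covered\n"
            "match_coverage() >= 0.8\n"
        )
        rule, _ = load_rule_file(str(path))
        assert rule.verdict(_candidate(length=1000, match_len=850)) is True
        assert rule.verdict(_candidate(length=1000, match_len=700)) is False
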