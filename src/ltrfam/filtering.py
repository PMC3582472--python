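"""Chainable boolean filtering rules over candidate feature trees.

A rule is a named, pure predicate Candidate -> bool; the convention is that
``True`` means the candidate is selected (filtered out).  Rules combine into
chains with ALL (boolean AND) / ANY (boolean OR) semantics and per-rule
negation, and drive one of two actions: withdrawing selected candidates to
the unclassified list (deleting them if already unclassified), or moving
them into a new family created on the fly.

User-defined rules are plain text files: a metadata header followed by an
expression in a small declarative dialect over the candidate-graph query
API — feature existence/count with per-node predicates over type, location,
strand, score and attributes, plus element length and reference-match
coverage.  Example::

    # author: curator@example.org
    # description: has at least one protein domain hit
    # version: 1.0
    exists(type == "protein_match")
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Optional

from .annotate import match_coverage
from .model import (
    Candidate,
    DOMAIN_TYPE,
    LtrfamError,
    ParseError,
    Project,
    ROOT_TYPE,
    UNCLASSIFIED,
)

#: default mapping of pHMM domain names to pol/gag functions
DEFAULT_FUNCTION_MAP = {
    "RVP": "AP",
    "RVP_2": "AP",
    "RVT_1": "RT",
    "RVT_2": "RT",
    "RVT_thumb": "RT",
    "RNase_H": "RH",
    "rve": "IN",
    "Integrase_Zn": "IN",
    "gag": "GAG",
    "Gag_p30": "GAG",
    "Gag_MA": "GAG",
    "Gag_p24": "GAG",
}


@dataclass
class FilterRule:
    name: str
    predicate: Callable[[Candidate], bool]
    metadata: dict = field(
        default_factory=lambda: {
            "author_contact": "",
            "description": "",
            "version": "",
        }
    )
    params: dict = field(default_factory=dict)
    negated: bool = False

    def verdict(self, candidate: Candidate) -> bool:
        return bool(self.predicate(candidate)) ^ self.negated


class Combinator(Enum):
    ALL = "all"
    ANY = "any"


class Action(Enum):
    UNCLASSIFY_OR_DELETE = "unclassify"
    MOVE_TO_NEW_FAMILY = "new-family"


@dataclass
class Scope:
    kind: str  # "all" | "family" | "selection"
    family: Optional[str] = None
    ids: Optional[list[str]] = None

    @classmethod
    def all(cls) -> "Scope":
        return cls(kind="all")

    @classmethod
    def of_family(cls, name: str) -> "Scope":
        return cls(kind="family", family=name)

    @classmethod
    def selection(cls, ids: Iterable[str]) -> "Scope":
        return cls(kind="selection", ids=list(ids))


@dataclass
class RuleChain:
    rules: list[FilterRule]
    combinator: Combinator = Combinator.ALL
    action: Action = Action.UNCLASSIFY_OR_DELETE
    scope: Scope = field(default_factory=Scope.all)

    def verdict(self, candidate: Candidate) -> bool:
        if not self.rules:
            raise LtrfamError("empty rule chain")
        verdicts = (rule.verdict(candidate) for rule in self.rules)
        return all(verdicts) if self.combinator is Combinator.ALL else any(verdicts)


def _resolve_scope(project: Project, scope: Scope) -> list[str]:
    if scope.kind == "all":
        return sorted(project.live_ids())
    if scope.kind == "family":
        if scope.family not in project.families:
            raise LtrfamError(f"unknown family {scope.family!r}")
        return list(project.families[scope.family])
    if scope.kind == "selection":
        for cid in scope.ids or []:
            if cid not in project.candidates:
                raise LtrfamError(f"unknown candidate {cid!r} in selection")
        return list(scope.ids or [])
    raise LtrfamError(f"unknown scope kind {scope.kind!r}")


def apply_chain(project: Project, chain: RuleChain) -> dict:
    """Evaluate the chain over its scope and apply the chain's action.

    Candidates with verdict False are untouched.  Returns a summary dict
    with ``selected``, ``kept``, ``deleted`` id lists and ``new_family``.
    """
    from .classification import delete_candidate, move_candidate

    if not chain.rules:
        raise LtrfamError("empty rule chain")
    ids = _resolve_scope(project, chain.scope)
    selected, kept = [], []
    for cid in ids:
        if chain.verdict(project.candidates[cid]):
            selected.append(cid)
        else:
            kept.append(cid)
    deleted: list[str] = []
    new_family: Optional[str] = None
    if chain.action is Action.MOVE_TO_NEW_FAMILY:
        if selected:
            n = 0
            while f"filtered_{n}" in project.families:
                n += 1
            new_family = f"filtered_{n}"
            for cid in selected:
                move_candidate(project, cid, new_family)
    else:
        for cid in selected:
            if project.container_of(cid) == UNCLASSIFIED:
                delete_candidate(project, cid)
                deleted.append(cid)
            else:
                move_candidate(project, cid, UNCLASSIFIED)
    return {
        "selected": selected,
        "kept": kept,
        "deleted": deleted,
        "new_family": new_family,
    }


# -- built-in rule catalogue --------------------------------------------------


def no_protein_domain(candidate: Candidate) -> bool:
    """True iff the candidate tree contains no protein_match feature."""
    return all(n.so_type != DOMAIN_TYPE for n in candidate.root.traverse())


def low_reference_coverage(candidate: Candidate, min_frac: float = 0.8) -> bool:
    """True iff no reference match covers >= min_frac of the element length.

    The comparison is inclusive: coverage exactly at the threshold counts as
    covered.  Non-element trees are ignored (False) so the rule can run over
    mixed annotation sets.
    """
    if candidate.root.so_type != ROOT_TYPE:
        return False
    return match_coverage(candidate) < min_frac


def full_domain_set(
    candidate: Candidate,
    function_map: Optional[dict[str, str]] = None,
    required: Iterable[str] = ("AP", "RT", "RH", "IN"),
    _warned: set = set(),
) -> bool:
    """True iff every required pol function has >= 1 mapped protein_match.

    This is a selector rule: combined with the new-family action it gathers
    candidates carrying a complete protease/RT/RNaseH/integrase complement.
    Unmapped domain names count as OTHER (warned once per name).
    """
    fmap = DEFAULT_FUNCTION_MAP if function_map is None else function_map
    present: set[str] = set()
    for node in candidate.root.traverse():
        if node.so_type != DOMAIN_TYPE:
            continue
        name = node.attributes.get("name", "")
        func = fmap.get(name)
        if func is None:
            if name not in _warned:
                _warned.add(name)
                import sys

                print(
                    f"ltrfam: warning: unmapped domain name {name!r} "
                    "treated as OTHER",
                    file=sys.stderr,
                )
            func = "OTHER"
        present.add(func)
    return all(f in present for f in required)


def make_rule(name: str, **params) -> FilterRule:
    """Instantiate a built-in rule by name."""
    catalogue = {
        "no_protein_domain": (
            no_protein_domain,
            "selects candidates without any protein domain hit",
        ),
        "low_reference_coverage": (
            lambda c: low_reference_coverage(
                c, min_frac=float(params.get("min_frac", 0.8))
            ),
            "selects candidates not covered by a long reference match",
        ),
        "full_domain_set": (
            lambda c: full_domain_set(c, function_map=params.get("function_map")),
            "selects candidates with a full AP/RT/RH/IN domain complement",
        ),
    }
    if name not in catalogue:
        raise LtrfamError(f"unknown built-in rule {name!r}")
    predicate, description = catalogue[name]
    return FilterRule(
        name=name,
        predicate=predicate,
        metadata={"author_contact": "ltrfam", "description": description, "version": "1"},
        params=dict(params),
    )


# -- rule file dialect ---------------------------------------------------------

_ALLOWED_NODES = (
    ast.Expression,
    ast.BoolOp,
    ast.And,
    ast.Or,
    ast.UnaryOp,
    ast.Not,
    ast.USub,
    ast.Compare,
    ast.Eq,
    ast.NotEq,
    ast.Lt,
    ast.LtE,
    ast.Gt,
    ast.GtE,
    ast.Call,
    ast.Name,
    ast.Load,
    ast.Constant,
    ast.BinOp,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
)

_NODE_FUNCS = {"exists", "count"}
_PLAIN_FUNCS = {"match_coverage", "attr"}
_CAND_NAMES = {"element_length"}
_NODE_NAMES = {"type", "length", "start", "end", "strand", "seqid", "score"}


def _check_tree(tree: ast.AST) -> None:
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ParseError(
                f"rule expression: construct {type(node).__name__} not allowed"
            )
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in (
                _NODE_FUNCS | _PLAIN_FUNCS
            ):
                raise ParseError("rule expression: unknown function call")


class _ExpressionRule:
    """Compiled rule expression; evaluated over one candidate at a time."""

    def __init__(self, expression: str):
        try:
            tree = ast.parse(expression, mode="eval")
        except SyntaxError as exc:
            raise ParseError(
                f"rule syntax error at line {exc.lineno}, column {exc.offset}: "
                f"{exc.msg}"
            ) from exc
        _check_tree(tree)
        self.tree = tree
        self.expression = expression

    def __call__(self, candidate: Candidate) -> bool:
        return bool(self._eval(self.tree.body, candidate, None))

    def _eval(self, node: ast.AST, cand: Candidate, feat):
        if isinstance(node, ast.Constant):
            return node.value
        if isinstance(node, ast.Name):
            return self._name(node.id, cand, feat)
        if isinstance(node, ast.BoolOp):
            vals = (self._eval(v, cand, feat) for v in node.values)
            return all(vals) if isinstance(node.op, ast.And) else any(vals)
        if isinstance(node, ast.UnaryOp):
            val = self._eval(node.operand, cand, feat)
            return (not val) if isinstance(node.op, ast.Not) else -val
        if isinstance(node, ast.BinOp):
            left = self._eval(node.left, cand, feat)
            right = self._eval(node.right, cand, feat)
            ops = {
                ast.Add: lambda a, b: a + b,
                ast.Sub: lambda a, b: a - b,
                ast.Mult: lambda a, b: a * b,
                ast.Div: lambda a, b: a / b,
            }
            return ops[type(node.op)](left, right)
        if isinstance(node, ast.Compare):
            left = self._eval(node.left, cand, feat)
            for op, comp in zip(node.ops, node.comparators):
                right = self._eval(comp, cand, feat)
                ops = {
                    ast.Eq: lambda a, b: a == b,
                    ast.NotEq: lambda a, b: a != b,
                    ast.Lt: lambda a, b: a < b,
                    ast.LtE: lambda a, b: a <= b,
                    ast.Gt: lambda a, b: a > b,
                    ast.GtE: lambda a, b: a >= b,
                }
                if not ops[type(op)](left, right):
                    return False
                left = right
            return True
        if isinstance(node, ast.Call):
            fname = node.func.id  # type: ignore[attr-defined]
            if fname in _NODE_FUNCS:
                if len(node.args) != 1:
                    raise LtrfamError(f"{fname}() takes exactly one predicate")
                hits = sum(
                    1
                    for n in cand.root.traverse()
                    if self._eval(node.args[0], cand, n)
                )
                return (hits > 0) if fname == "exists" else hits
            if fname == "match_coverage":
                return match_coverage(cand)
            if fname == "attr":
                key = self._eval(node.args[0], cand, feat)
                holder = feat if feat is not None else cand.root
                return holder.attributes.get(str(key), "")
        raise LtrfamError(f"cannot evaluate {ast.dump(node)}")

    def _name(self, name: str, cand: Candidate, feat):
        if name in _CAND_NAMES:
            return cand.element_length
        if name in _NODE_NAMES:
            if feat is None:
                raise LtrfamError(
                    f"{name!r} is only available inside exists()/count()"
                )
            if name == "type":
                return feat.so_type
            if name == "length":
                return feat.length
            if name == "score":
                return feat.score if feat.score is not None else math.nan
            return getattr(feat, name)
        if name in ("true", "false", "True", "False"):
            return name.lower() == "true"
        raise LtrfamError(f"unknown name {name!r} in rule expression")


def load_rule_file(path: str) -> tuple[FilterRule, list[str]]:
    """Load a rule from a text file: ``# key: value`` metadata header lines
    followed by one expression (may span lines).  Returns (rule, warnings)."""
    warnings: list[str] = []
    metadata = {"author_contact": "", "description": "", "version": ""}
    name = None
    expr_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key = key.strip().lower().replace(" ", "_")
                    if key in ("author", "author_contact"):
                        metadata["author_contact"] = value.strip()
                    elif key in metadata:
                        metadata[key] = value.strip()
                    elif key == "name":
                        name = value.strip()
                continue
            if stripped:
                expr_lines.append(stripped)
    for key, value in metadata.items():
        if not value:
            warnings.append(f"rule file {path}: missing metadata field {key!r}")
    if not expr_lines:
        raise ParseError(f"rule file {path}: no expression found")
    import os

    predicate = _ExpressionRule(" ".join(expr_lines))
    rule = FilterRule(
        name=name or os.path.splitext(os.path.basename(path))[0],
        predicate=predicate,
        metadata=metadata,
        params={},
    )
    return rule, warnings
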