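"""Boolean combinations of per-metric decisions (S-S and S-F composites).

Structure–structure (S-S) agreement requires concordant statistical
progression in a cpRNFL sector and a topographically matching macular GCL
region: the inferior variant is ``TI_small AND (TI_GCL OR I_GCL)``, the
superior variant ``TS_small AND (TS_GCL OR S_GCL)``, and the S-S metric is
their OR.  Structure–function (S-F) composites additionally require
visual-field MD progression, either globally or in the matching hemifield.

Rules form a small grammar — ``expr := term (OR term)*;
term := factor (AND factor)*; factor := METRIC | "(" expr ")"`` — with AND
binding tighter than OR.  Evaluation uses Kleene three-valued logic:
progressing = true, stable = false, ineligible/undetermined = unknown.
AND is false if any input is false, else unknown if any input is unknown;
OR is true if any input is true, else unknown if any input is unknown.
Unknown results surface as an ``undetermined`` decision (use
``missing_as_stable`` to force binary behavior).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Union

from .decision import Decision, DecisionTable, Status
from .metrics import builtin_metrics


class RuleParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class MetricLeaf:
    metric: str


@dataclass(frozen=True)
class And:
    children: tuple["Rule", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["Rule", ...]


Rule = Union[MetricLeaf, And, Or]

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z_][A-Za-z0-9_\-]*)")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            if expression[pos:].strip() == "":
                break
            raise RuleParseError(f"unexpected character {expression[pos]!r}", pos)
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_rule(expression: str) -> Rule:
    """Parse a rule expression into its tree; AND binds tighter than OR."""
    tokens = _tokenize(expression)
    if not tokens:
        raise RuleParseError("empty rule expression", 0)
    registry = builtin_metrics()
    idx = 0

    def peek() -> tuple[str, int] | None:
        return tokens[idx] if idx < len(tokens) else None

    def advance() -> tuple[str, int]:
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def parse_expr() -> Rule:
        terms = [parse_term()]
        while peek() is not None and peek()[0].upper() == "OR":
            advance()
            terms.append(parse_term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_term() -> Rule:
        factors = [parse_factor()]
        while peek() is not None and peek()[0].upper() == "AND":
            advance()
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_factor() -> Rule:
        tok = peek()
        if tok is None:
            raise RuleParseError("unexpected end of expression", len(expression))
        text, pos = advance()
        if text == "(":
            inner = parse_expr()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise RuleParseError("unbalanced parentheses", pos)
            advance()
            return inner
        if text == ")":
            raise RuleParseError("unbalanced parentheses", pos)
        if text.upper() in ("AND", "OR"):
            raise RuleParseError(f"operator {text!r} where a metric was expected", pos)
        if text not in registry:
            raise RuleParseError(f"unknown metric token {text!r}", pos)
        return MetricLeaf(text)

    tree = parse_expr()
    if idx != len(tokens):
        raise RuleParseError(f"trailing input {tokens[idx][0]!r}", tokens[idx][1])
    return tree


def serialize_rule(rule: Rule) -> str:
    """Canonical text form; non-leaf children are parenthesized."""

    def render(node: Rule) -> str:
        if isinstance(node, MetricLeaf):
            return node.metric
        op = " AND " if isinstance(node, And) else " OR "
        parts = [
            render(c) if isinstance(c, MetricLeaf) else f"({render(c)})"
            for c in node.children
        ]
        return op.join(parts)

    return render(rule)


def rule_leaves(rule: Rule) -> list[str]:
    """Distinct metric names referenced by a rule, in first-seen order."""
    out: list[str] = []

    def walk(node: Rule) -> None:
        if isinstance(node, MetricLeaf):
            if node.metric not in out:
                out.append(node.metric)
        else:
            for c in node.children:
                walk(c)

    walk(rule)
    return out


def evaluate_rule(
    rule: Rule,
    decisions: Mapping[str, Status],
    *,
    missing_as_stable: bool = False,
) -> Status:
    """Three-valued evaluation of a rule over one eye's per-metric statuses."""

    def value(node: Rule) -> bool | None:
        if isinstance(node, MetricLeaf):
            s = decisions.get(node.metric)
            if s is None or s in (Status.INELIGIBLE, Status.UNDETERMINED):
                return False if missing_as_stable else None
            return s == Status.PROGRESSING
        vals = [value(c) for c in node.children]
        if isinstance(node, And):
            if any(v is False for v in vals):
                return False
            if any(v is None for v in vals):
                return None
            return True
        if any(v is True for v in vals):
            return True
        if any(v is None for v in vals):
            return None
        return False

    v = value(rule)
    if v is None:
        return Status.UNDETERMINED
    return Status.PROGRESSING if v else Status.STABLE


def _named(expr: str) -> Rule:
    return parse_rule(expr)


INFERIOR_SS = "TI_small AND (TI_GCL OR I_GCL)"
SUPERIOR_SS = "TS_small AND (TS_GCL OR S_GCL)"
SS = f"({INFERIOR_SS}) OR ({SUPERIOR_SS})"
SF_GLOBAL = f"({SS}) AND (MD_24 OR MD_10)"
SF_SECTORAL = (
    f"(({INFERIOR_SS}) AND (infMD_24 OR infMD_10))"
    f" OR (({SUPERIOR_SS}) AND (supMD_24 OR supMD_10))"
)


def builtin_rules() -> dict[str, Rule]:
    """Named registry of the composite rules evaluated in the study tables.

    Includes the named S-S / S-F composites and every AND/OR pairing of the
    structure–structure and structure–function comparison tables; unnamed
    pairings are keyed by their expression text.
    """
    exprs: dict[str, str] = {
        # OCT–OCT pairings: cpRNFL with BMO-MRW
        "G_small OR G_MRW": "G_small OR G_MRW",
        "G_small AND G_MRW": "G_small AND G_MRW",
        "TI_small OR TI_MRW": "TI_small OR TI_MRW",
        "TI_small AND TI_MRW": "TI_small AND TI_MRW",
        "TS_small OR TS_MRW": "TS_small OR TS_MRW",
        "TS_small AND TS_MRW": "TS_small AND TS_MRW",
        # OCT–OCT pairings: cpRNFL with GCL
        "G_small AND G_GCL": "G_small AND G_GCL",
        "G_small OR G_GCL": "G_small OR G_GCL",
        "InferiorSS": INFERIOR_SS,
        "TI_small OR (TI_GCL OR I_GCL)": "TI_small OR (TI_GCL OR I_GCL)",
        "SuperiorSS": SUPERIOR_SS,
        "TS_small OR (TS_GCL OR S_GCL)": "TS_small OR (TS_GCL OR S_GCL)",
        "SS": SS,
        # Structure–function pairings
        "G_small AND MD_24": "G_small AND MD_24",
        "G_small OR MD_24": "G_small OR MD_24",
        "G_GCL AND MD_10": "G_GCL AND MD_10",
        "G_GCL OR MD_10": "G_GCL OR MD_10",
        "(G_small OR G_GCL) AND (MD_24 OR MD_10)": "(G_small OR G_GCL) AND (MD_24 OR MD_10)",
        "(G_small AND G_GCL) AND (MD_24 AND MD_10)": "(G_small AND G_GCL) AND (MD_24 AND MD_10)",
        "SF_global": SF_GLOBAL,
        "SF_sec": SF_SECTORAL,
    }
    return {name: _named(e) for name, e in exprs.items()}


def load_rules_file(source) -> dict[str, Rule]:
    """Read user rules, one ``name = expression`` per line; '#' comments."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    out: dict[str, Rule] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"rules file line {lineno}: expected 'name = expression'")
        name, expr = line.split("=", 1)
        out[name.strip()] = parse_rule(expr.strip())
    return out


def evaluate_rules_all(
    table: DecisionTable,
    rules: Mapping[str, Rule],
    *,
    missing_as_stable: bool = False,
) -> DecisionTable:
    """Evaluate each rule per eye over an event or trend decision table."""
    out: DecisionTable = {}
    for eye_id, decs in table.items():
        statuses = {m: d.status for m, d in decs.items()}
        out[eye_id] = {
            name: Decision(
                eye_id,
                name,
                evaluate_rule(rule, statuses, missing_as_stable=missing_as_stable),
            )
            for name, rule in rules.items()
        }
    return out
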