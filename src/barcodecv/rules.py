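"""Declarative identity/consensus discard rules and the
Local-then-World cascade.

A rule is a boolean *discard* expression over the two scores, written
in a small grammar: comparators ``< <= > >=``, operators ``and``,
``or``, ``not`` and parentheses, variables ``identity`` and
``consensus`` (e.g. ``"consensus < 40 and identity < 98.5"``).  A rule
set is an ordered cascade of (table, rule) stages: a query keeps the
first stage's assignment that its rule does not discard; a query whose
Local-DB assignment is discarded falls through to the World-DB stage;
a query failing every stage ends up unassigned.  Queries that were
already unassigned at a stage pass through as unassigned.

The shipped default rule sets are calibrated genus- and species-level
thresholds for the ITS2 and rbcL barcodes (the genus rules use the
World DB only).  The printed rbcL species Local rule contains the
vacuous clause ``identity <= 100``; it is encoded verbatim, and a
strict-inequality reading ships as the named variant
``rbcl-species-strict``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "parse_rule",
    "FilterRule",
    "RuleSet",
    "DEFAULT_RULE_SETS",
    "apply_rules",
    "summarize_filtering",
]


# ---------------------------------------------------------------------------
# Expression grammar

class RuleSyntaxError(ValueError):
    """Raised when a rule expression cannot be parsed."""


VARIABLES = ("identity", "consensus")
_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+(?:\.\d+)?)|(?P<op><=|>=|==|<|>)|(?P<lp>\()|(?P<rp>\))"
    r"|(?P<word>[A-Za-z_]+))"
)


@dataclass(frozen=True)
class Comparison:
    var: str
    op: str
    value: float

    def evaluate(self, env: Mapping[str, float]) -> bool:
        x = env[self.var]
        return {
            "<": x < self.value,
            "<=": x <= self.value,
            ">": x > self.value,
            ">=": x >= self.value,
            "==": x == self.value,
        }[self.op]

    def __str__(self) -> str:
        return f"{self.var} {self.op} {self.value:g}"


@dataclass(frozen=True)
class And:
    left: "Expr"
    right: "Expr"

    def evaluate(self, env: Mapping[str, float]) -> bool:
        return self.left.evaluate(env) and self.right.evaluate(env)

    def __str__(self) -> str:
        return f"({self.left} and {self.right})"


@dataclass(frozen=True)
class Or:
    left: "Expr"
    right: "Expr"

    def evaluate(self, env: Mapping[str, float]) -> bool:
        return self.left.evaluate(env) or self.right.evaluate(env)

    def __str__(self) -> str:
        return f"({self.left} or {self.right})"


@dataclass(frozen=True)
class Not:
    operand: "Expr"

    def evaluate(self, env: Mapping[str, float]) -> bool:
        return not self.operand.evaluate(env)

    def __str__(self) -> str:
        return f"(not {self.operand})"


Expr = Comparison | And | Or | Not


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise RuleSyntaxError(f"bad token at {text[pos:]!r}")
            break
        tokens.append(m.group().strip())
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent: or > and > not > comparison/parens."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise RuleSyntaxError(f"trailing tokens at {self.peek()!r}")
        return expr

    def parse_or(self) -> Expr:
        left = self.parse_and()
        while self.peek() == "or":
            self.take()
            left = Or(left, self.parse_and())
        return left

    def parse_and(self) -> Expr:
        left = self.parse_not()
        while self.peek() == "and":
            self.take()
            left = And(left, self.parse_not())
        return left

    def parse_not(self) -> Expr:
        if self.peek() == "not":
            self.take()
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> Expr:
        tok = self.take()
        if tok == "(":
            expr = self.parse_or()
            if self.take() != ")":
                raise RuleSyntaxError("missing closing parenthesis")
            return expr
        if tok not in VARIABLES:
            raise RuleSyntaxError(f"expected variable, got {tok!r}")
        op = self.take()
        if op not in ("<", "<=", ">", ">=", "=="):
            raise RuleSyntaxError(f"expected comparator, got {op!r}")
        val = self.take()
        try:
            value = float(val)
        except ValueError:
            raise RuleSyntaxError(f"expected number, got {val!r}") from None
        return Comparison(tok, op, value)


def parse_rule(text: str) -> Expr:
    """Parse a discard-rule expression into an evaluable tree."""
    return _Parser(_tokenize(text)).parse()


# ---------------------------------------------------------------------------
# Rule sets

@dataclass(frozen=True)
class FilterRule:
    """One discard rule scoped to a rank and database scope."""

    text: str
    rank: str
    db_scope: str

    @property
    def expression(self) -> Expr:
        return parse_rule(self.text)

    def discards(self, identity: float, consensus: float) -> bool:
        return self.expression.evaluate({"identity": identity, "consensus": consensus})


@dataclass(frozen=True)
class RuleSet:
    """Ordered cascade of (db_scope, discard rule) stages at one rank."""

    name: str
    rank: str
    stages: tuple[FilterRule, ...]

    def scopes(self) -> tuple[str, ...]:
        return tuple(r.db_scope for r in self.stages)


def _ruleset(name: str, rank: str, stages: list[tuple[str, str]]) -> RuleSet:
    rules = tuple(FilterRule(text, rank, scope) for scope, text in stages)
    for r in rules:
        parse_rule(r.text)  # fail fast on typos
    return RuleSet(name, rank, rules)


#: Calibrated discard-rule cascades shipped with the package.
DEFAULT_RULE_SETS: dict[str, RuleSet] = {
    rs.name: rs
    for rs in [
        _ruleset("its2-genus", "genus",
                 [("world", "consensus < 40 and identity < 98.5")]),
        _ruleset("rbcl-genus", "genus",
                 [("world", "consensus < 40 and identity < 99.7")]),
        _ruleset("its2-species", "species",
                 [("local", "identity < 99"),
                  ("world", "(consensus < 40 and identity < 99.9) or consensus < 20")]),
        _ruleset("rbcl-species", "species",
                 [("local", "identity < 99.7 or (identity <= 100 and consensus < 50)"),
                  ("world", "consensus < 30 or (consensus < 60 and identity < 100)")]),
        # strict-inequality reading of the vacuous "identity <= 100" clause
        _ruleset("rbcl-species-strict", "species",
                 [("local", "identity < 99.7 or (identity < 100 and consensus < 50)"),
                  ("world", "consensus < 30 or (consensus < 60 and identity < 100)")]),
        # OR reading of the genus conjunction, selectable by config
        _ruleset("its2-genus-or", "genus",
                 [("world", "consensus < 40 or identity < 98.5")]),
        _ruleset("rbcl-genus-or", "genus",
                 [("world", "consensus < 40 or identity < 99.7")]),
    ]
}


# ---------------------------------------------------------------------------
# Application to CV tables

def _indexed(rows: pd.DataFrame, what: str) -> pd.DataFrame:
    if rows is None:
        raise ValueError(f"rule set needs {what} rows but none were given")
    if rows["query_id"].duplicated().any():
        raise ValueError(f"{what} rows: query_id must be unique (single method)")
    return rows.set_index("query_id", drop=False)


def apply_rules(
    local_rows: pd.DataFrame | None,
    world_rows: pd.DataFrame | None,
    rule_set: RuleSet,
    keep_columns: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Apply a discard-rule cascade and return the filtered assignments.

    *local_rows* / *world_rows* are single-method CV result tables
    keyed by ``query_id`` (either may be omitted when no stage uses
    it; when both are used they must cover the same query set).  The
    output has one row per query with the surviving stage's taxon,
    scores and correctness under ``{rank}_*`` columns, ``stage`` naming
    the scope that supplied the assignment (``None`` when discarded
    everywhere), and any *keep_columns* copied from the first stage's
    table.
    """
    rank = rule_set.rank
    tables: dict[str, pd.DataFrame] = {}
    if "local" in rule_set.scopes():
        tables["local"] = _indexed(local_rows, "local")
    if "world" in rule_set.scopes():
        tables["world"] = _indexed(world_rows, "world")
    if not tables:
        raise ValueError("rule set has no stages")
    needed = [f"{rank}_taxon", f"{rank}_identity", f"{rank}_consensus"]
    for scope, tbl in tables.items():
        missing = [c for c in needed if c not in tbl.columns]
        if missing:
            raise ValueError(f"{scope} rows lack required columns {missing}")

    first = tables[rule_set.stages[0].db_scope]
    queries = list(first["query_id"])
    for scope, tbl in tables.items():
        if set(tbl.index) != set(queries):
            raise ValueError("local and world tables must cover the same queries")

    out_rows = []
    for qid in queries:
        chosen = None
        stage_name = None
        for rule in rule_set.stages:
            row = tables[rule.db_scope].loc[qid]
            if pd.isna(row[f"{rank}_taxon"]):
                break  # unassigned input passes through as unassigned
            if not rule.discards(row[f"{rank}_identity"], row[f"{rank}_consensus"]):
                chosen, stage_name = row, rule.db_scope
                break
        base = tables[rule_set.stages[0].db_scope].loc[qid]
        out: dict = {"query_id": qid, "stage": stage_name}
        for col in keep_columns:
            out[col] = base[col]
        if f"true_{rank}" in base.index:
            out[f"true_{rank}"] = base[f"true_{rank}"]
        if chosen is None:
            out[f"{rank}_taxon"] = None
            out[f"{rank}_identity"] = np.nan
            out[f"{rank}_consensus"] = np.nan
            out[f"{rank}_correct"] = False
        else:
            for col in needed:
                out[col] = chosen[col]
            out[f"{rank}_correct"] = (
                bool(chosen[f"{rank}_correct"])
                if f"{rank}_correct" in chosen.index
                else None
            )
        out_rows.append(out)
    return pd.DataFrame(out_rows)


def _shares(rows: pd.DataFrame, rank: str) -> dict[str, float]:
    pred = rows[f"{rank}_taxon"]
    assigned = pred.notna()
    correct = rows[f"{rank}_correct"].fillna(False).astype(bool) & assigned
    n = len(rows)
    n_correct = int(correct.sum())
    n_no_id = int((~assigned).sum())
    return {
        "pct_correct": 100.0 * n_correct / n,
        "pct_wrong": 100.0 * (n - n_correct - n_no_id) / n,
        "pct_no_id": 100.0 * n_no_id / n,
    }


def summarize_filtering(
    before_rows: pd.DataFrame, after_rows: pd.DataFrame, rank: str
) -> dict:
    """Correct / wrong / no-ID percentages before and after filtering.

    Also reports the post-filter error share among assigned sequences,
    wrong/(wrong+correct) — e.g. 17% wrong and 68% correct leave
    17/(17+68) = 20% of the assignments incorrect.  ``None`` when the
    filter discarded everything.
    """
    if set(before_rows["query_id"]) != set(after_rows["query_id"]):
        raise ValueError("before/after tables must cover the same queries")
    before = _shares(before_rows, rank)
    after = _shares(after_rows, rank)
    assigned = after["pct_correct"] + after["pct_wrong"]
    error_among_assigned = (
        100.0 * after["pct_wrong"] / assigned if assigned > 0 else None
    )
    return {
        "before": before,
        "after": after,
        "error_among_assigned": error_among_assigned,
    }
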