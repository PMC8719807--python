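"""Boolean gene–protein–reaction (GPR) rules.

Grammar: identifiers combined with ``and`` / ``or`` (case-insensitive) and
parentheses, as in SBML-fbc and BiGG text rules. An empty rule means the
reaction is always active.
"""

from __future__ import annotations

import re
from typing import Iterable

_TOKEN = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or"}


class GeneRuleError(ValueError):
    pass


def _tokenize(rule: str) -> list[str]:
    return _TOKEN.findall(rule)


class _Parser:
    """Recursive descent:  expr := term ('or' term)* ; term := factor ('and' factor)* ;
    factor := gene | '(' expr ')'."""

    def __init__(self, tokens: list[str], active) -> None:
        self.tokens = tokens
        self.pos = 0
        self.active = active

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GeneRuleError("unexpected end of gene rule")
        self.pos += 1
        return tok

    def expr(self) -> bool:
        value = self.term()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            value = self.term() or value
        return value

    def term(self) -> bool:
        value = self.factor()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            value = self.factor() and value
        return value

    def factor(self) -> bool:
        tok = self.next()
        if tok == "(":
            value = self.expr()
            if self.next() != ")":
                raise GeneRuleError("unbalanced parentheses in gene rule")
            return value
        if tok == ")" or tok.lower() in _KEYWORDS:
            raise GeneRuleError(f"unexpected token {tok!r} in gene rule")
        return self.active(tok)


def evaluate_gene_rule(rule: str, deleted: Iterable[str] = ()) -> bool:
    """Evaluate a GPR rule with the given genes deleted (False), all others
    present (True). Empty rule → always active."""
    if not rule or not rule.strip():
        return True
    deleted = set(deleted)
    parser = _Parser(_tokenize(rule), lambda g: g not in deleted)
    value = parser.expr()
    if parser.peek() is not None:
        raise GeneRuleError(f"trailing tokens in gene rule {rule!r}")
    return value


def rule_genes(rule: str) -> set[str]:
    """Set of gene identifiers appearing in a rule."""
    if not rule or not rule.strip():
        return set()
    return {
        t for t in _tokenize(rule)
        if t not in "()" and t.lower() not in _KEYWORDS
    }
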