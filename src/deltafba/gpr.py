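"""Gene-protein-reaction (GPR) rules and the Min/Max fold-change mapping.

A GPR rule is a boolean expression over gene identifiers: AND joins the
subunits of an enzyme complex, OR joins isozymes.  Differential expression is
propagated from genes to reactions by the Min/Max rule: a complex changes as
its least-changed subunit (minimum fold change over AND children) and a
reaction catalysed by isozymes changes as its most-changed isozyme (maximum
over OR children).  Fold changes live on the linear scale throughout; a gene
without data is neutral (fold change 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

__all__ = [
    "Gene",
    "And",
    "Or",
    "NO_RULE",
    "GPRExpression",
    "parse_gpr",
    "rule_genes",
    "reaction_fold_change",
    "map_all_reactions",
    "ExpressionDelta",
    "ReactionDelta",
    "read_expression_table",
]


@dataclass(frozen=True)
class Gene:
    name: str


@dataclass(frozen=True)
class And:
    children: tuple["GPRNode", ...]

    def __post_init__(self):
        if not self.children:
            raise ValueError("empty AND node")


@dataclass(frozen=True)
class Or:
    children: tuple["GPRNode", ...]

    def __post_init__(self):
        if not self.children:
            raise ValueError("empty OR node")


class _NoRule:
    """Marker for a reaction without a GPR rule (spontaneous/orphan)."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NO_RULE"


NO_RULE = _NoRule()
GPRNode = Union[Gene, And, Or]
GPRExpression = Union[Gene, And, Or, _NoRule]


class GPRParseError(ValueError):
    pass


def _tokenize(rule: str) -> list[str]:
    out: list[str] = []
    buf: list[str] = []
    for ch in rule:
        if ch in "()":
            if buf:
                out.append("".join(buf))
                buf = []
            out.append(ch)
        elif ch.isspace():
            if buf:
                out.append("".join(buf))
                buf = []
        else:
            buf.append(ch)
    if buf:
        out.append("".join(buf))
    return out


def parse_gpr(rule: str) -> GPRExpression:
    """Parse a rule string like ``"(g1 and g2) or g3"`` into an expression tree.

    Connectives ``and``/``or`` are case-insensitive ( ``&``/``|`` accepted);
    ``or`` binds looser than ``and``.  An empty string returns :data:`NO_RULE`.
    Raises :class:`GPRParseError` on unbalanced parentheses or dangling
    connectives.
    """
    tokens = _tokenize(rule)
    if not tokens:
        return NO_RULE
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def is_connective(tok: str | None, names: tuple[str, ...]) -> bool:
        return tok is not None and tok.lower() in names

    def parse_or() -> GPRNode:
        nonlocal pos
        terms = [parse_and()]
        while is_connective(peek(), ("or", "|")):
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and() -> GPRNode:
        nonlocal pos
        factors = [parse_atom()]
        while is_connective(peek(), ("and", "&")):
            pos += 1
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_atom() -> GPRNode:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GPRParseError(f"dangling connective in rule {rule!r}")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in rule {rule!r}")
            pos += 1
            return node
        if tok == ")" or is_connective(tok, ("and", "or", "&", "|")):
            raise GPRParseError(f"unexpected token {tok!r} in rule {rule!r}")
        pos += 1
        return Gene(tok)

    expr = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens {tokens[pos:]} in rule {rule!r}")
    return expr


def rule_genes(expr: GPRExpression) -> set[str]:
    """All gene ids appearing in the expression."""
    if isinstance(expr, _NoRule):
        return set()
    if isinstance(expr, Gene):
        return {expr.name}
    out: set[str] = set()
    for child in expr.children:
        out |= rule_genes(child)
    return out


@dataclass
class ExpressionDelta:
    """Per-gene fold changes (linear scale, > 0) with optional FDR values."""

    gene_fc: dict[str, float]
    gene_fdr: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for g, fc in self.gene_fc.items():
            if not (fc > 0 and math.isfinite(fc)):
                raise ValueError(f"fold change for gene {g!r} must be finite and > 0, got {fc}")

    def fdr_filtered(self, alpha: float) -> "ExpressionDelta":
        """Neutralize (fc -> 1) genes that are not significant at FDR < alpha.

        Genes with no FDR value are kept unchanged.
        """
        if self.gene_fdr is None:
            return self
        fc = {
            g: (v if self.gene_fdr.get(g, 0.0) < alpha else 1.0)
            for g, v in self.gene_fc.items()
        }
        return ExpressionDelta(gene_fc=fc, gene_fdr=self.gene_fdr)


@dataclass
class ReactionDelta:
    """Per-reaction fold changes; ``covered`` marks reactions whose rule had
    at least one gene with data."""

    reaction_ids: list[str]
    rxn_fc: np.ndarray
    covered: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.rxn_fc, index=self.reaction_ids)


def reaction_fold_change(expr: GPRExpression, delta: ExpressionDelta) -> float | None:
    """Evaluate the Min/Max rule: AND -> min of children, OR -> max.

    A gene absent from the data evaluates to the neutral fold change 1.
    Returns None for :data:`NO_RULE` or when no gene in the rule has data
    (the reaction is uncovered).
    """
    if isinstance(expr, _NoRule):
        return None
    if not (rule_genes(expr) & delta.gene_fc.keys()):
        return None
    return _evaluate(expr, delta.gene_fc)


def _evaluate(node: GPRNode, fc: Mapping[str, float]) -> float:
    if isinstance(node, Gene):
        return float(fc.get(node.name, 1.0))
    vals = [_evaluate(c, fc) for c in node.children]
    return min(vals) if isinstance(node, And) else max(vals)


def map_all_reactions(net, delta: ExpressionDelta) -> ReactionDelta:
    """Min/Max fold change for every reaction of a network.

    Uncovered reactions (no rule, or no rule gene with data) get fold change
    1 and ``covered=False``; they are never selected for regulation.
    """
    if not delta.gene_fc:
        raise ValueError("expression data is empty")
    n = net.n_reactions
    fc = np.ones(n)
    covered = np.zeros(n, dtype=bool)
    for j, rule in enumerate(net.gpr_rules):
        val = reaction_fold_change(parse_gpr(rule), delta)
        if val is not None:
            fc[j] = val
            covered[j] = True
    return ReactionDelta(reaction_ids=list(net.reaction_ids), rxn_fc=fc, covered=covered)


def read_expression_table(path: str | Path, fdr_filter: float | None = None) -> ExpressionDelta:
    """Read gene-level differential expression from TSV/CSV.

    Requires a ``gene_id`` column and exactly one of ``fold_change`` (linear)
    or ``log2_fold_change``; an optional ``fdr`` column enables the
    significance pre-filter (non-significant genes are neutralized when
    ``fdr_filter`` is given).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t" if path.suffix.lower() in (".tsv", ".txt") else ",",
                     float_precision="round_trip")
    if "gene_id" not in df.columns:
        raise ValueError("expression table must have a gene_id column")
    has_lin = "fold_change" in df.columns
    has_log = "log2_fold_change" in df.columns
    if has_lin == has_log:
        raise ValueError(
            "expression table must have exactly one of fold_change / log2_fold_change"
        )
    fc_vals = df["fold_change"] if has_lin else np.exp2(df["log2_fold_change"])
    gene_fc = dict(zip(df["gene_id"].astype(str), fc_vals.astype(float)))
    gene_fdr = None
    if "fdr" in df.columns:
        gene_fdr = dict(zip(df["gene_id"].astype(str), df["fdr"].astype(float)))
    delta = ExpressionDelta(gene_fc=gene_fc, gene_fdr=gene_fdr)
    if fdr_filter is not None:
        if gene_fdr is None:
            warnings.warn("fdr_filter requested but table has no fdr column; ignored")
        else:
            delta = delta.fdr_filtered(fdr_filter)
    return delta
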