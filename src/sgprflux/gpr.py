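"""Gene-protein-reaction (GPR) rules with subunit stoichiometry.

A classical GPR is a boolean expression over gene identifiers: ``and``
joins the subunits of an enzyme complex (all required), ``or`` joins
isoenzymes (any sufficient).  The stoichiometric variant (S-GPR)
additionally records, on each gene leaf, the number of transcript copies
needed to assemble one functional catalytic unit, written ``n*gene``.
Example: a complex of three subunits, one encoded by gene ``a`` and two by
gene ``b``, has GPR ``a and b`` and S-GPR ``a and 2*b``.

For data integration the boolean operators become arithmetic ones:
``and`` -> minimum (the scarcest subunit limits complex assembly),
``or`` -> mean or maximum (configurable).  Under S-GPR semantics each
leaf's expression is first divided by its copy number, so a gene that must
contribute several subunits weighs in at its effective per-complex level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterator, Literal, Mapping

__all__ = [
    "GprTree",
    "ExpressionProfile",
    "GprConfig",
    "GprParseError",
    "parse_gpr",
    "serialize_gpr",
    "evaluate_gpr",
]

NodeKind = Literal["GENE", "AND", "OR"]


class GprParseError(ValueError):
    """Raised when a rule string violates the GPR/S-GPR grammar."""


@dataclass(frozen=True)
class GprTree:
    """Node of a GPR/S-GPR expression tree.

    ``GENE`` leaves carry a gene id and a copy number (>= 1, default 1).
    ``AND``/``OR`` nodes carry an ordered tuple of >= 2 children.
    """

    kind: NodeKind
    gene_id: str | None = None
    copy_number: int = 1
    children: tuple["GprTree", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "GENE":
            if not self.gene_id:
                raise ValueError("GENE leaf requires a non-empty gene_id")
            if self.copy_number < 1 or int(self.copy_number) != self.copy_number:
                raise ValueError(
                    f"copy_number must be a positive integer, got {self.copy_number!r}"
                )
            if self.children:
                raise ValueError("GENE leaf cannot have children")
        else:
            if len(self.children) < 2:
                raise ValueError(f"{self.kind} node requires >= 2 children")
            if self.gene_id is not None:
                raise ValueError("operator node cannot carry a gene_id")

    # -- convenience -----------------------------------------------------
    @staticmethod
    def gene(gene_id: str, copy_number: int = 1) -> "GprTree":
        return GprTree("GENE", gene_id=gene_id, copy_number=copy_number)

    @staticmethod
    def and_(*children: "GprTree") -> "GprTree":
        return GprTree("AND", children=tuple(children))

    @staticmethod
    def or_(*children: "GprTree") -> "GprTree":
        return GprTree("OR", children=tuple(children))

    def leaves(self) -> Iterator["GprTree"]:
        if self.kind == "GENE":
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def genes(self) -> set[str]:
        return {leaf.gene_id for leaf in self.leaves()}  # type: ignore[misc]

    def strip_coefficients(self) -> "GprTree":
        """Classical GPR of this S-GPR: every copy number reset to 1."""
        if self.kind == "GENE":
            return GprTree.gene(self.gene_id, 1)  # type: ignore[arg-type]
        return GprTree(self.kind, children=tuple(c.strip_coefficients() for c in self.children))

    def canonical(self) -> tuple:
        """Hashable form with nested same-kind operators flattened.

        Two trees that differ only in associativity grouping (``a and (b
        and c)`` vs ``(a and b) and c``) share a canonical form; child
        order is preserved.
        """
        if self.kind == "GENE":
            return ("GENE", self.gene_id, self.copy_number)
        parts: list[tuple] = []
        for child in self.children:
            c = child.canonical()
            if c[0] == self.kind:
                parts.extend(c[1])
            else:
                parts.append(c)
        return (self.kind, tuple(parts))

    def equivalent(self, other: "GprTree") -> bool:
        return self.canonical() == other.canonical()


@dataclass
class ExpressionProfile:
    """Per-gene expression with optional significance annotations.

    ``values`` holds one non-negative level per gene (absolute intensities
    or treated/control ratios, depending on the downstream method).  When a
    platform reports several probes per gene they must be collapsed to one
    value before constructing the profile; :meth:`from_records` collapses
    by maximum.
    """

    values: dict[str, float]
    p_value: dict[str, float] = field(default_factory=dict)
    log_fc: dict[str, float] = field(default_factory=dict)
    condition: str = ""

    def __post_init__(self) -> None:
        for g, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative expression for gene {g!r}: {v}")
        for g, p in self.p_value.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value out of [0,1] for gene {g!r}: {p}")

    @classmethod
    def from_records(
        cls,
        records: Mapping[str, float] | list[tuple[str, float]],
        *,
        p_value: Mapping[str, float] | None = None,
        log_fc: Mapping[str, float] | None = None,
        condition: str = "",
    ) -> "ExpressionProfile":
        """Build a profile, collapsing duplicate gene entries by maximum."""
        items = records.items() if isinstance(records, Mapping) else records
        values: dict[str, float] = {}
        for gene, value in items:
            if gene in values:
                values[gene] = max(values[gene], float(value))
            else:
                values[gene] = float(value)
        return cls(
            values=values,
            p_value=dict(p_value or {}),
            log_fc=dict(log_fc or {}),
            condition=condition,
        )


@dataclass(frozen=True)
class GprConfig:
    """How rule trees are turned into reaction-level scores.

    ``and_mode`` is fixed to ``min``; ``or_mode`` chooses how isoenzyme
    branches pool (``mean`` by default, ``max`` optional).  ``gpr_mode``
    selects classical (``GPR``) or stoichiometric (``SGPR``) leaf
    semantics.  Genes absent from a profile are skipped by default
    (operator nodes aggregate over their defined children only); set
    ``missing_gene_policy="constant"`` with ``missing_value`` to impute.
    """

    or_mode: Literal["mean", "max"] = "mean"
    gpr_mode: Literal["GPR", "SGPR"] = "GPR"
    missing_gene_policy: Literal["skip", "constant"] = "skip"
    missing_value: float = 0.0

    and_mode: str = "min"  # fixed; kept as a field for introspection

    def __post_init__(self) -> None:
        if self.and_mode != "min":
            raise ValueError("and_mode is fixed to 'min'")
        if self.or_mode not in ("mean", "max"):
            raise ValueError(f"or_mode must be 'mean' or 'max', got {self.or_mode!r}")
        if self.gpr_mode not in ("GPR", "SGPR"):
            raise ValueError(f"gpr_mode must be 'GPR' or 'SGPR', got {self.gpr_mode!r}")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<coef>\d+)\s*\*|(?P<word>[A-Za-z0-9_.:\-]+))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise GprParseError(f"malformed token at {text[pos:pos + 20]!r} (offset {pos})")
        if m.group("lpar"):
            tokens.append(("LPAR", "(", m.start()))
        elif m.group("rpar"):
            tokens.append(("RPAR", ")", m.start()))
        elif m.group("coef"):
            tokens.append(("COEF", m.group("coef"), m.start()))
        else:
            word = m.group("word")
            low = word.lower()
            if low == "and":
                tokens.append(("AND", word, m.start()))
            elif low == "or":
                tokens.append(("OR", word, m.start()))
            else:
                tokens.append(("GENE", word, m.start()))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise GprParseError(f"unexpected end of rule in {self.text!r}")
        self.i += 1
        return tok

    # grammar: expr := term ("or" term)* ; term := atom ("and" atom)* ;
    # atom := [coef "*"] gene | "(" expr ")"
    def parse(self) -> GprTree:
        tree = self.expr()
        if self.peek() is not None:
            kind, val, off = self.peek()  # type: ignore[misc]
            raise GprParseError(f"unexpected {val!r} at offset {off} in {self.text!r}")
        return tree

    def expr(self) -> GprTree:
        terms = [self.term()]
        while self.peek() is not None and self.peek()[0] == "OR":  # type: ignore[index]
            self.take()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else GprTree.or_(*terms)

    def term(self) -> GprTree:
        atoms = [self.atom()]
        while self.peek() is not None and self.peek()[0] == "AND":  # type: ignore[index]
            self.take()
            atoms.append(self.atom())
        return atoms[0] if len(atoms) == 1 else GprTree.and_(*atoms)

    def atom(self) -> GprTree:
        kind, val, off = self.take()
        if kind == "COEF":
            n = int(val)
            if n < 1:
                raise GprParseError(f"zero or negative coefficient {val!r} at offset {off}")
            nxt = self.take()
            if nxt[0] == "LPAR":
                raise GprParseError(
                    f"coefficient applies to a parenthesized group at offset {off}; "
                    "coefficients attach to single gene leaves"
                )
            if nxt[0] != "GENE":
                raise GprParseError(f"expected gene after coefficient at offset {off}, got {nxt[1]!r}")
            return GprTree.gene(nxt[1], n)
        if kind == "GENE":
            return GprTree.gene(val, 1)
        if kind == "LPAR":
            inner = self.expr()
            closing = self.peek()
            if closing is None or closing[0] != "RPAR":
                raise GprParseError(f"unbalanced parentheses in {self.text!r} (opened at offset {off})")
            self.take()
            return inner
        raise GprParseError(f"unexpected {val!r} at offset {off} in {self.text!r}")


def parse_gpr(rule_text: str) -> GprTree:
    """Parse a GPR or S-GPR string into an expression tree.

    ``and`` binds tighter than ``or``; parentheses override; an integer
    coefficient written ``n*gene`` attaches to the immediately following
    gene leaf (default 1).  Operators are case-insensitive.
    """
    if not rule_text or not rule_text.strip():
        raise GprParseError("empty rule string")
    return _Parser(rule_text).parse()


def serialize_gpr(tree: GprTree, mode: Literal["GPR", "SGPR"] = "SGPR") -> str:
    """Render a tree back to rule text.

    ``SGPR`` writes ``n*gene`` for copy numbers > 1; ``GPR`` drops all
    coefficients.  The output re-parses to an equivalent tree.
    """
    if mode not in ("GPR", "SGPR"):
        raise ValueError(f"mode must be 'GPR' or 'SGPR', got {mode!r}")

    def render(node: GprTree, parent: NodeKind | None) -> str:
        if node.kind == "GENE":
            if mode == "SGPR" and node.copy_number > 1:
                return f"{node.copy_number}*{node.gene_id}"
            return str(node.gene_id)
        joiner = " and " if node.kind == "AND" else " or "
        body = joiner.join(render(c, node.kind) for c in node.children)
        # OR under AND needs parens; AND under OR binds tighter and does not.
        if node.kind == "OR" and parent == "AND":
            return f"({body})"
        return body

    return render(tree, None)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_values(
    tree: GprTree,
    gene_values: Mapping[str, float],
    config: GprConfig,
) -> float | None:
    """Aggregate an arbitrary per-gene value map through the rule tree.

    Leaf value is the gene's entry, divided by its copy number in SGPR
    mode.  AND nodes take the minimum over defined children, OR nodes the
    mean or maximum per config.  Returns None when every leaf is missing
    under the skip policy.  Values may be negative (used for log-fold-change
    propagation); :func:`evaluate_gpr` is the expression-level entry point.
    """
    if tree.kind == "GENE":
        if tree.gene_id in gene_values:
            v = float(gene_values[tree.gene_id])
        elif config.missing_gene_policy == "constant":
            v = config.missing_value
        else:
            return None
        if config.gpr_mode == "SGPR":
            v = v / tree.copy_number
        return v
    vals = [evaluate_values(c, gene_values, config) for c in tree.children]
    defined = [v for v in vals if v is not None]
    if not defined:
        return None
    if tree.kind == "AND":
        return min(defined)
    return max(defined) if config.or_mode == "max" else fmean(defined)


def evaluate_gpr(
    tree: GprTree,
    profile: ExpressionProfile,
    config: GprConfig | None = None,
) -> float | None:
    """Reaction-level expression score of a rule against a profile.

    Returns None (undefined) when no leaf gene is measured under the skip
    policy; missing data is governed by ``config.missing_gene_policy`` and
    is never an error.
    """
    config = config or GprConfig()
    return evaluate_values(tree, profile.values, config)
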