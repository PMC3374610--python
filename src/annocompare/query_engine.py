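"""Boolean filter language over annotation records (a small Lucene subset).

Grammar (EBNF)::

    query   = or_expr ;
    or_expr = and_expr { "OR" and_expr } ;
    and_expr = unary { [ "AND" ] unary } ;      (* bare adjacency means AND *)
    unary   = "NOT" unary | "(" query ")" | clause ;
    clause  = field ":" value ;

Operators are case-sensitive upper-case words.  Whitespace is allowed after
the colon (``ec_id: 1.8.1.4`` parses the same as ``ec_id:1.8.1.4``).  Field
names are the 17 column names of the tab-delimited import format.

Matching semantics
------------------
* Multi-valued fields (``go_id``, ``ec_id``, ``ko_id``): set membership.
* ``com_name``: case-insensitive substring match.
* ``blast_tree``: *subtree* semantics — ``blast_tree:7711`` matches a record
  whose taxon is 7711 or any descendant of it, so filtering out a whole clade
  (e.g. host-derived Chordata records) takes a single NOT clause.
* Numeric fields: exact value equality (no range queries).
* A missing field value never matches a positive clause and always satisfies
  the NOT of one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .annotation_store import (
    COLUMNS,
    MULTI_VALUED_FIELDS,
    AnnotationRecord,
    Dataset,
)
from .hierarchies import TaxonomyTree

QUERY_FIELDS = frozenset(COLUMNS)

_NUMERIC_FIELDS = frozenset({"blast_evalue", "blast_pid", "blast_cov", "weight"})


class QuerySyntaxError(ValueError):
    """Unparseable query text; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        self.offset = offset
        super().__init__(f"{message} (at offset {offset})")


class QueryEvaluationError(ValueError):
    """The query cannot be evaluated (e.g. taxonomy clause without a tree)."""


@dataclass(frozen=True)
class Clause:
    field: str
    value: str
    offset: int = 0


@dataclass(frozen=True)
class Not:
    child: "QueryNode"


@dataclass(frozen=True)
class And:
    children: tuple["QueryNode", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["QueryNode", ...]


QueryNode = Clause | Not | And | Or


@dataclass(frozen=True)
class _Token:
    kind: str  # "TERM" | "LPAREN" | "RPAREN"
    text: str
    offset: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i = 0
    n = len(text)
    while i < n:
        char = text[i]
        if char.isspace():
            i += 1
            continue
        if char == "(":
            tokens.append(_Token("LPAREN", "(", i))
            i += 1
            continue
        if char == ")":
            tokens.append(_Token("RPAREN", ")", i))
            i += 1
            continue
        start = i
        while i < n and not text[i].isspace() and text[i] not in "()":
            i += 1
        tokens.append(_Token("TERM", text[start:i], start))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.position = 0

    def peek(self) -> _Token | None:
        if self.position < len(self.tokens):
            return self.tokens[self.position]
        return None

    def advance(self) -> _Token:
        token = self.tokens[self.position]
        self.position += 1
        return token

    def parse(self) -> QueryNode:
        if not self.tokens:
            raise QuerySyntaxError("empty query", 0)
        node = self.parse_or()
        leftover = self.peek()
        if leftover is not None:
            raise QuerySyntaxError(
                f"unexpected {leftover.text!r}"
                if leftover.kind != "RPAREN"
                else "unbalanced parentheses: unmatched ')'",
                leftover.offset,
            )
        return node

    def parse_or(self) -> QueryNode:
        parts = [self.parse_and()]
        while True:
            token = self.peek()
            if token is not None and token.kind == "TERM" and token.text == "OR":
                self.advance()
                parts.append(self.parse_and())
            else:
                break
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self) -> QueryNode:
        parts = [self.parse_unary()]
        while True:
            token = self.peek()
            if token is None or token.kind == "RPAREN":
                break
            if token.kind == "TERM" and token.text == "OR":
                break
            if token.kind == "TERM" and token.text == "AND":
                self.advance()
                follow = self.peek()
                if follow is None or (follow.kind == "TERM" and follow.text in ("AND", "OR")):
                    raise QuerySyntaxError("dangling operator 'AND'", token.offset)
            parts.append(self.parse_unary())  # bare adjacency = AND
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_unary(self) -> QueryNode:
        token = self.peek()
        if token is None:
            raise QuerySyntaxError("dangling operator", len(self.text))
        if token.kind == "TERM" and token.text == "NOT":
            self.advance()
            return Not(self.parse_unary())
        if token.kind == "LPAREN":
            self.advance()
            node = self.parse_or()
            closing = self.peek()
            if closing is None or closing.kind != "RPAREN":
                raise QuerySyntaxError(
                    "unbalanced parentheses: missing ')'", token.offset
                )
            self.advance()
            return node
        if token.kind == "RPAREN":
            raise QuerySyntaxError("unbalanced parentheses: unmatched ')'", token.offset)
        return self.parse_clause()

    def parse_clause(self) -> Clause:
        token = self.advance()
        if token.text in ("AND", "OR"):
            raise QuerySyntaxError(f"dangling operator {token.text!r}", token.offset)
        if ":" not in token.text:
            raise QuerySyntaxError(
                f"expected field:value clause, got {token.text!r}", token.offset
            )
        fieldname, _, value = token.text.partition(":")
        if fieldname not in QUERY_FIELDS:
            raise QuerySyntaxError(f"unknown field name {fieldname!r}", token.offset)
        if not value:
            # whitespace after the colon: the value is the next token
            follow = self.peek()
            if (
                follow is None
                or follow.kind != "TERM"
                or follow.text in ("AND", "OR", "NOT")
            ):
                raise QuerySyntaxError(
                    f"clause {fieldname!r} is missing a value", token.offset
                )
            value = self.advance().text
        return Clause(fieldname, value, token.offset)


def parse_query(text: str) -> QueryNode:
    """Parse a filter expression into an AST.

    Raises :class:`QuerySyntaxError` (with a character offset) on unknown
    field names, dangling operators or unbalanced parentheses.
    """
    if not text or not text.strip():
        raise QuerySyntaxError("empty query", 0)
    return _Parser(text).parse()


def _clause_matches(
    clause: Clause, record: AnnotationRecord, tree: TaxonomyTree | None
) -> bool:
    """Reference single-record predicate; shared with index evaluation for
    fields that cannot be indexed by equality (substring match)."""
    field, value = clause.field, clause.value
    if field in MULTI_VALUED_FIELDS:
        return value in getattr(record, field)
    if field == "com_name":
        return bool(record.com_name) and value.lower() in record.com_name.lower()
    if field == "blast_tree":
        if tree is None:
            raise QueryEvaluationError(
                "blast_tree clause requires a loaded taxonomy"
            )
        if record.blast_tree is None:
            return False
        try:
            taxid = int(value)
        except ValueError:
            raise QueryEvaluationError(f"non-integer taxon id {value!r}") from None
        if taxid not in tree:
            return record.blast_tree == taxid
        return record.blast_tree in tree.subtree(taxid)
    if field in _NUMERIC_FIELDS:
        stored = getattr(record, field)
        if stored is None:
            return False
        try:
            return stored == float(value)
        except ValueError:
            raise QueryEvaluationError(f"non-numeric value {value!r} for {field}") from None
    stored = getattr(record, field)
    return bool(stored) and stored == value


class DatasetIndex:
    """Inverted index over a dataset's records, one posting map per field."""

    def __init__(self, dataset: Dataset, tree: TaxonomyTree | None = None):
        self.dataset = dataset
        self.tree = tree
        self.universe: frozenset[int] = frozenset(range(len(dataset.records)))
        self._postings: dict[str, dict[object, set[int]]] = {}

    def _field_postings(self, field: str) -> dict[object, set[int]]:
        postings = self._postings.get(field)
        if postings is None:
            postings = {}
            for i, record in enumerate(self.dataset.records):
                stored = getattr(record, field)
                if field in MULTI_VALUED_FIELDS:
                    values: Iterator[object] = iter(stored)
                elif stored is None or stored == "":
                    continue
                else:
                    values = iter((stored,))
                for value in values:
                    postings.setdefault(value, set()).add(i)
            self._postings[field] = postings
        return postings

    def matches(self, clause: Clause) -> frozenset[int]:
        field, value = clause.field, clause.value
        if field == "com_name":
            needle = value.lower()
            postings = self._field_postings(field)
            result: set[int] = set()
            for name, rows in postings.items():
                if needle in str(name).lower():
                    result |= rows
            return frozenset(result)
        if field == "blast_tree":
            if self.tree is None:
                raise QueryEvaluationError(
                    "blast_tree clause requires a loaded taxonomy"
                )
            try:
                taxid = int(value)
            except ValueError:
                raise QueryEvaluationError(f"non-integer taxon id {value!r}") from None
            postings = self._field_postings(field)
            if taxid not in self.tree:
                return frozenset(postings.get(taxid, set()))
            result = set()
            subtree = self.tree.subtree(taxid)
            # iterate whichever side is smaller: indexed taxa or the subtree
            if len(postings) <= len(subtree):
                for indexed_taxid, rows in postings.items():
                    if indexed_taxid in subtree:
                        result |= rows
            else:
                for member in subtree:
                    result |= postings.get(member, set())
            return frozenset(result)
        if field in _NUMERIC_FIELDS:
            try:
                key: object = float(value)
            except ValueError:
                raise QueryEvaluationError(f"non-numeric value {value!r} for {field}") from None
            return frozenset(self._field_postings(field).get(key, set()))
        return frozenset(self._field_postings(field).get(value, set()))

    def evaluate(self, node: QueryNode) -> frozenset[int]:
        if isinstance(node, Clause):
            return self.matches(node)
        if isinstance(node, Not):
            return self.universe - self.evaluate(node.child)
        if isinstance(node, And):
            result = self.universe
            for child in node.children:
                result = result & self.evaluate(child)
            return result
        if isinstance(node, Or):
            result: frozenset[int] = frozenset()
            for child in node.children:
                result = result | self.evaluate(child)
            return result
        raise TypeError(f"not a query node: {node!r}")


def evaluate(
    ast: QueryNode | str,
    dataset: Dataset,
    tree: TaxonomyTree | None = None,
) -> Dataset:
    """Filter a dataset, returning matching records with weights untouched.

    ``ast`` may be a parsed query or raw query text.  Record order is
    preserved; the result is a new dataset with the same library id.
    """
    if isinstance(ast, str):
        ast = parse_query(ast)
    index = DatasetIndex(dataset, tree)
    selected = index.evaluate(ast)
    records = [dataset.records[i] for i in sorted(selected)]
    return Dataset(dataset.library_id, records, dict(dataset.metadata))
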