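"""Brute-force per-record query oracle and a random query generator.

The oracle evaluates the AST record by record with independently written
predicate logic; notably, subtree matching is decided via the *ancestry* of
the record's taxon rather than the implementation's subtree expansion.
"""

from __future__ import annotations

import numpy as np

from annocompare.annotation_store import Dataset
from annocompare.query_engine import And, Clause, Not, Or, QueryNode


def record_matches(node: QueryNode, record, tree) -> bool:
    if isinstance(node, Clause):
        field, value = node.field, node.value
        if field in ("go_id", "ec_id", "ko_id"):
            return value in getattr(record, field)
        if field == "com_name":
            return bool(record.com_name) and value.lower() in record.com_name.lower()
        if field == "blast_tree":
            if record.blast_tree is None:
                return False
            taxid = int(value)
            if record.blast_tree == taxid:
                return True
            if taxid not in tree:
                return False
            return taxid in tree.ancestors(record.blast_tree)
        if field in ("blast_evalue", "blast_pid", "blast_cov", "weight"):
            stored = getattr(record, field)
            return stored is not None and stored == float(value)
        stored = getattr(record, field)
        return bool(stored) and stored == value
    if isinstance(node, Not):
        return not record_matches(node.child, record, tree)
    if isinstance(node, And):
        return all(record_matches(c, record, tree) for c in node.children)
    if isinstance(node, Or):
        return any(record_matches(c, record, tree) for c in node.children)
    raise TypeError(node)


def scan(node: QueryNode, dataset: Dataset, tree) -> list[str]:
    return [r.peptide_id for r in dataset.records if record_matches(node, r, tree)]


# value pools mirror fixtures.random_dataset so queries hit and miss
_CLAUSE_POOL = [
    ("ko_id", ["K00001", "K00002", "K00161", "K99999"]),
    ("ec_id", ["1.2.4.1", "2.3.1.12", "1.8.1.4", "1.2.7.1", "9.9.9.9"]),
    ("go_id", ["GO:0000002", "GO:0000005", "GO:0009265", "GO:0000099"]),
    ("com_name", ["pyruvate", "legumain", "transporter", "zzz"]),
    ("filter", ["repeat", "host", "none"]),
    ("hmm_id", ["PF02511", "TIGR00001", "PF99999"]),
]


def random_query(rng: np.random.Generator, taxon_pool, depth: int = 0) -> str:
    roll = rng.random()
    if depth >= 2 or roll < 0.45:
        if rng.random() < 0.25 and taxon_pool:
            taxid = taxon_pool[int(rng.integers(0, len(taxon_pool)))]
            clause = f"blast_tree:{taxid}"
        else:
            field, values = _CLAUSE_POOL[int(rng.integers(0, len(_CLAUSE_POOL)))]
            value = values[int(rng.integers(0, len(values)))]
            space = " " if rng.random() < 0.2 else ""
            clause = f"{field}:{space}{value}"
        if rng.random() < 0.2:
            clause = f"NOT {clause}"
        return clause
    left = random_query(rng, taxon_pool, depth + 1)
    right = random_query(rng, taxon_pool, depth + 1)
    operator = [" OR ", " AND ", " "][int(rng.integers(0, 3))]
    combined = f"{left}{operator}{right}"
    if rng.random() < 0.4:
        combined = f"({combined})"
    if rng.random() < 0.15:
        combined = f"NOT {combined}"
    return combined
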