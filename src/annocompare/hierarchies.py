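"""Taxonomy trees, ontology DAGs, EC classes and KO-to-pathway maps.

Rollup semantics
----------------
* Taxonomy rollup at a named rank partitions records: every taxon maps to
  exactly one ancestor at that rank, or to the reserved ``unresolved`` bucket
  when its lineage lacks the rank.  This keeps weight conservation testable.
* Ontology slim mapping sends a term to its *minimal* slim ancestors (the
  term itself if it is a slim term), with set semantics so DAG path
  multiplicity never inflates counts.
* KO-to-pathway rollup is deliberately non-conservative: an ortholog that
  participates in k pathways contributes its full weight to each of the k
  pathway buckets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

#: Reserved bucket for records whose lineage lacks the requested rank.
UNRESOLVED = "unresolved"

#: Rank labels from coarsest to finest.
RANK_ORDER: tuple[str, ...] = (
    "domain",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Common synonyms normalised onto RANK_ORDER labels.
RANK_ALIASES: dict[str, str] = {"superkingdom": "domain"}


class HierarchyError(ValueError):
    """Structural problem in a loaded hierarchy (cycle, orphan, unknown id)."""


def normalize_rank(rank: str) -> str:
    rank = rank.strip().lower()
    rank = RANK_ALIASES.get(rank, rank)
    if rank not in RANK_ORDER:
        raise HierarchyError(f"unknown rank {rank!r}; expected one of {RANK_ORDER}")
    return rank


@dataclass(frozen=True)
class TaxNode:
    parent: int
    rank: str
    name: str = ""


class TaxonomyTree:
    """Rooted taxonomy with ranks and scientific names.

    The root is its own parent; every other node's parent must exist and the
    parent relation must be acyclic.
    """

    def __init__(self, nodes: Mapping[int, TaxNode]):
        self.nodes: dict[int, TaxNode] = dict(nodes)
        self.root = self._validate()
        self._children: dict[int, list[int]] | None = None

    def _validate(self) -> int:
        roots = [t for t, node in self.nodes.items() if node.parent == t]
        if len(roots) != 1:
            raise HierarchyError(f"expected exactly one root, found {len(roots)}")
        root = roots[0]
        for taxid, node in self.nodes.items():
            if node.parent not in self.nodes:
                raise HierarchyError(
                    f"orphan node {taxid}: parent {node.parent} not present"
                )
        # cycle check by walking every lineage with a visited set
        resolved: set[int] = {root}
        for taxid in self.nodes:
            path = []
            current = taxid
            on_path: set[int] = set()
            while current not in resolved:
                if current in on_path:
                    raise HierarchyError(f"cycle detected at taxon {current}")
                on_path.add(current)
                path.append(current)
                current = self.nodes[current].parent
            resolved.update(path)
        return root

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def name(self, taxid: int) -> str:
        return self.nodes[taxid].name

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid].rank

    def ancestors(self, taxid: int) -> list[int]:
        """Lineage ordered root -> ... -> taxid (both endpoints included)."""
        if taxid not in self.nodes:
            raise HierarchyError(f"unknown taxon {taxid}")
        lineage = [taxid]
        while taxid != self.root:
            taxid = self.nodes[taxid].parent
            lineage.append(taxid)
        lineage.reverse()
        return lineage

    def rollup(self, taxid: int, rank: str) -> int | str:
        """The unique ancestor at ``rank``, or :data:`UNRESOLVED`."""
        rank = normalize_rank(rank)
        for ancestor in self.ancestors(taxid):
            node_rank = RANK_ALIASES.get(self.nodes[ancestor].rank, self.nodes[ancestor].rank)
            if node_rank == rank:
                return ancestor
        return UNRESOLVED

    def children(self, taxid: int) -> list[int]:
        if self._children is None:
            index: dict[int, list[int]] = {t: [] for t in self.nodes}
            for t, node in self.nodes.items():
                if t != self.root:
                    index[node.parent].append(t)
            self._children = index
        return self._children[taxid]

    def subtree(self, taxid: int) -> set[int]:
        """All descendants of ``taxid`` including itself."""
        if taxid not in self.nodes:
            raise HierarchyError(f"unknown taxon {taxid}")
        result: set[int] = set()
        stack = [taxid]
        while stack:
            current = stack.pop()
            result.add(current)
            stack.extend(self.children(current))
        return result


def rollup_taxon(tree: TaxonomyTree, taxid: int, rank: str) -> int | str:
    """Functional alias for :meth:`TaxonomyTree.rollup`."""
    return tree.rollup(taxid, rank)


def ancestors(tree: TaxonomyTree, taxid: int) -> list[int]:
    """Functional alias for :meth:`TaxonomyTree.ancestors`."""
    return tree.ancestors(taxid)


def _split_dmp_line(line: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return [f.strip() for f in line.split("\t|\t")]


def load_taxonomy(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTree:
    """Load a taxonomy from pipe-delimited node/name dump files.

    ``nodes``: ``taxid | parent taxid | rank | ...``;
    ``names``: ``taxid | name | unique name | name class``; rows whose class
    is ``scientific name`` win, otherwise the first name seen is used.
    """
    raw: dict[int, tuple[int, str]] = {}
    with Path(nodes_path).open("r", encoding="utf-8") as handle:
        for line in handle:
            if not line.strip():
                continue
            fields = _split_dmp_line(line)
            if len(fields) < 3:
                raise HierarchyError(f"malformed nodes line: {line!r}")
            raw[int(fields[0])] = (int(fields[1]), fields[2])
    names: dict[int, str] = {}
    with Path(names_path).open("r", encoding="utf-8") as handle:
        for line in handle:
            if not line.strip():
                continue
            fields = _split_dmp_line(line)
            taxid = int(fields[0])
            name_class = fields[3] if len(fields) > 3 else "scientific name"
            if name_class == "scientific name" or taxid not in names:
                names[taxid] = fields[1]
    nodes = {
        taxid: TaxNode(parent, rank, names.get(taxid, ""))
        for taxid, (parent, rank) in raw.items()
    }
    return TaxonomyTree(nodes)


@dataclass(frozen=True)
class OntologyTerm:
    name: str
    parents: frozenset[str]


class OntologyDAG:
    """Ontology terms linked by ``is_a`` edges, with an optional slim subset.

    The slim subset is a curated coarse selection of terms used to summarise
    fine-grained annotations.
    """

    def __init__(
        self,
        terms: Mapping[str, tuple[str, Iterable[str]]],
        slim: Iterable[str] = (),
    ):
        self.terms: dict[str, OntologyTerm] = {
            acc: OntologyTerm(name, frozenset(parents))
            for acc, (name, parents) in terms.items()
        }
        self.slim: frozenset[str] = frozenset(slim)
        missing = self.slim - self.terms.keys()
        if missing:
            raise HierarchyError(f"slim terms absent from ontology: {sorted(missing)}")
        self._graph = nx.DiGraph()  # edges child -> parent
        self._graph.add_nodes_from(self.terms)
        for acc, term in self.terms.items():
            for parent in term.parents:
                if parent not in self.terms:
                    raise HierarchyError(f"{acc}: unknown parent {parent}")
                self._graph.add_edge(acc, parent)
        if not nx.is_directed_acyclic_graph(self._graph):
            raise HierarchyError("ontology is_a graph contains a cycle")
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def name(self, accession: str) -> str:
        return self.terms[accession].name

    def ancestors_or_self(self, accession: str) -> frozenset[str]:
        if accession not in self.terms:
            raise HierarchyError(f"unknown term {accession}")
        cached = self._ancestor_cache.get(accession)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, accession)) | {accession}
            self._ancestor_cache[accession] = cached
        return cached

    def slim_map(self, accession: str) -> set[str]:
        """Minimal slim ancestors of ``accession`` (itself if it is slim).

        A slim ancestor is dropped when another slim ancestor of the term lies
        strictly below it, so a term is never double-counted along one path.
        """
        candidates = self.ancestors_or_self(accession) & self.slim
        result = set()
        for term in candidates:
            shadowed = any(
                term in self.ancestors_or_self(other)
                for other in candidates
                if other != term
            )
            if not shadowed:
                result.add(term)
        return result


def slim_map(dag: OntologyDAG, accession: str) -> set[str]:
    """Functional alias for :meth:`OntologyDAG.slim_map`."""
    return dag.slim_map(accession)


def load_ontology(
    path: str | Path,
    slim_terms: Iterable[str] | str | Path | None = None,
    slim_subset: str | None = None,
) -> OntologyDAG:
    """Load an OBO-format ontology, keeping only ``is_a`` relationships.

    The slim subset may be given as an iterable of accessions, a text file of
    accessions (one per line), or — via ``slim_subset`` — the name of a
    ``subset:`` tag inside the OBO file itself.
    """
    graph = obonet.read_obo(str(path))
    terms: dict[str, tuple[str, list[str]]] = {}
    subset_slim: set[str] = set()
    for node, data in graph.nodes(data=True):
        parents = [v for _, v, key in graph.out_edges(node, keys=True) if key == "is_a"]
        terms[node] = (data.get("name", ""), parents)
        if slim_subset and slim_subset in data.get("subset", []):
            subset_slim.add(node)
    slim: set[str] = set(subset_slim)
    if slim_terms is not None:
        if isinstance(slim_terms, (str, Path)):
            with Path(slim_terms).open("r", encoding="utf-8") as handle:
                slim.update(
                    line.strip() for line in handle if line.strip() and not line.startswith("#")
                )
        else:
            slim.update(slim_terms)
    return OntologyDAG(terms, slim)


class PathwayMap:
    """Many-to-many map from KEGG orthologs to pathways."""

    def __init__(self, ko_to_pathways: Mapping[str, Iterable[tuple[str, str]]]):
        self.ko_to_pathways: dict[str, frozenset[tuple[str, str]]] = {
            ko: frozenset(pathways) for ko, pathways in ko_to_pathways.items()
        }
        names: dict[str, str] = {}
        for pathways in self.ko_to_pathways.values():
            for pid, pname in pathways:
                if pid in names and names[pid] != pname:
                    raise HierarchyError(
                        f"pathway {pid} has conflicting names "
                        f"{names[pid]!r} / {pname!r}"
                    )
                names[pid] = pname
        self.pathway_names = names

    def pathways(self, ko: str) -> frozenset[tuple[str, str]]:
        return self.ko_to_pathways.get(ko, frozenset())

    def __len__(self) -> int:
        return len(self.ko_to_pathways)


def load_pathway_map(path: str | Path) -> PathwayMap:
    """Load a 2- or 3-column TSV: ``ko <tab> pathway_id [<tab> pathway name]``."""
    mapping: dict[str, set[tuple[str, str]]] = {}
    with Path(path).open("r", encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise HierarchyError(f"malformed pathway map line: {line!r}")
            ko, pid = fields[0].strip(), fields[1].strip()
            pname = fields[2].strip() if len(fields) > 2 else pid
            mapping.setdefault(ko, set()).add((pid, pname))
    return PathwayMap(mapping)


_EC_COMPONENT = re.compile(r"(\d+|-)$")


def ec_level(ec_string: str, level: int) -> str:
    """Truncate a dotted EC number to ``level`` components, '-'-padded to 4.

    ``ec_level("1.2.4.1", 2) == "1.2.-.-"``.  Components past the first may be
    '-' wildcards; components absent from the input are treated as wildcards.
    """
    if level not in (1, 2, 3, 4):
        raise ValueError(f"EC level must be 1..4, got {level!r}")
    components = ec_string.strip().split(".")
    if not 1 <= len(components) <= 4:
        raise ValueError(f"malformed EC number {ec_string!r}")
    if not components[0].isdigit():
        raise ValueError(f"malformed EC number {ec_string!r}")
    for component in components[1:]:
        if not _EC_COMPONENT.match(component):
            raise ValueError(f"malformed EC number {ec_string!r}")
    padded = components + ["-"] * (4 - len(components))
    return ".".join(padded[:level] + ["-"] * (4 - level))
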