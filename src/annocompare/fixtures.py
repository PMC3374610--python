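"""Synthetic hierarchies and annotation datasets for tests and demos.

Nothing here requires a download: the module generates

* the exact 100-entry weighted worked example (orthologs K00849/K00856)
  used to demonstrate dynamic weighting,
* ranked taxonomies with a designated chordate-analog subtree (so host-
  removal filters are exercisable),
* a small ontology DAG with a slim subset, a KO-to-pathway map,
* and families of habitat-structured annotation datasets drawn from a
  Dirichlet-multinomial model: each habitat has a centroid composition over
  orthologs (and a phylum emphasis over taxa), each sample draws its own
  composition around the habitat centroid, and per-record weights are
  log-normal.  This is the minimal generative model matching the structure
  of real body-habitat surveys — habitat-specific compositional profiles
  with inter-individual variation — and ships truth tables (habitat labels,
  planted fold-changes, host-record counts) so recovery assertions are
  executable.

A fixed seed fixes every byte of the output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation_store import AnnotationRecord, Dataset, write_tab_file
from .hierarchies import OntologyDAG, PathwayMap, TaxNode, TaxonomyTree

WORKED_EXAMPLE_LIBRARY = "EXAMPLE100"


def worked_example_dataset() -> Dataset:
    """The canonical dynamic-weighting example: 100 entries, two orthologs.

    70 entries carry K00849 (galactokinase) at weight 8, 10 more carry
    K00849 at weight 4, and 20 entries carry K00856 (adenosine kinase) at
    weight 20.  Total weight 70*8 + 10*4 + 20*20 = 1000; the weighted
    relative frequency of K00849 is 600/1000 = 60%, against 80% by plain
    counting.
    """
    blocks = [("K00849", 8.0, 70), ("K00849", 4.0, 10), ("K00856", 20.0, 20)]
    names = {"K00849": "galactokinase", "K00856": "adenosine kinase"}
    records = []
    i = 0
    for ko, weight, count in blocks:
        for _ in range(count):
            i += 1
            records.append(
                AnnotationRecord(
                    peptide_id=f"WE_{i:04d}",
                    library_id=WORKED_EXAMPLE_LIBRARY,
                    com_name=names[ko],
                    ko_id=(ko,),
                    ko_src="fixture",
                    weight=weight,
                )
            )
    return Dataset(WORKED_EXAMPLE_LIBRARY, records, {"habitat": "example"})


@dataclass(frozen=True)
class TaxonomyInfo:
    """Handles into a synthetic taxonomy."""

    chordate_root: int
    host_species: tuple[int, ...]
    phylum_ids: tuple[int, ...]
    species_by_phylum: dict[int, tuple[int, ...]]


def synth_taxonomy(
    n_phyla: int = 4, genera_per_phylum: int = 2, species_per_genus: int = 3
) -> tuple[TaxonomyTree, TaxonomyInfo]:
    """Deterministic ranked taxonomy (domain..species) with a host subtree.

    A bacteria-like domain carries ``n_phyla`` phyla, each a chain
    class/order/family fanning into genera and species.  A eukaryote-like
    domain carries one chordate-analog phylum ("Chordatoid") whose species
    stand in for host-derived records.
    """
    nodes: dict[int, TaxNode] = {1: TaxNode(1, "root", "root")}
    nodes[2] = TaxNode(1, "domain", "Bacteria-like")
    nodes[3] = TaxNode(1, "domain", "Eukaryota-like")

    # host lineage
    nodes[30] = TaxNode(3, "kingdom", "Metazoa-like")
    chordate_root = 31
    nodes[chordate_root] = TaxNode(30, "phylum", "Chordatoid")
    nodes[32] = TaxNode(31, "class", "Mammalia-like")
    nodes[33] = TaxNode(32, "order", "Primates-like")
    nodes[34] = TaxNode(33, "family", "Hominidae-like")
    nodes[35] = TaxNode(34, "genus", "Homo-like")
    host_species = (351, 352)
    nodes[351] = TaxNode(35, "species", "Host species 1")
    nodes[352] = TaxNode(35, "species", "Host species 2")

    next_id = 1000
    phylum_ids: list[int] = []
    species_by_phylum: dict[int, tuple[int, ...]] = {}
    for p in range(n_phyla):
        phylum = next_id
        next_id += 1
        nodes[phylum] = TaxNode(2, "phylum", f"Phylum {p}")
        phylum_ids.append(phylum)
        klass, order, family_ = next_id, next_id + 1, next_id + 2
        next_id += 3
        nodes[klass] = TaxNode(phylum, "class", f"Class {p}")
        nodes[order] = TaxNode(klass, "order", f"Order {p}")
        nodes[family_] = TaxNode(order, "family", f"Family {p}")
        species: list[int] = []
        for g in range(genera_per_phylum):
            genus = next_id
            next_id += 1
            nodes[genus] = TaxNode(family_, "genus", f"Genus {p}.{g}")
            for s in range(species_per_genus):
                sp = next_id
                next_id += 1
                nodes[sp] = TaxNode(genus, "species", f"Species {p}.{g}.{s}")
                species.append(sp)
        species_by_phylum[phylum] = tuple(species)
    tree = TaxonomyTree(nodes)
    info = TaxonomyInfo(chordate_root, host_species, tuple(phylum_ids), species_by_phylum)
    return tree, info


def write_taxonomy_dump(
    tree: TaxonomyTree, nodes_path: str | Path, names_path: str | Path
) -> None:
    """Write pipe-delimited node/name dump files (``\\t|\\t`` separators)."""
    with Path(nodes_path).open("w", encoding="utf-8") as handle:
        for taxid in sorted(tree.nodes):
            node = tree.nodes[taxid]
            handle.write(f"{taxid}\t|\t{node.parent}\t|\t{node.rank}\t|\n")
    with Path(names_path).open("w", encoding="utf-8") as handle:
        for taxid in sorted(tree.nodes):
            node = tree.nodes[taxid]
            handle.write(f"{taxid}\t|\t{node.name}\t|\t\t|\tscientific name\t|\n")


def synth_ontology() -> OntologyDAG:
    """Small deterministic DAG with a three-term slim subset.

    Includes a term with two slim ancestors on disjoint paths (maps to both)
    and a diamond whose two paths reach the same slim term (counted once).
    """
    terms = {
        "GO:0000001": ("root process", []),
        "GO:0000002": ("slim branch A", ["GO:0000001"]),
        "GO:0000003": ("slim branch B", ["GO:0000001"]),
        "GO:0000004": ("slim branch C", ["GO:0000001"]),
        "GO:0000005": ("mid A", ["GO:0000002"]),
        "GO:0000006": ("cross A/B", ["GO:0000002", "GO:0000003"]),
        "GO:0000007": ("mid A2", ["GO:0000005"]),
        "GO:0000008": ("diamond under A", ["GO:0000005", "GO:0000007"]),
        "GO:0000009": ("leaf under cross", ["GO:0000006"]),
        "GO:0000010": ("mid C", ["GO:0000004"]),
        "GO:0000011": ("leaf C", ["GO:0000010"]),
        "GO:0000012": ("orphan-ish leaf", ["GO:0000001"]),
    }
    slim = ("GO:0000002", "GO:0000003", "GO:0000004")
    return OntologyDAG(terms, slim)


def write_obo(dag: OntologyDAG, path: str | Path, slim_subset: str = "slim_generic") -> None:
    """Write the DAG as a minimal OBO file; slim terms get a ``subset:`` tag."""
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("format-version: 1.2\n")
        handle.write("ontology: synthetic\n")
        handle.write(f"subsetdef: {slim_subset} \"Synthetic slim subset\"\n\n")
        for accession in sorted(dag.terms):
            term = dag.terms[accession]
            handle.write("[Term]\n")
            handle.write(f"id: {accession}\n")
            handle.write(f"name: {term.name}\n")
            if accession in dag.slim:
                handle.write(f"subset: {slim_subset}\n")
            for parent in sorted(term.parents):
                handle.write(f"is_a: {parent} ! {dag.terms[parent].name}\n")
            handle.write("\n")


def synth_pathway_map(kos: Sequence[str], n_pathways: int = 3) -> PathwayMap:
    """Deterministic many-to-many KO-to-pathway map.

    Ortholog i maps to pathway ``i % n_pathways``; every third ortholog
    additionally maps to the next pathway, exercising the non-conservative
    (weight-duplicating) pathway rollup.
    """
    mapping: dict[str, set[tuple[str, str]]] = {}
    for i, ko in enumerate(kos):
        primary = i % n_pathways
        pathways = {(f"map{primary + 1:04d}", f"Pathway {primary + 1}")}
        if i % 3 == 0:
            secondary = (primary + 1) % n_pathways
            pathways.add((f"map{secondary + 1:04d}", f"Pathway {secondary + 1}"))
        mapping[ko] = pathways
    return PathwayMap(mapping)


def write_pathway_map(pathway_map: PathwayMap, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for ko in sorted(pathway_map.ko_to_pathways):
            for pid, pname in sorted(pathway_map.ko_to_pathways[ko]):
                handle.write(f"{ko}\t{pid}\t{pname}\n")


def default_ko_annotations(features: Sequence[str]) -> dict[str, tuple[str, str]]:
    """Deterministic EC and GO assignment per ortholog (for record synthesis)."""
    ontology = synth_ontology()
    leaves = sorted(
        acc for acc in ontology.terms if acc not in ("GO:0000001",)
    )
    out = {}
    for i, ko in enumerate(features):
        ec = f"{1 + i % 6}.{1 + i % 10}.{1 + i % 12}.{1 + i}"
        go = leaves[i % len(leaves)]
        out[ko] = (ec, go)
    return out


@dataclass(frozen=True)
class PlantedEffect:
    """A differential-abundance effect planted into one habitat's centroid.

    ``baseline`` pins the feature's centroid share before the fold-change is
    applied, so the planted effect size is well defined; left ``None`` the
    share is whatever the random centroid draw produced, which can be
    arbitrarily small.
    """

    feature: str
    fold_change: float
    group: int  # habitat index whose centroid is scaled
    baseline: float | None = None


@dataclass
class FixtureSpec:
    """Generation parameters for a family of habitat-structured datasets.

    ``concentration`` controls within-habitat dispersion of the Dirichlet
    draw around the habitat centroid (higher = tighter); ``math.inf`` makes
    samples exact copies of the centroid with unit weights and deterministic
    count allocation (zero-noise mode).  ``sparsity`` is the fraction of
    ortholog features zeroed out per habitat centroid, giving habitats
    partially disjoint feature supports.  ``host_fraction`` of each sample's
    records are drawn from the chordate-analog subtree with no functional
    annotation, emulating host-derived contamination.
    """

    seed: int = 0
    n_datasets: int = 8
    n_records: int = 300
    n_habitats: int = 2
    n_features: int = 20
    concentration: float = 50.0
    weight_mu: float = 0.0
    weight_sigma: float = 0.5
    host_fraction: float = 0.05
    sparsity: float = 0.25
    n_phyla: int = 4
    planted_effects: tuple[PlantedEffect, ...] = ()
    #: With independent centroids (default) habitats differ everywhere —
    #: the clustering regime.  With a shared centroid all habitats start
    #: from one baseline composition and differ ONLY by the planted
    #: fold-changes — the controlled differential-abundance regime.
    shared_centroid: bool = False


@dataclass
class FixtureTruth:
    """What was planted, for recovery assertions."""

    habitat: dict[str, int]
    host_records: dict[str, int]
    chordate_root: int
    features: list[str]
    centroids: np.ndarray  # habitats x features
    tree: TaxonomyTree
    info: TaxonomyInfo
    planted_effects: tuple[PlantedEffect, ...] = ()
    pathway_map: PathwayMap | None = None
    ontology: OntologyDAG | None = None
    spec: FixtureSpec | None = None


def _habitat_centroids(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    centroids = np.zeros((spec.n_habitats, spec.n_features))
    planted_idx = set()
    feature_names = [f"K{i + 1:05d}" for i in range(spec.n_features)]
    for effect in spec.planted_effects:
        planted_idx.add(feature_names.index(effect.feature))
    n_zero = int(spec.sparsity * spec.n_features)
    shared_base = None
    if spec.shared_centroid:
        shared_base = rng.dirichlet(np.full(spec.n_features, 1.0))
        if n_zero:
            zeroable = [i for i in range(spec.n_features) if i not in planted_idx]
            zeros = rng.choice(zeroable, size=min(n_zero, len(zeroable)), replace=False)
            shared_base[zeros] = 0.0
    for h in range(spec.n_habitats):
        if shared_base is not None:
            base = shared_base.copy()
        else:
            base = rng.dirichlet(np.full(spec.n_features, 1.0))
            if n_zero:
                zeroable = [i for i in range(spec.n_features) if i not in planted_idx]
                zeros = rng.choice(zeroable, size=min(n_zero, len(zeroable)), replace=False)
                base[zeros] = 0.0
        for effect in spec.planted_effects:
            idx = feature_names.index(effect.feature)
            if effect.baseline is not None:
                others = base.sum() - base[idx]
                if others > 0:
                    base *= (1.0 - effect.baseline) / others
                base[idx] = effect.baseline
            if effect.group == h:
                base[idx] *= effect.fold_change
        centroids[h] = base / base.sum()
    return centroids


def _deterministic_counts(p: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder allocation of n draws to probabilities p."""
    raw = p * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:remainder]] += 1
    return counts


def synth_datasets(spec: FixtureSpec) -> tuple[list[Dataset], FixtureTruth]:
    """Generate habitat-structured datasets plus their truth tables."""
    rng = np.random.default_rng(spec.seed)
    tree, info = synth_taxonomy(n_phyla=spec.n_phyla)
    features = [f"K{i + 1:05d}" for i in range(spec.n_features)]
    ko_annotations = default_ko_annotations(features)
    pathway_map = synth_pathway_map(features)
    ontology = synth_ontology()
    centroids = _habitat_centroids(spec, rng)
    zero_noise = math.isinf(spec.concentration)

    # habitat h emphasises phylum h % n_phyla tenfold in its taxon profile
    all_species = [sp for phylum in info.phylum_ids for sp in info.species_by_phylum[phylum]]
    taxon_weights = np.ones((spec.n_habitats, len(all_species)))
    for h in range(spec.n_habitats):
        emphasised = info.phylum_ids[h % spec.n_phyla]
        for j, sp in enumerate(all_species):
            if sp in info.species_by_phylum[emphasised]:
                taxon_weights[h, j] = 10.0
    taxon_probs = taxon_weights / taxon_weights.sum(axis=1, keepdims=True)

    datasets: list[Dataset] = []
    habitat_truth: dict[str, int] = {}
    host_truth: dict[str, int] = {}
    n_host = int(round(spec.host_fraction * spec.n_records))
    n_microbial = spec.n_records - n_host
    for i in range(spec.n_datasets):
        h = i % spec.n_habitats
        library_id = f"SYN{i:03d}"
        if zero_noise:
            p = centroids[h]
            counts = _deterministic_counts(p, n_microbial)
        else:
            alpha = np.maximum(centroids[h] * spec.concentration, 1e-6)
            p = rng.dirichlet(alpha)
            counts = rng.multinomial(n_microbial, p)
        records: list[AnnotationRecord] = []
        for j, feature in enumerate(features):
            for _ in range(int(counts[j])):
                if zero_noise:
                    taxon = all_species[j % len(all_species)]
                    weight = 1.0
                    evalue, pid, cov = 1e-10, 0.9, 0.9
                else:
                    taxon = all_species[rng.choice(len(all_species), p=taxon_probs[h])]
                    weight = float(rng.lognormal(spec.weight_mu, spec.weight_sigma))
                    evalue = float(10.0 ** rng.uniform(-30, -5))
                    pid = float(rng.uniform(0.7, 1.0))
                    cov = float(rng.uniform(0.7, 1.0))
                ec, go = ko_annotations[feature]
                records.append(
                    AnnotationRecord(
                        peptide_id="pending",
                        library_id=library_id,
                        com_name=f"protein of {feature}",
                        com_name_src="fixture",
                        go_id=(go,),
                        go_src=feature,
                        ec_id=(ec,),
                        ec_src="fixture",
                        blast_tree=taxon,
                        blast_evalue=evalue,
                        blast_pid=round(pid, 4),
                        blast_cov=round(cov, 4),
                        ko_id=(feature,),
                        ko_src="fixture",
                        weight=round(weight, 6),
                    )
                )
        for k in range(n_host):
            if zero_noise:
                taxon = info.host_species[k % len(info.host_species)]
                weight = 1.0
            else:
                taxon = int(rng.choice(info.host_species))
                weight = float(round(rng.lognormal(spec.weight_mu, spec.weight_sigma), 6))
            records.append(
                AnnotationRecord(
                    peptide_id="pending",
                    library_id=library_id,
                    com_name="host-like protein",
                    com_name_src="fixture",
                    blast_tree=taxon,
                    filter="host",
                    weight=weight,
                )
            )
        if not zero_noise:
            rng.shuffle(records)
        records = [
            dataclasses.replace(r, peptide_id=f"{library_id}_{k:06d}")
            for k, r in enumerate(records)
        ]
        datasets.append(
            Dataset(library_id, records, {"habitat": f"H{h}", "sample_id": library_id})
        )
        habitat_truth[library_id] = h
        host_truth[library_id] = n_host

    truth = FixtureTruth(
        habitat=habitat_truth,
        host_records=host_truth,
        chordate_root=info.chordate_root,
        features=features,
        centroids=centroids,
        tree=tree,
        info=info,
        planted_effects=spec.planted_effects,
        pathway_map=pathway_map,
        ontology=ontology,
        spec=spec,
    )
    return datasets, truth


def random_dataset(
    rng: np.random.Generator,
    n_records: int = 30,
    library_id: str = "RND",
    taxon_pool: Sequence[int] | None = None,
) -> Dataset:
    """Unstructured random dataset for property tests (valid but arbitrary).

    Field values are drawn from small vocabularies with missing values mixed
    in, so round-trip and query properties are exercised across the full
    record surface.
    """
    kos = ["K00001", "K00002", "K00003", "K00161", "K00162"]
    gos = ["GO:0000002", "GO:0000005", "GO:0000006", "GO:0009265"]
    ecs = ["1.2.4.1", "2.3.1.12", "1.8.1.4", "1.2.7.1", "2.3.1.54", "1.2.-.-"]
    names = ["pyruvate synthase", "sugar ABC transporter", "legumain", ""]
    filters = ["", "repeat", "host"]
    records = []
    for i in range(n_records):
        n_ko = int(rng.integers(0, 3))
        n_go = int(rng.integers(0, 3))
        n_ec = int(rng.integers(0, 3))
        taxon: int | None = None
        if taxon_pool is not None and rng.random() < 0.8:
            taxon = int(taxon_pool[int(rng.integers(0, len(taxon_pool)))])
        records.append(
            AnnotationRecord(
                peptide_id=f"{library_id}_{i:05d}",
                library_id=library_id,
                com_name=str(rng.choice(names)),
                com_name_src="rnd",
                go_id=tuple(rng.choice(gos, size=n_go, replace=False)),
                ec_id=tuple(rng.choice(ecs, size=n_ec, replace=False)),
                hmm_id=str(rng.choice(["", "PF02511", "TIGR00001"])),
                blast_tree=taxon,
                blast_evalue=None if rng.random() < 0.3 else float(10.0 ** rng.uniform(-40, -1)),
                blast_pid=None if rng.random() < 0.3 else round(float(rng.uniform(0, 1)), 3),
                blast_cov=None if rng.random() < 0.3 else round(float(rng.uniform(0, 1)), 3),
                filter=str(rng.choice(filters)),
                ko_id=tuple(rng.choice(kos, size=n_ko, replace=False)),
                weight=round(float(rng.uniform(0, 5)), 4),
            )
        )
    return Dataset(library_id, records)


def generate_fixture_directory(spec: FixtureSpec, out_dir: str | Path) -> dict[str, object]:
    """Materialise a fixture family on disk (TSV datasets + hierarchy files)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    datasets, truth = synth_datasets(spec)
    paths = []
    for dataset in datasets:
        path = out_dir / f"{dataset.library_id}.tsv"
        write_tab_file(dataset, path)
        paths.append(str(path))
    write_taxonomy_dump(truth.tree, out_dir / "nodes.dmp", out_dir / "names.dmp")
    write_obo(truth.ontology, out_dir / "ontology.obo")
    write_pathway_map(truth.pathway_map, out_dir / "pathways.tsv")
    import json

    truth_payload = {
        "habitat": truth.habitat,
        "host_records": truth.host_records,
        "chordate_root": truth.chordate_root,
        "features": truth.features,
        "planted_effects": [
            {"feature": e.feature, "fold_change": e.fold_change, "group": e.group}
            for e in truth.planted_effects
        ],
    }
    (out_dir / "truth.json").write_text(json.dumps(truth_payload, indent=2))
    return {"datasets": paths, "truth": truth_payload}
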