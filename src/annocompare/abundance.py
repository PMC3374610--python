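"""Weighted and unweighted abundance profiles at any hierarchy level.

Absolute frequency of a feature is the *sum of weights* of the records that
carry it (after hierarchy rollup); the relative frequency divides by the sum
of *all* record weights of the dataset under consideration — not only the
records carrying the attribute.  With all weights equal to 1 this reduces to
plain record counting (facet semantics), so weighted and unweighted
summaries share one code path.

Worked example: a dataset of 100 entries where 70 entries carry ortholog
K00849 at weight 8, 10 more carry K00849 at weight 4, and 20 entries carry
K00856 at weight 20.  The absolute frequency of K00849 is 70*8 + 10*4 = 600
out of a total weight of 1000, so its weighted relative frequency is 60%,
whereas the unweighted (count) frequency would be 80/100 = 80%.

Records lacking the requested attribute accumulate in the reserved
``unassigned`` bucket; taxa whose lineage lacks the requested rank land in
``unresolved``.  Emitting both buckets keeps weight conservation exact for
single-valued attributes.  Multi-valued attributes (several GO/EC/KO values
per record, KOs in several pathways) contribute their full weight to *each*
distinct value, so pathway-level relative frequencies may sum past 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

from .annotation_store import Dataset
from .hierarchies import (
    UNRESOLVED,
    OntologyDAG,
    PathwayMap,
    TaxonomyTree,
    ec_level,
    normalize_rank,
)

#: Reserved bucket for records that lack the requested attribute entirely.
UNASSIGNED = "unassigned"

ATTRIBUTES: tuple[str, ...] = (
    "taxonomy",
    "go",
    "go_slim",
    "ec",
    "ko",
    "pathway",
    "com_name",
    "hmm",
)

#: Attributes for which rollup partitions records, so per-feature absolute
#: frequencies (including the reserved buckets) sum exactly to total weight.
CONSERVATIVE_ATTRIBUTES = frozenset({"taxonomy", "com_name", "hmm"})


@dataclass(frozen=True)
class AbundanceProfile:
    """Per-feature frequencies of one attribute in one dataset.

    ``values`` holds absolute (sum-of-weight) or relative frequencies
    depending on ``mode``; ``total`` is the sum of all record weights of the
    (filtered) dataset, i.e. the relative-frequency denominator.
    """

    dataset_id: str
    attribute: str
    level: str | int | None
    values: dict[str, float]
    total: float
    mode: str = "absolute"

    def __getitem__(self, feature: str) -> float:
        return self.values.get(feature, 0.0)

    def features(self) -> list[str]:
        return sorted(self.values)

    def relative(self) -> "AbundanceProfile":
        if self.mode == "relative":
            return self
        if self.total <= 0:
            values = {f: 0.0 for f in self.values}
        else:
            values = {f: v / self.total for f, v in self.values.items()}
        return AbundanceProfile(
            self.dataset_id, self.attribute, self.level, values, self.total, "relative"
        )

    def drop_unassigned(self) -> "AbundanceProfile":
        values = {
            f: v for f, v in self.values.items() if f not in (UNASSIGNED, UNRESOLVED)
        }
        return AbundanceProfile(
            self.dataset_id, self.attribute, self.level, values, self.total, self.mode
        )


def _feature_extractor(
    attribute: str,
    level: str | int | None,
    tree: TaxonomyTree | None,
    ontology: OntologyDAG | None,
    pathway_map: PathwayMap | None,
) -> Callable:
    """Return a function mapping a record to its set of feature labels."""
    if attribute == "taxonomy":
        if level in (None, "raw"):
            return lambda r: {str(r.blast_tree)} if r.blast_tree is not None else set()
        if tree is None:
            raise ValueError("taxonomy rollup requires a loaded taxonomy tree")
        rank = normalize_rank(str(level))

        def taxonomy_features(record):
            if record.blast_tree is None:
                return set()
            if record.blast_tree not in tree:
                return {UNRESOLVED}
            bucket = tree.rollup(record.blast_tree, rank)
            return {bucket if isinstance(bucket, str) else str(bucket)}

        return taxonomy_features
    if attribute == "go":
        return lambda r: set(r.go_id)
    if attribute == "go_slim":
        if ontology is None:
            raise ValueError("go_slim rollup requires a loaded ontology")

        def slim_features(record):
            features: set[str] = set()
            for accession in record.go_id:
                if accession in ontology:
                    features |= ontology.slim_map(accession)
            return features

        return slim_features
    if attribute == "ec":
        if level in (None, "raw", 4):
            return lambda r: set(r.ec_id)
        ec_lvl = int(level)
        return lambda r: {ec_level(e, ec_lvl) for e in r.ec_id}
    if attribute == "ko":
        return lambda r: set(r.ko_id)
    if attribute == "pathway":
        if pathway_map is None:
            raise ValueError("pathway rollup requires a loaded KO-to-pathway map")

        def pathway_features(record):
            features: set[str] = set()
            for ko in record.ko_id:
                features |= {pid for pid, _ in pathway_map.pathways(ko)}
            return features

        return pathway_features
    if attribute == "com_name":
        return lambda r: {r.com_name} if r.com_name else set()
    if attribute == "hmm":
        return lambda r: {r.hmm_id} if r.hmm_id else set()
    raise ValueError(f"unknown attribute {attribute!r}; expected one of {ATTRIBUTES}")


def absolute_frequency(
    dataset: Dataset,
    attribute: str,
    level: str | int | None = None,
    *,
    tree: TaxonomyTree | None = None,
    ontology: OntologyDAG | None = None,
    pathway_map: PathwayMap | None = None,
    weighted: bool = True,
    include_unassigned: bool = True,
) -> AbundanceProfile:
    """Sum of weights per feature of ``attribute`` at ``level``.

    With ``weighted=False`` every record contributes 1 instead of its weight
    (facet/count semantics).  Records with no value for the attribute fall
    into the ``unassigned`` bucket unless ``include_unassigned`` is False.
    """
    extract = _feature_extractor(attribute, level, tree, ontology, pathway_map)
    values: dict[str, float] = {}
    total = 0.0
    for record in dataset.records:
        w = record.weight if weighted else 1.0
        total += w
        features = extract(record)
        if not features:
            if include_unassigned:
                values[UNASSIGNED] = values.get(UNASSIGNED, 0.0) + w
            continue
        for feature in features:
            values[feature] = values.get(feature, 0.0) + w
    # deterministic key order for reproducible export
    values = {feature: values[feature] for feature in sorted(values)}
    return AbundanceProfile(dataset.library_id, attribute, level, values, total, "absolute")


def relative_frequency(
    dataset: Dataset,
    attribute: str,
    level: str | int | None = None,
    *,
    tree: TaxonomyTree | None = None,
    ontology: OntologyDAG | None = None,
    pathway_map: PathwayMap | None = None,
    weighted: bool = True,
    include_unassigned: bool = True,
    denominator: float | None = None,
) -> AbundanceProfile:
    """Per-feature share of the dataset's total weight.

    The denominator defaults to the total weight of the dataset passed in —
    i.e. the *post-filter* total when called on a filtered dataset.  Pass
    ``denominator`` explicitly (e.g. the pre-filter total) to override.
    """
    profile = absolute_frequency(
        dataset,
        attribute,
        level,
        tree=tree,
        ontology=ontology,
        pathway_map=pathway_map,
        weighted=weighted,
        include_unassigned=include_unassigned,
    )
    if denominator is None:
        return profile.relative()
    if denominator <= 0:
        raise ValueError("relative-frequency denominator must be positive")
    values = {f: v / denominator for f, v in profile.values.items()}
    return AbundanceProfile(
        profile.dataset_id, attribute, level, values, denominator, "relative"
    )


def profile_to_tsv(profiles: list[AbundanceProfile], path: str | Path) -> Path:
    """Write profiles as a features x datasets TSV table (sorted feature rows)."""
    if not profiles:
        raise ValueError("no profiles to export")
    path = Path(path)
    features = sorted(set().union(*(p.values.keys() for p in profiles)))
    with path.open("w", encoding="utf-8") as handle:
        handle.write("feature\t" + "\t".join(p.dataset_id for p in profiles) + "\n")
        for feature in features:
            cells = "\t".join(f"{p[feature]:.10g}" for p in profiles)
            handle.write(f"{feature}\t{cells}\n")
    return path
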