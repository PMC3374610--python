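"""Read, validate, write and pool datasets of weighted annotation records.

The on-disk format is a 17-column tab-delimited table, one row per annotated
entity (short read, ORF, transcript, contig ...), in a fixed column order:

    peptide_id  library_id  com_name  com_name_src  go_id  go_src  ec_id
    ec_src  hmm_id  blast_tree  blast_evalue  blast_pid  blast_cov  filter
    ko_id  ko_src  weight

Multi-valued cells (``go_id``, ``ec_id``, ``ko_id``) join their values with
``'||'``.  The tokens ``''``, ``'N/A'``, ``'NA'`` and ``'median'`` denote a
missing value (annotation pipelines that summarise per-gene BLAST statistics
print the literal word ``median`` in the E-value / percent-identity columns).
A missing or empty weight defaults to 1, so unweighted data degenerates to
plain record counting.

Every record carries a non-negative ``weight`` that adjusts its contribution
to abundance summaries: weights typically encode normalised read support
(RPKM-like) or annotation confidence, and abundance is a *sum of weights*
rather than a row count.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Column order of the tab-delimited import format.
COLUMNS: tuple[str, ...] = (
    "peptide_id",
    "library_id",
    "com_name",
    "com_name_src",
    "go_id",
    "go_src",
    "ec_id",
    "ec_src",
    "hmm_id",
    "blast_tree",
    "blast_evalue",
    "blast_pid",
    "blast_cov",
    "filter",
    "ko_id",
    "ko_src",
    "weight",
)

#: Fields that may carry several ``'||'``-separated accessions per cell.
MULTI_VALUED_FIELDS = frozenset({"go_id", "ec_id", "ko_id"})

MULTI_VALUE_SEPARATOR = "||"

#: Tokens that denote a missing value in any cell.
MISSING_TOKENS = frozenset({"", "N/A", "NA", "median"})

DIALECTS = ("generic", "humann", "jpmap")

GO_PATTERN = re.compile(r"GO:\d{7}$")
KO_PATTERN = re.compile(r"K\d{5}$")
# 1-4 dotted components; the leading component is a class digit, trailing
# components may be '-' wildcards (e.g. "1.2.-.-").
EC_PATTERN = re.compile(r"\d+(\.(\d+|-)){0,3}$")


class ParseError(ValueError):
    """Malformed input file (wrong column count, unreadable line)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(ValueError):
    """A row or record violates a format invariant."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True, slots=True)
class AnnotationRecord:
    """One annotated entity with taxonomic and functional assignments.

    ``go_id`` / ``ec_id`` / ``ko_id`` are tuples (possibly empty); numeric
    BLAST statistics are ``None`` when missing; ``weight >= 0`` scales the
    record's contribution to abundance sums.
    """

    peptide_id: str
    library_id: str
    com_name: str = ""
    com_name_src: str = ""
    go_id: tuple[str, ...] = ()
    go_src: str = ""
    ec_id: tuple[str, ...] = ()
    ec_src: str = ""
    hmm_id: str = ""
    blast_tree: int | None = None
    blast_evalue: float | None = None
    blast_pid: float | None = None
    blast_cov: float | None = None
    filter: str = ""
    ko_id: tuple[str, ...] = ()
    ko_src: str = ""
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.peptide_id:
            raise ValidationError("peptide_id must be non-empty")
        if self.weight < 0:
            raise ValidationError(
                f"negative weight {self.weight!r} for {self.peptide_id!r}"
            )
        for value in self.go_id:
            if not GO_PATTERN.match(value):
                raise ValidationError(f"malformed GO accession {value!r}")
        for value in self.ko_id:
            if not KO_PATTERN.match(value):
                raise ValidationError(f"malformed KO accession {value!r}")
        for value in self.ec_id:
            if not EC_PATTERN.match(value):
                raise ValidationError(f"malformed EC number {value!r}")
        if self.blast_tree is not None and self.blast_tree <= 0:
            raise ValidationError(f"taxonomy ID must be positive: {self.blast_tree}")
        if self.blast_evalue is not None and self.blast_evalue < 0:
            raise ValidationError("blast_evalue must be non-negative")
        for name in ("blast_pid", "blast_cov"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]: {value}")


@dataclass
class Dataset:
    """An ordered collection of records sharing one ``library_id``.

    ``metadata`` carries free-form sample descriptors (habitat, donor, visit,
    gender ...) used only for labelling.
    """

    library_id: str
    records: list[AnnotationRecord] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for record in self.records:
            if record.library_id != self.library_id:
                raise ValidationError(
                    f"record {record.peptide_id!r} has library_id "
                    f"{record.library_id!r}, expected {self.library_id!r}"
                )
            if record.peptide_id in seen:
                raise ValidationError(f"duplicate peptide_id {record.peptide_id!r}")
            seen.add(record.peptide_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self.records)

    @property
    def total_weight(self) -> float:
        """Sum of all record weights (the relative-frequency denominator)."""
        return float(sum(r.weight for r in self.records))

    def label(self) -> str:
        """Compact sample label ``[donor]-[habitat]-[gender]-[visit]-[sample]-[type]``.

        Only metadata keys that are present contribute; falls back to the
        library id when no metadata is set.
        """
        parts = [
            self.metadata.get(key, "")
            for key in ("donor", "habitat", "gender", "visit", "sample_id", "annotation_type")
        ]
        parts = [p for p in parts if p]
        return "-".join(parts) if parts else self.library_id


def _parse_missing(token: str) -> str | None:
    token = token.strip()
    return None if token in MISSING_TOKENS else token


def _parse_list(token: str) -> tuple[str, ...]:
    token = token.strip()
    if token in MISSING_TOKENS:
        return ()
    return tuple(v.strip() for v in token.split(MULTI_VALUE_SEPARATOR) if v.strip())


def _parse_float(token: str, column: str, line_number: int) -> float | None:
    value = _parse_missing(token)
    if value is None:
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise ValidationError(f"non-numeric {column}: {value!r}", line_number) from exc


def _parse_int(token: str, column: str, line_number: int) -> int | None:
    value = _parse_missing(token)
    if value is None:
        return None
    try:
        return int(value)
    except ValueError as exc:
        raise ValidationError(f"non-integer {column}: {value!r}", line_number) from exc


def record_from_fields(fields: Sequence[str], line_number: int = 0) -> AnnotationRecord:
    """Build a validated record from the 17 cell values of one row."""
    if len(fields) != len(COLUMNS):
        raise ParseError(
            f"expected {len(COLUMNS)} columns, found {len(fields)}", line_number
        )
    weight_token = fields[16].strip()
    weight = 1.0 if weight_token in MISSING_TOKENS else None
    if weight is None:
        try:
            weight = float(weight_token)
        except ValueError as exc:
            raise ValidationError(
                f"non-numeric weight: {weight_token!r}", line_number
            ) from exc
    try:
        return AnnotationRecord(
            peptide_id=fields[0].strip(),
            library_id=fields[1].strip(),
            com_name=(_parse_missing(fields[2]) or ""),
            com_name_src=(_parse_missing(fields[3]) or ""),
            go_id=_parse_list(fields[4]),
            go_src=(_parse_missing(fields[5]) or ""),
            ec_id=_parse_list(fields[6]),
            ec_src=(_parse_missing(fields[7]) or ""),
            hmm_id=(_parse_missing(fields[8]) or ""),
            blast_tree=_parse_int(fields[9], "blast_tree", line_number),
            blast_evalue=_parse_float(fields[10], "blast_evalue", line_number),
            blast_pid=_parse_float(fields[11], "blast_pid", line_number),
            blast_cov=_parse_float(fields[12], "blast_cov", line_number),
            filter=(_parse_missing(fields[13]) or ""),
            ko_id=_parse_list(fields[14]),
            ko_src=(_parse_missing(fields[15]) or ""),
            weight=weight,
        )
    except ValidationError as exc:
        if exc.line_number is None:
            raise ValidationError(str(exc), line_number) from exc
        raise


def read_tab_file(
    path: str | Path,
    dialect: str = "generic",
    strict: bool = True,
    metadata: Mapping[str, str] | None = None,
) -> Dataset:
    """Read one dataset from a 17-column tab-delimited annotation file.

    Parameters
    ----------
    path:
        Input file; ``'#'``-prefixed lines are treated as header/comments.
    dialect:
        ``generic``, ``humann`` or ``jpmap``.  All three share the column
        layout; the HUMAnN dialect additionally prints the literal token
        ``median`` in the E-value / percent-identity columns, which every
        dialect maps to missing.
    strict:
        If True (default), any invalid row raises; if False, invalid rows are
        skipped with a logged warning (the column-count check still raises,
        because silently dropping misaligned rows corrupts abundance sums).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    records: list[AnnotationRecord] = []
    library_id: str | None = None
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == len(COLUMNS) - 1:
                # weight column absent entirely: every record defaults to 1
                fields = list(fields) + [""]
            if len(fields) != len(COLUMNS):
                raise ParseError(
                    f"expected {len(COLUMNS)} columns, found {len(fields)}",
                    line_number,
                )
            try:
                record = record_from_fields(fields, line_number)
                if record.peptide_id in seen:
                    raise ValidationError(
                        f"duplicate peptide_id {record.peptide_id!r}", line_number
                    )
                if library_id is not None and record.library_id != library_id:
                    raise ValidationError(
                        f"library_id {record.library_id!r} differs from "
                        f"{library_id!r}",
                        line_number,
                    )
            except ValidationError as exc:
                if strict:
                    raise
                logger.warning("%s: skipping row (%s)", path.name, exc)
                continue
            if library_id is None:
                library_id = record.library_id
            seen.add(record.peptide_id)
            records.append(record)
    if library_id is None:
        library_id = path.stem
    return Dataset(library_id, records, dict(metadata or {}))


def _format_float(value: float | None) -> str:
    if value is None:
        return ""
    if value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return repr(value)  # shortest exact round-trip representation


def record_to_fields(record: AnnotationRecord) -> list[str]:
    """Serialize a record into its 17 canonical cell values."""
    return [
        record.peptide_id,
        record.library_id,
        record.com_name,
        record.com_name_src,
        MULTI_VALUE_SEPARATOR.join(record.go_id),
        record.go_src,
        MULTI_VALUE_SEPARATOR.join(record.ec_id),
        record.ec_src,
        record.hmm_id,
        "" if record.blast_tree is None else str(record.blast_tree),
        _format_float(record.blast_evalue),
        _format_float(record.blast_pid),
        _format_float(record.blast_cov),
        record.filter,
        MULTI_VALUE_SEPARATOR.join(record.ko_id),
        record.ko_src,
        _format_float(record.weight),
    ]


def write_tab_file(dataset: Dataset, path: str | Path) -> Path:
    """Write a dataset in the canonical tab-delimited form (round-trip safe)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("#" + "\t".join(COLUMNS) + "\n")
        for record in dataset.records:
            handle.write("\t".join(record_to_fields(record)) + "\n")
    return path


def pool_datasets(datasets: Sequence[Dataset], pooled_id: str) -> Dataset:
    """Concatenate datasets into one pooled dataset.

    Peptide ids are namespaced by their source library so uniqueness survives
    pooling; total weight is additive.
    """
    if not datasets:
        raise ValueError("pool_datasets requires at least one dataset")
    records: list[AnnotationRecord] = []
    for dataset in datasets:
        for record in dataset.records:
            records.append(
                dataclasses.replace(
                    record,
                    peptide_id=f"{record.library_id}:{record.peptide_id}",
                    library_id=pooled_id,
                )
            )
    metadata = {"pooled_from": ",".join(d.library_id for d in datasets)}
    return Dataset(pooled_id, records, metadata)


@dataclass(frozen=True)
class KoAnnotation:
    """Functional annotation attached to one KEGG ortholog."""

    ec_ids: tuple[str, ...] = ()
    go_ids: tuple[str, ...] = ()
    description: str = ""
    taxon: int | None = None


def map_humann_record(
    raw_row: Sequence,
    ko_table: Mapping[str, KoAnnotation],
    gene_to_ko: Mapping[str, str] | None = None,
    library_id: str = "",
) -> AnnotationRecord:
    """Map one raw short-read annotation row onto a full annotation record.

    ``raw_row`` is ``(gene_id, evalue, pid, read_length, weight)`` as emitted
    per gene by read-based annotation: the BLAST statistics are medians over
    all reads matching the gene, and the weight is the gene's normalised
    relative abundance in the sample.  ``gene_to_ko`` resolves the gene to a
    KEGG ortholog, and ``ko_table`` supplies the ortholog's EC/GO/description/
    taxon annotation.  A gene with no mapping keeps its weight but gets empty
    functional fields.
    """
    gene_id, evalue, pid, _read_length, weight = raw_row
    try:
        weight = float(weight)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric weight {weight!r}") from exc

    ko = None
    if gene_to_ko and gene_id in gene_to_ko:
        ko = gene_to_ko[gene_id]
    elif gene_id in ko_table:  # rows may already be keyed by ortholog
        ko = gene_id
    annotation = ko_table.get(ko) if ko is not None else None

    def _num(token) -> float | None:
        if token is None:
            return None
        if isinstance(token, str) and token.strip() in MISSING_TOKENS:
            return None
        return float(token)

    if annotation is None:
        return AnnotationRecord(
            peptide_id=str(gene_id),
            library_id=library_id,
            com_name_src=str(gene_id),
            blast_evalue=_num(evalue),
            blast_pid=_num(pid),
            weight=weight,
        )
    return AnnotationRecord(
        peptide_id=str(gene_id),
        library_id=library_id,
        com_name=annotation.description,
        com_name_src=str(gene_id),
        go_id=tuple(annotation.go_ids),
        go_src=ko or "",
        ec_id=tuple(annotation.ec_ids),
        ec_src=str(gene_id),
        blast_tree=annotation.taxon,
        blast_evalue=_num(evalue),
        blast_pid=_num(pid),
        filter="",
        ko_id=(ko,) if ko else (),
        ko_src=str(gene_id),
        weight=weight,
    )


def datasets_from_paths(
    paths: Iterable[str | Path], dialect: str = "generic", strict: bool = True
) -> list[Dataset]:
    """Convenience loader for a collection of annotation files."""
    return [read_tab_file(p, dialect=dialect, strict=strict) for p in paths]
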