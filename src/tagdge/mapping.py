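"""One-mismatch tag-to-gene assignment, per-gene counts and TPM.

Clean distinct tags are looked up in the reference index.  Exact hits take
precedence; an exact hit shared by several genes is final (ambiguous — no
rescue through mismatch neighbours).  A tag with no exact hit is compared
against the 51 single-substitution neighbours of its 17-nt variable region
(the CATG anchor is structurally exact: a corrupted anchor was already
removed at QC).  The union of the neighbours' gene sets decides the status:
one gene -> mismatch_unique, several -> ambiguous, none -> unknown.

Only tags with a unique gene (exact or one-mismatch) are quantified.  A tag
whose reference hits are the sense and antisense tag of the *same* gene is
unique to that gene and counted once.  Expression is normalised to TPM:
tag copies per million clean tags in the library.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ConsistencyError, InputError, UndefinedValueError
from .qc import CleanTagLibrary, is_well_formed, percent
from .reference import ANCHOR, TAG_LENGTH, ReferenceTagIndex

_BASES = "ACGT"

EXACT_UNIQUE = "exact_unique"
MISMATCH_UNIQUE = "mismatch_unique"
AMBIGUOUS = "ambiguous"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class MappingResult:
    tag: str
    status: str
    gene_id: str | None = None
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.status in (EXACT_UNIQUE, MISMATCH_UNIQUE) and not self.gene_id:
            raise ConsistencyError(f"unique mapping for {self.tag!r} lacks gene_id")
        if self.status in (AMBIGUOUS, UNKNOWN) and self.gene_id is not None:
            raise ConsistencyError(f"{self.status} mapping for {self.tag!r} carries gene_id")

    @property
    def is_unique(self) -> bool:
        return self.status in (EXACT_UNIQUE, MISMATCH_UNIQUE)


def one_mismatch_neighbors(tag: str) -> list[str]:
    """The 51 tags differing from ``tag`` at exactly one variable-region base."""
    neighbors = []
    for i in range(len(ANCHOR), TAG_LENGTH):
        for b in _BASES:
            if b != tag[i]:
                neighbors.append(tag[:i] + b + tag[i + 1 :])
    return neighbors


def map_tag(tag: str, index: ReferenceTagIndex, max_mismatch: int = 1) -> MappingResult:
    """Assign one clean tag to a gene, allowing at most one mismatch."""
    if not is_well_formed(tag):
        raise InputError(f"malformed query tag {tag!r}")
    if max_mismatch not in (0, 1):
        raise InputError("max_mismatch must be 0 or 1")
    genes = index.genes_for(tag)
    if genes:
        if len(genes) == 1:
            return MappingResult(tag=tag, status=EXACT_UNIQUE, gene_id=next(iter(genes)))
        return MappingResult(tag=tag, status=AMBIGUOUS)
    if max_mismatch == 0:
        return MappingResult(tag=tag, status=UNKNOWN)
    hit_genes: set[str] = set()
    for neighbor in one_mismatch_neighbors(tag):
        hit_genes |= index.genes_for(neighbor)
    if not hit_genes:
        return MappingResult(tag=tag, status=UNKNOWN)
    if len(hit_genes) == 1:
        return MappingResult(tag=tag, status=MISMATCH_UNIQUE, gene_id=hit_genes.pop(), mismatches=1)
    return MappingResult(tag=tag, status=AMBIGUOUS)


def map_library(
    clean: CleanTagLibrary, index: ReferenceTagIndex, max_mismatch: int = 1
) -> dict[str, MappingResult]:
    """Map every distinct clean tag of a library."""
    return {tag: map_tag(tag, index, max_mismatch) for tag in clean.counts}


def tpm(raw_count: int, clean_total: int) -> float:
    """Tag copies per million clean tags."""
    if clean_total <= 0:
        raise UndefinedValueError("TPM undefined for non-positive clean total")
    if raw_count < 0:
        raise InputError("negative raw count")
    return 1e6 * raw_count / clean_total


@dataclass(frozen=True)
class MappingSummary:
    """Library-level mapping report in the standard row order.

    Copy-based percentages are relative to the clean total, distinct-tag
    percentages to the distinct clean count, and gene percentages to the
    total number of genes in the reference.
    """

    library_id: str
    clean_total: int
    clean_distinct: int
    mapped_copies: int          # tags mapping to genes, incl. ambiguous
    mapped_distinct: int
    tag_mapped_genes: int       # genes hit by any mapping tag, incl. ambiguous
    unambiguous_copies: int
    unambiguous_distinct: int
    unambiguous_genes: int
    unknown_copies: int
    unknown_distinct: int
    reference_genes: int

    def to_series(self) -> pd.Series:
        rows = [
            ("clean_total", self.clean_total),
            ("distinct_clean_tags", self.clean_distinct),
            ("tags_mapping_to_genes", self.mapped_copies),
            ("pct_tags_mapping_to_genes", percent(self.mapped_copies, self.clean_total)),
            ("distinct_tags_mapping_to_genes", self.mapped_distinct),
            ("pct_distinct_tags_mapping_to_genes", percent(self.mapped_distinct, self.clean_distinct)),
            ("all_tag_mapped_genes", self.tag_mapped_genes),
            ("pct_all_tag_mapped_genes", percent(self.tag_mapped_genes, self.reference_genes)),
            ("unambiguous_tags", self.unambiguous_copies),
            ("pct_unambiguous_tags", percent(self.unambiguous_copies, self.clean_total)),
            ("distinct_unambiguous_tags", self.unambiguous_distinct),
            ("pct_distinct_unambiguous_tags", percent(self.unambiguous_distinct, self.clean_distinct)),
            ("unambiguous_tag_mapped_genes", self.unambiguous_genes),
            ("pct_unambiguous_tag_mapped_genes", percent(self.unambiguous_genes, self.reference_genes)),
            ("unknown_tags", self.unknown_copies),
            ("pct_unknown_tags", percent(self.unknown_copies, self.clean_total)),
            ("distinct_unknown_tags", self.unknown_distinct),
            ("pct_distinct_unknown_tags", percent(self.unknown_distinct, self.clean_distinct)),
        ]
        return pd.Series(dict(rows), name=self.library_id)


def count_genes(
    results: Mapping[str, MappingResult],
    clean: CleanTagLibrary,
    index: ReferenceTagIndex,
) -> tuple[pd.DataFrame, MappingSummary]:
    """Aggregate unique-tag copies per gene and build the library summary.

    Returns a DataFrame with columns ``gene_id, library_id, raw_count, tpm``
    (one row per gene with at least one unambiguous tag) and the
    :class:`MappingSummary`.  Every clean distinct tag must have a mapping
    result; a missing one is an internal consistency error.
    """
    per_gene: dict[str, int] = {}
    mapped_copies = mapped_distinct = 0
    unamb_copies = unamb_distinct = 0
    unknown_copies = unknown_distinct = 0
    mapped_genes: set[str] = set()
    for tag, copies in clean.counts.items():
        res = results.get(tag)
        if res is None:
            raise ConsistencyError(f"no mapping result for clean tag {tag!r}")
        if res.status == UNKNOWN:
            unknown_copies += copies
            unknown_distinct += 1
            continue
        mapped_copies += copies
        mapped_distinct += 1
        if res.is_unique:
            unamb_copies += copies
            unamb_distinct += 1
            per_gene[res.gene_id] = per_gene.get(res.gene_id, 0) + copies
            mapped_genes.add(res.gene_id)
        else:  # ambiguous: contributes to "tag-mapped genes" but not to counts
            mapped_genes |= index.genes_for(tag) or _ambiguous_genes(tag, index)
    if mapped_copies + unknown_copies != clean.clean_total:
        raise ConsistencyError("mapping summary does not conserve the clean total")
    clean_total = clean.clean_total
    records = pd.DataFrame(
        [
            {
                "gene_id": g,
                "library_id": clean.library_id,
                "raw_count": c,
                "tpm": tpm(c, clean_total) if clean_total else 0.0,
            }
            for g, c in sorted(per_gene.items())
        ],
        columns=["gene_id", "library_id", "raw_count", "tpm"],
    )
    summary = MappingSummary(
        library_id=clean.library_id,
        clean_total=clean_total,
        clean_distinct=clean.clean_distinct,
        mapped_copies=mapped_copies,
        mapped_distinct=mapped_distinct,
        tag_mapped_genes=len(mapped_genes),
        unambiguous_copies=unamb_copies,
        unambiguous_distinct=unamb_distinct,
        unambiguous_genes=len(per_gene),
        unknown_copies=unknown_copies,
        unknown_distinct=unknown_distinct,
        reference_genes=index.n_genes,
    )
    return records, summary


def _ambiguous_genes(tag: str, index: ReferenceTagIndex) -> set[str]:
    """Gene set of an ambiguous one-mismatch hit (no exact hit exists)."""
    genes: set[str] = set()
    for neighbor in one_mismatch_neighbors(tag):
        genes |= index.genes_for(neighbor)
    return genes


def mapping_table(results: Mapping[str, MappingResult], clean: CleanTagLibrary) -> pd.DataFrame:
    """Per-tag mapping TSV content: tag, status, gene, mismatches, copies."""
    rows = [
        {
            "tag": tag,
            "status": res.status,
            "gene_id": res.gene_id or "",
            "mismatches": res.mismatches,
            "copies": clean.counts.get(tag, 0),
        }
        for tag, res in sorted(results.items())
    ]
    return pd.DataFrame(rows, columns=["tag", "status", "gene_id", "mismatches", "copies"])


def expression_matrix(per_library: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes x libraries matrices of raw counts and TPM (wide format).

    ``per_library`` maps library_id -> the per-gene frame from
    :func:`count_genes`.  Genes absent from a library get count 0 / TPM 0.
    """
    counts = {}
    tpms = {}
    for lib, df in per_library.items():
        counts[f"count_{lib}"] = df.set_index("gene_id")["raw_count"]
        tpms[f"tpm_{lib}"] = df.set_index("gene_id")["tpm"]
    wide = pd.DataFrame({**counts, **tpms}).fillna(0)
    wide[[c for c in wide.columns if c.startswith("count_")]] = wide[
        [c for c in wide.columns if c.startswith("count_")]
    ].astype(int)
    wide.index.name = "gene_id"
    return wide.sort_index()


def write_summary_tsv(summaries: list[MappingSummary], path: str | Path) -> None:
    df = pd.concat([s.to_series() for s in summaries], axis=1)
    df.index.name = "statistic"
    df.to_csv(path, sep="\t")
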