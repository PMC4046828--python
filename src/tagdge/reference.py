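"""In-silico NlaIII/MmeI digestion of transcripts into canonical 21-bp tags.

The tagging protocol anchors each transcript's 3' end on oligo(dT) beads,
cuts with NlaIII (recognition site CATG) and releases a 21-bp fragment with
MmeI: the CATG site plus the 17 nt immediately downstream.  Because only the
3'-most NlaIII fragment stays bead-bound, each transcript contributes at most
one canonical tag per strand: the tag at the 3'-most CATG that still has 17
valid (non-N) nucleotides downstream.

:func:`canonical_tag` extracts that tag for one sequence/strand and
:func:`build_reference_index` assembles the mapping index over a whole
transcript set, tracking which tags identify a unique gene (unambiguous) and
which are shared between genes (ambiguous, excluded from quantification
downstream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

TAG_LENGTH = 21
ANCHOR = "CATG"
#: nucleotides released downstream of the anchor by MmeI
DOWNSTREAM = TAG_LENGTH - len(ANCHOR)

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class Transcript:
    """A reference transcript (unigene) with a unique identifier."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise InputError("transcript gene_id must be non-empty")
        if not self.sequence:
            raise InputError(f"transcript {self.gene_id!r} has empty sequence")
        seq = self.sequence.upper()
        if set(seq) - _VALID_BASES:
            bad = sorted(set(seq) - _VALID_BASES)
            raise InputError(f"transcript {self.gene_id!r} contains invalid bases {bad}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class ReferenceTag:
    """One canonical 21-bp tag: CATG anchor plus 17 downstream nucleotides.

    ``site_offset`` is the 0-based position of the CATG on the oriented
    strand (i.e. after reverse complementation for strand ``-``).
    """

    tag: str
    gene_id: str
    strand: str
    site_offset: int

    def __post_init__(self) -> None:
        if len(self.tag) != TAG_LENGTH or not self.tag.startswith(ANCHOR):
            raise InputError(f"malformed reference tag {self.tag!r}")
        if "N" in self.tag:
            raise InputError(f"reference tag {self.tag!r} contains N")
        if self.strand not in ("+", "-"):
            raise InputError(f"invalid strand {self.strand!r}")


def canonical_tag(sequence: str, strand: str = "+", gene_id: str = "") -> ReferenceTag | None:
    """Extract the canonical tag of ``sequence`` on the requested strand.

    For strand ``-`` the sequence is reverse complemented first.  The tag is
    taken at the 3'-most CATG whose 17-nt downstream window is complete and
    free of N; sites with N in the window are skipped in favour of the next
    site upstream.  Returns ``None`` when no site qualifies — a siteless
    transcript is a valid (empty) result, not an error.
    """
    if strand not in ("+", "-"):
        raise InputError(f"invalid strand {strand!r}")
    seq = sequence.upper()
    if set(seq) - _VALID_BASES:
        raise InputError("sequence contains characters outside {A,C,G,T,N}")
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    # scan CATG occurrences from the 3' end
    pos = seq.rfind(ANCHOR)
    while pos != -1:
        window = seq[pos : pos + TAG_LENGTH]
        if len(window) == TAG_LENGTH and "N" not in window:
            return ReferenceTag(tag=window, gene_id=gene_id, strand=strand, site_offset=pos)
        pos = seq.rfind(ANCHOR, 0, pos)
    return None


class ReferenceTagIndex:
    """Mapping index: canonical tag -> set of gene ids, with ambiguity stats.

    Tags shared by more than one gene are retained but flagged ambiguous;
    quantification downstream uses only tags whose gene set has size one.
    Content is order-independent (set semantics over the input transcripts).
    """

    def __init__(self, records: Iterable[ReferenceTag], n_genes: int) -> None:
        self._records: list[ReferenceTag] = list(records)
        self._tags: dict[str, frozenset[str]] = {}
        self.n_genes = int(n_genes)
        by_tag: dict[str, set[str]] = {}
        for rec in self._records:
            by_tag.setdefault(rec.tag, set()).add(rec.gene_id)
        self._tags = {t: frozenset(g) for t, g in by_tag.items()}

    # -- queries ---------------------------------------------------------
    def genes_for(self, tag: str) -> frozenset[str]:
        return self._tags.get(tag, frozenset())

    def __contains__(self, tag: str) -> bool:
        return tag in self._tags

    def __len__(self) -> int:
        return len(self._tags)

    @property
    def tags(self) -> Mapping[str, frozenset[str]]:
        return self._tags

    @property
    def distinct_reference_tags(self) -> int:
        return len(self._tags)

    @property
    def unambiguous_reference_tags(self) -> int:
        return sum(1 for g in self._tags.values() if len(g) == 1)

    def records(self) -> Iterator[ReferenceTag]:
        return iter(self._records)

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tag": r.tag,
                "gene_ids": ",".join(sorted(self._tags[r.tag])),
                "gene_id": r.gene_id,
                "strand": r.strand,
                "site_offset": r.site_offset,
            }
            for r in sorted(self._records, key=lambda r: (r.tag, r.gene_id, r.strand))
        ]
        return pd.DataFrame(
            rows, columns=["tag", "gene_ids", "gene_id", "strand", "site_offset"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_genes: int | None = None) -> "ReferenceTagIndex":
        required = {"tag", "gene_id", "strand", "site_offset"}
        if not required <= set(df.columns):
            raise InputError(f"index table lacks columns {sorted(required - set(df.columns))}")
        records = [
            ReferenceTag(
                tag=row.tag, gene_id=row.gene_id, strand=row.strand, site_offset=int(row.site_offset)
            )
            for row in df.itertuples()
        ]
        if n_genes is None:
            n_genes = df["gene_id"].nunique()
        return cls(records, n_genes=n_genes)

    @classmethod
    def read_tsv(cls, path: str | Path, n_genes: int | None = None) -> "ReferenceTagIndex":
        return cls.from_frame(pd.read_csv(path, sep="\t"), n_genes=n_genes)

    def write_stats(self, path: str | Path) -> None:
        stats = {
            "n_genes": self.n_genes,
            "distinct_reference_tags": self.distinct_reference_tags,
            "unambiguous_reference_tags": self.unambiguous_reference_tags,
        }
        Path(path).write_text(json.dumps(stats, indent=2) + "\n")


def build_reference_index(
    transcripts: Iterable[Transcript], strand_mode: str = "both"
) -> ReferenceTagIndex:
    """Digest all transcripts and build the tag index.

    ``strand_mode`` is ``"both"`` (default: sense and antisense canonical
    tags, matching a non-strand-resolved reference) or ``"sense"``.
    Duplicate gene ids are an input error.
    """
    if strand_mode not in ("both", "sense"):
        raise InputError(f"strand_mode must be 'both' or 'sense', got {strand_mode!r}")
    transcripts = list(transcripts)
    if not transcripts:
        raise InputError("cannot build an index from an empty transcript set")
    seen: set[str] = set()
    for t in transcripts:
        if t.gene_id in seen:
            raise InputError(f"duplicate gene_id {t.gene_id!r}")
        seen.add(t.gene_id)
    strands = ("+",) if strand_mode == "sense" else ("+", "-")
    records: list[ReferenceTag] = []
    for t in transcripts:
        for strand in strands:
            tag = canonical_tag(t.sequence, strand=strand, gene_id=t.gene_id)
            if tag is not None:
                records.append(tag)
    return ReferenceTagIndex(records, n_genes=len(transcripts))


# -- FASTA I/O -----------------------------------------------------------
def read_fasta(path: str | Path) -> list[Transcript]:
    records = [
        Transcript(gene_id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.gene_id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")
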