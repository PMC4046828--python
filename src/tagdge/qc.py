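"""Raw-tag quality control: filtering, partition accounting and library stats.

A raw tag library is a multiset of nominally 21-bp sequences.  Cleaning
removes, in order: tags containing N or with a malformed structure (wrong
length or missing CATG anchor), tags that are exactly a configured adaptor
artifact, and distinct tags observed only once in the library (likely
sequencing errors).  The four partition counts — N/low-quality, adaptor-only,
singleton copies and clean copies — always sum exactly to the raw total, so
every raw tag is accounted for.

Copy-number distributions use the fixed bins [2,5], [6,10], [11,20], [21,50],
[51,100], >100 over both total copies and distinct tags.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InputError, UndefinedValueError
from .reference import ANCHOR, TAG_LENGTH

_TAG_BASES = frozenset("ACGT")

#: copy-number bins used for the abundance distribution (inclusive bounds)
COPY_BINS: tuple[tuple[int, float], ...] = (
    (2, 5),
    (6, 10),
    (11, 20),
    (21, 50),
    (51, 100),
    (101, float("inf")),
)


def _as_counts(tags: Iterable[str] | Mapping[str, int] | np.ndarray) -> Counter:
    """Normalise any accepted tag container to a Counter of str -> count."""
    if isinstance(tags, Mapping):
        counts = Counter()
        for tag, n in tags.items():
            if n < 0:
                raise InputError(f"negative copy number for tag {tag!r}")
            if n:
                counts[str(tag)] = int(n)
        return counts
    if isinstance(tags, np.ndarray):
        uniq, cnt = np.unique(tags, return_counts=True)
        return Counter(
            {
                (u.decode() if isinstance(u, bytes) else str(u)): int(c)
                for u, c in zip(uniq, cnt)
            }
        )
    return Counter(str(t) for t in tags)


@dataclass(frozen=True)
class RawTagLibrary:
    """A raw tag library as distinct tag -> multiplicity."""

    library_id: str
    counts: Mapping[str, int]

    @property
    def raw_total(self) -> int:
        return sum(self.counts.values())

    @property
    def raw_distinct(self) -> int:
        return len(self.counts)

    @classmethod
    def from_tags(cls, library_id: str, tags: Iterable[str] | np.ndarray) -> "RawTagLibrary":
        return cls(library_id=library_id, counts=dict(_as_counts(tags)))

    @classmethod
    def read_tags(cls, library_id: str, path: str | Path) -> "RawTagLibrary":
        """Read a one-tag-per-line text file."""
        with open(path) as fh:
            tags = [line.strip().upper() for line in fh if line.strip()]
        return cls.from_tags(library_id, tags)

    @classmethod
    def read_counts_tsv(cls, library_id: str, path: str | Path) -> "RawTagLibrary":
        """Read a tag -> count TSV (columns ``tag`` and ``count``)."""
        df = pd.read_csv(path, sep="\t")
        if not {"tag", "count"} <= set(df.columns):
            raise InputError(f"{path}: expected columns 'tag' and 'count'")
        return cls(
            library_id=library_id,
            counts={str(t).upper(): int(c) for t, c in zip(df["tag"], df["count"]) if c > 0},
        )


@dataclass(frozen=True)
class QCPartition:
    """Raw-tag accounting: the four categories partition the raw total."""

    n_containing: int
    adaptor_only: int
    singleton_copies: int
    clean: int

    @property
    def raw_total(self) -> int:
        return self.n_containing + self.adaptor_only + self.singleton_copies + self.clean

    def to_frame(self, library_id: str = "") -> pd.DataFrame:
        rows = [
            ("n_containing", self.n_containing),
            ("adaptor_only", self.adaptor_only),
            ("singleton_copies", self.singleton_copies),
            ("clean", self.clean),
            ("raw_total", self.raw_total),
        ]
        df = pd.DataFrame(rows, columns=["category", "count"])
        if library_id:
            df.insert(0, "library_id", library_id)
        return df


@dataclass(frozen=True)
class CleanTagLibrary:
    """Clean library: structurally valid tags with copy number >= 2."""

    library_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for tag, n in self.counts.items():
            if not is_well_formed(tag):
                raise InputError(f"clean library contains malformed tag {tag!r}")
            if n < 2:
                raise InputError(f"clean library tag {tag!r} has copy number {n} < 2")

    @property
    def clean_total(self) -> int:
        return sum(self.counts.values())

    @property
    def clean_distinct(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.counts.items())
        return pd.DataFrame(items, columns=["tag", "count"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, library_id: str, path: str | Path) -> "CleanTagLibrary":
        df = pd.read_csv(path, sep="\t")
        return cls(library_id=library_id, counts={str(t): int(c) for t, c in zip(df["tag"], df["count"])})


def is_well_formed(tag: str) -> bool:
    """True for a structurally valid clean tag: 21 nt, CATG anchor, ACGT only."""
    return (
        len(tag) == TAG_LENGTH
        and tag.startswith(ANCHOR)
        and not (set(tag) - _TAG_BASES)
    )


def filter_raw_tags(
    raw: RawTagLibrary, adaptor_tags: Iterable[str] = ()
) -> tuple[CleanTagLibrary, QCPartition]:
    """Partition a raw library into clean tags and the three reject classes.

    Order of precedence per distinct tag: N-containing, exact adaptor match,
    malformed structure (counted with the N/low-quality class), singleton
    copy number.  Counts are in raw-tag units and conserve the raw total.
    """
    adaptors = frozenset(str(a).upper() for a in adaptor_tags)
    n_containing = adaptor_only = singleton = 0
    clean: dict[str, int] = {}
    for tag, copies in raw.counts.items():
        if "N" in tag:
            n_containing += copies
        elif tag in adaptors:
            adaptor_only += copies
        elif not is_well_formed(tag):
            n_containing += copies
        elif copies < 2:
            singleton += copies
        else:
            clean[tag] = copies
    partition = QCPartition(
        n_containing=n_containing,
        adaptor_only=adaptor_only,
        singleton_copies=singleton,
        clean=sum(clean.values()),
    )
    if partition.raw_total != raw.raw_total:
        raise ConsistencyError(
            f"QC partition ({partition.raw_total}) does not conserve raw total ({raw.raw_total})"
        )
    return CleanTagLibrary(library_id=raw.library_id, counts=clean), partition


def percent(numerator: int, denominator: int) -> float:
    """100*numerator/denominator, rounded half-up to two decimals.

    Half-up rounding at two decimals reproduces the printed precision of the
    library summary reports this package emits.
    """
    if denominator == 0:
        raise UndefinedValueError("percent undefined for zero denominator")
    value = Decimal(100) * Decimal(int(numerator)) / Decimal(int(denominator))
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def copy_number_distribution(clean: CleanTagLibrary) -> pd.DataFrame:
    """Distribution of clean-tag abundance over the fixed copy-number bins.

    Returns one row per bin with total tag copies and distinct tag count;
    bins partition the library (totals sum to clean_total/clean_distinct).
    """
    rows = []
    for lo, hi in COPY_BINS:
        total = sum(c for c in clean.counts.values() if lo <= c <= hi)
        distinct = sum(1 for c in clean.counts.values() if lo <= c <= hi)
        label = f"[{lo},{int(hi)}]" if hi != float("inf") else f">{lo - 1}"
        rows.append({"bin": label, "total_copies": total, "distinct_tags": distinct})
    return pd.DataFrame(rows, columns=["bin", "total_copies", "distinct_tags"])


def qc_summary_frame(
    partitions: Mapping[str, QCPartition], raws: Mapping[str, RawTagLibrary] | None = None
) -> pd.DataFrame:
    """Library-report style QC summary: one row per statistic, one column per library."""
    libraries = list(partitions)
    rows: dict[str, list] = {}
    stats = [
        ("raw_total", lambda p: p.raw_total),
        ("n_containing", lambda p: p.n_containing),
        ("adaptor_only", lambda p: p.adaptor_only),
        ("singleton_copies", lambda p: p.singleton_copies),
        ("clean_total", lambda p: p.clean),
        ("clean_pct_of_raw", lambda p: percent(p.clean, p.raw_total)),
    ]
    for name, fn in stats:
        rows[name] = [fn(partitions[lib]) for lib in libraries]
    df = pd.DataFrame(rows, index=libraries).T
    df.index.name = "statistic"
    return df
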