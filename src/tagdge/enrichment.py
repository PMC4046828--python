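"""Hypergeometric pathway enrichment of DEG sets.

With N annotated genes in the background, n of them differentially
expressed, M genes annotated to a pathway and m DEGs among those, the
enrichment p-value is the hypergeometric upper tail

    P = P(X >= m) = 1 - sum_{i<m} C(M,i) C(N-M, n-i) / C(N,n).

Significance is flagged at raw P <= 0.05 (the convention of this assay
family); a BH-adjusted column is provided alongside but does not drive the
default flag.  Genes annotated to several pathways count in each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_fdr
from .errors import ConsistencyError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationMap:
    """Gene -> pathways mapping plus pathway descriptions."""

    gene_to_pathways: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_to_pathways:
            raise InputError("annotation is empty")
        for gene, pws in self.gene_to_pathways.items():
            if not pws:
                raise InputError(f"gene {gene!r} annotated to no pathway")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_to_pathways)

    @property
    def pathways(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for gene, pws in self.gene_to_pathways.items():
            for pw in pws:
                out.setdefault(pw, set()).add(gene)
        return {pw: frozenset(g) for pw, g in out.items()}

    @classmethod
    def from_pathways(
        cls, pathways: Mapping[str, Iterable[str]], descriptions: Mapping[str, str] | None = None
    ) -> "AnnotationMap":
        gene_to: dict[str, set[str]] = {}
        for pw, genes in pathways.items():
            genes = list(genes)
            if not genes:
                continue  # empty pathways are dropped
            for g in genes:
                gene_to.setdefault(str(g), set()).add(str(pw))
        return cls(
            gene_to_pathways={g: frozenset(p) for g, p in gene_to.items()},
            descriptions=dict(descriptions or {}),
        )

    @classmethod
    def read_gmt(cls, path: str | Path) -> "AnnotationMap":
        """Read a GMT file: pathway <tab> description <tab> gene1 <tab> ..."""
        pathways: dict[str, list[str]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                pathways[parts[0]] = [g for g in parts[2:] if g]
                descriptions[parts[0]] = parts[1]
        if not pathways:
            raise InputError(f"no pathway records in {path}")
        return cls.from_pathways(pathways, descriptions)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AnnotationMap":
        """Read a two-column gene <tab> pathway TSV (header optional)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise InputError(f"{path}: expected two columns (gene, pathway)")
        if str(df.iloc[0, 0]).lower() in ("gene", "gene_id"):
            df = df.iloc[1:]
        pathways: dict[str, list[str]] = {}
        for gene, pw in zip(df.iloc[:, 0], df.iloc[:, 1]):
            pathways.setdefault(str(pw), []).append(str(gene))
        return cls.from_pathways(pathways)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for pw, genes in sorted(self.pathways.items()):
                desc = self.descriptions.get(pw, "")
                fh.write("\t".join([pw, desc, *sorted(genes)]) + "\n")


def upper_tail_pvalue(N: int, n: int, M: int, m: int) -> float:
    """P(X >= m) for X hypergeometric(population N, successes M, draws n)."""
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise InputError(f"inconsistent hypergeometric counts N={N} n={n} M={M} m={m}")
    if m == 0:
        return 1.0
    p = float(hypergeom.sf(m - 1, N, M, n))
    return min(1.0, max(p, 0.0))


def enrich(
    deg_set: Iterable[str], annotation: AnnotationMap, alpha: float = 0.05
) -> pd.DataFrame:
    """Enrichment of a DEG set over every annotated pathway.

    DEGs without annotation are dropped (count logged).  Returns one row per
    pathway with N, n, M, m, pvalue, a BH-adjusted column and the raw-P
    significance flag, sorted by ascending p-value.
    """
    degs = {str(g) for g in deg_set}
    annotated = annotation.genes
    dropped = len(degs - annotated)
    if dropped:
        logger.info("dropping %d DEGs without pathway annotation", dropped)
    degs &= annotated
    N = len(annotated)
    n = len(degs)
    rows = []
    for pw, genes in sorted(annotation.pathways.items()):
        M = len(genes)
        m = len(genes & degs)
        if M > N or m > min(n, M):
            raise ConsistencyError(f"inconsistent contingency counts for pathway {pw!r}")
        p = upper_tail_pvalue(N, n, M, m)
        rows.append(
            {
                "pathway_id": pw,
                "description": annotation.descriptions.get(pw, ""),
                "N": N,
                "n": n,
                "M": M,
                "m": m,
                "pvalue": p,
            }
        )
    df = pd.DataFrame(
        rows, columns=["pathway_id", "description", "N", "n", "M", "m", "pvalue"]
    )
    df["fdr"] = bh_fdr(df["pvalue"]) if len(df) else []
    df["significant"] = df["pvalue"] <= alpha
    return df.sort_values("pvalue", kind="stable").reset_index(drop=True)
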