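"""Synthetic tag-library generator with known ground truth.

Emulates a five-stage tag-sequencing experiment end to end: a transcript
reference (i.i.d. bases at a configured GC content, uniform lengths, each
transcript rejection-sampled to carry at least one usable CATG site),
log-normal baseline abundances, planted fold changes between adjacent
stages, and raw 21-bp tag streams with per-base substitution errors,
N-containing artifacts and adaptor-only artifacts.

Artifact tags replace stream positions rather than being appended, so the
raw total equals the configured depth exactly and the QC partition of a
simulated library is a fixed-total decomposition.  Substitution errors are
i.i.d. over all 21 positions including the CATG anchor — real sequencing
errors do not respect the anchor, and anchor-corrupting errors exercise the
low-quality QC path.

All randomness flows from ``config.seed`` through fixed named substreams,
so identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationMap
from .errors import ConfigError, InputError
from .reference import ANCHOR, DOWNSTREAM, TAG_LENGTH, Transcript, canonical_tag

#: default adaptor-artifact 21-mer (adaptor-only reads carry no CATG anchor)
DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTGCTTG"

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Defaults mirror a deep five-stage fruit-development tag experiment:
    ~90k reference unigenes of mean length ~0.5 kb, ~6 million raw tags per
    stage library, a few percent of genes changing between adjacent stages,
    and low but non-zero sequencing error and artifact rates.
    """

    n_genes: int = 90_227
    length_min: int = 150
    length_max: int = 900
    gc_content: float = 0.45
    n_stages: int = 5
    expr_log_mean: float = 0.0
    expr_log_sd: float = 1.5
    de_fraction: float = 0.05
    log2fc_min: float = 1.0
    log2fc_max: float = 4.0
    depth_per_stage: int = 6_000_000
    substitution_rate: float = 0.002
    n_tag_rate: float = 0.005
    adaptor_tag_rate: float = 0.002
    seed: int = 0
    siteless_fraction: float = 0.0
    adaptor_sequence: str = DEFAULT_ADAPTOR
    de_tpm_floor: float | None = None

    def __post_init__(self) -> None:
        fractions = {
            "gc_content": self.gc_content,
            "de_fraction": self.de_fraction,
            "substitution_rate": self.substitution_rate,
            "n_tag_rate": self.n_tag_rate,
            "adaptor_tag_rate": self.adaptor_tag_rate,
            "siteless_fraction": self.siteless_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.n_tag_rate + self.adaptor_tag_rate > 1.0:
            raise ConfigError("artifact rates sum to more than 1")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be non-negative")
        if self.length_min < TAG_LENGTH + len(ANCHOR):
            raise ConfigError(
                f"length_min must be >= {TAG_LENGTH + len(ANCHOR)} "
                "(room for CATG plus the 17-nt tag body)"
            )
        if self.length_max < self.length_min:
            raise ConfigError("length_max must be >= length_min")
        if self.n_stages < 2:
            raise ConfigError("n_stages must be >= 2")
        if self.log2fc_min > self.log2fc_max or self.log2fc_min < 0:
            raise ConfigError("need 0 <= log2fc_min <= log2fc_max")
        if self.depth_per_stage < 0:
            raise ConfigError("depth_per_stage must be non-negative")
        if self.expr_log_sd < 0:
            raise ConfigError("expr_log_sd must be non-negative")
        if len(self.adaptor_sequence) != TAG_LENGTH:
            raise ConfigError("adaptor_sequence must be 21 nt")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """A named deterministic substream of the configured seed."""
    return np.random.default_rng([config.seed, stream])


_STREAM_TRANSCRIPTS = 0
_STREAM_EXPRESSION = 1
_STREAM_ANNOTATION = 2
_STREAM_TAGS_BASE = 100  # + stage index


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth of one simulation.

    ``abundances`` is (n_stages, n_genes) with each row on the simplex;
    ``log2fc`` and ``de_label`` are (n_stages - 1, n_genes): the planted
    log2 fold change of stage s+1 over stage s (0 for non-DE genes) and the
    planted-DE indicator.
    """

    gene_ids: tuple[str, ...]
    abundances: np.ndarray
    log2fc: np.ndarray
    de_label: np.ndarray

    def __post_init__(self) -> None:
        n_stages, n_genes = self.abundances.shape
        if len(self.gene_ids) != n_genes:
            raise InputError("gene_ids / abundance shape mismatch")
        if self.log2fc.shape != (n_stages - 1, n_genes):
            raise InputError("log2fc shape mismatch")
        if n_genes and not np.allclose(self.abundances.sum(axis=1), 1.0, atol=1e-9):
            raise InputError("stage abundances must sum to 1")

    @property
    def n_stages(self) -> int:
        return self.abundances.shape[0]

    def to_frame(self) -> pd.DataFrame:
        data = {"gene_id": list(self.gene_ids)}
        for s in range(self.n_stages):
            data[f"abundance_s{s + 1}"] = self.abundances[s]
        for p in range(self.n_stages - 1):
            data[f"log2fc_s{p + 1}_s{p + 2}"] = self.log2fc[p]
            data[f"de_s{p + 1}_s{p + 2}"] = self.de_label[p].astype(int)
        return pd.DataFrame(data)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------
def _random_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    codes = rng.choice(4, size=length, p=probs)
    return bytes(_BASE_BYTES[codes]).decode()


def _has_usable_site(seq: str) -> bool:
    return seq.find(ANCHOR, 0, len(seq) - DOWNSTREAM) != -1


def generate_transcriptome(config: SimulationConfig) -> list[Transcript]:
    """Generate ``n_genes`` random transcripts, each with a usable CATG site.

    A usable site is a CATG with at least 17 nt downstream; sequences are
    redrawn until one exists (up to a generous retry cap).  A configured
    ``siteless_fraction`` of genes (an exact-size random subset) is exempt
    from the requirement, for edge-case testing.
    """
    rng = _rng(config, _STREAM_TRANSCRIPTS)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    n = config.n_genes
    n_siteless = int(round(config.siteless_fraction * n))
    exempt = set(rng.choice(n, size=n_siteless, replace=False).tolist()) if n_siteless else set()
    width = max(4, len(str(max(n - 1, 0))))
    transcripts = []
    for i in range(n):
        length = int(rng.integers(config.length_min, config.length_max + 1))
        for attempt in range(10_000):
            seq = _random_sequence(rng, length, probs)
            if i in exempt or _has_usable_site(seq):
                break
        else:  # pragma: no cover - astronomically unlikely for valid configs
            raise ConfigError(
                f"could not place a usable CATG site in a {length}-nt transcript"
            )
        transcripts.append(Transcript(gene_id=f"gene{i:0{width}d}", sequence=seq))
    return transcripts


# ---------------------------------------------------------------------------
# expression truth
# ---------------------------------------------------------------------------
def plant_expression(
    config: SimulationConfig, gene_ids: Sequence[str] | None = None
) -> GroundTruth:
    """Draw baseline abundances and plant per-stage-pair fold changes.

    Baselines are log-normal then normalised to the simplex.  For each
    adjacent stage pair an exact-size random subset of ``de_fraction`` of
    the genes is multiplied by 2^(+-u), u ~ Uniform[log2fc_min, log2fc_max]
    with random sign, and the stage re-normalised.  With ``de_tpm_floor``
    set, only genes at or above that baseline TPM in the source stage are
    eligible for planting.
    """
    rng = _rng(config, _STREAM_EXPRESSION)
    n = config.n_genes
    if gene_ids is None:
        width = max(4, len(str(max(n - 1, 0))))
        gene_ids = tuple(f"gene{i:0{width}d}" for i in range(n))
    else:
        gene_ids = tuple(gene_ids)
        if len(gene_ids) != n:
            raise InputError("gene_ids length does not match n_genes")
    if n == 0:
        shape = (config.n_stages, 0)
        return GroundTruth(gene_ids, np.zeros(shape), np.zeros((config.n_stages - 1, 0)),
                           np.zeros((config.n_stages - 1, 0), dtype=bool))
    base = rng.lognormal(config.expr_log_mean, config.expr_log_sd, size=n)
    abund = np.zeros((config.n_stages, n))
    abund[0] = base / base.sum()
    log2fc = np.zeros((config.n_stages - 1, n))
    de = np.zeros((config.n_stages - 1, n), dtype=bool)
    k = int(round(config.de_fraction * n))
    for pair in range(config.n_stages - 1):
        current = abund[pair]
        if config.de_tpm_floor is not None:
            eligible = np.nonzero(current * 1e6 >= config.de_tpm_floor)[0]
        else:
            eligible = np.arange(n)
        k_pair = min(k, len(eligible))
        idx = rng.choice(eligible, size=k_pair, replace=False)
        u = rng.uniform(config.log2fc_min, config.log2fc_max, size=k_pair)
        sign = rng.choice([-1.0, 1.0], size=k_pair)
        log2fc[pair, idx] = sign * u
        de[pair, idx] = True
        nxt = current * np.exp2(log2fc[pair])
        abund[pair + 1] = nxt / nxt.sum()
    return GroundTruth(gene_ids=gene_ids, abundances=abund, log2fc=log2fc, de_label=de)


# ---------------------------------------------------------------------------
# raw tag streams
# ---------------------------------------------------------------------------
def simulate_raw_tags(
    transcripts: Sequence[Transcript],
    truth: GroundTruth,
    stage: int,
    config: SimulationConfig,
) -> np.ndarray:
    """Simulate one stage's raw tag stream (dtype ``S21``, length = depth).

    Real tags are the sampled gene's canonical sense-strand 21-mer with
    i.i.d. per-base substitutions; configured fractions of stream positions
    are replaced by N-containing artifacts (a random position set to N) and
    adaptor-only artifacts (the configured adaptor 21-mer).
    """
    if not 0 <= stage < truth.n_stages:
        raise InputError(f"stage {stage} out of range [0, {truth.n_stages})")
    if len(transcripts) != len(truth.gene_ids):
        raise InputError("transcripts and ground truth are of different sizes")
    rng = _rng(config, _STREAM_TAGS_BASE + stage)
    depth = config.depth_per_stage
    if depth == 0:
        return np.empty(0, dtype="S21")

    tags = [canonical_tag(t.sequence, "+", t.gene_id) for t in transcripts]
    has_tag = np.array([t is not None for t in tags])
    weights = truth.abundances[stage] * has_tag
    if weights.sum() <= 0:
        raise InputError("no transcript with a canonical tag has positive abundance")
    weights = weights / weights.sum()
    tag_bytes = np.zeros((len(transcripts), TAG_LENGTH), dtype=np.uint8)
    for i, t in enumerate(tags):
        if t is not None:
            tag_bytes[i] = np.frombuffer(t.tag.encode(), dtype=np.uint8)

    gene_idx = rng.choice(len(transcripts), size=depth, p=weights)
    mat = tag_bytes[gene_idx].copy()

    # i.i.d. substitutions over all 21 positions (anchor included)
    if config.substitution_rate > 0:
        mask = rng.random((depth, TAG_LENGTH)) < config.substitution_rate
        n_sub = int(mask.sum())
        if n_sub:
            orig = _CODE_LUT[mat[mask]]
            shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
            mat[mask] = _BASE_BYTES[(orig + shift) % 4]

    # artifact replacement keeps the stream length exact
    u = rng.random(depth)
    n_mask = u < config.n_tag_rate
    a_mask = (~n_mask) & (u < config.n_tag_rate + config.adaptor_tag_rate)
    n_rows = np.nonzero(n_mask)[0]
    if len(n_rows):
        cols = rng.integers(0, TAG_LENGTH, size=len(n_rows))
        mat[n_rows, cols] = ord("N")
    a_rows = np.nonzero(a_mask)[0]
    if len(a_rows):
        mat[a_rows] = np.frombuffer(config.adaptor_sequence.encode(), dtype=np.uint8)

    return mat.reshape(-1).view("S21").reshape(depth)


def simulate_annotation(
    gene_ids: Sequence[str],
    n_pathways: int = 120,
    size_min: int = 5,
    size_max: int = 200,
    seed: int = 0,
    annotated_fraction: float = 0.6,
) -> AnnotationMap:
    """Random GMT-style gene -> pathway annotation over a gene universe.

    A fraction of genes forms the annotated background; each pathway draws a
    random subset of it (genes may belong to several pathways, as in real
    pathway databases).
    """
    if not gene_ids:
        raise InputError("gene_ids must be non-empty")
    if not 0 < annotated_fraction <= 1:
        raise InputError("annotated_fraction must lie in (0, 1]")
    rng = np.random.default_rng([seed, _STREAM_ANNOTATION])
    genes = np.array(sorted(str(g) for g in gene_ids))
    n_annot = max(1, int(round(annotated_fraction * len(genes))))
    background = rng.choice(genes, size=n_annot, replace=False)
    pathways: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    width = len(str(n_pathways))
    for p in range(n_pathways):
        size = int(rng.integers(size_min, min(size_max, n_annot) + 1))
        members = rng.choice(background, size=size, replace=False)
        name = f"pw{p:0{width}d}"
        pathways[name] = members.tolist()
        descriptions[name] = f"synthetic pathway {p}"
    # make sure every background gene is annotated at least once
    covered = {g for members in pathways.values() for g in members}
    missing = [g for g in background if g not in covered]
    if missing:
        pathways[f"pw{n_pathways:0{width}d}"] = missing
        descriptions[f"pw{n_pathways:0{width}d}"] = "synthetic catch-all pathway"
    return AnnotationMap.from_pathways(pathways, descriptions)


# ---------------------------------------------------------------------------
# stream I/O
# ---------------------------------------------------------------------------
def write_tag_stream(stream: np.ndarray, path: str | Path) -> None:
    """Write a raw tag stream as one tag per line."""
    with open(path, "wb") as fh:
        for tag in stream:
            fh.write(tag + b"\n")


def read_tag_stream(path: str | Path) -> np.ndarray:
    with open(path, "rb") as fh:
        tags = [line.strip() for line in fh if line.strip()]
    return np.array(tags, dtype="S21")


def write_manifest(config: SimulationConfig, path: str | Path, **extra) -> None:
    from . import __version__

    manifest = {"tool": "tagdge", "version": __version__, "config": config.to_dict(), **extra}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
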