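"""End-to-end orchestration of the simulated tag-DGE analysis.

``run_pipeline`` chains the stages in protocol order — simulate, digest the
reference, QC each library, map, quantify, test adjacent stage pairs,
classify five-stage profiles, enrich DEG sets and subsample for saturation —
writing every intermediate as TSV/FASTA/JSON so each stage can be re-run
independently from the previous stage's files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import de, mapping, qc, reference, saturation, simulate
from .enrichment import AnnotationMap, enrich
from .errors import InputError


@dataclass
class PipelineResult:
    """In-memory handles to everything one pipeline run produced."""

    config: simulate.SimulationConfig
    outdir: Path
    transcripts: list
    truth: simulate.GroundTruth
    index: reference.ReferenceTagIndex
    clean_libraries: dict[str, qc.CleanTagLibrary]
    partitions: dict[str, qc.QCPartition]
    mapping_summaries: dict[str, mapping.MappingSummary]
    expression: pd.DataFrame
    de_results: dict[str, de.DGEResults]
    patterns: pd.DataFrame | None = None
    enrichments: dict[str, pd.DataFrame] = field(default_factory=dict)
    saturation: pd.DataFrame | None = None


def run_pipeline(
    config: simulate.SimulationConfig,
    outdir: str | Path,
    fdr_max: float = 0.001,
    min_abs_log2: float = 1.0,
    strand_mode: str = "both",
    max_mismatch: int = 1,
    annotation: AnnotationMap | None = None,
    simulate_pathways: bool = False,
    saturation_replicates: int = 3,
    write_streams: bool = False,
) -> PipelineResult:
    """Run the full simulated analysis and write all artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- simulate -------------------------------------------------------
    transcripts = simulate.generate_transcriptome(config)
    truth = simulate.plant_expression(config, [t.gene_id for t in transcripts])
    reference.write_fasta(transcripts, outdir / "transcripts.fasta")
    truth.write_tsv(outdir / "ground_truth.tsv")
    simulate.write_manifest(config, outdir / "manifest.json",
                            fdr_max=fdr_max, min_abs_log2=min_abs_log2,
                            strand_mode=strand_mode, max_mismatch=max_mismatch)

    # -- reference digestion -------------------------------------------
    index = reference.build_reference_index(transcripts, strand_mode=strand_mode)
    index.write_tsv(outdir / "reference_index.tsv")
    index.write_stats(outdir / "reference_stats.json")

    # -- per-stage libraries: simulate, QC, map ------------------------
    stage_ids = [f"S{s + 1}" for s in range(config.n_stages)]
    clean_libs: dict[str, qc.CleanTagLibrary] = {}
    partitions: dict[str, qc.QCPartition] = {}
    summaries: dict[str, mapping.MappingSummary] = {}
    per_gene: dict[str, pd.DataFrame] = {}
    results_by_lib: dict[str, dict[str, mapping.MappingResult]] = {}
    for s, lib in enumerate(stage_ids):
        stream = simulate.simulate_raw_tags(transcripts, truth, s, config)
        if write_streams:
            simulate.write_tag_stream(stream, outdir / f"raw_tags_{lib}.txt")
        raw = qc.RawTagLibrary.from_tags(lib, stream)
        raw_counts = pd.DataFrame(sorted(raw.counts.items()), columns=["tag", "count"])
        raw_counts.to_csv(outdir / f"raw_counts_{lib}.tsv", sep="\t", index=False)
        clean, part = qc.filter_raw_tags(raw, adaptor_tags=[config.adaptor_sequence])
        clean.write_tsv(outdir / f"clean_{lib}.tsv")
        clean_libs[lib], partitions[lib] = clean, part
        results = mapping.map_library(clean, index, max_mismatch=max_mismatch)
        results_by_lib[lib] = results
        mapping.mapping_table(results, clean).to_csv(
            outdir / f"mapping_{lib}.tsv", sep="\t", index=False
        )
        per_gene[lib], summaries[lib] = mapping.count_genes(results, clean, index)

    qc.qc_summary_frame(partitions).to_csv(outdir / "qc_summary.tsv", sep="\t")
    mapping.write_summary_tsv(list(summaries.values()), outdir / "mapping_summary.tsv")
    expression = mapping.expression_matrix(per_gene)
    expression.to_csv(outdir / "expression_matrix.tsv", sep="\t")

    # -- differential expression between adjacent stages ---------------
    de_results: dict[str, de.DGEResults] = {}
    for a, b in zip(stage_ids, stage_ids[1:]):
        model = de.PairwiseDGE.from_dataframe(
            expression, a, b,
            total_a=clean_libs[a].clean_total, total_b=clean_libs[b].clean_total,
        )
        res = model.fit(fdr_max=fdr_max, min_abs_log2=min_abs_log2)
        res.write_tsv(outdir / f"de_{a}_{b}.tsv")
        de_results[f"{a}_{b}"] = res

    # -- abundance categories and five-stage trend groups --------------
    tpm_cols = [f"tpm_{lib}" for lib in stage_ids]
    de.categorize_frame(expression[tpm_cols]).to_csv(
        outdir / "categories.tsv", sep="\t", index=False
    )
    patterns = None
    if config.n_stages == 5:
        expressed = expression[(expression[tpm_cols] > 0).any(axis=1)]
        patterns = de.classify_profiles(expressed[tpm_cols])
        patterns.to_csv(outdir / "patterns.tsv", sep="\t", index=False)

    # -- pathway enrichment ---------------------------------------------
    if annotation is None and simulate_pathways:
        annotation = simulate.simulate_annotation(
            [t.gene_id for t in transcripts], seed=config.seed
        )
        annotation.write_gmt(outdir / "annotation.gmt")
    enrichments: dict[str, pd.DataFrame] = {}
    if annotation is not None:
        for pair, res in de_results.items():
            degs = res.degs["gene_id"].tolist()
            table = enrich(degs, annotation)
            table.to_csv(outdir / f"enrichment_{pair}.tsv", sep="\t", index=False)
            enrichments[pair] = table

    # -- saturation on the first library --------------------------------
    sat = None
    first = stage_ids[0]
    if clean_libs[first].clean_total > 0:
        sat = saturation.saturation_curve(
            clean_libs[first], results_by_lib[first],
            replicates=saturation_replicates, seed=config.seed,
        )
        sat.to_csv(outdir / "saturation.tsv", sep="\t", index=False)

    return PipelineResult(
        config=config, outdir=outdir, transcripts=transcripts, truth=truth,
        index=index, clean_libraries=clean_libs, partitions=partitions,
        mapping_summaries=summaries, expression=expression, de_results=de_results,
        patterns=patterns, enrichments=enrichments, saturation=sat,
    )


def read_mapping_table(path: str | Path) -> dict[str, mapping.MappingResult]:
    """Rebuild per-tag mapping results from a mapping TSV."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"tag", "status", "gene_id", "mismatches"}
    if not required <= set(df.columns):
        raise InputError(f"{path}: mapping table lacks {sorted(required - set(df.columns))}")
    out: dict[str, mapping.MappingResult] = {}
    for row in df.itertuples():
        gene = row.gene_id or None
        out[row.tag] = mapping.MappingResult(
            tag=row.tag, status=row.status, gene_id=gene, mismatches=int(row.mismatches)
        )
    return out


def read_manifest(path: str | Path) -> simulate.SimulationConfig:
    data = json.loads(Path(path).read_text())
    return simulate.SimulationConfig(**data["config"])
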