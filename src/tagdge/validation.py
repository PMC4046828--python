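"""Self-validation harness: independent oracles and benchmark scenarios.

Every function here re-derives a pipeline quantity through a route that is
deliberately different from the implementation it checks — term-wise tail
summation instead of the adaptive two-tail logic, exact rational
enumeration instead of scipy's hypergeometric survival function, an
exhaustive Hamming scan instead of neighbour enumeration — or runs a
seeded simulation scenario with known ground truth and measures how well
the pipeline recovers it.  The test suite and the reproduction script are
both built on these functions.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import datasets, de, mapping, qc, reference, saturation, simulate
from .errors import InputError

# ---------------------------------------------------------------------------
# library-report arithmetic
# ---------------------------------------------------------------------------
def recomputed_report_percentages(library: str = "FS1") -> dict[str, float]:
    """Recompute one library's report percentages from its raw counts."""
    counts = datasets.library_summary_counts()[library]
    return {
        "pct_clean_of_raw": qc.percent(counts.clean_total, counts.raw_total),
        "pct_mapped_copies": qc.percent(counts.mapped_copies, counts.clean_total),
        "pct_mapped_distinct": qc.percent(counts.mapped_distinct, counts.clean_distinct),
        "pct_tag_mapped_genes": qc.percent(counts.tag_mapped_genes, datasets.REFERENCE_GENES),
        "pct_unambiguous_copies": qc.percent(counts.unambiguous_copies, counts.clean_total),
        "pct_unambiguous_distinct": qc.percent(
            counts.unambiguous_distinct, counts.clean_distinct
        ),
        "pct_unambiguous_genes": qc.percent(counts.unambiguous_genes, datasets.REFERENCE_GENES),
        "pct_unknown_copies": qc.percent(counts.unknown_copies, counts.clean_total),
        "pct_unknown_distinct": qc.percent(counts.unknown_distinct, counts.clean_distinct),
    }


# ---------------------------------------------------------------------------
# exact-test oracle
# ---------------------------------------------------------------------------
def _oracle_two_sided_row(x: int, r: float, y_max: int) -> np.ndarray:
    """Two-sided p for y = 0..y_max by direct term-wise tail summation."""
    mean = r * (x + 1)
    sd = np.sqrt(r * (1 + r) * (x + 1))
    K = int(max(y_max + 2, mean + 40 * sd + 200))
    k = np.arange(K + 1, dtype=float)
    log_t = (
        k * np.log(r)
        + gammaln(x + k + 1)
        - gammaln(x + 1)
        - gammaln(k + 1)
        - (x + k + 1) * np.log1p(r)
    )
    t = np.exp(log_t)
    lower = np.cumsum(t)  # F(y), inclusive
    # suffix sums accumulate the upper tail from small terms upward, so tiny
    # tails are formed without cancellation
    suffix = np.cumsum(t[::-1])[::-1]
    upper_excl = np.append(suffix[1:], 0.0)  # sum over k > y
    small = np.minimum(lower, upper_excl)
    return np.minimum(1.0, 2.0 * small)[: y_max + 1]


def ac_oracle_max_error(
    count_max: int = 200, totals: tuple[float, ...] = (1e5, 1e6, 5e6)
) -> float:
    """Max |ac_pvalue - term-wise oracle| over the full count/total grid."""
    worst = 0.0
    for n1 in totals:
        for n2 in totals:
            r = n2 / n1
            for x in range(count_max + 1):
                expected = _oracle_two_sided_row(x, r, count_max)
                for y in range(count_max + 1):
                    got = de.ac_pvalue(x, y, n1, n2)
                    err = abs(got - expected[y])
                    if err > worst:
                        worst = err
    return worst


# ---------------------------------------------------------------------------
# simulation scenarios
# ---------------------------------------------------------------------------
def _two_library_counts(config: simulate.SimulationConfig):
    """Simulate, QC and map both libraries of a two-stage configuration."""
    transcripts = simulate.generate_transcriptome(config)
    truth = simulate.plant_expression(config, [t.gene_id for t in transcripts])
    index = reference.build_reference_index(transcripts, strand_mode="both")
    per_gene = {}
    totals = {}
    for stage, lib in enumerate(("A", "B")):
        stream = simulate.simulate_raw_tags(transcripts, truth, stage, config)
        raw = qc.RawTagLibrary.from_tags(lib, stream)
        clean, part = qc.filter_raw_tags(raw, adaptor_tags=[config.adaptor_sequence])
        if part.raw_total != config.depth_per_stage:
            raise InputError("QC partition does not conserve the simulated depth")
        results = mapping.map_library(clean, index)
        records, summary = mapping.count_genes(results, clean, index)
        if summary.mapped_copies + summary.unknown_copies != clean.clean_total:
            raise InputError("mapping does not conserve the clean total")
        per_gene[lib] = records
        totals[lib] = clean.clean_total
    matrix = mapping.expression_matrix(per_gene)
    matrix = matrix.reindex([t.gene_id for t in transcripts], fill_value=0)
    return truth, matrix, totals


def null_de_call_count(seed: int) -> int:
    """Genes called DE in a null two-library simulation (no planted effects).

    2,000 genes, two libraries of one million raw tags, 0.2% per-base error,
    no planted fold changes; DE calling at FDR <= 0.001 and |log2| >= 1.
    """
    config = simulate.SimulationConfig(
        n_genes=2_000,
        n_stages=2,
        de_fraction=0.0,
        depth_per_stage=1_000_000,
        substitution_rate=0.002,
        seed=seed,
    )
    _, matrix, totals = _two_library_counts(config)
    model = de.PairwiseDGE.from_dataframe(matrix, "A", "B", totals["A"], totals["B"])
    res = model.fit(fdr_max=0.001, min_abs_log2=1.0)
    return res.n_up + res.n_down


def planted_recovery(seed: int) -> dict[str, float]:
    """Sensitivity and effect-size accuracy on planted 4-fold changes.

    10% of 2,000 genes planted at |log2 fc| = 2 among genes with baseline
    TPM >= 50; two libraries of two million raw tags.  Returns the fraction
    of planted genes called DE in the true direction and the median
    |observed - true| log2 ratio over the recovered genes.
    """
    config = simulate.SimulationConfig(
        n_genes=2_000,
        n_stages=2,
        de_fraction=0.1,
        log2fc_min=2.0,
        log2fc_max=2.0,
        de_tpm_floor=50.0,
        depth_per_stage=2_000_000,
        substitution_rate=0.002,
        seed=seed,
    )
    truth, matrix, totals = _two_library_counts(config)
    model = de.PairwiseDGE.from_dataframe(matrix, "A", "B", totals["A"], totals["B"])
    res = model.fit(fdr_max=0.001, min_abs_log2=1.0)
    frame = res.frame.set_index("gene_id")
    planted = np.nonzero(truth.de_label[0])[0]
    true_lfc = truth.log2fc[0]
    recovered = []
    for i in planted:
        gene = truth.gene_ids[i]
        call = frame.loc[gene, "call"]
        want = de.UP if true_lfc[i] > 0 else de.DOWN
        if call == want:
            recovered.append(abs(frame.loc[gene, "log2_ratio"] - true_lfc[i]))
    sensitivity = len(recovered) / len(planted)
    median_err = float(np.median(recovered)) if recovered else float("nan")
    return {
        "sensitivity": sensitivity,
        "median_abs_log2_error": median_err,
        "n_planted": int(len(planted)),
    }


# ---------------------------------------------------------------------------
# mapping oracle
# ---------------------------------------------------------------------------
def _brute_force_map(tag: str, index: reference.ReferenceTagIndex):
    exact: set[str] = set()
    one_off: set[str] = set()
    for ref, genes in index.tags.items():
        dist = sum(a != b for a, b in zip(tag, ref))
        if dist == 0:
            exact |= genes
        elif dist == 1 and tag[:4] == ref[:4]:
            one_off |= genes
    if exact:
        if len(exact) == 1:
            return mapping.EXACT_UNIQUE, next(iter(exact))
        return mapping.AMBIGUOUS, None
    if not one_off:
        return mapping.UNKNOWN, None
    if len(one_off) == 1:
        return mapping.MISMATCH_UNIQUE, next(iter(one_off))
    return mapping.AMBIGUOUS, None


def mapping_oracle_mismatches(
    n_queries: int = 1_000, n_genes: int = 300, seed: int = 0
) -> int:
    """Disagreements between map_tag and the exhaustive Hamming scan.

    Queries mix exact reference tags, single-substitution variants and
    random anchored 21-mers, so every status class is exercised.
    """
    config = simulate.SimulationConfig(n_genes=n_genes, depth_per_stage=0, seed=seed)
    transcripts = simulate.generate_transcriptome(config)
    index = reference.build_reference_index(transcripts, strand_mode="both")
    ref_tags = sorted(index.tags)
    rng = np.random.default_rng([seed, 7])
    bases = list("ACGT")
    mismatches = 0
    for _ in range(n_queries):
        kind = rng.integers(0, 3)
        if kind == 0:
            query = ref_tags[rng.integers(len(ref_tags))]
        elif kind == 1:
            base = ref_tags[rng.integers(len(ref_tags))]
            pos = int(rng.integers(4, 21))
            query = base[:pos] + str(rng.choice(bases)) + base[pos + 1 :]
        else:
            query = "CATG" + "".join(rng.choice(bases, size=17))
        got = mapping.map_tag(query, index)
        status, gene = _brute_force_map(query, index)
        if got.status != status or got.gene_id != gene:
            mismatches += 1
    return mismatches


# ---------------------------------------------------------------------------
# trend-classifier concordance
# ---------------------------------------------------------------------------
def pattern_concordance() -> tuple[int, int]:
    """(matching labels, panel size) on the bundled 39-profile panel."""
    panel = datasets.ripening_profiles()
    hits = 0
    for _, row in panel.iterrows():
        profile = row[["fs1", "fs2", "fs3", "fs4", "fs5"]].to_numpy(float)
        if de.classify_pattern(profile).group == row["group"]:
            hits += 1
    return hits, len(panel)


# ---------------------------------------------------------------------------
# enrichment oracle
# ---------------------------------------------------------------------------
def enrichment_oracle_max_error(max_population: int = 30) -> float:
    """Max |upper_tail_pvalue - exact rational enumeration| over all
    hypergeometric instances with population size <= max_population."""
    from .enrichment import upper_tail_pvalue

    worst = 0.0
    for N in range(1, max_population + 1):
        for n in range(N + 1):
            for M in range(1, N + 1):
                top = min(n, M)
                total = comb(N, n)
                pmf = [comb(M, i) * comb(N - M, n - i) for i in range(top + 1)]
                suffix = 0
                exact_tail = [0] * (top + 2)
                for i in range(top, -1, -1):
                    suffix += pmf[i]
                    exact_tail[i] = suffix
                for m in range(top + 1):
                    exact = float(Fraction(exact_tail[m], total))
                    got = upper_tail_pvalue(N, n, M, m)
                    err = abs(got - exact)
                    if err > worst:
                        worst = err
    return worst


# ---------------------------------------------------------------------------
# saturation closed form
# ---------------------------------------------------------------------------
def saturation_toy_max_z(replicates: int = 200, seed: int = 0) -> float:
    """Worst CI z-score of the mean saturation curve on the uniform toy.

    10 genes with 10 copies each; the mean detected-gene count at each grid
    depth is compared with the hypergeometric inclusion closed form, scaled
    by the theoretical standard error of the mean.  Values below ~3 are
    consistent with sampling noise at the grid level.
    """
    counts = {}
    results = {}
    bases = "ACGT"
    for i in range(10):
        body = np.base_repr(i, base=4).zfill(9)
        tag = "CATG" + "".join(bases[int(c)] for c in body) + "A" * 8
        counts[tag] = 10
        results[tag] = mapping.MappingResult(
            tag=tag, status=mapping.EXACT_UNIQUE, gene_id=f"g{i}"
        )
    clean = qc.CleanTagLibrary("toy", counts)
    grid = list(range(0, 101, 10))
    curve = saturation.saturation_curve(
        clean, results, depth_grid=grid, replicates=replicates, seed=seed
    )
    worst = 0.0
    for d in grid:
        vals = curve[curve["depth"] == d]["detected_genes"].to_numpy()
        expected = saturation.expected_detected_uniform(10, 10, d)
        p = expected / 10
        sd = np.sqrt(10 * p * (1 - p))
        if sd == 0:
            if abs(vals.mean() - expected) > 0:
                worst = max(worst, np.inf)
            continue
        z = abs(vals.mean() - expected) / (sd / np.sqrt(replicates))
        worst = max(worst, float(z))
    return worst


# ---------------------------------------------------------------------------
# conservation invariants
# ---------------------------------------------------------------------------
def conservation_check(seed: int = 0) -> dict[str, bool]:
    """Assert the bookkeeping invariants on one simulated library."""
    config = simulate.SimulationConfig(
        n_genes=1_000, n_stages=2, depth_per_stage=200_000,
        substitution_rate=0.002, seed=seed,
    )
    transcripts = simulate.generate_transcriptome(config)
    truth = simulate.plant_expression(config, [t.gene_id for t in transcripts])
    index = reference.build_reference_index(transcripts)
    stream = simulate.simulate_raw_tags(transcripts, truth, 0, config)
    raw = qc.RawTagLibrary.from_tags("A", stream)
    clean, part = qc.filter_raw_tags(raw, adaptor_tags=[config.adaptor_sequence])
    results = mapping.map_library(clean, index)
    records, summary = mapping.count_genes(results, clean, index)
    ambiguous_copies = sum(
        clean.counts[t] for t, r in results.items() if r.status == mapping.AMBIGUOUS
    )
    return {
        "qc_partition_conserves_raw_total": part.raw_total == raw.raw_total
        == config.depth_per_stage,
        "mapping_conserves_clean_total": summary.unambiguous_copies
        + ambiguous_copies
        + summary.unknown_copies
        == clean.clean_total,
        "tpm_sum_bounded": bool(records["tpm"].sum() <= 1e6 + 1e-6),
    }
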