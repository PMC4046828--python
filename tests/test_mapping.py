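"""One-mismatch mapping: oracle equivalence, counting and TPM."""

import numpy as np
import pytest

from tagdge.errors import ConsistencyError, InputError, UndefinedValueError
from tagdge.mapping import (
    AMBIGUOUS,
    EXACT_UNIQUE,
    MISMATCH_UNIQUE,
    UNKNOWN,
    count_genes,
    map_library,
    map_tag,
    one_mismatch_neighbors,
    tpm,
)
from tagdge.qc import CleanTagLibrary
from tagdge.reference import ReferenceTag, ReferenceTagIndex, Transcript, build_reference_index

T1 = "CATG" + "A" * 17
T2 = "CATG" + "C" * 17
T3 = "CATG" + "G" * 17


def make_index(tag_to_genes: dict[str, list[str]], n_genes: int | None = None) -> ReferenceTagIndex:
    records = [
        ReferenceTag(tag=t, gene_id=g, strand="+", site_offset=0)
        for t, genes in tag_to_genes.items()
        for g in genes
    ]
    genes = {r.gene_id for r in records}
    return ReferenceTagIndex(records, n_genes=n_genes or len(genes))


def brute_force_map(tag: str, index: ReferenceTagIndex):
    """Exhaustive Hamming scan over every reference tag, anchor fixed."""
    exact = set()
    one_off = set()
    for ref, genes in index.tags.items():
        dist = sum(a != b for a, b in zip(tag, ref))
        if dist == 0:
            exact |= genes
        elif dist == 1 and tag[:4] == ref[:4]:
            one_off |= genes
    if exact:
        return (EXACT_UNIQUE, next(iter(exact))) if len(exact) == 1 else (AMBIGUOUS, None)
    if not one_off:
        return (UNKNOWN, None)
    return (MISMATCH_UNIQUE, next(iter(one_off))) if len(one_off) == 1 else (AMBIGUOUS, None)


class TestMapTag:
    def test_exact_unique(self):
        idx = make_index({T1: ["g1"]})
        res = map_tag(T1, idx)
        assert res.status == EXACT_UNIQUE and res.gene_id == "g1" and res.mismatches == 0

    def test_shared_exact_is_ambiguous(self):
        idx = make_index({T1: ["g1", "g2"]})
        res = map_tag(T1, idx)
        assert res.status == AMBIGUOUS and res.gene_id is None

    def test_ambiguous_exact_not_rescued_by_mismatch(self):
        # T1 shared by two genes; its neighbour belongs uniquely to g3 —
        # the exact ambiguous hit must stand
        neighbor = T1[:-1] + "C"
        idx = make_index({T1: ["g1", "g2"], neighbor: ["g3"]})
        assert map_tag(T1, idx).status == AMBIGUOUS

    def test_single_mismatch_rescue(self):
        idx = make_index({T1: ["g1"]})
        query = T1[:10] + "T" + T1[11:]
        res = map_tag(query, idx)
        assert res.status == MISMATCH_UNIQUE and res.gene_id == "g1" and res.mismatches == 1

    def test_two_mismatches_stay_unknown(self):
        idx = make_index({T2: ["g1"]})
        query = T2[:4] + "AA" + T2[6:]
        assert map_tag(query, idx).status == UNKNOWN

    def test_unknown(self):
        idx = make_index({T1: ["g1"]})
        assert map_tag(T3, idx).status == UNKNOWN

    def test_max_mismatch_zero(self):
        idx = make_index({T1: ["g1"]})
        query = T1[:10] + "T" + T1[11:]
        assert map_tag(query, idx, max_mismatch=0).status == UNKNOWN

    def test_malformed_query_rejected(self):
        idx = make_index({T1: ["g1"]})
        with pytest.raises(InputError):
            map_tag("AAAA" + "A" * 17, idx)

    def test_neighbor_enumeration_size(self):
        assert len(set(one_mismatch_neighbors(T1))) == 51

    def test_matches_hamming_oracle_on_random_instances(self, small_index, rng):
        ref_tags = list(small_index.tags)
        queries = set()
        for _ in range(400):
            kind = rng.integers(0, 3)
            if kind == 0:
                q = ref_tags[rng.integers(len(ref_tags))]
            elif kind == 1:
                base = ref_tags[rng.integers(len(ref_tags))]
                pos = int(rng.integers(4, 21))
                q = base[:pos] + str(rng.choice(list("ACGT"))) + base[pos + 1 :]
            else:
                q = "CATG" + "".join(rng.choice(list("ACGT"), size=17))
            queries.add(q)
        for q in sorted(queries):
            res = map_tag(q, small_index)
            status, gene = brute_force_map(q, small_index)
            assert res.status == status, q
            assert res.gene_id == gene, q


class TestCountGenes:
    def _clean(self, counts):
        return CleanTagLibrary("L", counts)

    def test_single_gene_sum(self):
        idx = make_index({T1: ["g1"]})
        clean = self._clean({T1: 7})
        results = map_library(clean, idx)
        records, summary = count_genes(results, clean, idx)
        assert records.iloc[0]["raw_count"] == 7
        assert summary.unambiguous_copies == 7
        assert records.iloc[0]["tpm"] == 1e6

    def test_all_unknown(self):
        idx = make_index({T1: ["g1"]})
        clean = self._clean({T3: 5})
        records, summary = count_genes(map_library(clean, idx), clean, idx)
        assert len(records) == 0
        assert summary.unknown_copies == clean.clean_total

    def test_same_gene_both_strands_counted_once(self):
        # two distinct reference tags of the same gene; a clean tag matching
        # either is unique to that gene
        idx = make_index({T1: ["g1"], T2: ["g1"]})
        clean = self._clean({T1: 4, T2: 6})
        records, summary = count_genes(map_library(clean, idx), clean, idx)
        assert records.set_index("gene_id").loc["g1", "raw_count"] == 10
        assert summary.unambiguous_genes == 1

    def test_conservation(self, small_index, small_transcriptome, rng):
        ref_tags = list(small_index.tags)
        counts = {}
        for _ in range(300):
            if rng.random() < 0.7:
                tag = ref_tags[rng.integers(len(ref_tags))]
            else:
                tag = "CATG" + "".join(rng.choice(list("ACGT"), size=17))
            counts[tag] = counts.get(tag, 0) + int(rng.integers(2, 20))
        clean = self._clean(counts)
        results = map_library(clean, small_index)
        records, summary = count_genes(results, clean, small_index)
        ambiguous_copies = sum(
            c for t, c in counts.items() if results[t].status == AMBIGUOUS
        )
        assert (
            summary.unambiguous_copies + ambiguous_copies + summary.unknown_copies
            == clean.clean_total
        )
        assert summary.mapped_copies + summary.unknown_copies == clean.clean_total
        assert records["raw_count"].sum() == summary.unambiguous_copies
        assert records["tpm"].sum() <= 1e6 + 1e-6

    def test_missing_result_is_consistency_error(self):
        idx = make_index({T1: ["g1"]})
        clean = self._clean({T1: 3})
        with pytest.raises(ConsistencyError):
            count_genes({}, clean, idx)


class TestTpm:
    @pytest.mark.parametrize(
        "count, total, expected",
        [
            (0, 5_000_000, 0.0),
            (5, 1_000_000, 5.0),
            (347, 5_779_213, 1e6 * 347 / 5_779_213),
        ],
    )
    def test_values(self, count, total, expected):
        assert tpm(count, total) == pytest.approx(expected, rel=1e-12)

    def test_zero_total_undefined(self):
        with pytest.raises(UndefinedValueError):
            tpm(1, 0)


def test_noiseless_simulation_counts_exact(small_config, small_transcriptome, small_truth):
    """Without errors/artifacts every unique gene count equals its sampled count."""
    import dataclasses

    from tagdge.qc import RawTagLibrary, filter_raw_tags
    from tagdge.simulate import simulate_raw_tags

    cfg = dataclasses.replace(
        small_config, substitution_rate=0.0, n_tag_rate=0.0, adaptor_tag_rate=0.0
    )
    stream = simulate_raw_tags(small_transcriptome, small_truth, 0, cfg)
    idx = build_reference_index(small_transcriptome)
    raw = RawTagLibrary.from_tags("S1", stream)
    clean, _ = filter_raw_tags(raw)
    results = map_library(clean, idx)
    records, summary = count_genes(results, clean, idx)
    # every clean tag is a real reference tag
    assert summary.unknown_copies == 0
    # genes whose canonical tag is unambiguous must be recovered exactly
    from tagdge.reference import canonical_tag

    sampled = {}
    tag_of = {}
    for t in small_transcriptome:
        ct = canonical_tag(t.sequence, "+", t.gene_id)
        if ct is not None:
            tag_of[t.gene_id] = ct.tag
    counted = records.set_index("gene_id")["raw_count"].to_dict()
    for gene, tag in tag_of.items():
        if len(idx.genes_for(tag)) == 1 and clean.counts.get(tag, 0) >= 2:
            assert counted.get(gene, 0) == clean.counts[tag]
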