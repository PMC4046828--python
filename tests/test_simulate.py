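"""Synthetic-data generator: determinism, planted truth and noise statistics."""

import dataclasses

import numpy as np
import pytest

from tagdge.errors import ConfigError, InputError
from tagdge.reference import canonical_tag
from tagdge.simulate import (
    DEFAULT_ADAPTOR,
    GroundTruth,
    SimulationConfig,
    generate_transcriptome,
    plant_expression,
    simulate_annotation,
    simulate_raw_tags,
    write_tag_stream,
    read_tag_stream,
)


class TestConfig:
    def test_defaults_valid(self):
        SimulationConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gc_content": 1.5},
            {"de_fraction": -0.1},
            {"length_min": 20},
            {"length_max": 100, "length_min": 200},
            {"n_stages": 1},
            {"log2fc_min": 3, "log2fc_max": 1},
            {"depth_per_stage": -1},
            {"n_tag_rate": 0.7, "adaptor_tag_rate": 0.6},
            {"adaptor_sequence": "ACGT"},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)


class TestGenerateTranscriptome:
    def test_empty(self):
        assert generate_transcriptome(SimulationConfig(n_genes=0)) == []

    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_genes=50, depth_per_stage=0, seed=5)
        a = generate_transcriptome(cfg)
        b = generate_transcriptome(cfg)
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_transcriptome(SimulationConfig(n_genes=20, seed=1))
        b = generate_transcriptome(SimulationConfig(n_genes=20, seed=2))
        assert a != b

    def test_every_transcript_has_usable_site(self):
        cfg = SimulationConfig(n_genes=100, length_min=60, length_max=120, seed=3)
        for t in generate_transcriptome(cfg):
            assert canonical_tag(t.sequence) is not None

    def test_lengths_within_bounds(self):
        cfg = SimulationConfig(n_genes=60, length_min=150, length_max=200, seed=4)
        for t in generate_transcriptome(cfg):
            assert 150 <= len(t.sequence) <= 200

    def test_site_count_matches_iid_expectation(self):
        """Unconstrained sequences: mean CATG count ~ (L-3)/4^4 (99% CI)."""
        n, length = 500, 400
        cfg = SimulationConfig(
            n_genes=n, length_min=length, length_max=length,
            gc_content=0.5, siteless_fraction=1.0, seed=6,
        )
        counts = np.array(
            [t.sequence.count("CATG") for t in generate_transcriptome(cfg)]
        )
        # overlap-free approximation: occurrences ~ Poisson((L-3)/256)
        expected = (length - 3) / 256
        half_width = 2.576 * counts.std(ddof=1) / np.sqrt(n)
        assert abs(counts.mean() - expected) <= half_width


class TestPlantExpression:
    def test_null_configuration(self):
        cfg = SimulationConfig(n_genes=100, de_fraction=0.0, seed=1)
        truth = plant_expression(cfg)
        assert np.all(truth.log2fc == 0)
        assert not truth.de_label.any()

    def test_forced_effect_size(self):
        cfg = SimulationConfig(
            n_genes=50, de_fraction=1.0, log2fc_min=2, log2fc_max=2, seed=2
        )
        truth = plant_expression(cfg)
        assert np.all(np.abs(truth.log2fc) == 2)

    def test_exact_subset_size(self):
        cfg = SimulationConfig(n_genes=1000, de_fraction=0.1, seed=3)
        truth = plant_expression(cfg)
        for pair in range(cfg.n_stages - 1):
            assert truth.de_label[pair].sum() == 100

    def test_abundances_on_simplex(self):
        cfg = SimulationConfig(n_genes=200, de_fraction=0.2, seed=4)
        truth = plant_expression(cfg)
        assert np.allclose(truth.abundances.sum(axis=1), 1.0, atol=1e-9)

    def test_tpm_floor_restricts_eligibility(self):
        cfg = SimulationConfig(
            n_genes=500, de_fraction=0.05, de_tpm_floor=50.0, seed=5
        )
        truth = plant_expression(cfg)
        for pair in range(cfg.n_stages - 1):
            planted = np.nonzero(truth.de_label[pair])[0]
            assert np.all(truth.abundances[pair, planted] * 1e6 >= 50.0)

    def test_frame_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_genes=20, seed=6)
        truth = plant_expression(cfg)
        path = tmp_path / "truth.tsv"
        truth.write_tsv(path)
        import pandas as pd

        back = pd.read_csv(path, sep="\t")
        assert len(back) == 20
        assert np.allclose(back["abundance_s1"], truth.abundances[0])


class TestSimulateRawTags:
    @staticmethod
    @pytest.fixture(scope="class")
    def setup():
        cfg = SimulationConfig(
            n_genes=100, n_stages=2, depth_per_stage=50_000,
            substitution_rate=0.002, n_tag_rate=0.01, adaptor_tag_rate=0.005, seed=7,
        )
        transcripts = generate_transcriptome(cfg)
        truth = plant_expression(cfg, [t.gene_id for t in transcripts])
        return cfg, transcripts, truth

    def test_depth_zero(self, setup):
        cfg, transcripts, truth = setup
        cfg0 = dataclasses.replace(cfg, depth_per_stage=0)
        assert len(simulate_raw_tags(transcripts, truth, 0, cfg0)) == 0

    def test_stream_length_exact(self, setup):
        cfg, transcripts, truth = setup
        stream = simulate_raw_tags(transcripts, truth, 0, cfg)
        assert len(stream) == cfg.depth_per_stage

    def test_stage_out_of_range(self, setup):
        cfg, transcripts, truth = setup
        with pytest.raises(InputError):
            simulate_raw_tags(transcripts, truth, 5, cfg)

    def test_seeded_determinism(self, setup):
        cfg, transcripts, truth = setup
        a = simulate_raw_tags(transcripts, truth, 1, cfg)
        b = simulate_raw_tags(transcripts, truth, 1, cfg)
        assert np.array_equal(a, b)

    def test_noiseless_single_gene(self):
        cfg = SimulationConfig(
            n_genes=1, n_stages=2, depth_per_stage=500,
            substitution_rate=0.0, n_tag_rate=0.0, adaptor_tag_rate=0.0, seed=8,
        )
        transcripts = generate_transcriptome(cfg)
        truth = plant_expression(cfg, [t.gene_id for t in transcripts])
        stream = simulate_raw_tags(transcripts, truth, 0, cfg)
        expected = canonical_tag(transcripts[0].sequence).tag.encode()
        assert all(tag == expected for tag in stream)

    def test_noiseless_tags_are_reference_tags(self, setup):
        cfg, transcripts, truth = setup
        cfg0 = dataclasses.replace(
            cfg, substitution_rate=0.0, n_tag_rate=0.0, adaptor_tag_rate=0.0
        )
        stream = simulate_raw_tags(transcripts, truth, 0, cfg0)
        reference = {
            canonical_tag(t.sequence).tag.encode()
            for t in transcripts
            if canonical_tag(t.sequence) is not None
        }
        assert set(np.unique(stream)) <= reference

    def test_substitution_error_fraction_matches_closed_form(self):
        """P(tag has >= 1 error) = 1-(1-e)^21; simulated fraction in 99% CI."""
        depth = 100_000
        rate = 0.002
        cfg = SimulationConfig(
            n_genes=1, n_stages=2, depth_per_stage=depth,
            substitution_rate=rate, n_tag_rate=0.0, adaptor_tag_rate=0.0, seed=9,
        )
        transcripts = generate_transcriptome(cfg)
        truth = plant_expression(cfg, [t.gene_id for t in transcripts])
        stream = simulate_raw_tags(transcripts, truth, 0, cfg)
        clean_tag = canonical_tag(transcripts[0].sequence).tag.encode()
        frac = float(np.mean(stream != clean_tag))
        p = 1 - (1 - rate) ** 21
        half_width = 2.576 * np.sqrt(p * (1 - p) / depth)
        assert abs(frac - p) <= half_width

    def test_artifact_composition(self, setup):
        cfg, transcripts, truth = setup
        stream = simulate_raw_tags(transcripts, truth, 0, cfg)
        arr = stream.astype("S21")
        n_adaptor = int(np.sum(arr == DEFAULT_ADAPTOR.encode()))
        with_n = int(np.sum(np.char.find(arr, b"N") >= 0))
        depth = cfg.depth_per_stage
        for observed, rate in ((n_adaptor, cfg.adaptor_tag_rate), (with_n, cfg.n_tag_rate)):
            half_width = 2.576 * np.sqrt(rate * (1 - rate) / depth) * depth
            assert abs(observed - rate * depth) <= half_width

    def test_stream_file_round_trip(self, tmp_path, setup):
        cfg, transcripts, truth = setup
        cfg_small = dataclasses.replace(cfg, depth_per_stage=200)
        stream = simulate_raw_tags(transcripts, truth, 0, cfg_small)
        path = tmp_path / "tags.txt"
        write_tag_stream(stream, path)
        assert np.array_equal(read_tag_stream(path), stream)


class TestSimulateAnnotation:
    def test_structure_and_determinism(self):
        genes = [f"g{i}" for i in range(300)]
        a = simulate_annotation(genes, n_pathways=20, size_min=5, size_max=50, seed=1)
        b = simulate_annotation(genes, n_pathways=20, size_min=5, size_max=50, seed=1)
        assert a.pathways == b.pathways
        assert all(len(g) > 0 for g in a.pathways.values())
        assert a.genes <= set(genes)
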