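"""Generator contracts: determinism, planted truth, read statistics."""

import hashlib
import math

import numpy as np
import pytest

from histokit import motifs
from histokit.errors import InputError
from histokit.seq_io import reverse_complement
from histokit.synthetic_data import (
    SimulationConfig,
    generate_genome,
    make_sperm_h2b,
    simulate_reads,
    translate_cds,
    write_dataset,
)


class TestConfig:
    def test_invalid_field_named(self):
        with pytest.raises(InputError, match="background_gc"):
            SimulationConfig(seed=0, background_gc=1.5)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=3, cluster_copies=4)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert SimulationConfig.from_yaml(p) == cfg

    def test_unknown_yaml_field_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("seed: 1\nbogus_field: 2\n")
        with pytest.raises(InputError, match="bogus_field"):
            SimulationConfig.from_yaml(p)


class TestGenerateGenome:
    def test_no_cluster_leaves_variants_only(self):
        cfg = SimulationConfig(seed=2, cluster_copies=0)
        ds = generate_genome(cfg)
        clustered = [g for g in ds.truth.genes if g.n_copies > 1]
        assert clustered == []
        assert len(ds.truth.genes) == len(cfg.cluster_unit) + len(cfg.variant_loci)

    def test_cluster_instance_arithmetic(self):
        cfg = SimulationConfig(seed=2, cluster_copies=50)
        ds = generate_genome(cfg)
        gene_feats = [f for f in ds.features if f.ftype == "gene" and f.attr.get("gene_type") != "non_histone"]
        clustered = [f for f in gene_feats if "copy" in f.attr]
        assert len(clustered) == 50 * len(cfg.cluster_unit)
        units = [f for f in ds.features if f.ftype == "cluster_unit"]
        assert len(units) == 50

    def test_byte_identical_reruns(self, tmp_path):
        def run(d):
            paths = write_dataset(generate_genome(SimulationConfig(seed=9, cluster_copies=2)), d)
            return {
                k: hashlib.sha256(open(v, "rb").read()).hexdigest() for k, v in paths.items()
            }

        assert run(tmp_path / "a") == run(tmp_path / "b")

    def test_truth_sequences_match_genome(self, dataset19):
        """Re-extracting each planted coding span reproduces the CDS."""
        genome = dataset19.genome.residues
        for g in dataset19.truth.genes:
            genomic = genome[g.start : g.end]
            if g.strand == "-":
                genomic = reverse_complement(genomic)
            # introns out: the genomic span with introns removed equals the CDS
            assert translate_cds(g.cds) == g.protein
            exon_feats = sorted(
                (
                    f
                    for f in dataset19.features
                    if f.ftype == "CDS"
                    and f.attr.get("Parent") == g.name
                    and f.attr.get("copy", "0") == "0"
                    and g.start <= f.start < g.end
                ),
                key=lambda f: f.start,
            )
            spliced = "".join(genome[f.start : f.end] for f in exon_feats)
            assert spliced == g.cds

    def test_planted_spkk_counts(self, dataset19):
        for g in dataset19.truth.genes:
            assert motifs.count_spkk(g.protein).count == g.expected_spkk


class TestMakeSpermH2b:
    @pytest.mark.parametrize("n", range(11))
    def test_counts_exact(self, refs, n):
        base = refs.get("H2B", "canonical").record.residues
        assert motifs.count_spkk(make_sperm_h2b(base, n)).count == n

    def test_zero_repeats_unchanged(self, refs):
        base = refs.get("H2B", "canonical").record.residues
        assert make_sperm_h2b(base, 0) == base

    def test_out_of_range_rejected(self, refs):
        with pytest.raises(InputError):
            make_sperm_h2b("GGG", 11)


class TestSimulateReads:
    def test_read_count_formula(self):
        cfg = SimulationConfig(seed=1, background_length=2000, cluster_copies=0,
                               variant_loci=(), cluster_unit=(), coverage=20, read_length=250)
        ds = generate_genome(cfg)
        reads = simulate_reads(ds.genome.residues, cfg)
        assert len(reads) == math.ceil(20 * len(ds.genome) / 250)

    def test_error_free_reads_are_exact_substrings(self):
        cfg = SimulationConfig(seed=4, background_length=5000, cluster_copies=0,
                               variant_loci=(), cluster_unit=(), coverage=2, error_rate=0.0)
        ds = generate_genome(cfg)
        genome = ds.genome.residues
        for r in simulate_reads(genome, cfg)[:30]:
            assert r.residues in genome or reverse_complement(r.residues) in genome

    def test_error_rate_within_binomial_bounds(self):
        """Observed mismatch fraction over ~1e6 bases is within 3 sigma of 1%."""
        genome = "A" * 25_000
        cfg = SimulationConfig(seed=5, coverage=40, error_rate=0.01)
        reads = simulate_reads(genome, cfg, rng=np.random.default_rng(5))
        errors = bases = 0
        for r in reads:
            seq = r.residues
            non_a = len(seq) - seq.count("A")
            non_t = len(seq) - seq.count("T")
            errors += min(non_a, non_t)
            bases += len(seq)
        p = errors / bases
        sigma = math.sqrt(0.01 * 0.99 / bases)
        assert abs(p - 0.01) < 3 * sigma

    def test_paired_mode_emits_mates(self):
        cfg = SimulationConfig(seed=6, background_length=5000, cluster_copies=0,
                               variant_loci=(), cluster_unit=(), coverage=2, paired=True)
        ds = generate_genome(cfg)
        reads = simulate_reads(ds.genome.residues, cfg)
        assert len(reads) % 2 == 0
        assert reads[0].id.endswith("/1") and reads[1].id.endswith("/2")
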