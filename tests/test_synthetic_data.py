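"""Generators: determinism, realized-parameter bounds, and round-trips."""

from __future__ import annotations

import math

import numpy as np
import pytest

from genomesurvey import io
from genomesurvey.synthetic_data import (
    EARLY_WINDOW,
    OPTIMAL_CODONS,
    STAGES,
    simulate_annotation,
    simulate_coding_sequences,
    simulate_diploid,
    simulate_expression,
    simulate_reads,
    simulate_reference,
)
from genomesurvey.tandem_clusters import pairwise_identity


class TestReference:
    def test_rejects_empty_genome(self):
        with pytest.raises(ValueError):
            simulate_reference(0, 0.5, 1)

    def test_seed_determinism(self):
        assert simulate_reference(10_000, 0.5, 1) == simulate_reference(10_000, 0.5, 1)

    def test_gc_fraction_within_binomial_bound(self):
        seq = simulate_reference(100_000, 0.37, 7)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.37) < 0.01


class TestDiploid:
    def test_zero_het_rate_keeps_haplotypes_identical(self):
        ref = simulate_reference(5_000, 0.4, 2)
        dg = simulate_diploid(ref, 0.0, 3)
        assert dg.alt_haplotype == ref
        assert dg.variant_positions == []

    def test_variant_count_within_four_sigma(self):
        ref = simulate_reference(1_000_000, 0.5, 4)
        dg = simulate_diploid(ref, 0.02, 3)
        assert abs(len(dg.variant_positions) - 20_000) <= 560

    def test_realized_rate_tracks_requested_rate(self):
        ref = simulate_reference(1_000_000, 0.37, 9)
        dg = simulate_diploid(ref, 0.0159, 5)
        assert abs(dg.realized_het_rate - 0.0159) <= 0.0005

    def test_variant_list_is_exact(self):
        ref = simulate_reference(3_000, 0.5, 6)
        dg = simulate_diploid(ref, 0.05, 7)
        diff = {i for i in range(len(ref)) if ref[i] != dg.alt_haplotype[i]}
        assert diff == {pos for pos, _, _ in dg.variant_positions}
        for pos, ref_base, alt_base in dg.variant_positions:
            assert ref[pos] == ref_base
            assert dg.alt_haplotype[pos] == alt_base
            assert ref_base != alt_base

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_diploid("ACGT" * 100, 0.2, 1)


class TestReads:
    def test_total_bases_meet_coverage(self):
        ref = simulate_reference(100_000, 0.5, 8)
        dg = simulate_diploid(ref, 0.01, 9)
        reads = simulate_reads(dg, 30, 100, 0.0, 10)
        assert 30 * 100_000 <= reads.total_bases < 30 * 100_000 + 100

    def test_error_free_reads_are_haplotype_substrings(self):
        ref = simulate_reference(2_000, 0.5, 11)
        dg = simulate_diploid(ref, 0.03, 12)
        reads = simulate_reads(dg, 5, 150, 0.0, 13)
        for _, seq, _ in reads.reads:
            assert seq in dg.reference or seq in dg.alt_haplotype

    def test_fastq_bytes_reproducible(self, tmp_path):
        ref = simulate_reference(5_000, 0.5, 14)
        dg = simulate_diploid(ref, 0.02, 15)
        payloads = []
        for run in range(2):
            reads = simulate_reads(dg, 3, 100, 0.01, 16)
            path = tmp_path / f"run{run}.fastq"
            io.write_fastq(reads, path)
            payloads.append(path.read_bytes())
        assert payloads[0] == payloads[1]

    def test_read_longer_than_genome_rejected(self):
        dg = simulate_diploid("ACGT" * 10, 0.0, 1)
        with pytest.raises(ValueError):
            simulate_reads(dg, 1, 100, 0.0, 1)

    def test_fastq_round_trip(self, tmp_path):
        ref = simulate_reference(3_000, 0.5, 17)
        dg = simulate_diploid(ref, 0.01, 18)
        reads = simulate_reads(dg, 2, 80, 0.0, 19)
        path = tmp_path / "reads.fastq"
        io.write_fastq(reads, path)
        again = io.read_fastq(path)
        assert again.reads == reads.reads


class TestAnnotation:
    def test_planted_cluster_is_adjacent_and_homologous(self, planted_annotation):
        ann = planted_annotation
        assert len(ann.planted_clusters) == 1
        cluster = ann.planted_clusters[0]
        assert len(cluster) == 11
        scaffold = next(g[1] for g in ann.genes if g[0] == cluster[0])
        ordered = [g[0] for g in ann.scaffold_genes(scaffold)]
        first = ordered.index(cluster[0])
        assert ordered[first : first + 11] == cluster
        for a, b in zip(cluster, cluster[1:]):
            assert pairwise_identity(ann.proteins[a], ann.proteins[b]) >= 0.9

    def test_genes_sorted_and_non_overlapping(self, planted_annotation):
        for scaffold in planted_annotation.scaffolds:
            genes = planted_annotation.scaffold_genes(scaffold)
            for gene, nxt in zip(genes, genes[1:]):
                assert gene[2] <= nxt[2]
                assert gene[3] < nxt[2]

    def test_no_specs_is_valid(self):
        ann = simulate_annotation(2, 5, [], seed=1)
        assert ann.planted_clusters == []
        assert len(ann.genes) == 10

    def test_two_specs_land_on_distinct_scaffolds(self):
        ann = simulate_annotation(2, 12, [(4, 0.9), (5, 0.9)], seed=2)
        scaffolds = set()
        for cluster in ann.planted_clusters:
            owners = {g[1] for g in ann.genes if g[0] in cluster}
            assert len(owners) == 1
            scaffolds |= owners
        assert len(scaffolds) == 2

    def test_oversized_cluster_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotation(1, 5, [(6, 0.9)], seed=1)

    def test_round_trip(self, planted_annotation, tmp_path):
        paths = io.write_annotation(planted_annotation, tmp_path)
        again = io.read_annotation(paths["gff3"], paths["proteins"], paths["truth"])
        assert again.genes == planted_annotation.genes
        assert again.proteins == planted_annotation.proteins
        assert again.planted_clusters == planted_annotation.planted_clusters


class TestExpression:
    def test_library_sizes_are_column_sums(self):
        ids = [f"g{i}" for i in range(50)]
        cm = simulate_expression(ids, upregulated=ids[:5], fold=100, seed=3)
        assert (cm.counts.sum(axis=0) == cm.library_sizes).all()
        assert cm.stages == list(STAGES)

    def test_planted_fold_dominates_window(self):
        ids = [f"g{i}" for i in range(100)]
        cm = simulate_expression(
            ids, upregulated=ids[:11], fold=10_000, dispersion=0.1, seed=4
        )
        window = list(EARLY_WINDOW)
        for gene in ids[:11]:
            ratio = cm.counts.loc[gene, window].mean() / max(
                cm.counts.loc[gene, "control"], 1
            )
            assert ratio >= 1_000

    def test_zero_dispersion_gives_rounded_means(self):
        ids = [f"g{i}" for i in range(20)]
        a = simulate_expression(ids, dispersion=0.0, seed=5)
        b = simulate_expression(ids, dispersion=0.0, seed=5)
        assert (a.counts == b.counts).all().all()
        # flat profile: all stages identical when dispersion is 0 and no fold
        assert (a.counts.nunique(axis=1) == 1).all()

    def test_unknown_upregulated_gene_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression(["a", "b"], upregulated=["zz"], fold=10, seed=1)

    def test_round_trip(self, tmp_path):
        ids = [f"g{i}" for i in range(10)]
        cm = simulate_expression(ids, upregulated=ids[:2], fold=50, seed=6)
        io.write_counts(cm, tmp_path)
        again = io.read_counts(tmp_path)
        assert (again.counts == cm.counts).all().all()
        assert (again.gene_lengths == cm.gene_lengths).all()
        assert again.planted == cm.planted


class TestCodingSequences:
    def test_structure_and_determinism(self):
        cds = simulate_coding_sequences(5, 0.5, seed=7, n_codons=50)
        again = simulate_coding_sequences(5, 0.5, seed=7, n_codons=50)
        assert cds == again
        stops = {"TAA", "TAG", "TGA"}
        for seq in cds.values():
            assert len(seq) % 3 == 0
            assert seq.startswith("ATG")
            assert seq[-3:] in stops
            internal = [seq[i : i + 3] for i in range(3, len(seq) - 3, 3)]
            assert not (set(internal) & stops)

    def test_full_bias_uses_only_optimal_codons(self):
        cds = simulate_coding_sequences(3, 1.0, seed=8, n_codons=40)
        optimal = set(OPTIMAL_CODONS.values())
        for seq in cds.values():
            body = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
            assert set(body) <= optimal

    def test_fasta_bytes_reproducible(self, tmp_path):
        payloads = []
        for run in range(2):
            cds = simulate_coding_sequences(4, 0.3, seed=9, n_codons=30)
            path = tmp_path / f"cds{run}.fa"
            io.write_fasta(cds, path)
            payloads.append(path.read_bytes())
        assert payloads[0] == payloads[1]


def test_coverage_realized_over_many_seeds():
    """Realized heterozygosity stays within 4 sigma across seeds."""
    length, h = 200_000, 0.01
    sigma = math.sqrt(length * h * (1 - h))
    ref = simulate_reference(length, 0.4, 1)
    for seed in range(20):
        dg = simulate_diploid(ref, h, seed)
        assert abs(len(dg.variant_positions) - length * h) <= 4 * sigma
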