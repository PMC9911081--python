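"""Simulator determinism, truth consistency and construction invariants."""

import dataclasses

import pytest

from slannot.io_formats import revcomp
from slannot.sim import (
    DEFAULT_SL,
    PlacementError,
    SimConfig,
    simulate_dataset,
    simulate_mito_contig,
    write_dataset,
)
from slannot.util import round_half_up


class TestConfig:
    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="trans_spliced_fraction"):
            SimConfig(trans_spliced_fraction=1.5)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="polya_length_range"):
            SimConfig(polya_length_range=(20, 8))

    def test_polycistrons_require_trans_splicing(self):
        # downstream polycistron members must be trans-spliced
        with pytest.raises(ValueError, match="polycistronic"):
            SimConfig(polycistron_fraction=0.8, trans_spliced_fraction=0.0)

    def test_infeasible_placement_raises(self):
        with pytest.raises(PlacementError, match="cannot place"):
            simulate_dataset(
                SimConfig(genome_length=5_000, n_genes=20)
            )


class TestDataset:
    def test_identical_seeds_give_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed=1, n_genes=8, genome_length=40_000, n_reads=120)
        for d in ("a", "b"):
            write_dataset(simulate_dataset(cfg), tmp_path / d)
        for name in (
            "genome.fa", "transcripts.fa", "reads.fastq", "tag_reads.fastq",
            "truth_genes.gff3", "initial_models.gff3", "manifest.json",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_trans_spliced_count_uses_round_half_up(self):
        res = simulate_dataset(
            SimConfig(seed=2, n_genes=10, trans_spliced_fraction=0.302)
        )
        assert res.manifest.n_trans_spliced == 3 == round_half_up(0.302 * 10)

    @pytest.mark.parametrize("fraction", [0.0, 0.302, 1.0])
    def test_fraction_recovery_is_exact(self, fraction):
        n = 50
        cfg = SimConfig(
            seed=5,
            n_genes=n,
            trans_spliced_fraction=fraction,
            polycistron_fraction=0.2 if fraction else 0.0,
            genome_length=300_000,
        )
        res = simulate_dataset(cfg)
        assert res.manifest.n_trans_spliced == round_half_up(fraction * n)

    def test_trans_spliced_transcripts_start_with_sl_suffix(self, default_dataset):
        m = default_dataset.manifest
        for t in m.transcripts:
            if t.sl_fragment_length:
                assert t.sequence.startswith(
                    m.sl_sequence[len(m.sl_sequence) - t.sl_fragment_length :]
                )

    def test_noiseless_reads_are_exact_transcript_substrings(self, default_dataset):
        tx = {t.name: t.sequence for t in default_dataset.transcripts}
        truth = {r.id: r for r in default_dataset.manifest.reads}
        for read in default_dataset.reads:
            r = truth[read.name]
            expected = tx[r.transcript_id][r.offset : r.offset + len(read.sequence)]
            assert read.sequence == expected

    def test_truth_alignments_reconstruct_reads_from_genome(self, default_dataset):
        """Walking each truth alignment's CIGAR over the genome recovers the
        aligned (non-clipped) part of the read exactly."""
        genome = default_dataset.genome
        for rec in default_dataset.read_alignments + default_dataset.tag_alignments:
            aligned = []
            ref = rec.reference_start
            q = 0
            for op, length in rec.cigar:
                if op == "M":
                    aligned.append(
                        (genome[rec.reference_name][ref : ref + length],
                         rec.query_sequence[q : q + length])
                    )
                    ref += length
                    q += length
                elif op in ("D", "N"):
                    ref += length
                elif op in ("I", "S"):
                    q += length
            for genomic, query in aligned:
                assert genomic == query, rec.query_name

    def test_sl_fragments_encoded_as_leading_softclips(self, default_dataset):
        truth = {r.id: r for r in default_dataset.manifest.reads}
        for rec in default_dataset.read_alignments:
            assert rec.leading_clip == truth[rec.query_name].sl_fragment_length

    def test_planted_sl_rna_locus_sequence_matches(self, default_dataset):
        contig, start, end, strand = default_dataset.manifest.sl_rna_locus
        found = default_dataset.genome.fetch(contig, start, end, strand)
        assert found == DEFAULT_SL

    def test_junction_reads_cover_every_trans_spliced_gene(self, default_dataset):
        m = default_dataset.manifest
        ts_transcripts = {
            t.id for t in m.transcripts if t.sl_fragment_length > 0
        }
        junction_counts = {}
        for r in m.reads:
            if not r.tag and r.sl_fragment_length > 0:
                junction_counts[r.transcript_id] = (
                    junction_counts.get(r.transcript_id, 0) + 1
                )
        for tid in ts_transcripts:
            assert junction_counts.get(tid, 0) >= 3

    def test_polycistron_pairs_share_strand_and_are_adjacent(self):
        res = simulate_dataset(
            SimConfig(seed=9, n_genes=20, polycistron_fraction=0.5)
        )
        groups = {}
        for g in res.manifest.genes:
            if g.group is not None:
                groups.setdefault(g.group, []).append(g)
        assert len(groups) == 5
        for members in groups.values():
            assert len(members) == 2
            a, b = sorted(members, key=lambda g: g.start)
            assert a.strand == b.strand
            # downstream-in-transcription member is trans-spliced
            downstream = b if a.strand == "+" else a
            assert downstream.trans_spliced


class TestMitoContig:
    def test_construction_by_definition(self):
        contig, circle = simulate_mito_contig(2000, 535, seed=7)
        assert len(contig) == 2535
        assert contig == circle + circle[:535]

    def test_paper_scale_lengths(self):
        contig, circle = simulate_mito_contig(16000, 535, seed=7)
        assert len(contig) == 16535 and len(circle) == 16000

    def test_zero_repeat_rejected(self):
        with pytest.raises(ValueError):
            simulate_mito_contig(1000, 0, seed=1)

    def test_repeat_not_smaller_than_circle_rejected(self):
        with pytest.raises(ValueError):
            simulate_mito_contig(100, 100, seed=1)
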