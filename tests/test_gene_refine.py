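"""Locus merging, boundary refinement, polycistron splitting, ORF calling."""

import numpy as np
import pytest

from slannot.gene_refine import (
    AnnotationSummary,
    longest_orf,
    merge_models,
    refine_and_split,
    summarize,
)
from slannot.io_formats import GenomeSequence, TranscriptModel
from slannot.peaks import Peak


def _tm(id, strand, exons, contig="c"):
    return TranscriptModel(id, contig, strand, tuple(exons))


def _peak(summit, strand="+", kind="SL", contig="c"):
    return Peak(contig, strand, summit, summit + 1, summit, 10, kind)


class TestMergeModels:
    def test_overlapping_transcripts_form_one_locus(self):
        loci = merge_models(
            [_tm("a", "+", [(100, 200)]), _tm("b", "+", [(150, 300)])]
        )
        assert len(loci) == 1
        assert loci[0].members == ("a", "b")
        assert loci[0].exons == ((100, 300),)

    def test_opposite_strands_stay_separate(self):
        loci = merge_models(
            [_tm("a", "+", [(100, 200)]), _tm("b", "-", [(100, 200)])]
        )
        assert len(loci) == 2

    def test_exon_overlap_not_span_overlap(self):
        # b sits inside a's intron: spans overlap, exons do not
        a = _tm("a", "+", [(100, 150), (400, 500)])
        b = _tm("b", "+", [(200, 300)])
        assert len(merge_models([a, b])) == 2

    def test_transitive_chain_matches_graph_closure_oracle(self, rng):
        """Random model sets: clustering equals an independent
        pairwise-overlap graph closure (BFS)."""
        for _ in range(20):
            models = []
            for i in range(int(rng.integers(2, 12))):
                start = int(rng.integers(0, 600))
                models.append(
                    _tm(f"t{i}", "+", [(start, start + int(rng.integers(20, 120)))])
                )

            def overlap(m1, m2):
                return any(
                    s1 < e2 and s2 < e1
                    for s1, e1 in m1.exons
                    for s2, e2 in m2.exons
                )

            adj = {
                m.id: {o.id for o in models if o is not m and overlap(m, o)}
                for m in models
            }
            components = []
            todo = {m.id for m in models}
            while todo:
                stack = [todo.pop()]
                comp = set()
                while stack:
                    node = stack.pop()
                    comp.add(node)
                    for nb in adj[node]:
                        if nb in todo:
                            todo.remove(nb)
                            stack.append(nb)
                components.append(frozenset(comp))
            got = {frozenset(l.members) for l in merge_models(models)}
            assert got == set(components)

    def test_exon_beyond_contig_rejected(self):
        genome = GenomeSequence([("c", "A" * 100)])
        with pytest.raises(ValueError, match="beyond"):
            merge_models([_tm("a", "+", [(50, 150)])], genome=genome)


class TestRefineAndSplit:
    def test_internal_summit_splits_locus(self):
        loci = merge_models([_tm("a", "+", [(1000, 5000)])])
        genes = refine_and_split(loci, [_peak(3000)], [])
        assert [(g.start, g.end) for g in genes] == [(1000, 3000), (3000, 5000)]
        assert [g.sl_trans_spliced for g in genes] == [False, True]

    def test_no_nearby_peaks_leaves_locus_unchanged(self):
        loci = merge_models([_tm("a", "+", [(1000, 5000)])])
        genes = refine_and_split(loci, [], [])
        assert len(genes) == 1
        assert (genes[0].start, genes[0].end) == (1000, 5000)
        assert genes[0].sl_trans_spliced is False

    def test_upstream_gene_ends_at_polya_summit(self):
        loci = merge_models([_tm("a", "+", [(1000, 5000)])])
        genes = refine_and_split(
            loci, [_peak(3000)], [_peak(2899, kind="polyA")]
        )
        assert [(g.start, g.end) for g in genes] == [(1000, 2900), (3000, 5000)]

    def test_five_prime_promotion_within_window(self):
        loci = merge_models([_tm("a", "+", [(1000, 5000)])])
        genes = refine_and_split(loci, [_peak(1030)], [], promote_window=50)
        assert genes[0].start == 1030
        assert genes[0].sl_trans_spliced is True

    def test_minus_strand_split_mirrors_plus(self):
        loci = merge_models([_tm("a", "-", [(1000, 5000)])])
        # acceptor at 2999 (gene 5' boundary = end-1 on '-')
        genes = refine_and_split(loci, [_peak(2999, strand="-")], [])
        assert [(g.start, g.end) for g in genes] == [(1000, 3000), (3000, 5000)]
        assert [g.sl_trans_spliced for g in genes] == [True, False]

    def test_split_shorter_than_minimum_is_skipped(self):
        loci = merge_models([_tm("a", "+", [(1000, 1230)])])
        genes = refine_and_split(
            loci, [_peak(1200)], [], min_internal_offset=200, min_gene_len=50
        )
        assert len(genes) == 1  # downstream remainder would be 30 bp

    def test_territory_conservation_and_count_monotonicity(self):
        loci = merge_models(
            [_tm("a", "+", [(0, 2000)]), _tm("b", "+", [(3000, 9000)])]
        )
        sl = [_peak(3500), _peak(6000)]
        genes = refine_and_split(loci, sl, [])
        assert len(genes) == len(loci) + 2  # two accepted internal splits
        for g in genes:
            assert any(
                l.start <= g.start and g.end <= l.end for l in loci
            )
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_truth_recovery_on_simulated_polycistrons(self, default_dataset):
        from slannot.peaks import build_end_signal, call_peaks

        m = default_dataset.manifest
        sl_reads = {
            r.id for r in m.reads if not r.tag and r.sl_fragment_length >= 8
        }
        track5 = build_end_signal(
            [a for a in default_dataset.read_alignments if a.query_name in sl_reads],
            "five_prime",
        )
        track3 = build_end_signal(default_dataset.tag_alignments, "three_prime")
        sl_peaks = call_peaks(track5, kind="SL")
        pa_peaks = call_peaks(track3, kind="polyA")
        loci = merge_models(default_dataset.initial_models)
        genes = refine_and_split(loci, sl_peaks, pa_peaks)
        assert len(genes) == len(m.genes)
        assert sorted((g.contig, g.strand, g.start, g.end) for g in genes) == \
            sorted((g.contig, g.strand, g.start, g.end) for g in m.genes)
        recovered_ts = {
            (g.contig, g.strand, g.start if g.strand == "+" else g.end - 1)
            for g in genes
            if g.sl_trans_spliced
        }
        assert recovered_ts == m.acceptor_sites()


class TestLongestORF:
    def test_minimal_orf_hand_translated(self):
        assert longest_orf("ATGAAATAG", min_aa=2) == (0, 9)

    def test_all_a_sequence_has_no_orf(self):
        assert longest_orf("A" * 300, min_aa=2) is None

    def test_min_aa_threshold(self):
        assert longest_orf("ATGAAATAG", min_aa=3) is None

    def test_equals_bruteforce_atg_stop_scan(self, rng):
        stops = {"TAA", "TAG", "TGA"}

        def oracle(seq, min_aa):
            best = None
            for i in range(len(seq) - 2):
                if seq[i : i + 3] != "ATG":
                    continue
                for j in range(i + 3, len(seq) - 2, 3):
                    if seq[j : j + 3] in stops:
                        cand = (i, j + 3)
                        if (j + 3 - i) // 3 - 1 >= min_aa and (
                            best is None
                            or (cand[1] - cand[0], -cand[0])
                            > (best[1] - best[0], -best[0])
                        ):
                            best = cand
                        break
            return best

        bases = "ACGT"
        for _ in range(150):
            n = int(rng.integers(10, 400))
            seq = "".join(bases[i] for i in rng.integers(0, 4, n))
            assert longest_orf(seq, min_aa=5) == oracle(seq, 5), seq


class TestSummarize:
    def test_published_style_count_arithmetic(self):
        s = AnnotationSummary.from_counts(29_351, 5_142, 10_433)
        assert s.n_genes == 34_493
        assert s.sl_fraction == 30.2

    def test_single_gene_fraction(self):
        from slannot.gene_refine import GeneModel

        g = GeneModel(
            "g1", "c", "+", ((0, 300),), sl_trans_spliced=True, coding=True
        )
        s = summarize([g])
        assert s.n_genes == 1 and s.sl_fraction == 100.0
        assert s.mean_intron_count == 0.0

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize([])

    def test_count_identity_invariant(self, default_dataset):
        from slannot.gene_refine import classify_coding, merge_models, refine_and_split

        loci = merge_models(default_dataset.initial_models)
        genes = refine_and_split(loci, [], [])
        classify_coding(genes, default_dataset.genome, min_aa=50)
        s = summarize(genes)
        assert s.n_genes == s.n_coding + s.n_noncoding
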