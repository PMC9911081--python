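"""SL consensus reconstruction, SL RNA locus search, base-pair maximization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slannot.io_formats import AlignmentRecord, GenomeSequence, revcomp
from slannot.sim import SimConfig, simulate_dataset
from slannot.sl_discovery import (
    extract_unmapped_prefixes,
    find_sl_rna_loci,
    max_base_pairs,
    reconstruct_sl,
)

# ---------------------------------------------------------------------------
# independent oracles


def oracle_column_vote(prefixes, min_support, min_fraction):
    """Brute-force right-aligned column vote, written independently."""
    out = []
    j = 1
    while True:
        column = [p[len(p) - j] for p in prefixes if len(p) >= j]
        if len(column) < min_support:
            break
        best, best_count = None, -1
        for base in sorted(set(column)):
            if column.count(base) > best_count:
                best, best_count = base, column.count(base)
        if best_count / len(column) < min_fraction:
            break
        out.append(best)
        j += 1
    return "".join(reversed(out))


def oracle_max_pairs(seq, min_loop=3, allow_gu=True):
    """Enumerate every nested pairing structure explicitly and maximize."""
    s = seq.upper().replace("T", "U")
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    if allow_gu:
        pairs |= {("G", "U"), ("U", "G")}

    def structures(i, j):
        if i > j:
            yield frozenset()
            return
        yield from structures(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in pairs:
                for inner in structures(i + 1, k - 1):
                    for outer in structures(k + 1, j):
                        yield inner | outer | {(i, k)}

    return max(len(st_) for st_ in structures(0, len(s) - 1))


# ---------------------------------------------------------------------------
# prefix extraction


class TestExtractPrefixes:
    def _aln(self, name, cigar, seq, strand="+", start=0):
        return AlignmentRecord(name, "c", strand, start, cigar, seq)

    def test_leading_softclip_yields_prefix(self):
        rec = self._aln("t1", (("S", 20), ("M", 80)), "T" * 20 + "A" * 80)
        assert extract_unmapped_prefixes([rec]) == ["T" * 20]

    def test_fully_mapped_transcript_excluded(self):
        rec = self._aln("t1", (("M", 100),), "A" * 100)
        assert extract_unmapped_prefixes([rec]) == []

    @pytest.mark.parametrize("clip", [9, 60])
    def test_clip_outside_window_excluded(self, clip):
        rec = self._aln(
            "t1", (("S", clip), ("M", 40)), "G" * clip + "A" * 40
        )
        assert extract_unmapped_prefixes([rec], min_len=10, max_len=50) == []

    def test_minus_strand_prefix_in_transcript_orientation(self):
        read_fwd = "GATTACAGATTA" + "C" * 40  # 12 nt leader then body
        rec = self._aln(
            "t1", (("M", 40), ("S", 12)), revcomp(read_fwd), strand="-"
        )
        assert extract_unmapped_prefixes([rec]) == ["GATTACAGATTA"]

    def test_primary_alignment_is_longest_reference_span(self):
        short = self._aln("t1", (("S", 15), ("M", 30)), "G" * 15 + "A" * 30)
        long = self._aln("t1", (("S", 20), ("M", 80)), "T" * 20 + "A" * 80)
        assert extract_unmapped_prefixes([short, long]) == ["T" * 20]

    def test_missing_sequence_falls_back_to_transcript_set(self):
        rec = AlignmentRecord("t1", "c", "+", 0, (("S", 12), ("M", 30)), None)
        prefixes = extract_unmapped_prefixes(
            [rec], {"t1": "ACGTACGTACGT" + "A" * 30}
        )
        assert prefixes == ["ACGTACGTACGT"]
        with pytest.raises(ValueError, match="absent"):
            extract_unmapped_prefixes([rec], {})


# ---------------------------------------------------------------------------
# consensus


class TestReconstructSL:
    def test_suffix_mixture_recovers_full_leader(self, sl32):
        prefixes = (
            [sl32[-12:]] * 5 + [sl32[-16:]] * 3 + [sl32] * 2
        )
        cons = reconstruct_sl(prefixes, min_support=2)
        assert cons.sequence == sl32

    def test_unanimous_single_sequence(self):
        cons = reconstruct_sl(["ACGT"] * 3, min_support=2)
        assert cons.sequence == "ACGT"
        assert cons.support == (3, 3, 3, 3)

    def test_tied_column_stops_extension(self):
        # column 5 from the junction end is split A:3 / C:3
        prefixes = ["ATTTT"] * 3 + ["CTTTT"] * 3
        cons = reconstruct_sl(prefixes, min_support=2, min_fraction=0.8)
        assert cons.sequence == "TTTT"

    def test_support_non_increasing_toward_five_prime(self, sl32):
        prefixes = [sl32[-L:] for L in (10, 14, 20, 32, 32)]
        cons = reconstruct_sl(prefixes, min_support=1)
        assert list(cons.support) == sorted(cons.support)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            reconstruct_sl([])

    def test_no_qualifying_column_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty consensus"):
            cons = reconstruct_sl(["A", "C"], min_support=2, min_fraction=0.8)
        assert cons.sequence == ""

    @pytest.mark.filterwarnings("ignore:no consensus column")
    @given(st.data())
    @settings(max_examples=40)
    def test_matches_brute_force_column_vote(self, data):
        rng_lens = data.draw(
            st.lists(st.integers(1, 12), min_size=1, max_size=10)
        )
        prefixes = [
            "".join(
                data.draw(st.sampled_from("ACGT")) for _ in range(n)
            )
            for n in rng_lens
        ]
        got = reconstruct_sl(prefixes, min_support=2, min_fraction=0.6)
        assert got.sequence == oracle_column_vote(prefixes, 2, 0.6)

    def test_random_sl_recovery_property(self, rng):
        """Any SL (20-40 nt) is recovered exactly from >= 10 of its
        suffixes once enough full-length fragments are present."""
        bases = np.array(list("ACGT"))
        for _ in range(20):
            L = int(rng.integers(20, 41))
            sl = "".join(bases[rng.integers(0, 4, L)])
            lens = [int(x) for x in rng.integers(10, L + 1, size=10)] + [L, L]
            prefixes = [sl[L - l :] for l in lens]
            assert reconstruct_sl(prefixes, min_support=2).sequence == sl


# ---------------------------------------------------------------------------
# base-pair maximization


class TestMaxBasePairs:
    def test_no_complementary_bases(self):
        assert max_base_pairs("AAAA") == 0

    def test_perfect_stem(self):
        assert max_base_pairs("GGGAAACCC", min_loop=3) == 3

    def test_loop_constraint_blocks_short_hairpins(self):
        assert max_base_pairs("GC", min_loop=3) == 0
        assert max_base_pairs("GAAAC", min_loop=3) == 1

    def test_gu_wobble_toggle(self):
        seq = "GGGTTTTTT"  # G·U pairs only (T read as U)
        assert max_base_pairs(seq, allow_gu=True) == 3
        assert max_base_pairs(seq, allow_gu=False) == 0

    def test_extension_is_monotone(self, rng):
        bases = "ACGT"
        for _ in range(10):
            s = "".join(
                bases[i] for i in rng.integers(0, 4, int(rng.integers(5, 15)))
            )
            inner = max_base_pairs(s)
            assert max_base_pairs("G" + s + "C") >= inner

    def test_equals_structure_enumeration_oracle(self, rng):
        bases = "ACGU"
        for _ in range(30):
            n = int(rng.integers(4, 13))
            s = "".join(bases[i] for i in rng.integers(0, 4, n))
            assert max_base_pairs(s) == oracle_max_pairs(s), s


# ---------------------------------------------------------------------------
# SL RNA locus search


class TestFindSLRnaLoci:
    def test_planted_locus_recovered(self, default_dataset):
        m = default_dataset.manifest
        loci = find_sl_rna_loci(default_dataset.genome, m.sl_sequence)
        top = loci[0]
        assert (top.contig, top.start, top.end, top.strand) == m.sl_rna_locus
        assert top.mismatches == 0
        assert top.hairpin_score >= 8
        assert top.sm_interval is not None and top.canonical

    def test_absent_sl_gives_empty_result(self, rng, sl32):
        bases = "ACGT"
        genome = GenomeSequence(
            [("c", "".join(bases[i] for i in rng.integers(0, 4, 10_000)))]
        )
        # astronomically unlikely to contain the 32-mer within 1 mismatch
        assert find_sl_rna_loci(genome, sl32) == []

    def test_single_substitution_found_at_max_mismatch_one(self, rng, sl32):
        bases = "ACGT"
        background = "".join(bases[i] for i in rng.integers(0, 4, 3000))
        mutated = "T" + sl32[1:] if sl32[0] != "T" else "A" + sl32[1:]
        genome = GenomeSequence([("c", background[:1500] + mutated + background[1500:])])
        loci = find_sl_rna_loci(genome, sl32, max_mismatch=1)
        assert any(
            l.start == 1500 and l.strand == "+" and l.mismatches == 1
            for l in loci
        )

    def test_exact_search_equals_naive_string_scan(self, rng, sl32):
        bases = "ACGT"
        seq = "".join(bases[i] for i in rng.integers(0, 4, 4000))
        seq = seq[:700] + sl32 + seq[700:2000] + revcomp(sl32) + seq[2000:]
        genome = GenomeSequence([("c", seq)])
        loci = find_sl_rna_loci(genome, sl32, max_mismatch=0)
        got = {(l.start, l.strand) for l in loci}
        expect = set()
        for i in range(len(seq) - len(sl32) + 1):
            if seq[i : i + len(sl32)] == sl32:
                expect.add((i, "+"))
            if seq[i : i + len(sl32)] == revcomp(sl32):
                expect.add((i, "-"))
        assert got == expect

    def test_short_sl_rejected(self):
        genome = GenomeSequence([("c", "ACGT" * 100)])
        with pytest.raises(ValueError, match="unspecific"):
            find_sl_rna_loci(genome, "ACGTACGTACGT")
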