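"""Spliced-leader discovery from transcript alignments.

Trans-splicing prepends a short common leader (SL) to the 5' ends of many
distinct mRNAs.  When such transcripts are aligned to the genome, the SL
remnant does not match the acceptor locus and shows up as a leading
soft-clip.  This module extracts those unmapped 5' prefixes, reconstructs
the SL by right-anchored (junction-flush) consensus, and searches the
genome for the SL RNA donor gene (SL match + downstream Sm-like motif +
hairpin-forming region).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AlignmentRecord, GenomeSequence, revcomp


@dataclass(frozen=True)
class SLConsensus:
    """Reconstructed spliced-leader sequence.

    ``sequence`` is reported 5'->3'; its 3' end is the splice-junction end.
    ``support`` holds per-column contributing-prefix counts in the same
    orientation.  Because shorter soft-clipped fragments retain only the
    junction-proximal part of the SL, support is non-increasing from the
    3' end toward the 5' end.
    """

    sequence: str
    support: tuple[int, ...]
    n_prefixes_used: int


@dataclass(frozen=True)
class SLRnaLocus:
    """Candidate SL RNA gene locus.

    The SL match interval is on the forward genome ([start, end),
    length == SL length).  ``sm_interval`` is the first Sm-like motif match
    downstream of the SL 3' end (transcription sense), or None.
    ``hairpin_score`` is the maximum number of nested base pairs formable
    in the downstream window; ``canonical`` marks loci with both an Sm
    motif and a hairpin score above threshold.
    """

    contig: str
    strand: str
    start: int
    end: int
    mismatches: int
    sm_interval: tuple[int, int] | None
    hairpin_score: int
    canonical: bool


# ---------------------------------------------------------------------------
# prefix extraction


def extract_unmapped_prefixes(
    alignments: Iterable[AlignmentRecord],
    transcripts: Mapping[str, str] | GenomeSequence | None = None,
    min_len: int = 10,
    max_len: int = 50,
) -> list[str]:
    """Collect 5'-terminal soft-clipped substrings of aligned transcripts.

    For each transcript the primary alignment (longest reference span,
    ties broken by leftmost coordinate) is used.  Transcripts whose leading
    clip length L satisfies min_len <= L <= max_len contribute their first
    L nucleotides, in transcript orientation; others are excluded.
    """
    primary: dict[str, AlignmentRecord] = {}
    for rec in alignments:
        if not rec.mapped:
            continue
        prev = primary.get(rec.query_name)
        if prev is None or (
            rec.reference_span,
            -rec.reference_start,
        ) > (prev.reference_span, -prev.reference_start):
            primary[rec.query_name] = rec
    prefixes: list[str] = []
    for name in sorted(primary):
        rec = primary[name]
        clip = rec.leading_clip
        if not (min_len <= clip <= max_len):
            continue
        seq = rec.query_sequence_fwd
        if seq is None:
            if transcripts is None or name not in transcripts:
                raise ValueError(
                    f"alignment for {name!r} lacks a sequence and the "
                    "transcript is absent from the sequence set"
                )
            seq = transcripts[name]
        prefixes.append(seq[:clip])
    return prefixes


# ---------------------------------------------------------------------------
# consensus reconstruction


def reconstruct_sl(
    prefixes: Sequence[str],
    min_support: int = 2,
    min_fraction: float = 0.8,
) -> SLConsensus:
    """Build the SL consensus from unmapped 5' prefixes.

    The fragments share their 3' (junction) end, not their 5' end, so the
    prefixes are right-aligned and a majority vote is taken per column,
    extending 5'-ward while the column's contributing-prefix count stays
    at or above ``min_support`` and the majority base reaches
    ``min_fraction`` of contributors.
    """
    if not prefixes:
        raise ValueError("reconstruct_sl: empty prefix collection")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    max_len = max(len(p) for p in prefixes)
    consensus_rev: list[str] = []
    support_rev: list[int] = []
    for j in range(1, max_len + 1):
        column = [p[-j] for p in prefixes if len(p) >= j]
        if len(column) < min_support:
            break
        counts: dict[str, int] = {}
        for base in column:
            counts[base] = counts.get(base, 0) + 1
        # deterministic tie-break: highest count, then alphabetical
        top = min(counts, key=lambda b: (-counts[b], b))
        if counts[top] / len(column) < min_fraction:
            break
        consensus_rev.append(top)
        support_rev.append(len(column))
    if not consensus_rev:
        warnings.warn(
            "no consensus column met the support/majority thresholds; "
            "returning an empty consensus"
        )
    return SLConsensus(
        sequence="".join(reversed(consensus_rev)),
        support=tuple(reversed(support_rev)),
        n_prefixes_used=len(prefixes),
    )


# ---------------------------------------------------------------------------
# base-pair maximization (hairpin scoring)


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def max_base_pairs(seq: str, min_loop: int = 3, allow_gu: bool = True) -> int:
    """Maximum number of nested base pairs (Nussinov-style O(n^3) DP).

    Watson-Crick pairs plus, optionally, G·U wobble pairs; hairpin loops
    must contain at least ``min_loop`` unpaired bases.  T is read as U.
    This is a combinatorial stand-in for thermodynamic folding: it scores
    hairpin-forming potential, not free energy.
    """
    if not seq:
        raise ValueError("max_base_pairs: empty sequence")
    s = seq.upper().replace("T", "U")
    n = len(s)
    pairs = _WC | (_GU if allow_gu else set())
    can = [
        [(s[i], s[j]) in pairs for j in range(n)] for i in range(n)
    ]
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            row_i = dp[i]
            best = row_i[j - 1]
            for k in range(i, j - min_loop):
                if can[k][j]:
                    v = dp[k + 1][j - 1] + 1
                    if k > i:
                        v += row_i[k - 1]
                    if v > best:
                        best = v
            row_i[j] = best
    return dp[0][n - 1]


# ---------------------------------------------------------------------------
# SL RNA gene locus search


def _mismatch_scan(genome_bytes: np.ndarray, pattern: str) -> np.ndarray:
    """Per-offset substitution counts of `pattern` against the genome."""
    L = len(pattern)
    n = len(genome_bytes)
    if n < L:
        return np.empty(0, dtype=np.int32)
    pat = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    mism = np.zeros(n - L + 1, dtype=np.int32)
    for i in range(L):
        mism += genome_bytes[i : i + n - L + 1] != pat[i]
    return mism


def find_sl_rna_loci(
    genome: GenomeSequence,
    sl: str,
    max_mismatch: int = 1,
    sm_motif: str = "AATTTT",
    window: int = 120,
    min_hairpin_pairs: int = 8,
) -> list[SLRnaLocus]:
    """Locate SL RNA gene candidates: near-exact SL matches on either
    strand, scored for a downstream Sm-like motif and hairpin potential.

    The mismatch model is substitutions only (no indels).  Results are
    sorted by (fewest mismatches, highest hairpin score).
    """
    sl = sl.upper()
    if len(sl) < 15:
        raise ValueError(
            f"SL of length {len(sl)} is too unspecific for a genomic "
            "search (minimum 15)"
        )
    loci: list[SLRnaLocus] = []
    for contig, seq in genome.items():
        gbytes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for strand, pattern in (("+", sl), ("-", revcomp(sl))):
            mism = _mismatch_scan(gbytes, pattern)
            for pos in np.nonzero(mism <= max_mismatch)[0]:
                pos = int(pos)
                start, end = pos, pos + len(sl)
                if strand == "+":
                    wseq = seq[end : end + window]
                    woff = end
                else:
                    wseq = revcomp(seq[max(0, start - window) : start])
                    woff = start
                sm_interval = None
                hit = wseq.find(sm_motif)
                if hit >= 0:
                    if strand == "+":
                        sm_interval = (woff + hit, woff + hit + len(sm_motif))
                    else:
                        sm_interval = (
                            woff - hit - len(sm_motif),
                            woff - hit,
                        )
                hairpin = max_base_pairs(wseq) if wseq else 0
                loci.append(
                    SLRnaLocus(
                        contig=contig,
                        strand=strand,
                        start=start,
                        end=end,
                        mismatches=int(mism[pos]),
                        sm_interval=sm_interval,
                        hairpin_score=hairpin,
                        canonical=(
                            sm_interval is not None
                            and hairpin >= min_hairpin_pairs
                        ),
                    )
                )
    loci.sort(
        key=lambda l: (l.mismatches, -l.hairpin_score, l.contig, l.start)
    )
    return loci
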