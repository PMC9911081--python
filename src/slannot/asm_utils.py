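"""Assembly statistics, genome-size estimation, transcript-mapping
evaluation and terminal-repeat circularization of mitochondrial contigs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import AlignmentRecord, GenomeSequence
from .util import percent


# ---------------------------------------------------------------------------
# length statistics


@dataclass(frozen=True)
class LengthStats:
    """N50-style summary of a set of sequence lengths.

    N50 is the smallest length L such that sequences of length >= L sum to
    at least half the total; L50 is the number of such sequences in the
    minimal covering prefix.  GC is reported only when sequences (not bare
    lengths) were supplied, as 100*(G+C)/(A+C+G+T) with N excluded from the
    denominator.
    """

    n: int
    total: int
    mean: float
    min: int
    max: int
    n50: int
    l50: int
    gc: float | None = None


def length_stats(data) -> LengthStats:
    """Compute length statistics from sequences, a GenomeSequence, or ints."""
    if isinstance(data, GenomeSequence):
        seqs: list[str] | None = [s for _, s in data.items()]
    else:
        items = list(data)
        if not items:
            raise ValueError("length_stats: empty input")
        if isinstance(items[0], str):
            seqs = items
        else:
            seqs = None
            lengths = [int(x) for x in items]
    if seqs is not None:
        if not seqs:
            raise ValueError("length_stats: empty input")
        lengths = [len(s) for s in seqs]
    if not lengths or any(l <= 0 for l in lengths):
        raise ValueError("length_stats: lengths must be positive")

    lengths_sorted = sorted(lengths, reverse=True)
    total = sum(lengths_sorted)
    half = total / 2
    cum = 0
    n50 = lengths_sorted[-1]
    l50 = len(lengths_sorted)
    for i, length in enumerate(lengths_sorted):
        cum += length
        if cum >= half:
            n50 = length
            l50 = i + 1
            break

    gc = None
    if seqs is not None:
        g = sum(s.count("G") + s.count("C") for s in seqs)
        acgt = sum(
            s.count("A") + s.count("C") + s.count("G") + s.count("T")
            for s in seqs
        )
        gc = percent(g, acgt, 1) if acgt else None

    return LengthStats(
        n=len(lengths_sorted),
        total=total,
        mean=total / len(lengths_sorted),
        min=lengths_sorted[-1],
        max=lengths_sorted[0],
        n50=n50,
        l50=l50,
        gc=gc,
    )


# ---------------------------------------------------------------------------
# flow-cytometry genome-size estimation


def estimate_genome_size(
    sample_fluorescence: float,
    reference_fluorescence: float,
    reference_size: float,
) -> float:
    """Ratio estimator: G = reference_size * sample / reference.

    Flow-cytometry fluorescence is proportional to DNA content, so the
    unknown genome size follows from a co-measured reference standard of
    known size.
    """
    if (
        sample_fluorescence <= 0
        or reference_fluorescence <= 0
        or reference_size <= 0
    ):
        raise ValueError("fluorescence values and reference size must be positive")
    return reference_size * sample_fluorescence / reference_fluorescence


@dataclass(frozen=True)
class GenomeSizeEstimate:
    """Per-reference estimates plus their min-max range (all in bp)."""

    estimates: tuple[tuple[str, float], ...]
    low: float
    high: float

    def format_range(self, unit: float = 1e6, decimals: int = 0) -> str:
        lo = round(self.low / unit, decimals)
        hi = round(self.high / unit, decimals)
        if decimals == 0:
            return f"{int(lo)}–{int(hi)}"
        return f"{lo}–{hi}"


def estimate_genome_size_multi(
    sample_fluorescence: float,
    references: Mapping[str, tuple[float, float]],
) -> GenomeSizeEstimate:
    """Estimate against several references; report each and the range.

    `references` maps name -> (fluorescence, genome size in bp).
    """
    if not references:
        raise ValueError("at least one reference standard required")
    ests = tuple(
        (name, estimate_genome_size(sample_fluorescence, fluor, size))
        for name, (fluor, size) in references.items()
    )
    values = [v for _, v in ests]
    return GenomeSizeEstimate(estimates=ests, low=min(values), high=max(values))


# ---------------------------------------------------------------------------
# transcript-mapping evaluation


def transcript_mapping_fraction(
    alignments: Iterable[AlignmentRecord],
    n_transcripts: int,
    min_coverage: float = 0.9,
) -> float:
    """Percent of transcripts whose best alignment covers >= min_coverage.

    Coverage is aligned query bases (M+I) over query length; the best
    alignment per query is the one with highest coverage.  Unmapped records
    count toward nothing but are accepted as input.
    """
    if n_transcripts <= 0:
        raise ValueError("n_transcripts must be positive")
    best: dict[str, float] = {}
    seen: set[str] = set()
    for rec in alignments:
        seen.add(rec.query_name)
        if not rec.mapped or not rec.cigar:
            continue
        qlen = rec.query_length
        if qlen == 0:
            continue
        cov = rec.aligned_query_bases / qlen
        if cov > best.get(rec.query_name, -1.0):
            best[rec.query_name] = cov
    if len(seen) > n_transcripts:
        raise ValueError(
            f"more distinct aligned queries ({len(seen)}) than transcripts "
            f"({n_transcripts})"
        )
    mapped = sum(1 for cov in best.values() if cov >= min_coverage)
    return 100.0 * mapped / n_transcripts


# ---------------------------------------------------------------------------
# terminal-repeat circularization


@dataclass(frozen=True)
class CircularizationResult:
    """Outcome of terminal-repeat detection on a linear contig.

    A circular genome assembled as a linear contig carries an identical
    sequence copy at both ends; removing the trailing copy restores the
    circle.  ``circular`` is None when no terminal repeat of at least
    ``min_repeat`` was found.
    """

    circular: str | None
    repeat_length: int
    original_length: int

    @property
    def circularizable(self) -> bool:
        return self.circular is not None


def largest_terminal_repeat(contig: str) -> int:
    """Largest k <= len//2 with contig[:k] == contig[-k:] (0 if none)."""
    for k in range(len(contig) // 2, 0, -1):
        if contig[:k] == contig[len(contig) - k :]:
            return k
    return 0


def _least_rotation(s: str) -> str:
    """Booth's algorithm: lexicographically smallest rotation of s."""
    doubled = s + s
    n = len(s)
    f = [-1] * len(doubled)
    k = 0
    for j in range(1, len(doubled)):
        sj = doubled[j]
        i = f[j - k - 1]
        while i != -1 and sj != doubled[k + i + 1]:
            if sj < doubled[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != doubled[k + i + 1]:
            if sj < doubled[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return doubled[k : k + n]


def circularize_terminal_repeat(
    contig: str,
    min_repeat: int = 100,
    canonical_rotation: bool = False,
) -> CircularizationResult:
    """Detect an exact terminal repeat and collapse the contig to a circle.

    Only 100%-identical repeats are considered.  When no repeat of at least
    ``min_repeat`` exists the result is an explicit "not circularizable"
    value, not an exception.
    """
    contig = contig.upper()
    if len(contig) <= 2 * min_repeat:
        raise ValueError(
            f"contig length {len(contig)} must exceed 2*min_repeat "
            f"({2 * min_repeat})"
        )
    k = largest_terminal_repeat(contig)
    if k < min_repeat:
        return CircularizationResult(
            circular=None, repeat_length=0, original_length=len(contig)
        )
    circle = contig[: len(contig) - k]
    if canonical_rotation:
        circle = _least_rotation(circle)
    return CircularizationResult(
        circular=circle, repeat_length=k, original_length=len(contig)
    )
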