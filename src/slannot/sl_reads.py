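"""Identify and trim reads carrying the spliced leader or a polyA tail.

SL-carrying reads retain the junction-proximal (3') part of the leader at
their 5' end; matching is therefore suffix-anchored: the SL 3' end is
placed at the read 5' junction and the overlap extended leftward.  The
mismatch budget scales with overlap length so that short overlaps are not
over-accepted.  Trimmed reads are what gets remapped to build the
trans-splice acceptor (5' end) and polyadenylation (3' end) signal tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import FormatError, SeqRead


@dataclass(frozen=True)
class TrimReport:
    """Bookkeeping for one trimming run.

    Conservation: n_input = n_trimmed + n_excluded; the histogram of
    matched fragment (or tail) lengths sums to n_sl_detected.
    """

    n_input: int
    n_sl_detected: int
    n_trimmed: int
    n_excluded: int
    histogram: dict[int, int] = field(default_factory=dict)


def match_sl_prefix(
    read: str,
    sl: str,
    min_overlap: int = 8,
    max_mismatch_per_10: int = 1,
) -> int:
    """Length of the longest SL suffix matching the read's 5' end.

    Returns the largest L >= min_overlap such that the L-length suffix of
    the SL aligns to the read's first L bases with at most
    floor(L/10)*max_mismatch_per_10 substitutions; 0 when none qualifies.
    """
    if not read or not sl:
        raise ValueError("read and SL must be non-empty")
    for L in range(min(len(sl), len(read)), min_overlap - 1, -1):
        budget = (L // 10) * max_mismatch_per_10
        mismatches = 0
        sl_suffix = sl[len(sl) - L :]
        ok = True
        for a, b in zip(sl_suffix, read):
            if a != b:
                mismatches += 1
                if mismatches > budget:
                    ok = False
                    break
        if ok:
            return L
    return 0


def _polya_tail_length(seq: str, min_a: int = 8) -> int:
    """Length of a trailing polyA run (>= min_a A's, <= 1 non-A tolerated)."""
    n = len(seq)
    i = n - 1
    non_a = 0
    while i >= 0:
        if seq[i] == "A":
            i -= 1
        elif non_a == 0:
            non_a += 1
            i -= 1
        else:
            break
    start = i + 1
    # the tolerated non-A may not sit at the run's 5' boundary
    while start < n and seq[start] != "A":
        start += 1
    run = seq[start:]
    if run.count("A") >= min_a:
        return n - start
    return 0


def trim_reads(
    reads: list[SeqRead],
    sl: str | None = None,
    mode: str = "sl",
    *,
    min_overlap: int = 8,
    max_mismatch_per_10: int = 1,
    min_a: int = 8,
    min_len: int = 20,
) -> tuple[list[SeqRead], TrimReport]:
    """Trim SL fragments (mode='sl') or polyA tails (mode='polya').

    SL mode: reads whose 5' end matches an SL suffix are emitted with the
    matched bases (and qualities) removed; non-matching reads are excluded
    from the output but counted — only SL-evidence reads are remapped for
    trans-splice peaks.  polyA mode: trailing A-runs are removed and reads
    shorter than ``min_len`` after trimming are dropped.
    """
    if mode not in ("sl", "polya"):
        raise ValueError(f"unknown trim mode: {mode!r}")
    if mode == "sl" and not sl:
        raise ValueError("SL sequence required in SL mode")
    trimmed: list[SeqRead] = []
    histogram: dict[int, int] = {}
    n_detected = 0
    n_excluded = 0
    for read in reads:
        if read.quality is not None and len(read.quality) != len(read.sequence):
            raise FormatError(
                f"sequence/quality length mismatch for read {read.name!r}"
            )
        if mode == "sl":
            L = match_sl_prefix(
                read.sequence, sl, min_overlap, max_mismatch_per_10
            )
            if L == 0:
                n_excluded += 1
                continue
            n_detected += 1
            histogram[L] = histogram.get(L, 0) + 1
            trimmed.append(
                SeqRead(
                    read.name,
                    read.sequence[L:],
                    read.quality[L:] if read.quality is not None else None,
                )
            )
        else:
            L = _polya_tail_length(read.sequence, min_a)
            if L == 0:
                n_excluded += 1
                continue
            n_detected += 1
            histogram[L] = histogram.get(L, 0) + 1
            new_seq = read.sequence[: len(read.sequence) - L]
            if len(new_seq) < min_len:
                n_excluded += 1
                continue
            trimmed.append(
                SeqRead(
                    read.name,
                    new_seq,
                    read.quality[: len(new_seq)]
                    if read.quality is not None
                    else None,
                )
            )
    report = TrimReport(
        n_input=len(reads),
        n_sl_detected=n_detected,
        n_trimmed=len(trimmed),
        n_excluded=n_excluded,
        histogram=histogram,
    )
    return trimmed, report
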