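"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based, half-open on the forward genomic
strand; conversion to the 1-based closed convention happens only at the
GFF3/SAM boundaries.  Downstream modules consume only the types defined
here (:class:`GenomeSequence`, :class:`SeqRead`, :class:`AlignmentRecord`,
:class:`TranscriptModel`, :class:`SignalTrack`).
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import pysam
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: pysam numeric CIGAR codes -> characters.
_CIGAR_CODE = "MIDNSHP=X"
_SUPPORTED_OPS = frozenset("MIDNSH")
_REF_OPS = frozenset("MDN")
_QUERY_OPS = frozenset("MIS")


class FormatError(ValueError):
    """A malformed input file, record or in-memory object."""


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# sequences


class GenomeSequence:
    """Ordered, named collection of uppercase nucleotide sequences.

    Provides strand-aware slicing via :meth:`fetch`.  Names must be unique
    and sequences restricted to the A/C/G/T/N alphabet; violations raise
    :class:`FormatError` at construction.
    """

    def __init__(self, items: Iterable[tuple[str, str]]):
        self._seqs: dict[str, str] = {}
        for name, seq in items:
            if name in self._seqs:
                raise FormatError(f"duplicate sequence name: {name!r}")
            up = seq.upper()
            bad = set(up) - VALID_BASES
            if bad:
                raise FormatError(
                    f"illegal characters {sorted(bad)} in sequence {name!r}"
                )
            self._seqs[name] = up

    # mapping-ish interface -------------------------------------------------
    def __len__(self) -> int:
        return len(self._seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSequence) and self._seqs == other._seqs

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._seqs.items()}

    def fetch(
        self,
        name: str,
        start: int | None = None,
        end: int | None = None,
        strand: str = "+",
    ) -> str:
        """Return the sub-sequence [start, end); reverse-complemented for '-'."""
        seq = self._seqs[name][start:end]
        return revcomp(seq) if strand == "-" else seq

    # I/O -------------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        return cls(
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
        )

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class SeqRead:
    """A single FASTA/FASTQ record (quality is None for FASTA)."""

    name: str
    sequence: str
    quality: str | None = None


def read_sequences(path: str | Path, format: str = "fasta"):
    """Parse FASTA into a :class:`GenomeSequence` or FASTQ into SeqReads.

    Lowercase input is uppercased; duplicate names or characters outside
    A/C/G/T/N raise :class:`FormatError` naming the offending record.
    """
    fmt = format.lower()
    if fmt == "fasta":
        return GenomeSequence.from_fasta(path)
    if fmt == "fastq":
        reads: list[SeqRead] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(str(path), "fastq"):
            if rec.id in seen:
                raise FormatError(f"duplicate read name: {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"illegal characters {sorted(bad)} in read {rec.id!r}"
                )
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            reads.append(SeqRead(rec.id, seq, qual))
        return reads
    raise ValueError(f"unknown sequence format: {format!r}")


def write_fastq(reads: Iterable[SeqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            if len(qual) != len(r.sequence):
                raise FormatError(
                    f"sequence/quality length mismatch for read {r.name!r}"
                )
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{qual}\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# alignments


@dataclass(frozen=True)
class AlignmentRecord:
    """One read/transcript-to-genome alignment.

    `query_sequence` is stored in SAM orientation (reverse-complemented
    relative to the read for '-' strand records); `query_sequence_fwd`
    recovers the read orientation.  Coordinates are 0-based half-open.
    """

    query_name: str
    reference_name: str | None
    strand: str
    reference_start: int
    cigar: tuple[tuple[str, int], ...]
    query_sequence: str | None = None
    mapped: bool = True

    def __post_init__(self):
        for op, length in self.cigar:
            if op not in _SUPPORTED_OPS:
                raise FormatError(
                    f"unsupported CIGAR op {op!r} in record {self.query_name!r}"
                )
            if length <= 0:
                raise FormatError(
                    f"non-positive CIGAR length in record {self.query_name!r}"
                )
        if self.mapped and self.query_sequence is not None and self.cigar:
            qlen = sum(l for op, l in self.cigar if op in _QUERY_OPS)
            if qlen != len(self.query_sequence):
                raise FormatError(
                    f"CIGAR query length {qlen} != sequence length "
                    f"{len(self.query_sequence)} for {self.query_name!r}"
                )

    @property
    def reference_end(self) -> int:
        return self.reference_start + self.reference_span

    @property
    def reference_span(self) -> int:
        return sum(l for op, l in self.cigar if op in _REF_OPS)

    @property
    def query_length(self) -> int:
        if self.cigar:
            return sum(l for op, l in self.cigar if op in _QUERY_OPS)
        return len(self.query_sequence or "")

    @property
    def aligned_query_bases(self) -> int:
        return sum(l for op, l in self.cigar if op in ("M", "I"))

    @property
    def leading_clip(self) -> int:
        """Soft-clip length at the query 5' end, in read orientation."""
        ops = [(op, l) for op, l in self.cigar if op != "H"]
        if not ops:
            return 0
        op, length = ops[0] if self.strand == "+" else ops[-1]
        return length if op == "S" else 0

    @property
    def query_sequence_fwd(self) -> str | None:
        """Query sequence in read (5'->3') orientation."""
        if self.query_sequence is None:
            return None
        if self.strand == "-":
            return revcomp(self.query_sequence)
        return self.query_sequence


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Parse a SAM file (text) into AlignmentRecords.

    Unmapped records (FLAG bit 4) are retained with ``mapped=False`` so that
    denominator statistics remain computable.  CIGAR ops P/=/X raise a
    :class:`FormatError` listing the record.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam.fetch(until_eof=True):
            if seg.is_unmapped:
                records.append(
                    AlignmentRecord(
                        query_name=seg.query_name,
                        reference_name=None,
                        strand="+",
                        reference_start=-1,
                        cigar=(),
                        query_sequence=seg.query_sequence,
                        mapped=False,
                    )
                )
                continue
            cig: list[tuple[str, int]] = []
            for code, length in seg.cigartuples or ():
                op = _CIGAR_CODE[code]
                if op not in _SUPPORTED_OPS:
                    raise FormatError(
                        f"unsupported CIGAR op {op!r} in record "
                        f"{seg.query_name!r}"
                    )
                cig.append((op, length))
            records.append(
                AlignmentRecord(
                    query_name=seg.query_name,
                    reference_name=seg.reference_name,
                    strand="-" if seg.is_reverse else "+",
                    reference_start=seg.reference_start,
                    cigar=tuple(cig),
                    query_sequence=seg.query_sequence,
                    mapped=True,
                )
            )
    return records


def write_alignments(
    records: Iterable[AlignmentRecord],
    path: str | Path,
    references: Mapping[str, int],
) -> None:
    """Write records as SAM with an @SQ header built from `references`."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
    }
    ref_ids = {name: i for i, name in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.query_name
            seg.query_sequence = rec.query_sequence
            if rec.query_sequence is not None:
                seg.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(rec.query_sequence)
                )
            if not rec.mapped:
                seg.is_unmapped = True
                out.write(seg)
                continue
            seg.reference_id = ref_ids[rec.reference_name]
            seg.reference_start = rec.reference_start
            seg.cigartuples = [
                (_CIGAR_CODE.index(op), l) for op, l in rec.cigar
            ]
            seg.flag = 16 if rec.strand == "-" else 0
            seg.mapping_quality = 60
            out.write(seg)


# ---------------------------------------------------------------------------
# gene features (GFF3)


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded exon-chain transcript model (0-based half-open exons)."""

    id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    attributes: tuple[tuple[str, str], ...] = ()

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def _check_exons(exons: Sequence[tuple[int, int]], owner: str) -> None:
    prev_end = None
    for s, e in exons:
        if e <= s:
            raise FormatError(f"empty exon interval in {owner!r}")
        if prev_end is not None and s < prev_end:
            raise FormatError(f"overlapping/unsorted exons in {owner!r}")
        prev_end = e


def _fmt_flag(value) -> str:
    return "true" if value else "false"


def write_features(genes, path: str | Path, source: str = "slannot") -> None:
    """Write gene models as GFF3 (gene/mRNA/exon rows, 1-based closed).

    Accepts any objects exposing ``id``, ``contig``, ``strand``, ``exons``
    and optionally ``sl_trans_spliced`` / ``coding`` flags (written as
    custom attributes when not None).  Output ordering is deterministic:
    (contig, start, id).
    """
    rows = []
    for g in genes:
        _check_exons(g.exons, g.id)
        rows.append(g)
    rows.sort(key=lambda g: (g.contig, g.exons[0][0], g.id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in rows:
            start = g.exons[0][0]
            end = g.exons[-1][1]
            attrs = [f"ID={g.id}"]
            sl = getattr(g, "sl_trans_spliced", None)
            coding = getattr(g, "coding", None)
            if sl is not None:
                attrs.append(f"sl_trans_spliced={_fmt_flag(sl)}")
            if coding is not None:
                attrs.append(f"coding={_fmt_flag(coding)}")
            fh.write(
                f"{g.contig}\t{source}\tgene\t{start + 1}\t{end}\t.\t"
                f"{g.strand}\t.\t{';'.join(attrs)}\n"
            )
            mrna = f"{g.id}.t1"
            fh.write(
                f"{g.contig}\t{source}\tmRNA\t{start + 1}\t{end}\t.\t"
                f"{g.strand}\t.\tID={mrna};Parent={g.id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tID={mrna}.exon{i};Parent={mrna}\n"
                )


def read_features(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models (mRNA/transcript + exon children) from GFF3."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        force=True,
    )
    models: list[TranscriptModel] = []
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            exons = sorted(
                (child.start - 1, child.end)
                for child in db.children(feat, featuretype="exon")
            )
            if not exons:
                exons = [(feat.start - 1, feat.end)]
            attrs = tuple(
                (k, v[0]) for k, v in feat.attributes.items() if k not in ("ID", "Parent")
            )
            models.append(
                TranscriptModel(
                    id=feat.id,
                    contig=feat.seqid,
                    strand=feat.strand,
                    exons=tuple(exons),
                    attributes=attrs,
                )
            )
    models.sort(key=lambda m: (m.contig, m.start, m.id))
    return models


# ---------------------------------------------------------------------------
# signal tracks (bedGraph)


class SignalTrack:
    """Strand-aware per-base integer counts; absent positions mean zero."""

    __slots__ = ("_counts",)

    def __init__(self):
        self._counts: dict[tuple[str, str], dict[int, int]] = {}

    def add(self, contig: str, strand: str, pos: int, count: int = 1) -> None:
        if count < 0 or pos < 0:
            raise ValueError("positions and counts must be non-negative")
        if count == 0:
            return
        key = (contig, strand)
        bucket = self._counts.setdefault(key, {})
        bucket[pos] = bucket.get(pos, 0) + count

    def count(self, contig: str, strand: str, pos: int) -> int:
        return self._counts.get((contig, strand), {}).get(pos, 0)

    def mass(self) -> int:
        return sum(sum(b.values()) for b in self._counts.values())

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._counts)

    def positions(self, contig: str, strand: str) -> dict[int, int]:
        return dict(self._counts.get((contig, strand), {}))

    def nonzero(self) -> Iterator[tuple[str, str, int, int]]:
        for (contig, strand) in sorted(self._counts):
            bucket = self._counts[(contig, strand)]
            for pos in sorted(bucket):
                if bucket[pos]:
                    yield contig, strand, pos, bucket[pos]

    def _stripped(self) -> dict:
        return {
            key: {p: c for p, c in bucket.items() if c}
            for key, bucket in self._counts.items()
            if any(bucket.values())
        }

    def __eq__(self, other) -> bool:
        return isinstance(other, SignalTrack) and self._stripped() == other._stripped()


_STRAND_SUFFIX = (("+", "plus"), ("-", "minus"))


def write_signal(track: SignalTrack, prefix: str | Path) -> tuple[Path, Path]:
    """Write one bedGraph per strand (0-based half-open, equal runs merged)."""
    prefix = Path(prefix)
    paths = []
    for strand, suffix in _STRAND_SUFFIX:
        path = prefix.parent / f"{prefix.name}.{suffix}.bedgraph"
        with open(path, "w") as fh:
            contigs = sorted(
                c for (c, s) in track._counts if s == strand
            )
            for contig in contigs:
                bucket = track._counts[(contig, strand)]
                run_start = run_end = None
                run_val = None
                for pos in sorted(bucket):
                    val = bucket[pos]
                    if not val:
                        continue
                    if run_val is not None and pos == run_end and val == run_val:
                        run_end = pos + 1
                        continue
                    if run_val is not None:
                        fh.write(f"{contig}\t{run_start}\t{run_end}\t{run_val}\n")
                    run_start, run_end, run_val = pos, pos + 1, val
                if run_val is not None:
                    fh.write(f"{contig}\t{run_start}\t{run_end}\t{run_val}\n")
        paths.append(path)
    return paths[0], paths[1]


def read_signal(plus_path: str | Path, minus_path: str | Path) -> SignalTrack:
    track = SignalTrack()
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise FormatError(
                        f"{path}: line {lineno}: expected 4 bedGraph columns"
                    )
                contig, start, end, val = parts
                for pos in range(int(start), int(end)):
                    track.add(contig, strand, pos, int(val))
    return track
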