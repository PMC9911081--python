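"""Synthetic data generator with ground truth.

Emulates the data a spliced-leader annotation pipeline consumes: a toy
genome carrying one SL RNA gene cassette, mono- and polycistronic gene
loci, trans-spliced transcripts bearing variable-length SL prefixes,
RNA-seq reads (with guaranteed junction coverage), polyadenylated 3'-tag
reads, initial (run-through) gene models, and truth alignments encoding
SL remnants as leading soft-clips.  Identical configurations (including
the seed) give byte-identical outputs.

Design notes: genes are intronless by default (introns via
``introns_per_gene_range``); downstream members of polycistronic pairs
are always trans-spliced, since trans-splicing is what resolves a
polycistron; trans-spliced transcripts retain a 3'-terminal suffix of
the SL, and at least two of them (when available) retain the full
leader, mirroring the presence of full-length 5' ends in real de novo
transcriptome assemblies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .asm_utils import largest_terminal_repeat
from .io_formats import (
    AlignmentRecord,
    GenomeSequence,
    SeqRead,
    TranscriptModel,
    revcomp,
    write_alignments,
    write_fasta,
    write_fastq,
    write_features,
)
from .util import round_half_up

#: The 32-nt spliced leader used as the default simulated SL.
DEFAULT_SL = "GCCTAATTGTTGTGATAAACTTATTAAATAGA"
DEFAULT_SM_MOTIF = "AATTTT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(ValueError):
    """The requested loci do not fit into the genome."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset.

    Fractions must lie in [0,1] and all (min, max) ranges must be ordered.
    ``trans_spliced_fraction`` defaults to 0.302 (the fraction observed in
    acoel annotation); counts derived from fractions use round-half-up.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_genes: int = 20
    polycistron_fraction: float = 0.2
    sl_sequence: str = DEFAULT_SL
    trans_spliced_fraction: float = 0.302
    n_reads: int = 600
    read_length: int = 100
    sl_prefix_length_range: tuple[int, int] = (10, 32)
    n_tag_reads: int = 120
    polya_length_range: tuple[int, int] = (8, 20)
    error_rate: float = 0.0
    gene_length_range: tuple[int, int] = (300, 800)
    introns_per_gene_range: tuple[int, int] = (0, 0)
    intron_length_range: tuple[int, int] = (60, 200)
    min_intergenic_gap: int = 200
    sm_motif: str = DEFAULT_SM_MOTIF
    contig_name: str = "contig1"

    def __post_init__(self):
        for name in ("polycistron_fraction", "trans_spliced_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in (
            "sl_prefix_length_range",
            "polya_length_range",
            "gene_length_range",
            "introns_per_gene_range",
            "intron_length_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if set(self.sl_sequence.upper()) - set("ACGT"):
            raise ValueError("sl_sequence must be over A/C/G/T")
        if self.sl_prefix_length_range[0] < 1:
            raise ValueError("sl_prefix_length_range min must be >= 1")
        if self.read_length > self.gene_length_range[0]:
            raise ValueError(
                "read_length must not exceed the minimum gene length "
                f"({self.read_length} > {self.gene_length_range[0]})"
            )
        if self.polya_length_range[1] >= self.read_length:
            raise ValueError("polyA tails must be shorter than the read length")
        n_ts = round_half_up(self.trans_spliced_fraction * self.n_genes)
        n_pairs = round_half_up(self.polycistron_fraction * self.n_genes) // 2
        if n_pairs > n_ts:
            raise ValueError(
                f"{n_pairs} polycistronic pairs require at least {n_pairs} "
                f"trans-spliced genes, but only {n_ts} are requested "
                "(downstream polycistron members must be trans-spliced)"
            )

    @property
    def n_trans_spliced(self) -> int:
        return round_half_up(self.trans_spliced_fraction * self.n_genes)

    @property
    def n_polycistron_pairs(self) -> int:
        return round_half_up(self.polycistron_fraction * self.n_genes) // 2


# ---------------------------------------------------------------------------
# truth records


@dataclass(frozen=True)
class GeneTruth:
    id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    trans_spliced: bool
    group: int | None  # polycistron group id, None for monocistronic
    acceptor_site: int | None  # genomic trans-splice acceptor position
    polya_site: int

    coding = None  # truth GFF3 carries no coding call

    @property
    def sl_trans_spliced(self) -> bool:
        return self.trans_spliced

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class TranscriptTruth:
    id: str
    gene_id: str
    sequence: str
    sl_fragment_length: int


@dataclass(frozen=True)
class ReadTruth:
    id: str
    transcript_id: str
    offset: int
    sl_fragment_length: int  # 0 for reads not covering the junction
    polya_length: int  # 0 for plain RNA-seq reads
    tag: bool  # True for 3'-tag reads


@dataclass(frozen=True)
class TruthManifest:
    sl_sequence: str
    sl_rna_locus: tuple[str, int, int, str]
    genes: tuple[GeneTruth, ...]
    transcripts: tuple[TranscriptTruth, ...]
    reads: tuple[ReadTruth, ...]

    @property
    def n_trans_spliced(self) -> int:
        return sum(1 for g in self.genes if g.trans_spliced)

    def acceptor_sites(self) -> set[tuple[str, str, int]]:
        return {
            (g.contig, g.strand, g.acceptor_site)
            for g in self.genes
            if g.trans_spliced
        }


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeSequence
    manifest: TruthManifest
    transcripts: list[SeqRead]
    reads: list[SeqRead]
    tag_reads: list[SeqRead]
    transcript_alignments: list[AlignmentRecord]
    read_alignments: list[AlignmentRecord]
    tag_alignments: list[AlignmentRecord]
    initial_models: list[TranscriptModel]


# ---------------------------------------------------------------------------
# helpers


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _exonic_blocks(
    exons: Sequence[tuple[int, int]], a: int, b: int
) -> list[tuple[int, int]]:
    """Map the exonic-coordinate interval [a,b) to genomic blocks."""
    blocks: list[tuple[int, int]] = []
    offset = 0
    for s, e in exons:
        length = e - s
        lo, hi = max(a, offset), min(b, offset + length)
        if lo < hi:
            blocks.append((s + lo - offset, s + hi - offset))
        offset += length
    return blocks


def _body_blocks(gene: GeneTruth, b0: int, b1: int) -> list[tuple[int, int]]:
    """Genomic blocks for the transcript-body interval [b0,b1)."""
    total = gene.exonic_length
    if gene.strand == "+":
        return _exonic_blocks(gene.exons, b0, b1)
    return _exonic_blocks(gene.exons, total - b1, total - b0)


def _blocks_cigar(blocks: Sequence[tuple[int, int]]) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            if gap > 0:
                ops.append(("N", gap))
        ops.append(("M", e - s))
    return ops


def _alignment_for(
    name: str,
    gene: GeneTruth,
    read_seq: str,
    b0: int,
    b1: int,
    clip5: int,
    clip3: int,
) -> AlignmentRecord:
    """Truth alignment of a read covering body [b0,b1) with soft clips.

    clip5/clip3 are clip lengths at the read's 5'/3' ends in read
    orientation (SL remnant / polyA tail).
    """
    blocks = _body_blocks(gene, b0, b1)
    mid = _blocks_cigar(blocks)
    if gene.strand == "+":
        cigar = (
            ([("S", clip5)] if clip5 else [])
            + mid
            + ([("S", clip3)] if clip3 else [])
        )
        seq = read_seq
    else:
        cigar = (
            ([("S", clip3)] if clip3 else [])
            + mid
            + ([("S", clip5)] if clip5 else [])
        )
        seq = revcomp(read_seq)
    return AlignmentRecord(
        query_name=name,
        reference_name=gene.contig,
        strand=gene.strand,
        reference_start=blocks[0][0],
        cigar=tuple(cigar),
        query_sequence=seq,
        mapped=True,
    )


# ---------------------------------------------------------------------------
# dataset simulation


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate a complete synthetic dataset with ground truth."""
    rng = np.random.default_rng(config.seed)
    sl = config.sl_sequence.upper()
    contig = config.contig_name
    n = config.n_genes

    # --- gene structures (lengths, exon/intron layout) --------------------
    exonic_lens = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
    )
    intron_counts = rng.integers(
        config.introns_per_gene_range[0],
        config.introns_per_gene_range[1] + 1,
        size=n,
    )
    gene_layouts: list[dict] = []
    for i in range(n):
        exonic = int(exonic_lens[i])
        k = int(intron_counts[i])
        min_exon = 60
        if exonic < (k + 1) * min_exon:
            k = max(0, exonic // min_exon - 1)
        slack = exonic - (k + 1) * min_exon
        parts = (
            rng.multinomial(slack, [1.0 / (k + 1)] * (k + 1))
            if k + 1 > 1
            else np.array([slack])
        )
        exon_lens = [min_exon + int(p) for p in parts]
        intron_lens = [
            int(x)
            for x in rng.integers(
                config.intron_length_range[0],
                config.intron_length_range[1] + 1,
                size=k,
            )
        ]
        genomic = sum(exon_lens) + sum(intron_lens)
        gene_layouts.append(
            {"exon_lens": exon_lens, "intron_lens": intron_lens, "genomic": genomic}
        )

    # --- polycistron pairing and trans-spliced assignment -----------------
    n_ts = config.n_trans_spliced
    n_pairs = config.n_polycistron_pairs
    perm = [int(x) for x in rng.permutation(n)]
    pairs = [(perm[2 * i], perm[2 * i + 1]) for i in range(n_pairs)]
    downstream = {b for _, b in pairs}
    ts_flags = [False] * n
    for b in downstream:
        ts_flags[b] = True
    candidates = [i for i in range(n) if i not in downstream]
    extra = n_ts - len(downstream)
    if extra > 0:
        chosen = rng.choice(len(candidates), size=extra, replace=False)
        for c in sorted(int(x) for x in chosen):
            ts_flags[candidates[c]] = True

    # --- SL RNA gene cassette ---------------------------------------------
    stem = _arr_to_str(_random_bases(rng, 12))
    cassette = (
        sl
        + "GT"
        + _arr_to_str(_random_bases(rng, 8))
        + stem
        + "TTCGA"
        + revcomp(stem)
        + _arr_to_str(_random_bases(rng, 6))
        + config.sm_motif
        + _arr_to_str(_random_bases(rng, 10))
    )

    # --- placement ---------------------------------------------------------
    paired_ids = {a for a, _ in pairs} | downstream
    units: list[tuple] = [("pair", a, b) for a, b in pairs]
    units += [("gene", i) for i in range(n) if i not in paired_ids]
    units.append(("cassette",))
    order = [int(x) for x in rng.permutation(len(units))]
    units = [units[i] for i in order]
    strands = ["+" if x < 0.5 else "-" for x in rng.random(len(units))]
    intra_gaps = [
        int(x) for x in rng.integers(80, 151, size=len(units))
    ]  # used only by pair units

    def unit_length(idx: int) -> int:
        unit = units[idx]
        if unit[0] == "pair":
            return (
                gene_layouts[unit[1]]["genomic"]
                + intra_gaps[idx]
                + gene_layouts[unit[2]]["genomic"]
            )
        if unit[0] == "gene":
            return gene_layouts[unit[1]]["genomic"]
        return len(cassette)

    total_units = sum(unit_length(i) for i in range(len(units)))
    n_slots = len(units) + 1
    needed = total_units + n_slots * config.min_intergenic_gap
    if needed > config.genome_length:
        raise PlacementError(
            f"cannot place {n} genes plus the SL RNA cassette in a "
            f"{config.genome_length} bp genome (needs >= {needed} bp)"
        )
    slack = config.genome_length - needed
    extra_gaps = rng.multinomial(slack, [1.0 / n_slots] * n_slots)
    gaps = [config.min_intergenic_gap + int(g) for g in extra_gaps]

    genome_arr = _random_bases(rng, config.genome_length)

    placed: list[dict] = []  # per gene: exons, strand, ts, group
    cassette_pos = None
    cassette_strand = "+"
    cursor = 0
    group_counter = 0
    for idx, unit in enumerate(units):
        cursor += gaps[idx]
        strand = strands[idx]
        if unit[0] == "cassette":
            cassette_pos = cursor
            cassette_strand = strand
            cseq = cassette if strand == "+" else revcomp(cassette)
            genome_arr[cursor : cursor + len(cassette)] = np.frombuffer(
                cseq.encode("ascii"), dtype=np.uint8
            )
            cursor += len(cassette)
            continue
        if unit[0] == "gene":
            members = [unit[1]]
        else:
            group_counter += 1
            # downstream (trans-spliced) member sits 3' in transcription:
            # genomically right on '+', left on '-'
            members = [unit[1], unit[2]] if strand == "+" else [unit[2], unit[1]]
        for mi, gi in enumerate(members):
            if mi:
                cursor += intra_gaps[idx]
            layout = gene_layouts[gi]
            exons: list[tuple[int, int]] = []
            pos = cursor
            for j, el in enumerate(layout["exon_lens"]):
                exons.append((pos, pos + el))
                pos += el
                if j < len(layout["intron_lens"]):
                    pos += layout["intron_lens"][j]
            placed.append(
                {
                    "orig": gi,
                    "exons": tuple(exons),
                    "strand": strand,
                    "ts": ts_flags[gi],
                    "group": group_counter if unit[0] == "pair" else None,
                }
            )
            cursor += layout["genomic"]

    if cassette_pos is None:  # pragma: no cover - cassette always placed
        raise PlacementError("internal error: SL cassette not placed")

    # force the transcript's two 3'-terminal bases non-A so that polyA-tail
    # trimming never eats genomic sequence
    a_code, t_code = ord("A"), ord("T")
    for g in placed:
        s, e = g["exons"][0][0], g["exons"][-1][1]
        if g["strand"] == "+":
            for p in (e - 2, e - 1):
                if genome_arr[p] == a_code:
                    genome_arr[p] = _BASES[int(rng.integers(1, 4))]  # C/G/T
        else:
            for p in (s, s + 1):
                if genome_arr[p] == t_code:
                    genome_arr[p] = _BASES[int(rng.integers(0, 3))]  # A/C/G

    genome_str = _arr_to_str(genome_arr)
    genome = GenomeSequence([(contig, genome_str)])

    if cassette_strand == "+":
        sl_locus = (contig, cassette_pos, cassette_pos + len(sl), "+")
    else:
        end = cassette_pos + len(cassette)
        sl_locus = (contig, end - len(sl), end, "-")

    # --- gene truth, transcripts -------------------------------------------
    placed.sort(key=lambda g: g["exons"][0][0])
    genes: list[GeneTruth] = []
    for i, g in enumerate(placed):
        s, e = g["exons"][0][0], g["exons"][-1][1]
        genes.append(
            GeneTruth(
                id=f"G{i + 1:05d}",
                contig=contig,
                strand=g["strand"],
                exons=g["exons"],
                trans_spliced=g["ts"],
                group=g["group"],
                acceptor_site=(s if g["strand"] == "+" else e - 1)
                if g["ts"]
                else None,
                polya_site=e - 1 if g["strand"] == "+" else s,
            )
        )

    lo, hi = config.sl_prefix_length_range
    hi = min(hi, len(sl))
    lo = min(lo, hi)
    ts_ids = [g.id for g in genes if g.trans_spliced]
    full_length_carriers = set(ts_ids[:2])

    transcripts: list[SeqRead] = []
    transcript_truth: list[TranscriptTruth] = []
    transcript_alignments: list[AlignmentRecord] = []
    bodies: dict[str, str] = {}
    frags: dict[str, int] = {}
    for i, gene in enumerate(genes):
        body = "".join(genome_str[s:e] for s, e in gene.exons)
        if gene.strand == "-":
            body = revcomp(body)
        tid = f"T{i + 1:05d}"
        if gene.trans_spliced:
            frag = (
                len(sl)
                if gene.id in full_length_carriers
                else int(rng.integers(lo, hi + 1))
            )
        else:
            frag = 0
        seq = sl[len(sl) - frag :] + body if frag else body
        bodies[tid] = body
        frags[tid] = frag
        transcripts.append(SeqRead(tid, seq))
        transcript_truth.append(
            TranscriptTruth(
                id=tid, gene_id=gene.id, sequence=seq, sl_fragment_length=frag
            )
        )
        transcript_alignments.append(
            _alignment_for(tid, gene, seq, 0, len(body), clip5=frag, clip3=0)
        )

    # --- RNA-seq reads ------------------------------------------------------
    reads: list[SeqRead] = []
    read_truth: list[ReadTruth] = []
    read_alignments: list[AlignmentRecord] = []
    n_tx = len(transcripts)
    base, rem = divmod(config.n_reads, n_tx)
    read_no = 0
    for i, tx in enumerate(transcripts):
        gene = genes[i]
        count = base + (1 if i < rem else 0)
        frag = frags[tx.name]
        n_junction = min(count, max(3, count // 3)) if frag else 0
        len_t = len(tx.sequence)
        for r in range(count):
            if r < n_junction:
                offset = 0
            elif frag:
                offset = int(
                    rng.integers(frag, len_t - config.read_length + 1)
                )
            else:
                offset = int(rng.integers(0, len_t - config.read_length + 1))
            read_no += 1
            name = f"r{read_no:06d}"
            seq = tx.sequence[offset : offset + config.read_length]
            seq = _apply_errors(seq, config.error_rate, rng)
            reads.append(SeqRead(name, seq, "I" * len(seq)))
            s_cov = max(0, frag - offset)
            read_truth.append(
                ReadTruth(
                    id=name,
                    transcript_id=tx.name,
                    offset=offset,
                    sl_fragment_length=s_cov,
                    polya_length=0,
                    tag=False,
                )
            )
            b0 = max(offset, frag) - frag
            b1 = offset + config.read_length - frag
            read_alignments.append(
                _alignment_for(name, gene, seq, b0, b1, clip5=s_cov, clip3=0)
            )

    # --- 3'-tag reads -------------------------------------------------------
    tag_reads: list[SeqRead] = []
    tag_alignments: list[AlignmentRecord] = []
    alo, ahi = config.polya_length_range
    base_t, rem_t = divmod(config.n_tag_reads, n_tx)
    tag_no = 0
    for i, tx in enumerate(transcripts):
        gene = genes[i]
        body = bodies[tx.name]
        count = base_t + (1 if i < rem_t else 0)
        for _ in range(count):
            a = int(rng.integers(alo, ahi + 1))
            k = config.read_length - a
            tag_no += 1
            name = f"p{tag_no:06d}"
            seq = body[len(body) - k :] + "A" * a
            seq = _apply_errors(seq, config.error_rate, rng)
            tag_reads.append(SeqRead(name, seq, "I" * len(seq)))
            read_truth.append(
                ReadTruth(
                    id=name,
                    transcript_id=tx.name,
                    offset=len(body) - k + frags[tx.name],
                    sl_fragment_length=0,
                    polya_length=a,
                    tag=True,
                )
            )
            tag_alignments.append(
                _alignment_for(
                    name, gene, seq, len(body) - k, len(body), clip5=0, clip3=a
                )
            )

    # --- initial (unrefined) gene models ------------------------------------
    initial_models: list[TranscriptModel] = []
    by_group: dict[int | None, list[GeneTruth]] = {}
    for gene in genes:
        if gene.group is None:
            initial_models.append(
                TranscriptModel(
                    id="",
                    contig=contig,
                    strand=gene.strand,
                    exons=gene.exons,
                )
            )
        else:
            by_group.setdefault(gene.group, []).append(gene)
    for group in sorted(by_group):
        members = sorted(by_group[group], key=lambda g: g.start)
        exons = tuple(x for g in members for x in g.exons)
        initial_models.append(
            TranscriptModel(
                id="",
                contig=contig,
                strand=members[0].strand,
                exons=exons,
            )
        )
    initial_models.sort(key=lambda m: (m.contig, m.start))
    initial_models = [
        TranscriptModel(
            id=f"M{i + 1:05d}",
            contig=m.contig,
            strand=m.strand,
            exons=m.exons,
        )
        for i, m in enumerate(initial_models)
    ]

    manifest = TruthManifest(
        sl_sequence=sl,
        sl_rna_locus=sl_locus,
        genes=tuple(genes),
        transcripts=tuple(transcript_truth),
        reads=tuple(read_truth),
    )
    return SimResult(
        config=config,
        genome=genome,
        manifest=manifest,
        transcripts=transcripts,
        reads=reads,
        tag_reads=tag_reads,
        transcript_alignments=transcript_alignments,
        read_alignments=read_alignments,
        tag_alignments=tag_alignments,
        initial_models=initial_models,
    )


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for pos in hits:
        choices = [b for b in _BASES if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(0, len(choices)))]
    return _arr_to_str(arr)


# ---------------------------------------------------------------------------
# mitochondrial contig simulation


def simulate_mito_contig(
    circle_length: int, repeat_length: int, seed: int = 0
) -> tuple[str, str]:
    """Linearize a random circular genome with a terminal repeat.

    Returns (contig, circle) where contig = circle + circle[:repeat_length].
    The circle is resampled until the planted terminal repeat is the
    largest one on the contig, so circularization inverts this operation
    exactly.
    """
    if repeat_length <= 0:
        raise ValueError("repeat_length must be positive")
    if repeat_length >= circle_length:
        raise ValueError(
            f"repeat_length {repeat_length} must be smaller than "
            f"circle_length {circle_length}"
        )
    rng = np.random.default_rng(seed)
    for _ in range(100):
        arr = _random_bases(rng, circle_length)
        if arr[-1] == arr[0]:  # break the dominant accidental extension
            others = [b for b in _BASES if b != arr[0]]
            arr[-1] = others[int(rng.integers(0, len(others)))]
        circle = _arr_to_str(arr)
        contig = circle + circle[:repeat_length]
        if largest_terminal_repeat(contig) == repeat_length:
            return contig, circle
    raise RuntimeError(
        "could not generate a contig whose largest terminal repeat is the "
        "planted one"
    )  # pragma: no cover


# ---------------------------------------------------------------------------
# on-disk representation


def write_dataset(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write every component of a simulated dataset to `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = result.genome.lengths()
    paths = {
        "genome": outdir / "genome.fa",
        "transcripts": outdir / "transcripts.fa",
        "reads": outdir / "reads.fastq",
        "tag_reads": outdir / "tag_reads.fastq",
        "transcript_alignments": outdir / "transcripts.sam",
        "read_alignments": outdir / "reads.sam",
        "tag_alignments": outdir / "tag_reads.sam",
        "truth_genes": outdir / "truth_genes.gff3",
        "initial_models": outdir / "initial_models.gff3",
        "manifest_json": outdir / "manifest.json",
        "genes_tsv": outdir / "genes.tsv",
        "reads_tsv": outdir / "reads.tsv",
    }
    result.genome.to_fasta(paths["genome"])
    write_fasta(
        ((t.name, t.sequence) for t in result.transcripts), paths["transcripts"]
    )
    write_fastq(result.reads, paths["reads"])
    write_fastq(result.tag_reads, paths["tag_reads"])
    write_alignments(
        result.transcript_alignments, paths["transcript_alignments"], refs
    )
    write_alignments(result.read_alignments, paths["read_alignments"], refs)
    write_alignments(result.tag_alignments, paths["tag_alignments"], refs)
    write_features(result.manifest.genes, paths["truth_genes"])
    write_features(result.initial_models, paths["initial_models"])

    m = result.manifest
    manifest_dict = {
        "sl_sequence": m.sl_sequence,
        "sl_rna_locus": list(m.sl_rna_locus),
        "genes": [
            {
                "id": g.id,
                "contig": g.contig,
                "strand": g.strand,
                "exons": [list(x) for x in g.exons],
                "trans_spliced": g.trans_spliced,
                "group": g.group,
                "acceptor_site": g.acceptor_site,
                "polya_site": g.polya_site,
            }
            for g in m.genes
        ],
        "transcripts": [
            {
                "id": t.id,
                "gene_id": t.gene_id,
                "sl_fragment_length": t.sl_fragment_length,
            }
            for t in m.transcripts
        ],
        "reads": [
            {
                "id": r.id,
                "transcript_id": r.transcript_id,
                "offset": r.offset,
                "sl_fragment_length": r.sl_fragment_length,
                "polya_length": r.polya_length,
                "tag": r.tag,
            }
            for r in m.reads
        ],
    }
    with open(paths["manifest_json"], "w") as fh:
        json.dump(manifest_dict, fh, indent=1)
        fh.write("\n")
    with open(paths["genes_tsv"], "w") as fh:
        fh.write(
            "id\tcontig\tstrand\tstart\tend\ttrans_spliced\tgroup\t"
            "acceptor_site\tpolya_site\n"
        )
        for g in m.genes:
            fh.write(
                f"{g.id}\t{g.contig}\t{g.strand}\t{g.start}\t{g.end}\t"
                f"{int(g.trans_spliced)}\t{g.group if g.group else ''}\t"
                f"{g.acceptor_site if g.acceptor_site is not None else ''}\t"
                f"{g.polya_site}\n"
            )
    with open(paths["reads_tsv"], "w") as fh:
        fh.write("id\ttranscript_id\toffset\tsl_fragment_length\tpolya_length\ttag\n")
        for r in m.reads:
            fh.write(
                f"{r.id}\t{r.transcript_id}\t{r.offset}\t"
                f"{r.sl_fragment_length}\t{r.polya_length}\t{int(r.tag)}\n"
            )
    return paths
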