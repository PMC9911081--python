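"""Gene-model merging, boundary refinement and polycistron splitting.

Transcript models from one or more sources are clustered into loci by
exon overlap; trans-splice acceptor (SL) peaks and polyadenylation peaks
then refine locus boundaries and split run-through/polycistronic loci into
separate trans-spliced genes.  A simplified longest-ORF scan classifies
genes as coding or noncoding — it is a stand-in for a dedicated ORF
predictor and is labelled as such in output headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .io_formats import GenomeSequence, TranscriptModel, revcomp
from .peaks import Peak
from .util import percent

logger = logging.getLogger(__name__)

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class GeneModel:
    """A refined, stranded exon-chain gene with SL/polyA annotations."""

    id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    sl_trans_spliced: bool = False
    sl_peak: int | None = None  # summit position
    polya_peak: int | None = None
    coding: bool | None = None
    orf: tuple[int, int] | None = None  # transcript coordinates
    source_locus: str | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class Locus:
    """A cluster of exon-overlapping transcript models on one strand."""

    id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # union exon structure
    members: tuple[str, ...]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class AnnotationSummary:
    """Headline annotation counts and means.

    Invariants: n_genes = n_coding + n_noncoding;
    sl_fraction = 100 * n_sl_trans_spliced / n_genes (1 decimal).
    """

    n_genes: int
    n_coding: int
    n_noncoding: int
    n_sl_trans_spliced: int
    sl_fraction: float
    mean_transcript_length: float | None = None
    mean_gene_span: float | None = None
    mean_intron_count: float | None = None
    mean_intron_length: float | None = None

    @classmethod
    def from_counts(
        cls, n_coding: int, n_noncoding: int, n_sl_trans_spliced: int
    ) -> "AnnotationSummary":
        """Summary arithmetic from externally obtained counts."""
        n_genes = n_coding + n_noncoding
        if n_genes <= 0:
            raise ValueError("empty gene set")
        return cls(
            n_genes=n_genes,
            n_coding=n_coding,
            n_noncoding=n_noncoding,
            n_sl_trans_spliced=n_sl_trans_spliced,
            sl_fraction=percent(n_sl_trans_spliced, n_genes, 1),
        )


# ---------------------------------------------------------------------------
# merging


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def merge_models(
    *model_sets: Sequence[TranscriptModel],
    genome: GenomeSequence | None = None,
) -> list[Locus]:
    """Cluster transcripts into loci by transitive exon overlap.

    Transcripts on the same contig and strand whose exons overlap by at
    least 1 bp are clustered transitively; each locus carries the union
    exon structure and its member transcript ids.  Locus ids are assigned
    deterministically by (contig, start, strand).
    """
    models: list[TranscriptModel] = [m for ms in model_sets for m in ms]
    if genome is not None:
        lengths = genome.lengths()
        for m in models:
            if m.contig not in lengths:
                raise ValueError(f"model {m.id!r} on unknown contig {m.contig!r}")
            if m.end > lengths[m.contig]:
                raise ValueError(
                    f"model {m.id!r} exon beyond contig length "
                    f"({m.end} > {lengths[m.contig]})"
                )
    uf = _UnionFind(len(models))
    by_key: dict[tuple[str, str], list[int]] = {}
    for i, m in enumerate(models):
        by_key.setdefault((m.contig, m.strand), []).append(i)
    for indices in by_key.values():
        exon_events = sorted(
            (s, e, i) for i in indices for s, e in models[i].exons
        )
        active_end = -1
        rep = -1
        for s, e, i in exon_events:
            if s < active_end:
                uf.union(rep, i)
            else:
                rep = i
            active_end = max(active_end, e)
            rep = uf.find(rep)
    clusters: dict[int, list[int]] = {}
    for i in range(len(models)):
        clusters.setdefault(uf.find(i), []).append(i)
    loci: list[Locus] = []
    for members in clusters.values():
        contig = models[members[0]].contig
        strand = models[members[0]].strand
        exons = _merge_intervals(
            (s, e) for i in members for s, e in models[i].exons
        )
        loci.append(
            Locus(
                id="",
                contig=contig,
                strand=strand,
                exons=exons,
                members=tuple(sorted(models[i].id for i in members)),
            )
        )
    loci.sort(key=lambda l: (l.contig, l.start, l.strand))
    return [
        replace(locus, id=f"LOC{i + 1:05d}") for i, locus in enumerate(loci)
    ]


# ---------------------------------------------------------------------------
# refinement and splitting


def _clip_exons(
    exons: Sequence[tuple[int, int]], start: int, end: int
) -> tuple[tuple[int, int], ...]:
    out = []
    for s, e in exons:
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            out.append((lo, hi))
    return tuple(out)


def _nearest(candidates: list[int], anchor: int) -> int:
    return min(candidates, key=lambda x: (abs(x - anchor), x))


def _segments_plus(
    locus: Locus,
    sl_summits: list[int],
    pa_summits: list[int],
    promote_window: int,
    min_internal_offset: int,
    min_gene_len: int,
) -> list[tuple[int, int]]:
    L, R = locus.start, locus.end
    near5 = [s for s in sl_summits if L - promote_window <= s <= L + promote_window]
    start5 = _nearest(near5, L) if near5 else L
    near3 = [p for p in pa_summits if abs((p + 1) - R) <= promote_window]
    end3 = (_nearest(near3, R - 1) + 1) if near3 else R
    internal = [s for s in sl_summits if L + min_internal_offset <= s < end3]
    segments: list[tuple[int, int]] = []
    cur = start5
    for s in sorted(internal):
        upstream_pa = [p for p in pa_summits if cur <= p < s]
        up_end = (max(upstream_pa) + 1) if upstream_pa else s
        if up_end - cur < min_gene_len or end3 - s < min_gene_len:
            logger.info(
                "locus %s: skipping split at %d (would create a gene "
                "shorter than %d bp)", locus.id, s, min_gene_len,
            )
            continue
        segments.append((cur, up_end))
        cur = s
    segments.append((cur, end3))
    return segments


def _segments_minus(
    locus: Locus,
    sl_summits: list[int],
    pa_summits: list[int],
    promote_window: int,
    min_internal_offset: int,
    min_gene_len: int,
) -> list[tuple[int, int]]:
    # mirror image: the 5' end is at R-1, transcription runs right-to-left
    L, R = locus.start, locus.end
    near5 = [s for s in sl_summits if abs(s - (R - 1)) <= promote_window]
    end5 = (_nearest(near5, R - 1) + 1) if near5 else R
    near3 = [p for p in pa_summits if abs(p - L) <= promote_window]
    start3 = _nearest(near3, L) if near3 else L
    internal = [
        s for s in sl_summits if start3 < s <= R - 1 - min_internal_offset
    ]
    segments: list[tuple[int, int]] = []
    cur_end = end5
    for s in sorted(internal, reverse=True):
        upstream_pa = [p for p in pa_summits if s < p < cur_end]
        up_start = min(upstream_pa) if upstream_pa else s + 1
        if cur_end - up_start < min_gene_len or (s + 1) - start3 < min_gene_len:
            logger.info(
                "locus %s: skipping split at %d (would create a gene "
                "shorter than %d bp)", locus.id, s, min_gene_len,
            )
            continue
        segments.append((up_start, cur_end))
        cur_end = s + 1
    segments.append((start3, cur_end))
    segments.reverse()
    return segments


def refine_and_split(
    loci: Sequence[Locus],
    sl_peaks: Sequence[Peak],
    polya_peaks: Sequence[Peak],
    promote_window: int = 50,
    min_internal_offset: int = 200,
    min_gene_len: int = 50,
) -> list[GeneModel]:
    """Refine locus boundaries with peaks and split polycistronic loci.

    (a) an SL summit within ``promote_window`` of a locus 5' end retargets
    the 5' boundary to the summit; (b) an SL summit at least
    ``min_internal_offset`` inside a locus splits it there — the upstream
    gene ends at the nearest upstream polyA summit within the locus (or
    just before the SL summit), the downstream gene starts at the summit;
    multiple internal summits split iteratively 5'->3'; (c) a polyA summit
    within ``promote_window`` of the locus 3' end retargets the 3'
    boundary; (d) every gene whose final 5' boundary coincides with an SL
    summit is flagged trans-spliced.  Splits that would create a gene
    shorter than ``min_gene_len`` are skipped and logged.
    """
    sl_by_key: dict[tuple[str, str], list[int]] = {}
    for p in sl_peaks:
        sl_by_key.setdefault((p.contig, p.strand), []).append(p.summit)
    pa_by_key: dict[tuple[str, str], list[int]] = {}
    for p in polya_peaks:
        pa_by_key.setdefault((p.contig, p.strand), []).append(p.summit)

    genes: list[GeneModel] = []
    for locus in loci:
        key = (locus.contig, locus.strand)
        sl_summits = sorted(sl_by_key.get(key, []))
        pa_summits = sorted(pa_by_key.get(key, []))
        if locus.strand == "+":
            segments = _segments_plus(
                locus, sl_summits, pa_summits,
                promote_window, min_internal_offset, min_gene_len,
            )
        else:
            segments = _segments_minus(
                locus, sl_summits, pa_summits,
                promote_window, min_internal_offset, min_gene_len,
            )
        sl_set = set(sl_summits)
        pa_set = set(pa_summits)
        for a, b in segments:
            exons = _clip_exons(locus.exons, a, b)
            if not exons:
                logger.warning(
                    "locus %s: segment [%d,%d) contains no exonic sequence",
                    locus.id, a, b,
                )
                continue
            if locus.strand == "+":
                five = exons[0][0]
                three = exons[-1][1] - 1
            else:
                five = exons[-1][1] - 1
                three = exons[0][0]
            is_sl = five in sl_set
            genes.append(
                GeneModel(
                    id="",
                    contig=locus.contig,
                    strand=locus.strand,
                    exons=exons,
                    sl_trans_spliced=is_sl,
                    sl_peak=five if is_sl else None,
                    polya_peak=three if three in pa_set else None,
                    source_locus=locus.id,
                )
            )
    genes.sort(key=lambda g: (g.contig, g.start, g.strand))
    for i, g in enumerate(genes):
        g.id = f"G{i + 1:05d}"
    return genes


# ---------------------------------------------------------------------------
# coding classification (simplified longest-ORF stand-in)


def longest_orf(seq: str, min_aa: int = 100) -> tuple[int, int] | None:
    """Longest ATG..stop span across the 3 forward frames, or None.

    The returned interval (0-based half-open, transcript coordinates)
    includes the stop codon; the peptide (ATG included, stop excluded)
    must be at least ``min_aa`` codons.  Ties go to the leftmost start.
    This is a deliberately simple longest-ORF scan, not a full ORF
    predictor: no reverse-strand ORFs, no incomplete (stopless) ORFs.
    """
    seq = seq.upper()
    best: tuple[int, int] | None = None
    for frame in range(3):
        open_start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if open_start is not None:
                    cand = (open_start, i + 3)
                    if _better_orf(cand, best):
                        best = cand
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
    if best is None:
        return None
    aa = (best[1] - best[0]) // 3 - 1
    return best if aa >= min_aa else None


def _better_orf(
    cand: tuple[int, int], best: tuple[int, int] | None
) -> bool:
    if best is None:
        return True
    cl, bl = cand[1] - cand[0], best[1] - best[0]
    return (cl, -cand[0]) > (bl, -best[0])


def spliced_sequence(genome: GenomeSequence, gene: GeneModel) -> str:
    """The gene's transcript sequence (exons joined, sense orientation)."""
    seq = "".join(genome.fetch(gene.contig, s, e) for s, e in gene.exons)
    return revcomp(seq) if gene.strand == "-" else seq


def classify_coding(
    genes: Iterable[GeneModel],
    genome: GenomeSequence,
    min_aa: int = 100,
) -> None:
    """Set each gene's coding flag from the longest-ORF scan (in place)."""
    for gene in genes:
        orf = longest_orf(spliced_sequence(genome, gene), min_aa=min_aa)
        gene.orf = orf
        gene.coding = orf is not None


# ---------------------------------------------------------------------------
# summary


def summarize(genes: Sequence[GeneModel]) -> AnnotationSummary:
    """Counts and means over a classified gene set (fractions to 1 dp)."""
    if not genes:
        raise ValueError("summarize: empty gene set")
    n = len(genes)
    n_coding = sum(1 for g in genes if g.coding)
    n_sl = sum(1 for g in genes if g.sl_trans_spliced)
    intron_lengths = [
        genes_exons[i + 1][0] - genes_exons[i][1]
        for g in genes
        for genes_exons in [g.exons]
        for i in range(len(genes_exons) - 1)
    ]
    return AnnotationSummary(
        n_genes=n,
        n_coding=n_coding,
        n_noncoding=n - n_coding,
        n_sl_trans_spliced=n_sl,
        sl_fraction=percent(n_sl, n, 1),
        mean_transcript_length=sum(g.transcript_length for g in genes) / n,
        mean_gene_span=sum(g.span for g in genes) / n,
        mean_intron_count=sum(len(g.exons) - 1 for g in genes) / n,
        mean_intron_length=(
            sum(intron_lengths) / len(intron_lengths) if intron_lengths else 0.0
        ),
    )
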