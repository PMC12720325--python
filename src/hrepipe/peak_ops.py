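"""Peak filtering, merging, set overlap, genomic-category annotation,
nearest-TSS assignment, and promoter-HRE gene selection."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .core_io import GeneModel, GenomicInterval, Peak
from .motif_scan import Motif, MotifHit, scan_motif

__all__ = [
    "PeakFilterConfig",
    "PromoterWindowConfig",
    "GenomicCategory",
    "MergedPeak",
    "filter_definitive_peaks",
    "merge_peaks",
    "count_set_overlap",
    "promoter_window",
    "classify_genomic_category",
    "assign_peak_to_nearest_gene",
    "select_promoter_hre_bound_genes",
    "genomic_distribution_summary",
]


@dataclass(frozen=True)
class PeakFilterConfig:
    """Definitive-peak score cutoff; kept peaks must score strictly above it."""

    min_score_exclusive: float = 20.0

    def __post_init__(self) -> None:
        if self.min_score_exclusive < 0:
            raise ValueError("min_score_exclusive must be >= 0")


@dataclass(frozen=True)
class PromoterWindowConfig:
    """Promoter window extent around the TSS, in transcription orientation."""

    upstream_bp: int = 1500
    downstream_bp: int = 500

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window extents must be >= 0")
        if self.upstream_bp + self.downstream_bp <= 0:
            raise ValueError("promoter window must be non-empty")

    @property
    def length(self) -> int:
        return self.upstream_bp + self.downstream_bp


class GenomicCategory(str, Enum):
    PROMOTER = "promoter"
    EXON = "exon"
    INTRON_OR_INTERGENIC = "intron_or_intergenic"


def filter_definitive_peaks(
    peaks: Sequence[Peak], config: PeakFilterConfig = PeakFilterConfig()
) -> list[Peak]:
    """Keep peaks with score strictly greater than the threshold, preserving order."""
    return [p for p in peaks if p.score > config.min_score_exclusive]


@dataclass(frozen=True)
class MergedPeak:
    """Union interval absorbing >= 1 overlapping input peaks, with provenance."""

    interval: GenomicInterval
    sources: frozenset[int]
    n_peaks: int


def merge_peaks(*peak_sets: Sequence[Peak]) -> list[MergedPeak]:
    """Merge peaks that share >= 1 bp of overlap (transitively) into unions.

    Book-ended intervals (end == start) are NOT merged. Each merged
    interval records the indices of the input sets it absorbed.
    """
    events: list[tuple[str, int, int, int]] = []  # chrom, start, end, set_id
    for set_id, peaks in enumerate(peak_sets):
        for p in peaks:
            iv = p.interval
            events.append((iv.chrom, iv.start, iv.end, set_id))
    events.sort()
    merged: list[MergedPeak] = []
    cur: tuple[str, int, int, set[int], int] | None = None
    for chrom, start, end, set_id in events:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur = (chrom, cur[1], max(cur[2], end), cur[3] | {set_id}, cur[4] + 1)
        else:
            if cur is not None:
                merged.append(
                    MergedPeak(
                        GenomicInterval(cur[0], cur[1], cur[2]),
                        frozenset(cur[3]),
                        cur[4],
                    )
                )
            cur = (chrom, start, end, {set_id}, 1)
    if cur is not None:
        merged.append(
            MergedPeak(GenomicInterval(cur[0], cur[1], cur[2]), frozenset(cur[3]), cur[4])
        )
    return merged


def count_set_overlap(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> tuple[int, int, int]:
    """Venn counts over merged intervals: (a_only, b_only, shared)."""
    merged = merge_peaks(peaks_a, peaks_b)
    a_only = sum(1 for m in merged if m.sources == frozenset({0}))
    b_only = sum(1 for m in merged if m.sources == frozenset({1}))
    shared = sum(1 for m in merged if m.sources == frozenset({0, 1}))
    return a_only, b_only, shared


def promoter_window(
    gene: GeneModel,
    config: PromoterWindowConfig = PromoterWindowConfig(),
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at chromosome bounds.

    On the + strand the window is [tss - upstream, tss + downstream); on
    the - strand it is the mirror image about the TSS base, so it covers
    the same extent in transcription orientation (TSS base included).
    """
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - config.upstream_bp, tss + config.downstream_bp
    else:
        start = tss - config.downstream_bp + 1
        end = tss + config.upstream_bp + 1
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def classify_genomic_category(
    peak: Peak,
    genes: Sequence[GeneModel],
    window_config: PromoterWindowConfig = PromoterWindowConfig(),
) -> GenomicCategory:
    """Categorize a peak by its midpoint with priority promoter > exon > rest."""
    mid = peak.midpoint
    chrom = peak.interval.chrom
    for gene in genes:
        if gene.chrom != chrom:
            continue
        if promoter_window(gene, window_config).contains(chrom, mid):
            return GenomicCategory.PROMOTER
    for gene in genes:
        if gene.chrom != chrom:
            continue
        for exon in gene.exons:
            if exon.contains(chrom, mid):
                return GenomicCategory.EXON
    return GenomicCategory.INTRON_OR_INTERGENIC


def assign_peak_to_nearest_gene(
    peak: Peak, genes: Sequence[GeneModel]
) -> tuple[str, int]:
    """Assign the peak to the gene with the nearest TSS.

    Returns ``(gene_id, signed_distance)`` where the distance is midpoint
    minus TSS with the sign flipped on - strand genes, so positive always
    means downstream of the TSS in transcription orientation. Ties on
    absolute distance go to the lexicographically smallest gene_id.
    """
    if not genes:
        raise ValueError("no genes to assign to")
    mid = peak.midpoint
    chrom = peak.interval.chrom
    candidates = [g for g in genes if g.chrom == chrom]
    if not candidates:
        raise ValueError(f"no genes on chromosome {chrom}")
    best: tuple[int, str, int] | None = None
    for gene in candidates:
        delta = mid - gene.tss
        signed = delta if gene.strand == "+" else -delta
        key = (abs(signed), gene.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (abs(signed), gene.gene_id, signed)
    return best[1], best[2]


def select_promoter_hre_bound_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_sequences: Mapping[str, str],
    motif: Motif,
    window_config: PromoterWindowConfig = PromoterWindowConfig(),
    both_strands: bool = True,
) -> list[str]:
    """Genes whose promoter window holds a motif hit overlapped by a peak.

    A gene is selected iff some peak interval intersects some motif hit
    lying inside the gene's promoter window (three-way intersection at the
    hit level). ``peaks`` are assumed already score-filtered;
    ``promoter_sequences`` maps gene_id to the + strand sequence of the
    promoter window and must match the window length exactly.
    """
    peaks_by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.interval.chrom, []).append(p)

    selected: set[str] = set()
    for gene in genes:
        if gene.gene_id not in promoter_sequences:
            continue
        window = promoter_window(gene, window_config)
        seq = promoter_sequences[gene.gene_id]
        if len(seq) != window.length:
            raise ValueError(
                f"promoter sequence for {gene.gene_id} has length {len(seq)}, "
                f"window is {window.length} bp"
            )
        gene_peaks = peaks_by_chrom.get(gene.chrom, [])
        if not gene_peaks:
            continue
        for hit in scan_motif(seq, motif, both_strands, seq_name=gene.gene_id):
            hit_iv = GenomicInterval(
                gene.chrom, window.start + hit.start, window.start + hit.end
            )
            if any(p.interval.overlaps(hit_iv) for p in gene_peaks):
                selected.add(gene.gene_id)
                break
    return sorted(selected)


def genomic_distribution_summary(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window_config: PromoterWindowConfig = PromoterWindowConfig(),
) -> dict[GenomicCategory, float]:
    """Fraction of peaks per genomic category; fractions sum to 1."""
    if not peaks:
        raise ValueError("no peaks")
    counts = {cat: 0 for cat in GenomicCategory}
    for p in peaks:
        counts[classify_genomic_category(p, genes, window_config)] += 1
    total = len(peaks)
    return {cat: counts[cat] / total for cat in GenomicCategory}
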