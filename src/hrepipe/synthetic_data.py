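"""Synthetic benchmark generator: toy gene models, promoter sequences with
planted RCGTG motifs, condition/timepoint-structured peak sets, and WT/KO
expression time courses with planted responsive / unresponsive gene groups.

Everything is a pure function of (config, seed): per-stage RNG streams are
derived from the global seed, so repeated calls are byte-identical.

The ground-truth contract used by downstream oracle tests: a gene is
selectable by the promoter-HRE criterion iff bound AND has_hre. To make
that exact, the peak-footprint region of every bound gene's promoter is
scrubbed of chance motif occurrences before (optionally) planting exactly
one; chance occurrences elsewhere in the window are left alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    Condition,
    ExpressionMatrix,
    GeneModel,
    Genotype,
    GenomicInterval,
    Peak,
    SampleMeta,
    Scale,
    write_bed,
    write_fasta,
    write_gff3_genes,
    write_sample_metadata,
    write_tsv_matrix,
)
from .expression import GeneClass
from .motif_scan import HRE_MOTIF, Motif, reverse_complement, scan_motif
from .peak_ops import PromoterWindowConfig, promoter_window

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_genome",
    "simulate_peaks",
    "simulate_expression",
    "simulate_counts",
    "simulate_dataset",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 100
    chrom_length: int = 1_000_000
    n_chroms: int = 2
    frac_bound: float = 0.5
    frac_hre: float = 0.8  # of bound genes
    frac_responsive: float = 0.5  # of bound+HRE genes
    effect_log2fc: float = 2.0
    noise_sd: float = 0.25
    gc_content: float = 0.5
    bound_score_mean: float = 100.0
    bound_score_sd: float = 10.0
    decoy_score_mean: float = 10.0
    decoy_score_sd: float = 3.0
    n_decoy_peaks: int = 20
    n_replicates: int = 2
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    gene_body_bp: int = 2000
    gene_spacing_bp: int = 2000
    peak_halfwidth_bp: int = 100
    # HIF-independent induction of bound+HRE-but-unresponsive genes (both
    # genotypes); None means "same magnitude as effect_log2fc".
    shared_induction_log2fc: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_bound", "frac_hre", "frac_responsive", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_genes < 1 or self.n_chroms < 1:
            raise ValueError("n_genes and n_chroms must be >= 1")
        per_chrom = -(-self.n_genes // self.n_chroms)
        footprint = 1500 + self.gene_body_bp + 1500 + self.gene_spacing_bp
        if 2000 + per_chrom * footprint > self.chrom_length:
            raise ValueError(
                f"{self.n_genes} genes do not fit: need "
                f"{2000 + per_chrom * footprint} bp per chromosome, have "
                f"{self.chrom_length}"
            )

    @property
    def resolved_shared_induction(self) -> float:
        if self.shared_induction_log2fc is None:
            return self.effect_log2fc
        return self.shared_induction_log2fc


@dataclass
class GroundTruth:
    """Per-gene planted labels; responsive implies bound and has_hre."""

    gene_ids: list[str]
    bound: dict[str, bool]
    has_hre: dict[str, bool]
    responsive: dict[str, bool]
    cluster: dict[str, int]

    def __post_init__(self) -> None:
        for g in self.gene_ids:
            if self.responsive[g] and not (self.bound[g] and self.has_hre[g]):
                raise ValueError(f"gene {g}: responsive requires bound and has_hre")

    def selectable(self, gene_id: str) -> bool:
        """True iff the promoter-HRE selection should pick this gene."""
        return self.bound[gene_id] and self.has_hre[gene_id]

    def expected_class(self, gene_id: str) -> GeneClass:
        if not self.selectable(gene_id):
            return GeneClass.UNBOUND
        if self.responsive[gene_id]:
            return GeneClass.RESPONSIVE
        return GeneClass.UNRESPONSIVE

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "bound": [int(self.bound[g]) for g in self.gene_ids],
                "has_hre": [int(self.has_hre[g]) for g in self.gene_ids],
                "responsive": [int(self.responsive[g]) for g in self.gene_ids],
                "cluster": [self.cluster[g] for g in self.gene_ids],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GroundTruth":
        ids = [str(g) for g in df["gene_id"]]
        return cls(
            gene_ids=ids,
            bound=dict(zip(ids, df["bound"].astype(bool))),
            has_hre=dict(zip(ids, df["has_hre"].astype(bool))),
            responsive=dict(zip(ids, df["responsive"].astype(bool))),
            cluster=dict(zip(ids, df["cluster"].astype(int))),
        )


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _make_truth(config: SimulationConfig, gene_ids: list[str]) -> GroundTruth:
    rng = _stage_rng(config, 0)
    n = len(gene_ids)
    order = rng.permutation(n)
    n_bound = round(config.frac_bound * n)
    bound_idx = set(order[:n_bound].tolist())
    bound_list = [i for i in order[:n_bound]]
    n_hre = round(config.frac_hre * n_bound)
    hre_idx = set(bound_list[:n_hre])
    n_resp = round(config.frac_responsive * n_hre)
    resp_idx = set(bound_list[:n_resp])
    bound, has_hre, responsive, cluster = {}, {}, {}, {}
    for i, g in enumerate(gene_ids):
        bound[g] = i in bound_idx
        has_hre[g] = i in hre_idx
        responsive[g] = i in resp_idx
        if responsive[g]:
            cluster[g] = 1
        elif bound[g] and has_hre[g]:
            cluster[g] = 2
        else:
            cluster[g] = 0
    return GroundTruth(list(gene_ids), bound, has_hre, responsive, cluster)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(_BASES, size=n, p=probs)


def _peak_region_hits(
    window_seq: str, region_start: int, region_end: int, motif: Motif
) -> list:
    return [
        h
        for h in scan_motif(window_seq, motif, both_strands=True)
        if h.start < region_end and region_start < h.end
    ]


def simulate_genome(
    config: SimulationConfig,
    window_config: PromoterWindowConfig = PromoterWindowConfig(),
    motif: Motif = HRE_MOTIF,
) -> tuple[list[GeneModel], dict[str, str], GroundTruth]:
    """Lay out non-overlapping gene models and generate promoter sequences.

    Returns (gene models, {gene_id: promoter window sequence}, truth).
    Windows are i.i.d. at ``gc_content``; for bound genes the peak
    footprint is scrubbed of chance motif occurrences (rejection
    resampling, <= 100 tries) and, for has_hre genes, exactly one motif
    instance (R drawn from {A, G}, strand uniform) is planted inside it.
    """
    n_digits = len(str(config.n_genes))
    gene_ids = [f"gene{str(i + 1).zfill(n_digits)}" for i in range(config.n_genes)]
    truth = _make_truth(config, gene_ids)

    rng = _stage_rng(config, 1)
    footprint = 1500 + config.gene_body_bp + 1500 + config.gene_spacing_bp
    cursors = {f"chr{c + 1}": 2000 for c in range(config.n_chroms)}
    genes: list[GeneModel] = []
    for i, gene_id in enumerate(gene_ids):
        chrom = f"chr{(i % config.n_chroms) + 1}"
        body_start = cursors[chrom] + 1500
        body_end = body_start + config.gene_body_bp
        if body_end + 1500 > config.chrom_length:
            raise ValueError(f"gene {gene_id} does not fit on {chrom}")
        strand = "+" if rng.random() < 0.5 else "-"
        third = config.gene_body_bp // 3
        exons = (
            GenomicInterval(chrom, body_start, body_start + third, strand),
            GenomicInterval(chrom, body_end - third, body_end, strand),
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(chrom, body_start, body_end, strand),
                strand=strand,
                exons=exons,
            )
        )
        cursors[chrom] += footprint

    promoters: dict[str, str] = {}
    motif_len = len(motif)
    for gene in genes:
        window = promoter_window(gene, window_config)
        region_start = (gene.tss - config.peak_halfwidth_bp) - window.start
        region_end = (gene.tss + config.peak_halfwidth_bp) - window.start
        is_bound = truth.bound[gene.gene_id]
        plant = truth.has_hre[gene.gene_id]
        seq_arr = _random_bases(rng, window.length, config.gc_content)
        if is_bound:
            ok = False
            for attempt in range(100):
                seq = "".join(seq_arr)
                if not _peak_region_hits(seq, region_start, region_end, motif):
                    ok = True
                    break
                seq_arr = _random_bases(rng, window.length, config.gc_content)
            if not ok:
                logger.warning(
                    "could not scrub chance motifs from peak region of %s",
                    gene.gene_id,
                )
            if plant:
                planted = False
                for attempt in range(100):
                    candidate = seq_arr.copy()
                    pos = int(
                        rng.integers(region_start, region_end - motif_len + 1)
                    )
                    core = "ACGTG" if rng.random() < 0.5 else "GCGTG"
                    if rng.random() < 0.5:
                        core = reverse_complement(core)
                    candidate[pos : pos + motif_len] = list(core)
                    cand_seq = "".join(candidate)
                    hits = _peak_region_hits(cand_seq, region_start, region_end, motif)
                    if len(hits) == 1:
                        seq_arr = candidate
                        planted = True
                        break
                if not planted:
                    logger.warning(
                        "planting a single motif in %s failed after 100 tries; "
                        "keeping last attempt",
                        gene.gene_id,
                    )
                    seq_arr = candidate
        promoters[gene.gene_id] = "".join(seq_arr)
    return genes, promoters, truth


def _occupied_intervals(
    genes: Sequence[GeneModel], window_config: PromoterWindowConfig
) -> dict[str, list[tuple[int, int]]]:
    occ: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        w = promoter_window(g, window_config)
        lo = min(w.start, g.interval.start)
        hi = max(w.end, g.interval.end)
        occ.setdefault(g.chrom, []).append((lo, hi))
    for chrom in occ:
        occ[chrom].sort()
    return occ


def simulate_peaks(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
    window_config: PromoterWindowConfig = PromoterWindowConfig(),
) -> list[Peak]:
    """One promoter peak per bound gene plus sub-threshold intergenic decoys.

    Bound-gene peaks are centered on the TSS with scores drawn from the
    bound score distribution (floored at 0); decoys land in gene-free gaps
    with sub-threshold scores. KO genotype gets no true peaks.
    """
    rng = _stage_rng(config, 2)
    peaks: list[Peak] = []
    for gene in genes:
        if not truth.bound[gene.gene_id]:
            continue
        score = max(0.0, float(rng.normal(config.bound_score_mean, config.bound_score_sd)))
        iv = GenomicInterval(
            gene.chrom,
            gene.tss - config.peak_halfwidth_bp,
            gene.tss + config.peak_halfwidth_bp,
        )
        peaks.append(
            Peak(
                iv,
                score=score,
                name=f"{gene.gene_id}_peak",
                condition=Condition.LPS,
                timepoint_h=24.0,
                genotype=Genotype.WT,
            )
        )

    occ = _occupied_intervals(genes, window_config)
    chroms = sorted({g.chrom for g in genes})
    width = 2 * config.peak_halfwidth_bp
    min_gap = width + 201  # room for the decoy plus 100 bp margins
    gaps: list[tuple[str, int, int]] = []
    for chrom in chroms:
        prev = 0
        for lo, hi in occ.get(chrom, []):
            if lo - prev >= min_gap:
                gaps.append((chrom, prev, lo))
            prev = max(prev, hi)
        if config.chrom_length - prev >= min_gap:
            gaps.append((chrom, prev, config.chrom_length))
    for i in range(config.n_decoy_peaks):
        chrom, lo, hi = gaps[int(rng.integers(len(gaps)))]
        start = int(rng.integers(lo + 100, hi - 100 - width))
        score = max(0.0, float(rng.normal(config.decoy_score_mean, config.decoy_score_sd)))
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, start + width),
                score=score,
                name=f"decoy{i + 1}",
                condition=Condition.LPS,
                timepoint_h=24.0,
                genotype=Genotype.WT,
            )
        )
    return peaks


def _design(config: SimulationConfig) -> list[SampleMeta]:
    samples = []
    for gt in (Genotype.WT, Genotype.KO):
        for cond in (Condition.LPS, Condition.HYPOXIA):
            for tp in (0.0, 4.0, 24.0):
                for rep in range(1, config.n_replicates + 1):
                    samples.append(
                        SampleMeta(
                            sample_id=f"{gt.value}_{cond.value}_{int(tp)}h_r{rep}",
                            genotype=gt,
                            condition=cond,
                            timepoint_h=tp,
                            replicate=rep,
                        )
                    )
    return samples


def _induced(cond: Condition, tp: float) -> bool:
    # LPS effects peak at 24 h; hypoxia effects at 4 h
    return (cond is Condition.LPS and tp == 24.0) or (
        cond is Condition.HYPOXIA and tp == 4.0
    )


def simulate_expression(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """log2-TPM matrix over {WT,KO} x {LPS,hypoxia} x {0,4,24 h} x replicates.

    Responsive genes gain ``effect_log2fc`` in WT only at the induced
    timepoint of each condition; bound+HRE-but-unresponsive genes gain the
    shared (genotype-independent) induction; everything gets
    Normal(0, noise_sd) noise on the log2 scale.
    """
    rng = _stage_rng(config, 3)
    samples = _design(config)
    gene_ids = [g.gene_id for g in genes]
    n_g, n_s = len(gene_ids), len(samples)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_g)
    values = np.tile(baseline[:, None], (1, n_s))
    shared = config.resolved_shared_induction
    for j, s in enumerate(samples):
        if not _induced(s.condition, s.timepoint_h):
            continue
        for i, g in enumerate(gene_ids):
            if truth.responsive[g]:
                if s.genotype is Genotype.WT:
                    values[i, j] += config.effect_log2fc
            elif truth.bound[g] and truth.has_hre[g]:
                values[i, j] += shared
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, values.shape)
    return ExpressionMatrix(gene_ids, samples, values, Scale.LOG2TPM)


def simulate_counts(
    log2tpm: ExpressionMatrix,
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    depth: int = 2_000_000,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Poisson read counts consistent with a log2-TPM matrix.

    Exists to exercise the counts -> TPM transform; expected per-gene rates
    are proportional to TPM x gene length, scaled to the target depth.
    """
    rng = _stage_rng(config, 4)
    lengths = {g.gene_id: g.interval.length for g in genes}
    len_kb = np.array([lengths[g] / 1000.0 for g in log2tpm.gene_ids])
    tpm = np.exp2(log2tpm.values)
    rates = tpm * len_kb[:, None]
    lam = rates / rates.sum(axis=0, keepdims=True) * depth
    counts = rng.poisson(lam).astype(float)
    matrix = ExpressionMatrix(
        list(log2tpm.gene_ids), list(log2tpm.samples), counts, Scale.COUNTS
    )
    return matrix, lengths


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list[GeneModel]
    promoters: dict[str, str]
    truth: GroundTruth
    peaks: list[Peak]
    expression: ExpressionMatrix


def simulate_dataset(
    config: SimulationConfig,
    window_config: PromoterWindowConfig = PromoterWindowConfig(),
    motif: Motif = HRE_MOTIF,
) -> SyntheticDataset:
    """Generate every component of a benchmark dataset in one call."""
    genes, promoters, truth = simulate_genome(config, window_config, motif)
    peaks = simulate_peaks(genes, truth, config, window_config)
    expression = simulate_expression(genes, truth, config)
    return SyntheticDataset(config, genes, promoters, truth, peaks, expression)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all components as the plain-text formats core_io reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.gff3",
        "promoters": outdir / "promoters.fa",
        "peaks": outdir / "peaks.bed",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_gff3_genes(dataset.genes, paths["genes"])
    write_fasta(dataset.promoters, paths["promoters"])
    write_bed(dataset.peaks, paths["peaks"])
    write_tsv_matrix(dataset.expression, paths["expression"])
    write_sample_metadata(dataset.expression.samples, paths["samples"])
    dataset.truth.to_dataframe().to_csv(paths["truth"], sep="\t", index=False)
    return paths
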