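"""Shared domain types and readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open. BED is already 0-based
half-open; GFF3 (1-based inclusive) is converted at the I/O boundary and
converted back on write, so round-trips are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "Condition",
    "Genotype",
    "Scale",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "SampleMeta",
    "ExpressionMatrix",
    "read_bed",
    "write_bed",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_fasta",
    "write_fasta",
    "read_tsv_matrix",
    "write_tsv_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
]

_VALID_BASES = set("ACGTN")


class Condition(str, Enum):
    """Stimulus applied to a sample or associated with a peak set."""

    LPS = "LPS"
    HYPOXIA = "hypoxia"
    NONE = "none"


class Genotype(str, Enum):
    WT = "WT"
    KO = "KO"


class Scale(str, Enum):
    """Scale of the values stored in an :class:`ExpressionMatrix`."""

    COUNTS = "counts"
    TPM = "tpm"
    LOG2TPM = "log2tpm"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (book-ended is False)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A located, scored binding event with experimental metadata."""

    interval: GenomicInterval
    score: float = 0.0
    name: str = "."
    condition: Condition = Condition.NONE
    timepoint_h: float = 0.0
    genotype: Genotype = Genotype.WT

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")
        if self.timepoint_h < 0:
            raise ValueError("timepoint_h must be >= 0")

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, exon structure and a strand-aware TSS."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        for exon in self.exons:
            if exon.chrom != self.interval.chrom:
                raise ValueError(f"exon chrom mismatch for gene {self.gene_id}")
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(
                    f"exon {exon.start}-{exon.end} outside gene body of {self.gene_id}"
                )
        sorted_exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(sorted_exons, sorted_exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")

    @property
    def tss(self) -> int:
        """Transcription start site: leftmost base on +, rightmost on -."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    genotype: Genotype
    condition: Condition
    timepoint_h: float
    replicate: int = 1


@dataclass
class ExpressionMatrix:
    """A gene x sample value matrix with typed sample metadata.

    ``scale`` records whether values are raw counts, TPM, or log2(TPM+pc).
    """

    gene_ids: list[str]
    samples: list[SampleMeta]
    values: np.ndarray
    scale: Scale = Scale.LOG2TPM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids")
        if self.scale is Scale.COUNTS:
            finite = self.values[np.isfinite(self.values)]
            if (finite < 0).any() or not np.allclose(finite, np.round(finite)):
                raise ValueError("counts scale requires non-negative integers")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.samples), self.values[rows, :], self.scale
        )

    def select_samples(
        self,
        genotype: Genotype | None = None,
        condition: Condition | None = None,
        timepoint_h: float | None = None,
    ) -> "ExpressionMatrix":
        cols = [
            i
            for i, s in enumerate(self.samples)
            if (genotype is None or s.genotype == genotype)
            and (condition is None or s.condition == condition)
            and (timepoint_h is None or s.timepoint_h == timepoint_h)
        ]
        return ExpressionMatrix(
            list(self.gene_ids),
            [self.samples[i] for i in cols],
            self.values[:, cols],
            self.scale,
        )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Peak]:
    """Read BED3/BED6 into peaks.

    Coordinates are taken verbatim (BED is 0-based half-open). A missing
    score column yields score 0; condition/timepoint/genotype default to
    none/0/WT and can be set afterwards by the caller.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            score = 0.0
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            peaks.append(
                Peak(GenomicInterval(chrom, start, end, strand), score=score, name=name)
            )
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GFF3


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene and exon features from a GFF3 file.

    GFF3 coordinates (1-based inclusive) are shifted to internal 0-based
    half-open: ``(start - 1, end)``. Exons are attached to their parent
    gene, resolving Parent chains through intermediate features (mRNA).
    Exons with no resolvable gene parent are skipped with a warning.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except EmptyInputError:
        return []
    genes: dict[str, dict] = {}
    for feat in db.features_of_type("gene"):
        genes[feat.id] = {
            "chrom": feat.seqid,
            "start": feat.start - 1,
            "end": feat.end,
            "strand": feat.strand,
            "exons": [],
        }
    for exon in db.features_of_type("exon"):
        parents = [p for p in db.parents(exon) if p.featuretype == "gene"]
        if not parents:
            logger.warning(
                "exon at %s:%d-%d has no resolvable gene parent; skipped",
                exon.seqid,
                exon.start,
                exon.end,
            )
            continue
        genes[parents[0].id]["exons"].append(
            GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand or ".")
        )
    models = []
    for gene_id, rec in genes.items():
        models.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(
                    rec["chrom"], rec["start"], rec["end"], rec["strand"]
                ),
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"], key=lambda e: e.start)),
            )
        )
    models.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    return models


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\threpipe\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, exon in enumerate(g.exons, start=1):
                fh.write(
                    f"{exon.chrom}\threpipe\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{name: sequence}``; sequences are uppercased.

    Letters outside A/C/G/T/N are mapped to N with a warning; duplicate
    record names are an error.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA record name {record.id!r} in {path}")
        seq = str(record.seq).upper()
        if not set(seq) <= _VALID_BASES:
            bad = sorted(set(seq) - _VALID_BASES)
            logger.warning(
                "record %s contains non-ACGTN letters %s; mapped to N",
                record.id,
                "".join(bad),
            )
            seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
        seqs[record.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV matrices and sample metadata


def write_tsv_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the value matrix as TSV: first column gene_id, header sample ids."""
    df = matrix.to_dataframe()
    df.index.name = "gene_id"
    # %.17g round-trips float64 exactly through text
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_tsv_matrix(
    path: str | Path,
    samples: Sequence[SampleMeta] | None = None,
    scale: Scale = Scale.LOG2TPM,
) -> ExpressionMatrix:
    """Read a gene x sample TSV.

    If ``samples`` is not given, minimal placeholder metadata is created
    from the header; pass the sidecar sample table for full metadata.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if samples is None:
        samples = [
            SampleMeta(str(c), Genotype.WT, Condition.NONE, 0.0, 1) for c in df.columns
        ]
    else:
        by_id = {s.sample_id: s for s in samples}
        missing = [c for c in df.columns if str(c) not in by_id]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
        samples = [by_id[str(c)] for c in df.columns]
    return ExpressionMatrix(
        [str(g) for g in df.index], list(samples), df.to_numpy(dtype=float), scale
    )


def write_sample_metadata(samples: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "genotype": s.genotype.value,
            "condition": s.condition.value,
            "timepoint_h": s.timepoint_h,
            "replicate": s.replicate,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            genotype=Genotype(r.genotype),
            condition=Condition(r.condition),
            timepoint_h=float(r.timepoint_h),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]
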