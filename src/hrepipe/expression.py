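"""Count-to-TPM transformation, the expression filter cascade, and
stimulus-dependence gene classification.

Fold thresholds are evaluated on the linear scale via differences of mean
log2 values, with strict inequalities throughout ("more than" semantics).
A ``linear_means`` flag switches to ratios of linear-scale means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .core_io import Condition, ExpressionMatrix, Genotype, Scale

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "GeneClass",
    "counts_to_tpm",
    "counts_to_log2_tpm",
    "drop_na_rows",
    "drop_zero_sd_rows",
    "filter_induced",
    "classify_hif_dependence",
    "stimulus_specific_gene_sets",
]


@dataclass(frozen=True)
class FilterConfig:
    """Linear-scale fold thresholds for the filter cascade and classification."""

    induction_ratio: float = 1.2  # late vs early timepoint, within WT
    dependence_ratio: float = 2.0  # WT vs KO
    require_positive_sd: bool = True
    linear_means: bool = False  # ratios of linear means instead of mean-log2 diffs

    def __post_init__(self) -> None:
        if self.induction_ratio <= 1 or self.dependence_ratio <= 1:
            raise ValueError("fold-change ratios must be > 1")


class GeneClass(str, Enum):
    RESPONSIVE = "responsive"
    UNRESPONSIVE = "unresponsive"
    UNBOUND = "unbound"


# ---------------------------------------------------------------------------
# TPM


def counts_to_tpm(
    counts: np.ndarray, gene_lengths_bp: np.ndarray
) -> np.ndarray:
    """Per-column TPM: length-normalized rates scaled to sum to 1e6."""
    counts = np.asarray(counts, dtype=float)
    lengths_kb = np.asarray(gene_lengths_bp, dtype=float) / 1000.0
    if (lengths_kb <= 0).any():
        raise ValueError("all gene lengths must be > 0")
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    rates = counts / lengths_kb[:, None]
    col_sums = rates.sum(axis=0)
    zero = np.flatnonzero(col_sums == 0)
    if zero.size:
        raise ValueError(f"all-zero count column(s) at index {zero.tolist()}")
    return rates / col_sums[None, :] * 1e6


def counts_to_log2_tpm(
    matrix: ExpressionMatrix,
    gene_lengths_bp: Mapping[str, int] | Sequence[int],
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Convert a counts matrix to log2(TPM + pseudocount).

    Raises if any sample column is all zeros (named in the message).
    """
    if matrix.scale is not Scale.COUNTS:
        raise ValueError(f"expected counts scale, got {matrix.scale.value}")
    if isinstance(gene_lengths_bp, Mapping):
        lengths = np.array([gene_lengths_bp[g] for g in matrix.gene_ids], dtype=float)
    else:
        lengths = np.asarray(gene_lengths_bp, dtype=float)
    if lengths.shape[0] != len(matrix.gene_ids):
        raise ValueError("gene_lengths length mismatch")
    zero_cols = np.flatnonzero(matrix.values.sum(axis=0) == 0)
    if zero_cols.size:
        names = [matrix.samples[i].sample_id for i in zero_cols]
        raise ValueError(f"all-zero count column for sample(s) {names}")
    tpm = counts_to_tpm(matrix.values, lengths)
    return ExpressionMatrix(
        list(matrix.gene_ids),
        list(matrix.samples),
        np.log2(tpm + pseudocount),
        Scale.LOG2TPM,
    )


# ---------------------------------------------------------------------------
# Filter cascade


def drop_na_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove any gene row containing a missing value."""
    keep = ~np.isnan(matrix.values).any(axis=1)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("drop_na_rows: removed %d rows", n_removed)
    if not keep.any():
        logger.warning("drop_na_rows: all rows removed")
    return ExpressionMatrix(
        [g for g, k in zip(matrix.gene_ids, keep) if k],
        list(matrix.samples),
        matrix.values[keep, :],
        matrix.scale,
    )


def drop_zero_sd_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove gene rows whose standard deviation across samples is exactly 0.

    The SD of a single value is 0, so a one-sample matrix loses all rows.
    """
    if len(matrix.samples) <= 1:
        logger.warning("drop_zero_sd_rows: <= 1 sample; removing all rows")
        keep = np.zeros(len(matrix.gene_ids), dtype=bool)
    else:
        keep = matrix.values.std(axis=1) != 0
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("drop_zero_sd_rows: removed %d rows", n_removed)
    return ExpressionMatrix(
        [g for g, k in zip(matrix.gene_ids, keep) if k],
        list(matrix.samples),
        matrix.values[keep, :],
        matrix.scale,
    )


def _mean_log2(matrix: ExpressionMatrix, **sel) -> np.ndarray:
    sub = matrix.select_samples(**sel)
    if not sub.samples:
        raise ValueError(f"no samples matching {sel}")
    return sub.values.mean(axis=1)


def _log2_ratio(
    matrix: ExpressionMatrix, config: FilterConfig, num_sel: dict, den_sel: dict
) -> np.ndarray:
    """log2 of the linear-scale ratio between two sample selections."""
    if config.linear_means:
        num = np.exp2(matrix.select_samples(**num_sel).values).mean(axis=1)
        den = np.exp2(matrix.select_samples(**den_sel).values).mean(axis=1)
        with np.errstate(divide="ignore"):
            return np.log2(num / den)
    return _mean_log2(matrix, **num_sel) - _mean_log2(matrix, **den_sel)


def filter_induced(
    matrix: ExpressionMatrix,
    condition: Condition = Condition.LPS,
    config: FilterConfig = FilterConfig(),
    genotype: Genotype = Genotype.WT,
    early_h: float = 4.0,
    late_h: float = 24.0,
) -> set[str]:
    """Genes whose late-timepoint expression exceeds induction_ratio x early.

    On log2 input this is ``mean_log2(late) - mean_log2(early) >
    log2(ratio)``, strict, matching "more than" wording.
    """
    if matrix.scale is not Scale.LOG2TPM:
        raise ValueError("filter_induced expects a log2tpm matrix")
    ratio = _log2_ratio(
        matrix,
        config,
        dict(genotype=genotype, condition=condition, timepoint_h=late_h),
        dict(genotype=genotype, condition=condition, timepoint_h=early_h),
    )
    threshold = np.log2(config.induction_ratio)
    return {g for g, r in zip(matrix.gene_ids, ratio) if r > threshold}


def classify_hif_dependence(
    matrix: ExpressionMatrix,
    bound_genes: set[str] | Sequence[str],
    config: FilterConfig = FilterConfig(),
    conditions: Sequence[Condition] = (Condition.LPS, Condition.HYPOXIA),
    timepoints: Sequence[float] = (4.0, 24.0),
) -> dict[str, GeneClass]:
    """Classify every gene as responsive / unresponsive / unbound.

    A bound gene is responsive iff the WT/KO linear ratio exceeds
    ``dependence_ratio`` (strictly) at some post-stimulus timepoint in at
    least one condition; other bound genes are unresponsive; genes outside
    ``bound_genes`` are unbound.
    """
    bound = set(bound_genes)
    for genotype in (Genotype.WT, Genotype.KO):
        if not matrix.select_samples(genotype=genotype).samples:
            raise ValueError(f"no samples for genotype {genotype.value}")
    best = np.full(len(matrix.gene_ids), -np.inf)
    for condition in conditions:
        for tp in timepoints:
            wt_sel = dict(genotype=Genotype.WT, condition=condition, timepoint_h=tp)
            ko_sel = dict(genotype=Genotype.KO, condition=condition, timepoint_h=tp)
            if not matrix.select_samples(**wt_sel).samples:
                continue
            best = np.maximum(best, _log2_ratio(matrix, config, wt_sel, ko_sel))
    threshold = np.log2(config.dependence_ratio)
    out: dict[str, GeneClass] = {}
    for gene, b in zip(matrix.gene_ids, best):
        if gene not in bound:
            out[gene] = GeneClass.UNBOUND
        elif b > threshold:
            out[gene] = GeneClass.RESPONSIVE
        else:
            out[gene] = GeneClass.UNRESPONSIVE
    return out


def stimulus_specific_gene_sets(
    matrix: ExpressionMatrix,
    config: FilterConfig = FilterConfig(),
    induced_timepoints: Mapping[Condition, float] = None,
) -> tuple[set[str], set[str]]:
    """Condition-specific gene sets: (lps_specific, hypoxia_specific).

    A gene is LPS-specific iff WT expression under LPS at its induced
    timepoint exceeds dependence_ratio x WT under hypoxia at its induced
    timepoint, AND WT exceeds KO under LPS at that timepoint; symmetric
    for hypoxia. The two sets are disjoint by construction.
    """
    if induced_timepoints is None:
        induced_timepoints = {Condition.LPS: 24.0, Condition.HYPOXIA: 4.0}
    threshold = np.log2(config.dependence_ratio)
    sets: dict[Condition, set[str]] = {}
    pairs = [
        (Condition.LPS, Condition.HYPOXIA),
        (Condition.HYPOXIA, Condition.LPS),
    ]
    for cond, other in pairs:
        tp, tp_other = induced_timepoints[cond], induced_timepoints[other]
        vs_other = _log2_ratio(
            matrix,
            config,
            dict(genotype=Genotype.WT, condition=cond, timepoint_h=tp),
            dict(genotype=Genotype.WT, condition=other, timepoint_h=tp_other),
        )
        vs_ko = _log2_ratio(
            matrix,
            config,
            dict(genotype=Genotype.WT, condition=cond, timepoint_h=tp),
            dict(genotype=Genotype.KO, condition=cond, timepoint_h=tp),
        )
        sets[cond] = {
            g
            for g, a, b in zip(matrix.gene_ids, vs_other, vs_ko)
            if a > threshold and b > 0
        }
    return sets[Condition.LPS], sets[Condition.HYPOXIA]
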