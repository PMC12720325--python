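"""Known-motif enrichment by cumulative binomial against a matched
background, plus Benjamini-Hochberg adjustment."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .motif_scan import Motif, count_sequences_with_hit

__all__ = [
    "EnrichmentResult",
    "binomial_enrichment",
    "run_known_motif_enrichment",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class EnrichmentResult:
    motif_name: str
    n_target: int
    k_target: int
    n_background: int
    k_background: int
    background_fraction: float
    p_value: float
    bh_adjusted: float = float("nan")


def binomial_enrichment(
    k_target: int, n_target: int, k_background: int, n_background: int
) -> float:
    """Upper-tail binomial p-value for over-representation.

    With p0 the background hit fraction, p = P(X >= k_target) for
    X ~ Binomial(n_target, p0), evaluated via the survival function. A
    degenerate background (k = 0 or k = n) is clamped to
    eps = 1 / (2 n_background) away from {0, 1} to avoid p = 0 artifacts.
    """
    for k, n, side in ((k_target, n_target, "target"), (k_background, n_background, "background")):
        if k < 0 or n < 0 or k > n:
            raise ValueError(f"inconsistent {side} counts k={k}, n={n}")
    if n_background == 0:
        raise ValueError("n_background must be > 0")
    p0 = k_background / n_background
    eps = 1.0 / (2.0 * n_background)
    p0 = min(max(p0, eps), 1.0 - eps)
    if k_target == 0:
        return 1.0
    return float(binom.sf(k_target - 1, n_target, p0))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment; input order preserved in the output."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def run_known_motif_enrichment(
    target_seqs: Mapping[str, str] | Sequence[str],
    background_seqs: Mapping[str, str] | Sequence[str],
    motifs: Sequence[Motif],
    both_strands: bool = True,
) -> list[EnrichmentResult]:
    """Presence/absence enrichment of each motif in targets vs background.

    Returns results sorted by ascending p-value with the BH column filled
    across the motif panel.
    """
    results: list[EnrichmentResult] = []
    for motif in motifs:
        k_t, n_t = count_sequences_with_hit(target_seqs, motif, both_strands)
        k_b, n_b = count_sequences_with_hit(background_seqs, motif, both_strands)
        p = binomial_enrichment(k_t, n_t, k_b, n_b)
        results.append(
            EnrichmentResult(
                motif_name=motif.name,
                n_target=n_t,
                k_target=k_t,
                n_background=n_b,
                k_background=k_b,
                background_fraction=(k_b / n_b if n_b else float("nan")),
                p_value=p,
            )
        )
    adjusted = benjamini_hochberg([r.p_value for r in results])
    results = [replace(r, bh_adjusted=float(a)) for r, a in zip(results, adjusted)]
    results.sort(key=lambda r: (r.p_value, r.motif_name))
    return results
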