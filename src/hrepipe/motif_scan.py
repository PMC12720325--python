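"""IUPAC consensus scanning over DNA sequences, plus GC/length-matched
background sampling for enrichment.

The scanner handles the degenerate-base subset {A,C,G,T,R,Y,S,W,K,M,N}.
An ``N`` in the *sequence* never matches any motif letter (including motif
``N``), so masked bases cannot create hits.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "IUPAC_CODES",
    "Motif",
    "MotifHit",
    "BackgroundSpec",
    "HRE_MOTIF",
    "reverse_complement",
    "scan_motif",
    "count_sequences_with_hit",
    "gc_fraction",
    "sample_matched_background",
]

# motif letter -> concrete sequence bases it matches (sequence N matches nothing)
IUPAC_CODES: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T",
    "T": "A",
    "C": "G",
    "G": "C",
    "R": "Y",
    "Y": "R",
    "S": "S",
    "W": "W",
    "K": "M",
    "M": "K",
    "N": "N",
}

_SEQ_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence or IUPAC consensus."""
    if set(seq) <= set("ACGTN"):
        return seq.translate(_SEQ_COMPLEMENT)[::-1]
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(seq))


@dataclass(frozen=True)
class Motif:
    """A named IUPAC consensus."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty motif consensus")
        bad = set(self.consensus) - set(IUPAC_CODES)
        if bad:
            raise ValueError(
                f"motif {self.name!r}: letters {sorted(bad)} outside the "
                "supported IUPAC subset"
            )

    def __len__(self) -> int:
        return len(self.consensus)


#: The hypoxia-response-element core consensus (R = A or G).
HRE_MOTIF = Motif("HRE", "RCGTG")


@dataclass(frozen=True)
class MotifHit:
    """A consensus match, reported in + strand coordinates.

    ``matched_text`` is the window as read on the + strand; for - strand
    hits its reverse complement matches the consensus.
    """

    seq_name: str
    start: int
    end: int
    strand: str
    matched_text: str


def _consensus_regex(consensus: str) -> re.Pattern[str]:
    # lookahead so overlapping matches are all found
    body = "".join(f"[{IUPAC_CODES[c]}]" for c in consensus)
    return re.compile(f"(?=({body}))")


def scan_motif(
    seq: str,
    motif: Motif,
    both_strands: bool = True,
    seq_name: str = "",
) -> list[MotifHit]:
    """Find every occurrence of ``motif`` in ``seq``.

    Forward-strand hits are positions where the consensus matches the
    sequence; minus-strand hits are positions where the reverse complement
    of the window matches. Hits are sorted by start, ``+`` before ``-`` at
    the same position, and overlapping hits are all reported.
    """
    seq = seq.upper()
    if not set(seq) <= set("ACGTN"):
        raise ValueError("sequence contains letters outside A/C/G/T/N")
    hits: list[MotifHit] = []
    m = len(motif)
    for match in _consensus_regex(motif.consensus).finditer(seq):
        start = match.start()
        hits.append(MotifHit(seq_name, start, start + m, "+", match.group(1)))
    if both_strands:
        # window matches on - strand <=> window matches revcomp(consensus) on +
        rc = reverse_complement(motif.consensus)
        for match in _consensus_regex(rc).finditer(seq):
            start = match.start()
            hits.append(MotifHit(seq_name, start, start + m, "-", match.group(1)))
    hits.sort(key=lambda h: (h.start, 0 if h.strand == "+" else 1))
    return hits


def count_sequences_with_hit(
    seqs: Mapping[str, str] | Sequence[str],
    motif: Motif,
    both_strands: bool = True,
) -> tuple[int, int]:
    """Presence/absence count: (sequences with >= 1 hit, total sequences)."""
    values = list(seqs.values()) if isinstance(seqs, Mapping) else list(seqs)
    k = sum(1 for s in values if scan_motif(s, motif, both_strands))
    return k, len(values)


def gc_fraction(seq: str) -> float:
    """G+C fraction over the full sequence length (0 for empty input)."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class BackgroundSpec:
    """How to draw GC/length-matched background sequences."""

    gc_bins: int = 10
    length_bins: int = 1
    n_background_per_target: int = 1
    seed: int = 0
    allow_replacement_fallback: bool = True

    def __post_init__(self) -> None:
        if self.gc_bins < 1 or self.length_bins < 1:
            raise ValueError("bins must be >= 1")
        if self.n_background_per_target < 1:
            raise ValueError("n_background_per_target must be >= 1")


def _gc_bin(seq: str, n_bins: int) -> int:
    return min(int(gc_fraction(seq) * n_bins), n_bins - 1)


def _length_bin(length: int, n_bins: int, lo: int, hi: int) -> int:
    if n_bins == 1 or hi == lo:
        return 0
    frac = (length - lo) / (hi - lo)
    return min(int(frac * n_bins), n_bins - 1)


def sample_matched_background(
    targets: Mapping[str, str],
    pool: Mapping[str, str],
    spec: BackgroundSpec,
) -> list[tuple[str, str]]:
    """Sample pool sequences matched to each target's (GC bin, length bin).

    For every target, ``n_background_per_target`` sequences are drawn from
    the pool bin matching the target. Sampling is without replacement
    within a bin until the bin is exhausted, then with replacement (with a
    warning) if the spec allows it. Deterministic under ``spec.seed``.
    """
    if not pool:
        raise ValueError("background pool is empty")
    rng = np.random.default_rng(spec.seed)
    lengths = [len(s) for s in pool.values()] + [len(s) for s in targets.values()]
    lo, hi = min(lengths), max(lengths)

    bins: dict[tuple[int, int], list[str]] = {}
    for name in sorted(pool):
        seq = pool[name]
        key = (_gc_bin(seq, spec.gc_bins), _length_bin(len(seq), spec.length_bins, lo, hi))
        bins.setdefault(key, []).append(name)

    remaining = {key: list(names) for key, names in bins.items()}
    chosen: list[tuple[str, str]] = []
    for tname in sorted(targets):
        tseq = targets[tname]
        key = (
            _gc_bin(tseq, spec.gc_bins),
            _length_bin(len(tseq), spec.length_bins, lo, hi),
        )
        if key not in bins:
            raise ValueError(
                f"no pool sequences in GC bin {key[0]} / length bin {key[1]} "
                f"for target {tname!r}"
            )
        for _ in range(spec.n_background_per_target):
            avail = remaining[key]
            if avail:
                idx = int(rng.integers(len(avail)))
                name = avail.pop(idx)
            else:
                if not spec.allow_replacement_fallback:
                    raise ValueError(
                        f"pool bin {key} exhausted and replacement fallback disabled"
                    )
                logger.warning("pool bin %s exhausted; sampling with replacement", key)
                name = bins[key][int(rng.integers(len(bins[key])))]
            chosen.append((name, pool[name]))
    return chosen
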