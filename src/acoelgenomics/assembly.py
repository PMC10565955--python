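"""Contiguity and composition metrics of an assembly.

N50 follows the standard convention: accumulate contig lengths from the
longest down; N50 is the length at which the running sum first reaches
half the total assembly length. N-content counts both ``N`` and ``n``
(so a lowercase n contributes to both the N tally and the soft-masked
tally); GC fraction is computed over non-N bases only.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .types import Assembly

__all__ = ["AssemblySummary", "summarize_assembly", "cumulative_length_curve",
           "masked_fraction", "n50"]


@dataclass(frozen=True)
class AssemblySummary:
    total_length: int
    n_contigs: int
    longest: int
    mean_length: float
    n50: int
    n_count: int
    n_percent: float
    masked_count: int
    masked_percent: float
    gc_fraction: float

    def to_dict(self) -> dict:
        return asdict(self)


def n50(lengths: list[int]) -> int:
    if not lengths:
        raise ValueError("empty assembly")
    half = sum(lengths) / 2.0
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def summarize_assembly(assembly: Assembly) -> AssemblySummary:
    """Full contiguity/composition summary; raises on an empty assembly."""
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    lengths = [len(c) for c in assembly]
    total = sum(lengths)
    n_count = 0
    masked = 0
    gc = 0
    for c in assembly:
        s = c.seq
        n_count += s.count("N") + s.count("n")
        masked += sum(s.count(ch) for ch in "acgturyswkmbdhvn")
        gc += sum(s.count(ch) for ch in "GCgcSs")
    non_n = total - n_count
    return AssemblySummary(
        total_length=total,
        n_contigs=len(assembly),
        longest=max(lengths),
        mean_length=total / len(assembly),
        n50=n50(lengths),
        n_count=n_count,
        n_percent=100.0 * n_count / total,
        masked_count=masked,
        masked_percent=100.0 * masked / total,
        gc_fraction=gc / non_n if non_n else 0.0,
    )


def cumulative_length_curve(assembly: Assembly) -> list[tuple[int, int]]:
    """(rank, cumulative bp) pairs with contigs sorted longest-first."""
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    lengths = sorted((len(c) for c in assembly), reverse=True)
    out = []
    acc = 0
    for rank, length in enumerate(lengths, start=1):
        acc += length
        out.append((rank, acc))
    return out


def masked_fraction(assembly: Assembly) -> float:
    """Percentage of soft-masked (lowercase) bases."""
    total = assembly.total_length
    if total == 0:
        return 0.0
    masked = sum(
        sum(c.seq.count(ch) for ch in "acgturyswkmbdhvn") for c in assembly
    )
    return 100.0 * masked / total
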