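"""Shared domain types for the comparative-genomics pipeline.

All genomic coordinates are 1-based inclusive (GFF3 convention). Sequence
case is preserved everywhere: lowercase marks soft-masked repeat bases,
``N``/``n`` marks gap fill.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Contig",
    "Assembly",
    "Interval",
    "Transcript",
    "GeneModel",
    "AnnotationSet",
    "OrthogroupTable",
    "CladeAssignment",
    "HitRecord",
    "TaxonomyMap",
    "CoverageTable",
    "NO_HIT",
]

#: Sentinel taxon label for contigs without any alignment hit.
NO_HIT = "no-hit"

_IUPAC_NT = re.compile(r"^[ACGTURYSWKMBDHVNacgturyswkmbdhvn]+$")


@dataclass(frozen=True)
class Contig:
    """A named assembly sequence; case preserved, IUPAC alphabet enforced."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id!r} has empty sequence")
        if not _IUPAC_NT.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTURYSWKMBDHVNacgturyswkmbdhvn"))
            raise ValueError(f"contig {self.id!r} has non-IUPAC characters: {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """Ordered collection of contigs with unique ids."""

    contigs: list[Contig]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.contigs:
            if c.id in seen:
                raise ValueError(f"duplicate contig id: {c.id!r}")
            seen.add(c.id)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.contigs]

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)

    def get(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)


@dataclass(frozen=True, order=True)
class Interval:
    """1-based inclusive interval; length = end - start + 1."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    id: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.id!r}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"transcript {self.id!r}: overlapping exons")

    @property
    def exon_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def intron_lengths(self) -> list[int]:
        """Gap between consecutive exons: next.start - prev.end - 1."""
        return [
            b.start - a.end - 1 for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass
class GeneModel:
    id: str
    contig_id: str
    transcripts: list[Transcript]
    representative: str | None = None

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.id!r} has no transcripts")
        if self.representative is None:
            self.representative = pick_representative(self.transcripts)
        if self.representative not in {t.id for t in self.transcripts}:
            raise ValueError(
                f"gene {self.id!r}: representative {self.representative!r} "
                "not among its transcripts"
            )

    @property
    def rep(self) -> Transcript:
        for t in self.transcripts:
            if t.id == self.representative:
                return t
        raise AssertionError("unreachable")


def pick_representative(transcripts: list[Transcript]) -> str:
    """Longest summed CDS length; ties go to the smallest transcript id."""
    return min(transcripts, key=lambda t: (-t.cds_length, t.id)).id


@dataclass
class AnnotationSet:
    genes: list[GeneModel]
    contig_universe: set[str] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id: {g.id!r}")
            seen.add(g.id)
        if self.contig_universe is not None:
            off = sorted(
                {g.contig_id for g in self.genes} - self.contig_universe
            )
            if off:
                raise ValueError(
                    f"genes on contigs outside the universe: {off[:10]}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class OrthogroupTable:
    """Orthogroup x species gene counts, plus the explicit species universe."""

    counts: dict[str, dict[str, int]]
    species: list[str]

    def __post_init__(self) -> None:
        universe = set(self.species)
        for og, row in self.counts.items():
            total = 0
            for sp, n in row.items():
                if sp not in universe:
                    raise ValueError(f"orthogroup {og!r}: unknown species {sp!r}")
                if not (isinstance(n, int) and n >= 0):
                    raise ValueError(f"orthogroup {og!r}: bad count for {sp!r}")
                total += n
            if total < 1:
                raise ValueError(f"orthogroup {og!r} is empty")

    def species_present(self, og: str) -> set[str]:
        return {sp for sp, n in self.counts[og].items() if n >= 1}

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class CladeAssignment:
    clade: dict[str, str]
    subclade: dict[str, str] = field(default_factory=dict)

    def clade_of(self, species: str) -> str:
        try:
            return self.clade[species]
        except KeyError:
            raise KeyError(f"species {species!r} has no clade assignment") from None

    def species_of(self, clade: str) -> set[str]:
        return {sp for sp, c in self.clade.items() if c == clade}


@dataclass(frozen=True)
class HitRecord:
    """One row of 12-column tabular alignment output plus a subject taxid.

    Alignment coordinates are retained so query coverage can be computed
    downstream when query lengths are known.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float
    subject_taxid: int
    aln_length: int = 0
    qstart: int = 0
    qend: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (self.bitscore == self.bitscore and self.bitscore > 0):
            raise ValueError("bitscore must be finite and > 0")

    def query_span(self) -> int:
        return abs(self.qend - self.qstart) + 1 if self.qend else self.aln_length


class UnknownTaxidError(KeyError):
    pass


@dataclass
class TaxonomyMap:
    """taxid -> ordered (rank, name) lineage; unknown taxid raises."""

    lineages: dict[int, list[tuple[str, str]]]

    def lineage(self, taxid: int) -> list[tuple[str, str]]:
        try:
            return self.lineages[taxid]
        except KeyError:
            raise UnknownTaxidError(taxid) from None

    def name_at_rank(self, taxid: int, rank: str) -> str | None:
        for r, name in self.lineage(taxid):
            if r == rank and name:
                return name
        return None

    def lineage_names(self, taxid: int) -> set[str]:
        return {name for _, name in self.lineage(taxid) if name}


@dataclass
class CoverageTable:
    """contig id -> (mean read coverage, GC fraction)."""

    rows: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for cid, (cov, gc) in self.rows.items():
            if cov < 0:
                raise ValueError(f"{cid}: coverage must be >= 0")
            if not (0.0 <= gc <= 1.0):
                raise ValueError(f"{cid}: GC must be in [0,1]")
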