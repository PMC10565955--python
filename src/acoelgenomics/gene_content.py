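"""Orthogroup gene-content partition across four clades.

An orthogroup is "present" in a clade as soon as one species of that
clade carries at least one gene. Orthogroups present in a cnidarian and
at least one bilaterian clade form the metazoan shared set; those
present in two or more bilaterian clades but in no cnidarian form the
bilaterian shared set — the two sets are disjoint by construction and
together make up every orthogroup found in at least two clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import CladeAssignment, OrthogroupTable

__all__ = [
    "CNIDARIA",
    "BILATERIAN_CLADES",
    "partition_by_clade",
    "exclusivity_stats",
    "venn_counts",
    "shared_sets",
    "missing_fractions",
    "within_clade_sharing",
    "summarize_content",
    "ContentSummary",
]

CNIDARIA = "Cnidaria"
BILATERIAN_CLADES = ("Acoelomorpha", "Deuterostomia", "Protostomia")


def partition_by_clade(
    table: OrthogroupTable, clades: CladeAssignment
) -> dict[str, frozenset[str]]:
    """Map each orthogroup to the set of clades in which it is present."""
    unassigned = sorted(sp for sp in table.species if sp not in clades.clade)
    if unassigned:
        raise ValueError(f"species without clade assignment: {unassigned}")
    partition: dict[str, frozenset[str]] = {}
    for og in table.counts:
        present = frozenset(
            clades.clade_of(sp) for sp in table.species_present(og)
        )
        partition[og] = present
    return partition


@dataclass(frozen=True)
class CladeExclusivity:
    present: int
    exclusive: int
    percent_exclusive: float | None  # None when the clade has nothing present


def exclusivity_stats(
    partition: dict[str, frozenset[str]]
) -> dict[str, CladeExclusivity]:
    """Per clade: orthogroups present, exclusive to it, and % exclusive."""
    if not partition:
        raise ValueError("empty partition")
    clades = sorted({c for s in partition.values() for c in s})
    out = {}
    for clade in clades:
        present = sum(1 for s in partition.values() if clade in s)
        exclusive = sum(1 for s in partition.values() if s == frozenset({clade}))
        out[clade] = CladeExclusivity(
            present=present,
            exclusive=exclusive,
            percent_exclusive=(100.0 * exclusive / present) if present else None,
        )
    return out


def venn_counts(partition: dict[str, frozenset[str]]) -> dict[frozenset[str], int]:
    """Counts of the (up to 15) non-empty clade subsets."""
    out: dict[frozenset[str], int] = {}
    for s in partition.values():
        out[s] = out.get(s, 0) + 1
    return out


def shared_sets(
    partition: dict[str, frozenset[str]],
    cnidaria: str = CNIDARIA,
) -> tuple[set[str], set[str], int]:
    """(metazoan_set, bilaterian_set, shared_total).

    metazoan: contains Cnidaria plus at least one other clade;
    bilaterian: no Cnidaria, at least two clades. shared_total is the size
    of their (disjoint) union.
    """
    metazoan = {
        og for og, s in partition.items() if cnidaria in s and len(s) >= 2
    }
    bilaterian = {
        og for og, s in partition.items() if cnidaria not in s and len(s) >= 2
    }
    return metazoan, bilaterian, len(metazoan) + len(bilaterian)


def missing_fractions(
    partition: dict[str, frozenset[str]], gene_set: set[str], clade: str
) -> float:
    """% of ``gene_set`` orthogroups from which ``clade`` is absent."""
    if not gene_set:
        raise ValueError("empty gene set")
    stray = gene_set - set(partition)
    if stray:
        raise ValueError(f"gene set not within partition: {sorted(stray)[:5]}")
    missing = sum(1 for og in gene_set if clade not in partition[og])
    return 100.0 * missing / len(gene_set)


@dataclass(frozen=True)
class SubcladeSharing:
    shared: int
    unique_a: int
    unique_b: int
    subclade_a: str
    subclade_b: str

    @property
    def total(self) -> int:
        return self.shared + self.unique_a + self.unique_b

    def percents(self) -> tuple[float, float, float]:
        t = self.total
        return (100.0 * self.shared / t, 100.0 * self.unique_a / t,
                100.0 * self.unique_b / t)


def within_clade_sharing(
    table: OrthogroupTable,
    subclade_map: dict[str, str],
    focal_species: set[str] | None = None,
) -> SubcladeSharing:
    """Shared / unique split between the two subclades of a focal clade.

    ``subclade_map`` maps every focal-clade species to one of exactly two
    subclade labels. Computed over orthogroups present in at least one
    focal species.
    """
    labels = sorted(set(subclade_map.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two subclades, got {labels}")
    by_label = {lab: {sp for sp, l in subclade_map.items() if l == lab}
                for lab in labels}
    for lab, sps in by_label.items():
        if not sps:
            raise ValueError(f"subclade {lab!r} has no species")
    focal = focal_species or set(subclade_map)
    shared = ua = ub = 0
    for og in table.counts:
        present = table.species_present(og) & focal
        if not present:
            continue
        in_a = bool(present & by_label[labels[0]])
        in_b = bool(present & by_label[labels[1]])
        if in_a and in_b:
            shared += 1
        elif in_a:
            ua += 1
        else:
            ub += 1
    return SubcladeSharing(shared=shared, unique_a=ua, unique_b=ub,
                           subclade_a=labels[0], subclade_b=labels[1])


@dataclass
class ContentSummary:
    n_orthogroups: int
    exclusivity: dict[str, CladeExclusivity]
    venn: dict[frozenset[str], int]
    metazoan_set: set[str]
    bilaterian_set: set[str]
    shared_total: int
    percent_shared: float                    # of all orthogroups
    missing: dict[str, dict[str, float]] = field(default_factory=dict)
    # missing[clade] = {"metazoan": %, "bilaterian": %}
    percent_all_four_of_shared: float = 0.0
    percent_bilaterian_only_of_shared: float = 0.0
    percent_all_four_of_total: float = 0.0
    percent_bilaterian_only_of_total: float = 0.0


def summarize_content(
    partition: dict[str, frozenset[str]],
    bilaterian_clades: tuple[str, ...] = BILATERIAN_CLADES,
) -> ContentSummary:
    """Assemble the full gene-content summary from a clade partition."""
    n = len(partition)
    metazoan, bilaterian, shared_total = shared_sets(partition)
    venn = venn_counts(partition)
    all_four = venn.get(frozenset({CNIDARIA, *bilaterian_clades}), 0)
    bil_only = venn.get(frozenset(bilaterian_clades), 0)
    missing = {}
    for clade in bilaterian_clades:
        missing[clade] = {
            "metazoan": missing_fractions(partition, metazoan, clade)
            if metazoan else float("nan"),
            "bilaterian": missing_fractions(partition, bilaterian, clade)
            if bilaterian else float("nan"),
        }
    return ContentSummary(
        n_orthogroups=n,
        exclusivity=exclusivity_stats(partition),
        venn=venn,
        metazoan_set=metazoan,
        bilaterian_set=bilaterian,
        shared_total=shared_total,
        percent_shared=100.0 * shared_total / n if n else 0.0,
        missing=missing,
        percent_all_four_of_shared=100.0 * all_four / shared_total if shared_total else 0.0,
        percent_bilaterian_only_of_shared=100.0 * bil_only / shared_total if shared_total else 0.0,
        percent_all_four_of_total=100.0 * all_four / n if n else 0.0,
        percent_bilaterian_only_of_total=100.0 * bil_only / n if n else 0.0,
    )
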