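"""Excretory-gene panel: presence/absence calls and gene-architecture
statistics.

The panel covers the nine genes of the ultrafiltration excretory system
— three structural proteins (Nephrin, Kirrel, ZO1) and six transcription
factors (Eya, Lhx1/5, Osr, POU3, Sall, Six1). Three metrics are compared
per gene family across clades: protein length (aa), exons per protein,
and mean exon length (bp). Fragmented annotations are removed by a
single-pass filter (protein shorter than half the family-wide mean
length), and group differences are tested with a decision cascade:
Shapiro-Wilk per group and Bartlett across groups gate the choice
between one-way ANOVA (pairwise t tests, Bonferroni) and Kruskal-Wallis
(Dunn's z tests with tie correction, Bonferroni), both at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .types import AnnotationSet, HitRecord

__all__ = [
    "PANEL",
    "METRICS",
    "ArchitectureRecord",
    "PresenceMatrix",
    "TestOutcome",
    "build_presence_matrix",
    "extract_architecture",
    "fragment_filter",
    "dunn_test",
    "compare_clades",
    "run_panel_comparison",
]

#: family name -> role
PANEL: dict[str, str] = {
    "Nephrin": "structural",
    "Kirrel": "structural",
    "ZO1": "structural",
    "Eya": "transcription factor",
    "Lhx1/5": "transcription factor",
    "Osr": "transcription factor",
    "POU3": "transcription factor",
    "Sall": "transcription factor",
    "Six1": "transcription factor",
}

METRICS = ("protein_length", "n_exons", "mean_exon_length")

ANNOTATED = "annotated"
GENBANK = "genbank-supported"
ABSENT = "absent"
NO_DATA = "no-data"


@dataclass
class ArchitectureRecord:
    """One annotated gene copy's architecture metrics."""

    species: str
    clade: str
    family: str
    gene_id: str
    protein_length: int | None  # aa; None when no protein sequence resolved
    n_exons: int
    mean_exon_length: float     # bp

    def __post_init__(self) -> None:
        if self.protein_length is not None and self.protein_length < 1:
            raise ValueError(f"{self.gene_id}: protein_length must be >= 1")
        if self.n_exons < 1 or self.mean_exon_length <= 0:
            raise ValueError(f"{self.gene_id}: invalid exon metrics")

    def metric(self, name: str):
        return getattr(self, name)


# ---------------------------------------------------------------------------
# Presence / absence

@dataclass
class PresenceMatrix:
    """family x species -> one of annotated / genbank-supported / absent /
    no-data."""

    states: dict[tuple[str, str], str]
    families: list[str]
    species: list[str]

    def state(self, family: str, species: str) -> str:
        return self.states[(family, species)]

    def by_clade(self, clades: dict[str, str]) -> dict[tuple[str, str], str]:
        """Aggregate to family x clade: annotated beats genbank beats absent."""
        order = {ANNOTATED: 0, GENBANK: 1, ABSENT: 2, NO_DATA: 3}
        agg: dict[tuple[str, str], str] = {}
        for (fam, sp), st in self.states.items():
            clade = clades[sp]
            key = (fam, clade)
            if key not in agg or order[st] < order[agg[key]]:
                agg[key] = st
        return agg


def build_presence_matrix(
    hits_by_species: dict[str, list[HitRecord] | None],
    query_lengths: dict[str, int],
    query_family,
    families: list[str] | None = None,
    max_evalue: float = 1e-5,
    min_query_cov: float = 0.5,
    genbank_override: set[tuple[str, str]] | None = None,
) -> PresenceMatrix:
    """Call gene-family presence per species from panel-vs-proteome hits.

    ``hits_by_species`` maps species -> hit records (``None`` marks a
    species with no searchable proteome: recorded as no-data, never as
    absent). ``query_family`` maps a query id to its family (callable or
    mapping; ``None`` return skips the hit). A family is *annotated* in a
    species iff at least one hit passes both the e-value and query-coverage
    thresholds; otherwise *genbank-supported* when the override table says
    so, else *absent*.
    """
    if callable(query_family):
        qfam = query_family
    else:
        qfam = lambda q: query_family.get(q)  # noqa: E731
    families = list(families) if families is not None else list(PANEL)
    genbank_override = genbank_override or set()
    states: dict[tuple[str, str], str] = {}
    for sp, hits in hits_by_species.items():
        if hits is None:
            for fam in families:
                states[(fam, sp)] = NO_DATA
            continue
        passing: set[str] = set()
        for h in hits:
            fam = qfam(h.query_id)
            if fam is None:
                continue
            if h.evalue > max_evalue:
                continue
            qlen = query_lengths.get(h.query_id)
            if qlen is None or qlen <= 0:
                continue
            if h.query_span() / qlen < min_query_cov:
                continue
            passing.add(fam)
        for fam in families:
            if fam in passing:
                states[(fam, sp)] = ANNOTATED
            elif (fam, sp) in genbank_override:
                states[(fam, sp)] = GENBANK
            else:
                states[(fam, sp)] = ABSENT
    return PresenceMatrix(
        states=states, families=families, species=list(hits_by_species)
    )


# ---------------------------------------------------------------------------
# Metric extraction

def extract_architecture(
    annotation: AnnotationSet,
    proteome: dict[str, str],
    panel_gene_ids: dict[str, str],
    species: str,
    clade: str,
) -> tuple[list[ArchitectureRecord], list[tuple[str, str]]]:
    """Per panel gene copy: protein length, exon count, mean exon length.

    ``panel_gene_ids`` maps gene id -> family. The protein is looked up by
    representative-transcript id, then by gene id; a gene with exon
    structure but no resolvable protein still yields a record (protein
    length ``None``). Returns ``(records, warnings)``.
    """
    by_id = {g.id: g for g in annotation}
    records: list[ArchitectureRecord] = []
    warn: list[tuple[str, str]] = []
    for gid, family in panel_gene_ids.items():
        gene = by_id.get(gid)
        if gene is None:
            warn.append((gid, "gene id not in annotation"))
            continue
        rep = gene.rep
        if rep.n_exons == 0:
            warn.append((gid, "no exon features"))
            continue
        prot = proteome.get(rep.id, proteome.get(gid))
        plen = len(prot) if prot else None
        if prot is None:
            warn.append((gid, "no protein sequence; exon metrics only"))
        records.append(
            ArchitectureRecord(
                species=species,
                clade=clade,
                family=family,
                gene_id=gid,
                protein_length=plen,
                n_exons=rep.n_exons,
                mean_exon_length=rep.exon_length / rep.n_exons,
            )
        )
    return records, warn


def fragment_filter(
    records: list[ArchitectureRecord],
) -> tuple[list[ArchitectureRecord], list[ArchitectureRecord]]:
    """Remove fragmented copies: protein shorter than half the family mean.

    The threshold per family is 0.5 x the arithmetic mean protein length
    over ALL records of that family (all clades pooled), computed once
    before any removal — a single pass, not iterated. Records without a
    protein length are never removed.
    """
    thresholds: dict[str, float] = {}
    by_family: dict[str, list[int]] = {}
    for r in records:
        if r.protein_length is not None:
            by_family.setdefault(r.family, []).append(r.protein_length)
    for fam, lens in by_family.items():
        thresholds[fam] = 0.5 * (sum(lens) / len(lens))
    kept, removed = [], []
    for r in records:
        thr = thresholds.get(r.family)
        if (
            thr is not None
            and r.protein_length is not None
            and r.protein_length < thr
        ):
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


# ---------------------------------------------------------------------------
# Statistics

@dataclass
class TestOutcome:
    family: str
    metric: str
    group_sizes: dict[str, int]
    normality_pass: bool
    homoscedasticity_pass: bool
    omnibus: str                     # "ANOVA" | "Kruskal-Wallis"
    omnibus_p: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    significant_pairs: list[tuple[str, str]] = field(default_factory=list)
    brackets: list[list[str]] = field(default_factory=list)
    degenerate: bool = False
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.omnibus_p < self.alpha


def _group_normal(x: np.ndarray, alpha: float) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def _homoscedastic(groups: list[np.ndarray], alpha: float) -> bool:
    if any(np.ptp(g) == 0 for g in groups):
        return False
    return stats.bartlett(*groups).pvalue > alpha


def dunn_test(
    groups: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> dict[tuple[str, str], tuple[float, float]]:
    """Dunn's post-hoc z tests on joint ranks with tie correction.

    For groups i, j with mean joint ranks Ri, Rj over N observations:

        z = (Ri - Rj) / sqrt((N(N+1)/12 - T) * (1/ni + 1/nj))
        T = sum(t^3 - t) / (12 (N - 1))   over tied-value multiplicities t

    Returns pair -> (z, adjusted two-sided p). Pairs are ordered by group
    name; z is antisymmetric under swapping the pair.
    """
    names = sorted(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n_total = len(values)
    ranks = stats.rankdata(values)
    mean_ranks = {}
    offset = 0
    for g in names:
        mean_ranks[g] = ranks[offset : offset + sizes[g]].mean()
        offset += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(combinations(names, 2))
    raw: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in pairs:
        se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        raw[(a, b)] = (z, p)

    if adjust == "none":
        return raw
    if adjust == "bonferroni":
        m = len(pairs)
        return {k: (z, min(1.0, p * m)) for k, (z, p) in raw.items()}
    if adjust == "holm":
        items = sorted(raw.items(), key=lambda kv: kv[1][1])
        m = len(items)
        out = {}
        running = 0.0
        for i, (k, (z, p)) in enumerate(items):
            adj = min(1.0, (m - i) * p)
            running = max(running, adj)
            out[k] = (z, running)
        return out
    raise ValueError(f"unknown adjustment {adjust!r}")


def _brackets(
    clades: list[str],
    medians: dict[str, float],
    significant: set[tuple[str, str]],
) -> list[list[str]]:
    """Maximal runs of clades (ordered by metric median) whose members are
    pairwise non-significant — the underlining/bracket display."""
    order = sorted(clades, key=lambda c: (medians[c], c))

    def nonsig(a: str, b: str) -> bool:
        return (a, b) not in significant and (b, a) not in significant

    windows: list[tuple[int, int]] = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and all(
            nonsig(order[k], order[j + 1]) for k in range(i, j + 1)
        ):
            j += 1
        windows.append((i, j))
    maximal = [
        (i, j)
        for i, j in windows
        if not any((a <= i and j <= b and (a, b) != (i, j)) for a, b in windows)
    ]
    seen = set()
    out = []
    for i, j in maximal:
        if (i, j) not in seen:
            seen.add((i, j))
            out.append(order[i : j + 1])
    return out


def compare_clades(
    records: list[ArchitectureRecord],
    family: str,
    metric: str,
    alpha: float = 0.05,
    posthoc_adjust: str = "bonferroni",
) -> TestOutcome:
    """Omnibus + post-hoc comparison of one metric across clades.

    Normality requires every group with n >= 3 to pass Shapiro-Wilk at
    ``alpha`` (groups with n < 3 or constant data force non-normality);
    homoscedasticity is Bartlett at ``alpha``. Both passing selects ANOVA
    with pairwise pooled-variance t tests (Bonferroni over the pairs
    tested); otherwise Kruskal-Wallis with Dunn's post-hoc. Pairwise
    tests run only when the omnibus p is below ``alpha``.
    """
    groups: dict[str, np.ndarray] = {}
    for r in records:
        if r.family != family:
            continue
        v = r.metric(metric)
        if v is None:
            continue
        groups.setdefault(r.clade, []).append(float(v))
    groups = {c: np.asarray(v) for c, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError(
            f"{family}/{metric}: need >= 2 clades with >= 2 records, "
            f"got {len(groups)}"
        )
    names = sorted(groups)
    arrays = [groups[c] for c in names]
    pooled = np.concatenate(arrays)
    degenerate = np.ptp(pooled) == 0

    normal = all(_group_normal(g, alpha) for g in arrays)
    homosced = _homoscedastic(arrays, alpha)

    if degenerate:
        omnibus, omnibus_p = "Kruskal-Wallis", 1.0
    elif normal and homosced:
        omnibus = "ANOVA"
        omnibus_p = float(stats.f_oneway(*arrays).pvalue)
    else:
        omnibus = "Kruskal-Wallis"
        omnibus_p = float(stats.kruskal(*arrays).pvalue)

    pairwise: dict[tuple[str, str], float] = {}
    significant: list[tuple[str, str]] = []
    if not degenerate and omnibus_p < alpha:
        pairs = list(combinations(names, 2))
        if omnibus == "ANOVA":
            m = len(pairs)
            for a, b in pairs:
                p = float(stats.ttest_ind(groups[a], groups[b], equal_var=True).pvalue)
                padj = min(1.0, p * m) if posthoc_adjust == "bonferroni" else p
                pairwise[(a, b)] = padj
        else:
            dunn = dunn_test(groups, adjust=posthoc_adjust)
            pairwise = {k: p for k, (_, p) in dunn.items()}
        significant = [k for k, p in pairwise.items() if p < alpha]

    medians = {c: float(np.median(groups[c])) for c in names}
    brackets = _brackets(names, medians, set(significant))
    return TestOutcome(
        family=family,
        metric=metric,
        group_sizes={c: len(groups[c]) for c in names},
        normality_pass=normal,
        homoscedasticity_pass=homosced,
        omnibus=omnibus,
        omnibus_p=omnibus_p,
        pairwise=pairwise,
        significant_pairs=significant,
        brackets=brackets,
        degenerate=bool(degenerate),
        alpha=alpha,
    )


def run_panel_comparison(
    records: list[ArchitectureRecord],
    alpha: float = 0.05,
    metrics: tuple[str, ...] = METRICS,
) -> tuple[list[TestOutcome], list[tuple[str, str, str]]]:
    """One TestOutcome per family x metric with usable data.

    Families/metrics with fewer than two clades carrying >= 2 records each
    are skipped with an explicit reason. Returns ``(outcomes, skipped)``.
    """
    families = sorted({r.family for r in records})
    outcomes: list[TestOutcome] = []
    skipped: list[tuple[str, str, str]] = []
    for fam in families:
        for metric in metrics:
            try:
                outcomes.append(compare_clades(records, fam, metric, alpha=alpha))
            except ValueError as exc:
                skipped.append((fam, metric, str(exc)))
    return outcomes, skipped
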