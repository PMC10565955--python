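"""Seeded, manifest-backed synthetic fixtures for every pipeline stage.

The generator emulates the statistical structure of a draft genome
project on microscopic marine worms: contig length distributions with
N-gap runs and soft-masked repeat tracts; multi-exon gene models with
clade-specific exon-count and intron-length laws and translatable
(stop-free) CDS embedded in the contig sequence; OrthoFinder-style
orthogroup tables realizing a configurable 15-class clade-sharing
design; contaminant contigs with shifted GC and coverage carrying
foreign-taxon alignment hits; and gene-panel hit tables with planted
presences/absences.

Every run is driven by a ``numpy`` Generator seeded from a single
integer, and returns a :class:`Manifest` holding the exact realized
ground truth, so every summary statistic the pipeline computes on a
fixture can be predicted from the manifest alone (the closure tests).
Orthogroup class counts default to the proportions of the comparative
study the pipeline targets (three cnidarian, three acoelomorph, four
deuterostome and eight protostome genomes).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Seq import Seq

from .types import (
    Assembly,
    CladeAssignment,
    Contig,
    CoverageTable,
    HitRecord,
    Interval,
    OrthogroupTable,
    TaxonomyMap,
    Transcript,
    GeneModel,
    AnnotationSet,
)

__all__ = [
    "AssemblySim",
    "AnnotationSim",
    "OrthogroupSim",
    "HitSim",
    "PanelSim",
    "Manifest",
    "simulate_assembly",
    "simulate_annotation",
    "simulate_orthogroups",
    "simulate_hits",
    "simulate_panel_hits",
    "simulate_panel_dataset",
    "write_gff3",
    "write_orthogroups_tsv",
    "write_taxonomy_tsv",
    "write_clade_map",
    "write_coverage_tsv",
    "default_taxonomy",
    "PAPER_CLASS_DESIGN",
    "DEFAULT_SPECIES",
]

# ---------------------------------------------------------------------------
# Configuration


@dataclass
class AssemblySim:
    """Contig-level genome model.

    Lengths are log-normal (a long right tail of big contigs over many
    small ones, as in draft long-read assemblies); N runs model gap fill
    and masked tracts model repeat families found by a repeat masker.
    """

    n_contigs: int = 200
    length_log_mean: float = math.log(20_000.0)
    length_log_sigma: float = 0.9
    min_length: int = 1_000
    gc: float = 0.40
    n_run_rate: float = 2e-5            # expected N runs per bp
    n_run_length: tuple[int, int] = (10, 200)
    masked_fraction: float = 0.30
    masked_tract_length: tuple[int, int] = (200, 2_000)
    contamination_fraction: float = 0.20
    contaminant_gc_shift: float = 0.15
    coverage_mean: float = 40.0
    coverage_sd: float = 6.0
    contaminant_coverage_factor: float = 0.35

    def validate(self) -> None:
        for name in ("masked_fraction", "contamination_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0,1)")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")


@dataclass
class AnnotationSim:
    """Gene-model law: genes per contig, exons per gene, intron lengths."""

    genes_per_contig_mean: float = 2.5      # Poisson
    exon_count_mean: float = 4.0            # 1 + Poisson(mean - 1)
    exon_length_mean: float = 220.0         # lognormal, rounded to codons
    exon_length_sigma: float = 0.45
    intron_min: int = 30
    intron_max: int = 5_000                 # log-uniform between min and max
    intergenic_min: int = 100
    intergenic_max: int = 1_000
    max_retries: int = 20


@dataclass
class OrthogroupSim:
    """15-class clade-sharing design over a fixed species panel."""

    species: dict[str, list[str]] = field(default_factory=lambda: {
        c: list(sp) for c, sp in DEFAULT_SPECIES.items()
    })
    class_counts: dict[tuple[str, ...], int] = field(
        default_factory=lambda: dict(PAPER_CLASS_DESIGN)
    )
    subclades: dict[str, str] = field(default_factory=lambda: {
        "Nwestbladi": "Nemertodermatida",
        "Pnaikaiensis": "Acoela",
        "Sroscoffensis": "Acoela",
    })
    # (shared, unique-to-first-label, unique-to-second-label) over the focal
    # clade's orthogroups; labels sorted, so (both, Acoela, Nemertodermatida).
    within_focal: tuple[int, int, int] | None = (3923, 3768, 1389)
    focal_clade: str = "Acoelomorpha"
    species_presence_p: float = 0.6
    extra_genes_mean: float = 0.4           # counts are 1 + Poisson(this)

    def validate(self) -> None:
        for cls, n in self.class_counts.items():
            if n < 0:
                raise ValueError(f"negative class count for {cls}")
            for clade in cls:
                if not self.species.get(clade):
                    raise ValueError(f"class {cls}: clade {clade!r} has no species")


@dataclass
class HitSim:
    """Taxon-labelled alignment hits for decontamination."""

    host_phylum: str = "Xenacoelomorpha"
    no_hit_fraction: float = 0.15
    hits_per_contig_mean: float = 2.0       # 1 + Poisson
    host_bitscore_mean: float = 400.0
    noise_bitscore_mean: float = 60.0
    cross_hit_p: float = 0.3                # chance of a weak off-taxon hit


@dataclass
class PanelSim:
    """Excretory-gene panel design: which family is present in which
    species, and the per-clade architecture laws behind each family."""

    species: dict[str, str] = field(default_factory=lambda: {
        # species -> clade; a compact genome panel with annotation available
        "Chrysaora": "Cnidaria", "Nematostella": "Cnidaria",
        "Nwestbladi": "Acoelomorpha", "Pnaikaiensis": "Acoelomorpha",
        "Sroscoffensis": "Acoelomorpha",
        "Bfloridae": "Deuterostomia", "Drerio": "Deuterostomia",
        "Apectinifera": "Deuterostomia",
        "Dmelanogaster": "Protostomia", "Cteleta": "Protostomia",
        "Tricolia": "Protostomia", "Mmembranacea": "Protostomia",
        "Celegans": "Protostomia",
    })
    #: (family, clade) pairs that are absent (no passing hits, no gene model)
    absences: set[tuple[str, str]] = field(default_factory=lambda: {
        ("Osr", "Acoelomorpha"), ("Osr", "Cnidaria"),
        ("Nephrin", "Cnidaria"), ("Kirrel", "Cnidaria"),
        ("Eya", "Cnidaria"), ("POU3", "Cnidaria"), ("Sall", "Cnidaria"),
    })
    #: absences that GenBank nonetheless supports (presence matrix override)
    genbank: set[tuple[str, str]] = field(default_factory=lambda: {
        ("Nephrin", "Cnidaria"), ("Eya", "Cnidaria"), ("POU3", "Cnidaria"),
    })
    copies_per_species: int = 2
    #: family -> (baseline exons per gene, baseline mean exon length in bp)
    baseline: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "Nephrin": (10.0, 360.0), "Kirrel": (6.0, 360.0), "ZO1": (12.0, 380.0),
        "Eya": (6.0, 300.0), "Lhx1/5": (4.0, 300.0), "Osr": (2.0, 380.0),
        "POU3": (1.5, 600.0), "Sall": (3.0, 900.0), "Six1": (2.0, 450.0),
    })
    #: planted clade effects: (family, clade) -> multipliers applied to the
    #: baseline (exon-count factor, exon-length factor); mirror the kinds of
    #: shifts the analysis is meant to detect
    effects: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("Kirrel", "Acoelomorpha"): (1.0, 1.8),
            ("ZO1", "Deuterostomia"): (1.6, 1.3),
            ("ZO1", "Acoelomorpha"): (0.5, 1.0),
            ("ZO1", "Protostomia"): (1.0, 0.6),
            ("Eya", "Acoelomorpha"): (0.5, 1.6),
            ("Lhx1/5", "Acoelomorpha"): (1.0, 1.7),
            ("Sall", "Deuterostomia"): (1.0, 1.5),
            ("Osr", "Deuterostomia"): (1.0, 1.5),
            ("POU3", "Acoelomorpha"): (1.8, 1.0),
        }
    )
    exon_length_sigma: float = 0.18
    query_length: int = 400


# Species panel of the comparative design: 3 cnidarians, 3 acoelomorphs,
# 4 deuterostomes, 8 protostomes.
DEFAULT_SPECIES: dict[str, tuple[str, ...]] = {
    "Cnidaria": ("Chrysaora", "Nematostella", "Hydra"),
    "Acoelomorpha": ("Nwestbladi", "Pnaikaiensis", "Sroscoffensis"),
    "Deuterostomia": ("Bfloridae", "Drerio", "Apectinifera", "Hsapiens"),
    "Protostomia": (
        "Dmelanogaster", "Cteleta", "Tricolia", "Mmembranacea",
        "Celegans", "Lanatina", "Obimaculoides", "Tcastaneum",
    ),
}

#: Default 15-class orthogroup design. The counts realize the headline
#: proportions of the four-clade comparison this pipeline reproduces:
#: exclusives 1754/2101/7976/9573, 8,418 metazoan-shared + 2,318
#: bilaterian-shared = 10,736 shared orthogroups.
PAPER_CLASS_DESIGN: dict[tuple[str, ...], int] = {
    ("Cnidaria",): 1754,
    ("Acoelomorpha",): 2101,
    ("Deuterostomia",): 7976,
    ("Protostomia",): 9573,
    ("Acoelomorpha", "Cnidaria"): 33,
    ("Cnidaria", "Deuterostomia"): 342,
    ("Cnidaria", "Protostomia"): 545,
    ("Acoelomorpha", "Cnidaria", "Deuterostomia"): 100,
    ("Acoelomorpha", "Cnidaria", "Protostomia"): 150,
    ("Cnidaria", "Deuterostomia", "Protostomia"): 1515,
    ("Acoelomorpha", "Cnidaria", "Deuterostomia", "Protostomia"): 5733,
    ("Acoelomorpha", "Deuterostomia"): 165,
    ("Acoelomorpha", "Protostomia"): 391,
    ("Deuterostomia", "Protostomia"): 1355,
    ("Acoelomorpha", "Deuterostomia", "Protostomia"): 407,
}

#: taxid -> (superkingdom, kingdom, phylum). The host is a metazoan;
#: contaminants follow the usual suspects in wild-caught meiofauna.
TAXON_TABLE: dict[int, tuple[str, str, str]] = {
    1001: ("Eukaryota", "Metazoa", "Xenacoelomorpha"),
    7711: ("Eukaryota", "Metazoa", "Chordata"),
    6447: ("Eukaryota", "Metazoa", "Mollusca"),
    1224: ("Bacteria", "", "Proteobacteria"),
    976: ("Bacteria", "", "Bacteroidetes"),
    201174: ("Bacteria", "", "Actinobacteria"),
    1117: ("Bacteria", "", "Cyanobacteria"),
    1239: ("Bacteria", "", "Firmicutes"),
    4890: ("Eukaryota", "Fungi", "Ascomycota"),
    5204: ("Eukaryota", "Fungi", "Basidiomycota"),
    3041: ("Eukaryota", "Viridiplantae", "Chlorophyta"),
    2763: ("Eukaryota", "Viridiplantae", "Rhodophyta"),
}

HOST_TAXIDS = (1001, 7711, 6447)
CONTAMINANT_TAXIDS = tuple(
    t for t in TAXON_TABLE if t not in HOST_TAXIDS
)


def default_taxonomy() -> TaxonomyMap:
    return TaxonomyMap({
        taxid: [r for r in
                (("superkingdom", sk), ("kingdom", k), ("phylum", ph)) if r[1]]
        for taxid, (sk, k, ph) in TAXON_TABLE.items()
    })


# ---------------------------------------------------------------------------
# Manifest


@dataclass
class Manifest:
    """Exact ground truth realized by a generation run."""

    seed: int | None = None
    contigs: dict[str, dict] = field(default_factory=dict)
    genes: list[dict] = field(default_factory=list)
    orthogroups: dict[str, dict] = field(default_factory=dict)
    panel: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# Assembly

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].copy()


def _seq_stats(seq: str) -> dict:
    n = seq.count("N") + seq.count("n")
    masked = sum(seq.count(ch) for ch in "acgtn")
    gc = sum(seq.count(ch) for ch in "GCgc")
    return {
        "length": len(seq),
        "n_count": n,
        "masked_bp": masked,
        "gc_bases": gc,
    }


def simulate_assembly(
    config: AssemblySim, rng: np.random.Generator | int
) -> tuple[Assembly, CoverageTable, Manifest]:
    """Generate a soft-masked draft assembly with planted contaminants.

    Deterministic for a given seed. The manifest records, per contig, the
    realized length, N count, masked bp, GC, contaminant status/taxid and
    simulated read coverage.
    """
    config.validate()
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    manifest = Manifest()
    lengths = np.maximum(
        config.min_length,
        rng.lognormal(config.length_log_mean, config.length_log_sigma,
                      config.n_contigs).astype(int),
    )
    n_contam = int(round(config.contamination_fraction * config.n_contigs))
    contam_idx = set(
        rng.choice(config.n_contigs, size=n_contam, replace=False).tolist()
    )
    contigs: list[Contig] = []
    coverage_rows: dict[str, tuple[float, float]] = {}
    for i, length in enumerate(lengths):
        length = int(length)
        is_contam = i in contam_idx
        gc = config.gc + (config.contaminant_gc_shift if is_contam else 0.0)
        arr = _random_bases(rng, length, min(gc, 0.95))
        # soft-masked repeat tracts
        if config.masked_fraction > 0:
            lo, hi = config.masked_tract_length
            target = config.masked_fraction * length
            masked_sofar = 0
            while masked_sofar < target:
                tlen = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, max(1, length - tlen)))
                arr[start : start + tlen] |= 0x20  # lowercase
                masked_sofar += tlen
        # N runs (gap fill)
        n_runs = rng.poisson(config.n_run_rate * length)
        for _ in range(n_runs):
            rlen = int(rng.integers(*config.n_run_length))
            start = int(rng.integers(0, max(1, length - rlen)))
            arr[start : start + rlen] = ord("N")
        seq = arr.tobytes().decode("ascii")
        cid = f"contig_{i + 1:05d}"
        contigs.append(Contig(cid, seq))
        cov = max(0.0, rng.normal(config.coverage_mean, config.coverage_sd))
        if is_contam:
            cov *= config.contaminant_coverage_factor
        st = _seq_stats(seq)
        gc_frac = (
            st["gc_bases"] / (st["length"] - st["n_count"])
            if st["length"] > st["n_count"] else 0.0
        )
        coverage_rows[cid] = (cov, gc_frac)
        taxid = (
            int(rng.choice(CONTAMINANT_TAXIDS)) if is_contam
            else int(rng.choice(HOST_TAXIDS))
        )
        manifest.contigs[cid] = {
            **st,
            "gc_fraction": gc_frac,
            "is_contaminant": is_contam,
            "taxid": taxid,
            "taxon_phylum": TAXON_TABLE[taxid][2],
            "coverage": cov,
        }
    assembly = Assembly(contigs)
    manifest.totals["assembly"] = {
        "n_contigs": len(contigs),
        "total_length": assembly.total_length,
        "n_count": sum(c["n_count"] for c in manifest.contigs.values()),
        "masked_bp": sum(c["masked_bp"] for c in manifest.contigs.values()),
        "contaminant_contigs": n_contam,
        "contaminant_bp": sum(
            c["length"] for c in manifest.contigs.values() if c["is_contaminant"]
        ),
    }
    return assembly, CoverageTable(coverage_rows), manifest


# ---------------------------------------------------------------------------
# Annotation

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_CODONS), size=n_codons)
    return "".join(_CODONS[i] for i in idx)


def _log_uniform_int(rng, lo: int, hi: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


@dataclass
class _PlacedGene:
    gene_id: str
    tx_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_seq: str
    protein: str
    family: str | None


def _draw_exon_lengths(rng, k: int, mean: float, sigma: float) -> list[int]:
    lens = rng.lognormal(math.log(mean), sigma, size=k)
    return [max(30, 3 * int(round(x / 3.0))) for x in lens]


def _place_gene(
    rng, contig_len: int, cursor: int, exon_lens: list[int],
    intron_min: int, intron_max: int,
) -> tuple[list[tuple[int, int]], int] | None:
    """Lay exons left to right from ``cursor``; None when it does not fit."""
    introns = [
        _log_uniform_int(rng, intron_min, intron_max)
        for _ in range(len(exon_lens) - 1)
    ]
    span = sum(exon_lens) + sum(introns)
    if cursor + span > contig_len:
        return None
    exons = []
    pos = cursor + 1  # 1-based start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el - 1))
        pos += el
        if i < len(introns):
            pos += introns[i]
    return exons, pos - 1


def _embed_cds(arr: np.ndarray, exons: list[tuple[int, int]],
               strand: str, cds: str) -> None:
    genomic = cds if strand == "+" else cds.encode()[::-1].translate(
        _COMPLEMENT).decode()
    off = 0
    for s, e in exons:
        ln = e - s + 1
        arr[s - 1 : e] = np.frombuffer(
            genomic[off : off + ln].encode(), dtype=np.uint8
        )
        off += ln


def simulate_annotation(
    assembly: Assembly,
    config: AnnotationSim,
    rng: np.random.Generator | int,
    species: str = "sim",
    planted: list[dict] | None = None,
    manifest: Manifest | None = None,
) -> tuple[AnnotationSet, dict[str, str], Assembly, Manifest]:
    """Annotate an assembly with multi-exon gene models.

    Stop-free CDS codons are embedded into the contig sequence (uppercase),
    so the written protein FASTA is the exact translation of the genomic
    exons and protein length = total CDS length / 3. ``planted`` entries
    (dicts with ``family``, ``n_exons``, ``exon_length_mean``) force
    specific panel genes with known architecture; each is retried on fresh
    contigs up to ``config.max_retries`` times, then is a hard error.

    Returns ``(annotation, proteins, updated_assembly, manifest)``; contig
    composition stats in the manifest are recomputed after embedding.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    manifest = manifest if manifest is not None else Manifest()
    arrays = {
        c.id: np.frombuffer(c.seq.encode(), dtype=np.uint8).copy()
        for c in assembly
    }
    lengths = {c.id: len(c) for c in assembly}
    cursors = {c.id: 0 for c in assembly}
    placed: list[_PlacedGene] = []
    gene_no = 0

    def new_ids():
        nonlocal gene_no
        gene_no += 1
        gid = f"{species}_g{gene_no:05d}"
        return gid, gid + ".t1"

    def try_place(cid: str, exon_lens: list[int]) -> list[tuple[int, int]] | None:
        gap = int(rng.integers(config.intergenic_min, config.intergenic_max + 1))
        res = _place_gene(
            rng, lengths[cid], cursors[cid] + gap, exon_lens,
            config.intron_min, config.intron_max,
        )
        if res is None:
            return None
        exons, end = res
        cursors[cid] = end
        return exons

    def realize(cid: str, exon_lens: list[int], family: str | None):
        exons = try_place(cid, exon_lens)
        if exons is None:
            return False
        strand = "+" if rng.random() < 0.5 else "-"
        n_codons = sum(e - s + 1 for s, e in exons) // 3
        cds = _random_cds(rng, n_codons)
        _embed_cds(arrays[cid], exons, strand, cds)
        gid, tid = new_ids()
        placed.append(_PlacedGene(
            gene_id=gid, tx_id=tid, contig_id=cid, strand=strand,
            exons=exons, cds_seq=cds,
            protein=str(Seq(cds).translate()), family=family,
        ))
        return True

    # background genes
    for c in assembly:
        n_genes = rng.poisson(config.genes_per_contig_mean)
        for _ in range(n_genes):
            k = 1 + rng.poisson(max(0.0, config.exon_count_mean - 1.0))
            exon_lens = _draw_exon_lengths(
                rng, k, config.exon_length_mean, config.exon_length_sigma
            )
            for _ in range(config.max_retries):
                if realize(c.id, exon_lens, None):
                    break
                if len(exon_lens) > 1:
                    exon_lens = exon_lens[:-1]
            # unplaceable background genes are simply dropped

    # planted panel genes
    for spec in planted or []:
        k = int(spec["n_exons"])
        exon_lens = spec.get("exon_lengths") or _draw_exon_lengths(
            rng, k, spec["exon_length_mean"], spec.get("exon_length_sigma", 0.2)
        )
        ok = False
        for _ in range(config.max_retries):
            cid = assembly.ids[int(rng.integers(0, len(assembly)))]
            if realize(cid, list(exon_lens), spec["family"]):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place planted gene {spec['family']!r}: "
                "contigs too short for the requested architecture"
            )

    genes = []
    proteins: dict[str, str] = {}
    for pg in placed:
        tx = Transcript(
            pg.tx_id,
            exons=[Interval(s, e) for s, e in pg.exons],
            cds=[Interval(s, e) for s, e in pg.exons],
            strand=pg.strand,
        )
        genes.append(GeneModel(
            id=pg.gene_id, contig_id=pg.contig_id,
            transcripts=[tx], representative=pg.tx_id,
        ))
        proteins[pg.tx_id] = pg.protein
        n_ex = len(pg.exons)
        exon_total = sum(e - s + 1 for s, e in pg.exons)
        manifest.genes.append({
            "gene_id": pg.gene_id,
            "tx_id": pg.tx_id,
            "species": species,
            "contig_id": pg.contig_id,
            "strand": pg.strand,
            "family": pg.family,
            "exons": pg.exons,
            "n_exons": n_ex,
            "exon_total_bp": exon_total,
            "mean_exon_length": exon_total / n_ex,
            "intron_lengths": [
                pg.exons[i + 1][0] - pg.exons[i][1] - 1
                for i in range(n_ex - 1)
            ],
            "protein_length": len(pg.protein),
        })

    new_contigs = [
        Contig(c.id, arrays[c.id].tobytes().decode("ascii")) for c in assembly
    ]
    new_assembly = Assembly(new_contigs)
    for c in new_contigs:
        st = _seq_stats(c.seq)
        entry = manifest.contigs.setdefault(c.id, {})
        entry.update(st)
        entry["gc_fraction"] = (
            st["gc_bases"] / (st["length"] - st["n_count"])
            if st["length"] > st["n_count"] else 0.0
        )
    per_contig_genes: dict[str, int] = {c.id: 0 for c in new_contigs}
    for pg in placed:
        per_contig_genes[pg.contig_id] += 1
    manifest.totals["annotation"] = {
        "n_genes": len(placed),
        "genes_per_contig": per_contig_genes,
        "mean_exons_per_gene": (
            sum(len(p.exons) for p in placed) / len(placed) if placed else 0.0
        ),
        "intron_lengths_n": sum(len(p.exons) - 1 for p in placed),
    }
    return AnnotationSet(genes), proteins, new_assembly, manifest


def write_gff3(annotation: AnnotationSet, path) -> None:
    """Minimal GFF3 writer for simulated gene models (exon == CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            for t in g.transcripts:
                gstart = min(e.start for e in t.exons)
                gend = max(e.end for e in t.exons)
                fh.write(
                    f"{g.contig_id}\tsim\tgene\t{gstart}\t{gend}\t.\t"
                    f"{t.strand}\t.\tID={g.id}\n"
                )
                fh.write(
                    f"{g.contig_id}\tsim\tmRNA\t{gstart}\t{gend}\t.\t"
                    f"{t.strand}\t.\tID={t.id};Parent={g.id}\n"
                )
                exons = t.exons if t.strand == "+" else list(reversed(t.exons))
                phase = 0
                for i, e in enumerate(t.exons, 1):
                    fh.write(
                        f"{g.contig_id}\tsim\texon\t{e.start}\t{e.end}\t.\t"
                        f"{t.strand}\t.\tID={t.id}.exon{i};Parent={t.id}\n"
                    )
                for e in exons:
                    fh.write(
                        f"{g.contig_id}\tsim\tCDS\t{e.start}\t{e.end}\t.\t"
                        f"{t.strand}\t{phase}\tID={t.id}.cds;Parent={t.id}\n"
                    )
                    phase = (3 - ((len(e) - phase) % 3)) % 3


def write_protein_fasta(proteins: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Orthogroups


def simulate_orthogroups(
    config: OrthogroupSim, rng: np.random.Generator | int
) -> tuple[OrthogroupTable, CladeAssignment, dict[str, dict[str, list[str]]], Manifest]:
    """Realize the configured 15-class clade-sharing design exactly.

    Within a class, species occupancy is drawn uniformly subject to every
    clade of the class being hit by at least one species; the optional
    ``within_focal`` triple additionally constrains how the focal clade's
    orthogroups split between its two subclades. Returns the table, the
    clade map, the per-orthogroup gene-id lists (for TSV writing) and the
    manifest.
    """
    config.validate()
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    manifest = Manifest()
    clade_map = {
        sp: clade for clade, sps in config.species.items() for sp in sps
    }
    species_order = [sp for sps in config.species.values() for sp in sps]

    # per-orthogroup clade classes, deterministic order then realized
    classes: list[tuple[str, ...]] = []
    for cls in sorted(config.class_counts):
        classes.extend([cls] * config.class_counts[cls])

    # subclade labels for focal-clade-containing orthogroups
    focal = config.focal_clade
    focal_labels: dict[int, str] | None = None
    if config.within_focal is not None and config.subclades:
        sub_names = sorted(set(config.subclades.values()))
        if len(sub_names) != 2:
            raise ValueError("subclades must define exactly two labels")
        focal_ogs = [i for i, cls in enumerate(classes) if focal in cls]
        shared, uniq_a, uniq_b = config.within_focal
        if shared + uniq_a + uniq_b != len(focal_ogs):
            raise ValueError(
                f"within_focal must sum to the focal clade's orthogroup "
                f"count ({len(focal_ogs)}), got {shared + uniq_a + uniq_b}"
            )
        labels = (["both"] * shared + [sub_names[0]] * uniq_a
                  + [sub_names[1]] * uniq_b)
        rng.shuffle(labels)
        focal_labels = dict(zip(focal_ogs, labels))

    by_subclade = {
        lab: [sp for sp, l in config.subclades.items() if l == lab]
        for lab in set(config.subclades.values())
    }

    def pick_species(pool: list[str]) -> list[str]:
        chosen = [sp for sp in pool if rng.random() < config.species_presence_p]
        if not chosen:
            chosen = [pool[int(rng.integers(0, len(pool)))]]
        return chosen

    counts: dict[str, dict[str, int]] = {}
    gene_lists: dict[str, dict[str, list[str]]] = {}
    width = len(str(len(classes)))
    for i, cls in enumerate(classes):
        og = f"OG{i:0{width}d}"
        row: dict[str, int] = {}
        genes: dict[str, list[str]] = {}
        for clade in cls:
            pool = list(config.species[clade])
            if clade == focal and focal_labels is not None:
                lab = focal_labels[i]
                if lab == "both":
                    subs = sorted(by_subclade)
                    chosen = []
                    for s in subs:
                        chosen.extend(pick_species(by_subclade[s]))
                else:
                    chosen = pick_species(by_subclade[lab])
            else:
                chosen = pick_species(pool)
            for sp in chosen:
                n = 1 + int(rng.poisson(config.extra_genes_mean))
                row[sp] = n
                genes[sp] = [f"{sp}_{og}_g{j + 1}" for j in range(n)]
        counts[og] = row
        gene_lists[og] = genes
        manifest.orthogroups[og] = {
            "clades": sorted(cls),
            "species": sorted(row),
            "focal_label": focal_labels.get(i) if focal_labels else None,
        }
    table = OrthogroupTable(counts=counts, species=species_order)
    manifest.totals["orthogroups"] = {
        "n_orthogroups": len(classes),
        "class_counts": {";".join(cls): n for cls, n in
                         sorted(config.class_counts.items())},
        "per_species_genes": {
            sp: sum(row.get(sp, 0) for row in counts.values())
            for sp in species_order
        },
        "within_focal": config.within_focal,
    }
    clades = CladeAssignment(clade=clade_map, subclade=dict(config.subclades))
    return table, clades, gene_lists, manifest


def write_orthogroups_tsv(
    gene_lists: dict[str, dict[str, list[str]]], species: list[str], path
) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(species) + "\n")
        for og in gene_lists:
            cells = [", ".join(gene_lists[og].get(sp, [])) for sp in species]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


def write_clade_map(clades: CladeAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tclade\tsubclade\n")
        for sp, clade in clades.clade.items():
            fh.write(f"{sp}\t{clade}\t{clades.subclade.get(sp, '')}\n")


def write_taxonomy_tsv(path, taxa: dict[int, tuple[str, str, str]] | None = None) -> None:
    taxa = taxa or TAXON_TABLE
    with open(path, "w") as fh:
        fh.write("taxid\tsuperkingdom\tkingdom\tphylum\n")
        for taxid, (sk, k, ph) in sorted(taxa.items()):
            fh.write(f"{taxid}\t{sk}\t{k}\t{ph}\n")


def write_coverage_tsv(coverage: CoverageTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tcoverage\tgc\n")
        for cid, (cov, gc) in coverage.rows.items():
            fh.write(f"{cid}\t{cov:.3f}\t{gc:.4f}\n")


# ---------------------------------------------------------------------------
# Hits


def simulate_hits(
    manifest: Manifest, config: HitSim, rng: np.random.Generator | int
) -> tuple[list[HitRecord], TaxonomyMap]:
    """Taxon-labelled contig hits consistent with the assembly manifest.

    Contaminant contigs receive their planted foreign taxon's bitscore
    mass (plus an occasional weak metazoan cross-hit); host contigs the
    reverse. A seeded fraction of host contigs gets no hits at all; the
    manifest records, per contig, whether any hit was emitted and which
    taxon carries the best summed bitscore.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    taxonomy = default_taxonomy()
    hits: list[HitRecord] = []
    for cid, info in manifest.contigs.items():
        if not info["is_contaminant"] and rng.random() < config.no_hit_fraction:
            info["has_hits"] = False
            continue
        info["has_hits"] = True
        main_taxid = info["taxid"]
        n_hits = 1 + int(rng.poisson(config.hits_per_contig_mean))
        for j in range(n_hits):
            bs = max(40.0, rng.normal(config.host_bitscore_mean, 60.0))
            aln = int(rng.integers(80, 400))
            hits.append(HitRecord(
                query_id=cid,
                subject_id=f"sub_{main_taxid}_{j}",
                percent_identity=float(rng.uniform(55, 95)),
                evalue=float(10 ** rng.uniform(-60, -10)),
                bitscore=float(bs),
                subject_taxid=main_taxid,
                aln_length=aln,
                qstart=1, qend=aln,
            ))
        if rng.random() < config.cross_hit_p:
            other = int(rng.choice(
                HOST_TAXIDS if info["is_contaminant"] else CONTAMINANT_TAXIDS
            ))
            aln = int(rng.integers(40, 120))
            hits.append(HitRecord(
                query_id=cid,
                subject_id=f"sub_{other}_x",
                percent_identity=float(rng.uniform(40, 70)),
                evalue=float(10 ** rng.uniform(-8, -3)),
                bitscore=float(
                    max(25.0, rng.normal(config.noise_bitscore_mean, 15.0))
                ),
                subject_taxid=other,
                aln_length=aln,
                qstart=1, qend=aln,
            ))
    manifest.totals["hits"] = {
        "n_hits": len(hits),
        "no_hit_contigs": sum(
            1 for i in manifest.contigs.values() if not i.get("has_hits", False)
        ),
    }
    return hits, taxonomy


def simulate_panel_hits(
    config: PanelSim, rng: np.random.Generator | int
) -> tuple[dict[str, list[HitRecord]], dict[str, int], dict[str, str], Manifest]:
    """Per-species panel-query hit tables with planted absences.

    Present (family, species) pairs get 1-3 hits passing the default
    thresholds; absent pairs get either nothing or a single sub-threshold
    hit. Returns ``(hits_by_species, query_lengths, query_family, manifest)``.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    manifest = Manifest()
    queries = {f"{fam.replace('/', '_')}_query": fam for fam in
               ["Nephrin", "Kirrel", "ZO1", "Eya", "Lhx1/5", "Osr",
                "POU3", "Sall", "Six1"]}
    qlen = {q: config.query_length for q in queries}
    by_species: dict[str, list[HitRecord]] = {}
    for sp, clade in config.species.items():
        rows: list[HitRecord] = []
        for q, fam in queries.items():
            present = (fam, clade) not in config.absences
            manifest.panel[f"{fam}|{sp}"] = {
                "family": fam, "species": sp, "clade": clade,
                "present": present,
            }
            if present:
                for j in range(int(rng.integers(1, 4))):
                    span = int(config.query_length * rng.uniform(0.6, 1.0))
                    start = int(rng.integers(1, config.query_length - span + 2))
                    rows.append(HitRecord(
                        query_id=q, subject_id=f"{sp}_prot_{fam}_{j}",
                        percent_identity=float(rng.uniform(60, 95)),
                        evalue=float(10 ** rng.uniform(-80, -20)),
                        bitscore=float(rng.uniform(200, 900)),
                        subject_taxid=1001,
                        aln_length=span, qstart=start, qend=start + span - 1,
                    ))
            elif rng.random() < 0.5:
                # a spurious weak hit that must fail the thresholds
                span = int(config.query_length * rng.uniform(0.1, 0.3))
                rows.append(HitRecord(
                    query_id=q, subject_id=f"{sp}_prot_weak",
                    percent_identity=float(rng.uniform(30, 50)),
                    evalue=float(10 ** rng.uniform(-4, -1)),
                    bitscore=float(rng.uniform(25, 45)),
                    subject_taxid=1001,
                    aln_length=span, qstart=1, qend=span,
                ))
        by_species[sp] = rows
    return by_species, qlen, queries, manifest


# ---------------------------------------------------------------------------
# Engineered fixtures: deterministic objects with exact printed totals


def engineered_assembly(n_contigs: int, total_bp: int, n_bp: int = 0) -> Assembly:
    """A homopolymer assembly with exact contig count, total length and
    N content — for checking derived summary cells against printed tables
    where only the counts matter, not the sequence."""
    if n_contigs < 1 or total_bp < n_contigs or n_bp > total_bp:
        raise ValueError("infeasible engineered assembly")
    base, extra = divmod(total_bp, n_contigs)
    contigs = []
    n_left = n_bp
    for i in range(n_contigs):
        length = base + (1 if i < extra else 0)
        use_n = min(n_left, length)
        n_left -= use_n
        contigs.append(
            Contig(f"c{i + 1:05d}", "N" * use_n + "A" * (length - use_n))
        )
    return Assembly(contigs)


def engineered_gene_spread(
    n_genes: int, universe: list[str], species: str = "x"
) -> AnnotationSet:
    """Minimal single-exon gene models spread round-robin over a contig
    universe — for genes-per-contig means over universes that include
    gene-less contigs."""
    genes = []
    for i in range(n_genes):
        cid = universe[i % max(1, len(universe) // 2)]  # leave some gene-less
        tx = Transcript(f"{species}_g{i}.t1", exons=[Interval(1, 300)],
                        cds=[Interval(1, 300)])
        genes.append(GeneModel(f"{species}_g{i}", cid, [tx], f"{species}_g{i}.t1"))
    return AnnotationSet(genes, contig_universe=set(universe))


# ---------------------------------------------------------------------------
# Panel dataset (per-species genomes + annotations for architecture work)


def simulate_panel_dataset(
    config: PanelSim,
    rng: np.random.Generator | int,
    annotation_config: AnnotationSim | None = None,
):
    """Per-species mini-genomes whose annotations carry the panel genes.

    For every species, a small assembly is generated and the present
    panel families are planted with clade-specific architecture laws
    (baseline exon count / exon length scaled by the configured effect
    multipliers). Yields a dict: species -> (annotation, proteins,
    assembly, manifest, panel_gene_ids) where ``panel_gene_ids`` maps
    planted gene ids to families.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    ann_cfg = annotation_config or AnnotationSim(
        genes_per_contig_mean=0.5, exon_count_mean=3.0,
        intron_max=1_500,
    )
    out = {}
    for sp, clade in config.species.items():
        asm_cfg = AssemblySim(
            n_contigs=30,
            length_log_mean=math.log(60_000.0),
            length_log_sigma=0.3,
            min_length=30_000,
            contamination_fraction=0.0,
            masked_fraction=0.05,
            n_run_rate=0.0,
        )
        assembly, _, manifest = simulate_assembly(asm_cfg, rng)
        planted = []
        for fam, (base_k, base_len) in config.baseline.items():
            if (fam, clade) in config.absences:
                continue
            k_factor, len_factor = config.effects.get((fam, clade), (1.0, 1.0))
            for _ in range(config.copies_per_species):
                k = max(1, int(round(rng.normal(base_k * k_factor, 0.8))))
                planted.append({
                    "family": fam,
                    "n_exons": k,
                    "exon_length_mean": base_len * len_factor,
                    "exon_length_sigma": config.exon_length_sigma,
                })
        annotation, proteins, assembly2, manifest = simulate_annotation(
            assembly, ann_cfg, rng, species=sp, planted=planted,
            manifest=manifest,
        )
        panel_ids = {
            g["gene_id"]: g["family"]
            for g in manifest.genes if g["family"] is not None
        }
        out[sp] = (annotation, proteins, assembly2, manifest, panel_ids)
    return out
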