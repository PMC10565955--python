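"""Readers and writers for the external formats the pipeline consumes.

FASTA goes through Biopython, GFF3 through gffutils (two-pass ID/Parent
resolution, so feature order does not matter), tabular formats through
pandas. All readers accept plain or gzip-compressed input, reject
structurally invalid files rather than repairing them, and preserve
sequence case.
"""

from __future__ import annotations

import gzip
import io as _io
import os
import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO

from .types import (
    Assembly,
    CladeAssignment,
    Contig,
    CoverageTable,
    GeneModel,
    HitRecord,
    Interval,
    OrthogroupTable,
    TaxonomyMap,
    Transcript,
    pick_representative,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "GffWarnings",
    "read_orthogroups_tsv",
    "read_hits_tsv",
    "write_hits_tsv",
    "read_taxonomy_tsv",
    "read_clade_map",
    "read_coverage_tsv",
]

HITS_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "staxid",
]


def _open_text(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> Assembly:
    """Read a (possibly gzipped) FASTA into an :class:`Assembly`.

    The header token before the first whitespace becomes the contig id;
    contig order and sequence case are preserved. Duplicate ids and empty
    records are hard errors.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
            seq = str(rec.seq)
            if not seq:
                raise ValueError(f"empty sequence record in {path}: {rec.id!r}")
            seen.add(rec.id)
            contigs.append(Contig(rec.id, seq))
    return Assembly(contigs)


def read_protein_fasta(path) -> dict[str, str]:
    """Protein FASTA as an id -> sequence map (no nucleotide alphabet check)."""
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
            out[rec.id] = str(rec.seq)
    return out


def write_fasta(assembly: Assembly, path, width: int = 60) -> None:
    """Write contigs in input order, wrapped at ``width`` columns."""
    with _open_text(path, "wt") as fh:
        for c in assembly:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

@dataclass
class GffWarnings:
    """Non-fatal problems collected while reading a GFF3 file."""

    orphan_features: list[tuple[str, str]] = field(default_factory=list)
    skipped_transcripts: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.orphan_features) + len(self.skipped_transcripts)


_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def read_gff3(path, id_attribute: str = "ID"):
    """Parse gene/mRNA/exon(/CDS) models from a GFF3 file.

    Coordinates stay 1-based inclusive. Exons are grouped per transcript
    and sorted; a transcript with CDS children but no exon children gets
    exons synthesized from its CDS intervals. The representative
    transcript per gene is the one with the longest summed CDS length
    (ties: smallest transcript id). Features whose Parent cannot be
    resolved are skipped and recorded in the warnings report; a feature
    with end < start is a hard error.

    Returns ``(AnnotationSet, GffWarnings)``.
    """
    from .types import AnnotationSet

    report = GffWarnings()

    with _open_text(path) as fh:
        text = fh.read()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )

    for feat in db.all_features():
        if feat.end < feat.start:
            raise ValueError(
                f"{path}: feature {feat.id!r} has end < start "
                f"({feat.start}..{feat.end})"
            )

    known_tx = {
        f.id for f in db.all_features() if f.featuretype in _TRANSCRIPT_TYPES
    }
    known_genes = {f.id for f in db.all_features() if f.featuretype == "gene"}

    # orphan exon/CDS: Parent points at a transcript the file never defines
    for feat in db.all_features():
        if feat.featuretype in ("exon", "CDS"):
            parents = feat.attributes.get("Parent", [])
            if not parents or all(p not in known_tx for p in parents):
                report.orphan_features.append(
                    (feat.featuretype, feat.attributes.get("ID", [feat.id])[0])
                )
        elif feat.featuretype in _TRANSCRIPT_TYPES:
            parents = feat.attributes.get("Parent", [])
            if parents and all(p not in known_genes for p in parents):
                report.skipped_transcripts.append((feat.id, "missing parent gene"))

    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene", order_by="start"):
        gid = gf.attributes.get(id_attribute, [gf.id])[0]
        transcripts: list[Transcript] = []
        for tf in db.children(gf, level=1):
            if tf.featuretype not in _TRANSCRIPT_TYPES:
                continue
            exons = [
                Interval(c.start, c.end)
                for c in db.children(tf, featuretype="exon", order_by="start")
            ]
            cds = [
                Interval(c.start, c.end)
                for c in db.children(tf, featuretype="CDS", order_by="start")
            ]
            if not exons and cds:
                exons = list(cds)
            if not exons:
                report.skipped_transcripts.append((tf.id, "no exon or CDS children"))
                continue
            try:
                transcripts.append(
                    Transcript(tf.id, exons=exons, cds=cds, strand=tf.strand)
                )
            except ValueError as exc:  # e.g. overlapping exons
                report.skipped_transcripts.append((tf.id, str(exc)))
        if not transcripts:
            report.skipped_transcripts.append((gid, "gene without usable transcripts"))
            continue
        genes.append(
            GeneModel(
                id=gid,
                contig_id=gf.seqid,
                transcripts=transcripts,
                representative=pick_representative(transcripts),
            )
        )
    return AnnotationSet(genes=genes), report


# ---------------------------------------------------------------------------
# Orthogroups TSV (OrthoFinder Orthogroups.tsv dialect)

def read_orthogroups_tsv(path, species_list: list[str] | None = None) -> OrthogroupTable:
    """Read an "orthogroup x species -> comma-separated gene list" table.

    Cell count = number of comma-separated tokens after trimming; an empty
    or all-whitespace cell is 0. A duplicated orthogroup id is a hard error.
    """
    df = pd.read_csv(_open_text(path), sep="\t", dtype=str, keep_default_na=False)
    species = list(df.columns[1:])
    if species_list is not None:
        missing = [s for s in species_list if s not in species]
        if missing:
            raise ValueError(f"species missing from {path}: {missing}")
        species = list(species_list)
    og_col = df.columns[0]
    counts: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        og = row[og_col]
        if og in counts:
            raise ValueError(f"duplicate orthogroup id in {path}: {og!r}")
        cell_counts: dict[str, int] = {}
        for sp in species:
            cell = row[sp].strip()
            if cell:
                cell_counts[sp] = len([t for t in cell.split(",") if t.strip()])
        counts[og] = cell_counts
    return OrthogroupTable(counts=counts, species=species)


# ---------------------------------------------------------------------------
# Alignment hits (12-column outfmt 6 + subject taxid)

def read_hits_tsv(path) -> list[HitRecord]:
    """Parse 13-column tabular hits; invalid numerics fail with a line number."""
    try:
        df = pd.read_csv(
            _open_text(path), sep="\t", header=None, names=HITS_COLUMNS, dtype=str
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != len(HITS_COLUMNS):
        raise ValueError(f"{path}: expected 13 tab-separated columns")
    numeric = ["pident", "length", "mismatch", "gapopen", "qstart", "qend",
               "sstart", "send", "evalue", "bitscore", "staxid"]
    conv = {c: pd.to_numeric(df[c], errors="coerce") for c in numeric}
    for c in numeric:
        bad = conv[c].isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(
                f"{path}: non-numeric value {df[c][bad.idxmax()]!r} "
                f"in column {c!r} at line {line}"
            )
        if conv[c].isna().any():
            line = int(conv[c].isna().idxmax()) + 1
            raise ValueError(f"{path}: missing value in column {c!r} at line {line}")
    records = []
    for i in range(len(df)):
        records.append(
            HitRecord(
                query_id=df["qseqid"].iat[i],
                subject_id=df["sseqid"].iat[i],
                percent_identity=float(conv["pident"].iat[i]),
                evalue=float(conv["evalue"].iat[i]),
                bitscore=float(conv["bitscore"].iat[i]),
                subject_taxid=int(conv["staxid"].iat[i]),
                aln_length=int(conv["length"].iat[i]),
                qstart=int(conv["qstart"].iat[i]),
                qend=int(conv["qend"].iat[i]),
            )
        )
    return records


def write_hits_tsv(records: list[HitRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            mism = max(0, round(r.aln_length * (1 - r.percent_identity / 100.0)))
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.subject_id, f"{r.percent_identity:.1f}",
                        r.aln_length, mism, 0, r.qstart, r.qend,
                        1, max(1, r.aln_length), f"{r.evalue:.2e}",
                        f"{r.bitscore:.1f}", r.subject_taxid,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Taxonomy, clade map, coverage

def read_taxonomy_tsv(path) -> TaxonomyMap:
    """Read a taxid -> ranked-lineage table.

    Header: ``taxid`` followed by rank names (at least superkingdom,
    kingdom, phylum); lineage order follows column order; empty cells mean
    the rank is absent for that taxid.
    """
    df = pd.read_csv(_open_text(path), sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "taxid":
        raise ValueError(f"{path}: first column must be 'taxid'")
    ranks = list(df.columns[1:])
    required = {"superkingdom", "kingdom", "phylum"}
    if not required.issubset(ranks):
        raise ValueError(f"{path}: rank columns must include {sorted(required)}")
    lineages: dict[int, list[tuple[str, str]]] = {}
    for _, row in df.iterrows():
        taxid = int(row["taxid"])
        lineages[taxid] = [(r, row[r]) for r in ranks if row[r]]
    return TaxonomyMap(lineages)


def read_clade_map(path) -> CladeAssignment:
    """Two- (or three-) column TSV: species, clade [, subclade]."""
    df = pd.read_csv(_open_text(path), sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    clade = dict(zip(df[cols[0]], df[cols[1]]))
    sub: dict[str, str] = {}
    if len(cols) >= 3:
        for sp, sc in zip(df[cols[0]], df[cols[2]]):
            if sc:
                sub[sp] = sc
    return CladeAssignment(clade=clade, subclade=sub)


def read_coverage_tsv(path) -> CoverageTable:
    """Three-column TSV: contig, mean coverage, GC fraction."""
    df = pd.read_csv(_open_text(path), sep="\t")
    cols = list(df.columns)
    rows = {
        str(r[cols[0]]): (float(r[cols[1]]), float(r[cols[2]]))
        for _, r in df.iterrows()
    }
    return CoverageTable(rows)
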