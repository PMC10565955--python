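#!/usr/bin/env python
"""Generate the synthetic study inputs for the downstream analyses.

Writes, under scratch/fixtures/ (bulky sequence data) and with the
ground-truth manifest alongside: a contaminated soft-masked assembly
with coverage and taxon-labelled contig hits; its gene annotation and
proteome; the four-clade orthogroup table with clade/subclade maps; and
the per-species excretory-panel mini-genomes with their hit tables.
"""

import json
import sys
from pathlib import Path

import numpy as np

from acoelgenomics import simulate as sim
from acoelgenomics.io import write_fasta, write_hits_tsv

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1]
FIX = ROOT / "scratch" / "fixtures"
FIX.mkdir(parents=True, exist_ok=True)

rng = np.random.default_rng(SEED)

# genome + annotation + decontamination inputs
assembly, coverage, manifest = sim.simulate_assembly(sim.AssemblySim(), rng)
annotation, proteins, assembly, manifest = sim.simulate_annotation(
    assembly, sim.AnnotationSim(), rng, species="simworm", manifest=manifest
)
hits, _ = sim.simulate_hits(manifest, sim.HitSim(), rng)
write_fasta(assembly, FIX / "assembly.fasta")
sim.write_gff3(annotation, FIX / "annotation.gff3")
sim.write_protein_fasta(proteins, FIX / "proteins.faa")
sim.write_coverage_tsv(coverage, FIX / "coverage.tsv")
sim.write_taxonomy_tsv(FIX / "taxonomy.tsv")
write_hits_tsv(hits, FIX / "contig_hits.tsv")

# orthogroup table realizing the four-clade sharing design
table, clades, gene_lists, og_manifest = sim.simulate_orthogroups(
    sim.OrthogroupSim(), rng
)
sim.write_orthogroups_tsv(gene_lists, table.species, FIX / "orthogroups.tsv")
sim.write_clade_map(clades, FIX / "clades.tsv")
manifest.orthogroups = og_manifest.orthogroups
manifest.totals.update(og_manifest.totals)

# excretory-panel dataset: per-species mini genomes + panel hit tables
panel_cfg = sim.PanelSim()
phits, qlen, qmap, pman = sim.simulate_panel_hits(panel_cfg, rng)
panel_dir = FIX / "panel"
panel_dir.mkdir(exist_ok=True)
panel_map_rows = []
for sp, rows in phits.items():
    write_hits_tsv(rows, panel_dir / f"{sp}.hits.tsv")
for sp, (ann, prots, asm, man, ids) in sim.simulate_panel_dataset(
    panel_cfg, rng
).items():
    sim.write_gff3(ann, panel_dir / f"{sp}.gff3")
    sim.write_protein_fasta(prots, panel_dir / f"{sp}.faa")
    panel_map_rows += [f"{sp}\t{gid}\t{fam}" for gid, fam in ids.items()]
    manifest.panel[sp] = {"planted_genes": ids}
(panel_dir / "panel_genes.tsv").write_text(
    "species\tgene_id\tfamily\n" + "\n".join(panel_map_rows) + "\n"
)
(panel_dir / "query_lengths.json").write_text(json.dumps(qlen))
(panel_dir / "query_families.json").write_text(json.dumps(qmap))
manifest.panel["presence_truth"] = pman.panel
manifest.seed = SEED
manifest.to_json(FIX / "manifest.json")

print(f"seed {SEED}: wrote fixtures to {FIX}")
print(f"  assembly: {len(assembly)} contigs, {assembly.total_length:,} bp "
      f"({manifest.totals['assembly']['contaminant_contigs']} planted contaminants)")
print(f"  annotation: {manifest.totals['annotation']['n_genes']} genes")
print(f"  orthogroups: {manifest.totals['orthogroups']['n_orthogroups']:,}")
print(f"  panel: {len(panel_cfg.species)} species x 9 families")
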