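# acoelgenomics

Comparative genomics of draft genomes from microscopic marine worms
(Acoelomorpha and relatives): assembly/annotation QC metrics,
taxon-based contig decontamination, a four-clade orthogroup gene-content
partition, and statistical comparison of excretory-system gene
architecture — as a tested Python library, a set of numbered analysis
drivers, and a CLI. All stages run end-to-end on synthetic data from a
seeded generator; no downloads are required.

It is aimed at people who have a draft assembly (FASTA), gene models
(GFF3), OrthoFinder-style orthogroup tables and tabular alignment hits,
and want the downstream comparative numbers with explicit, reproducible
conventions.

## What it computes

* **Assembly QC** — total length, N50 (cumulative ≥ half-total
  convention), N content, soft-masked (lowercase) fraction, GC over
  non-N bases, cumulative-length curves.
* **Annotation QC** — genes per contig (denominator = *all* contigs,
  gene-less included), exons per gene and intron lengths on a
  deterministic representative transcript (longest summed CDS, ties to
  smallest id), with parameterized exon-count outlier exclusion.
* **Decontamination** — best-sum bitscore taxon assignment per contig
  (`taxon* = argmax_t Σ bitscore(hits of t)` at a chosen rank), keep
  policy over lineages (default Metazoa + no-hit), contaminant
  breakdowns that conserve bp exactly.
* **Gene content** — orthogroup → clade-subset partition over
  {Cnidaria, Acoelomorpha, Deuterostomia, Protostomia}; per-clade
  exclusivity; disjoint metazoan (Cnidaria + ≥1 bilaterian clade) and
  bilaterian (≥2 bilaterian clades, no Cnidaria) shared sets; per-clade
  missing fractions; Acoela vs Nemertodermatida sharing.
* **Gene architecture** — per gene copy of the nine excretory-system
  families (Nephrin, Kirrel, ZO1; Eya, Lhx1/5, Osr, POU3, Sall, Six1):
  protein length, exons per protein, mean exon length; a single-pass
  fragment filter (protein < ½ × family mean length); and per
  family × metric the decision cascade

  Shapiro-Wilk (every group) + Bartlett → ANOVA (+ pairwise t,
  Bonferroni) or Kruskal-Wallis (+ Dunn's z with tie correction,
  Bonferroni), α = 0.05, with bracket (compact-letter) summaries.

* **Synthetic data** — seeded generators for all of the above with an
  exact ground-truth manifest (see `docs/methods.md`).

## Worked example

```
python analysis/01_simulate_data.py 1      # fixtures under scratch/fixtures/
python analysis/02_assembly_annotation_qc.py
python analysis/03_decontamination.py
python analysis/04_gene_content.py
python analysis/05_excretory_panel.py      # tables under results/
```

With seed 1 the chain prints (abridged):

```
200 contigs, 5.322 Mb, N50 36.3 kb, 25.8% soft-masked, N's 0.159%
501 genes, 2.505 genes/contig (max 7), 3.433 exons/gene (max 10)
kept 160/200 contigs (4.276 of 5.322 Mb); 19 no-hit contigs retained
agreement with planted truth: 100.0% (200/200)
Cnidaria: 1754/10172 exclusive (17.2%)
Acoelomorpha: 2101/9080 exclusive (23.1%)
shared in >=2 clades: 10736/32140 (33.4%) = 8418 metazoan + 2318 bilaterian
Acoelomorpha carries 71.5% of metazoan and 41.5% of bilaterian shared genes
within Acoelomorpha: 43.2% shared, 41.5% Acoela-only, 15.3% Nemertodermatida-only
15/27 family x metric comparisons significant (alpha 0.05); skipped: 0
  Kirrel   mean_exon_length   ANOVA  p=5.71e-12  brackets: Deuterostomia,Protostomia | Acoelomorpha
```

Reading this: the simulated 5.3 Mb draft carries 20% planted
contaminant contigs, all recovered by best-sum filtering; the orthogroup
table realizes the four-clade sharing design exactly (17.2% of
Cnidaria-present orthogroups are cnidarian-exclusive, the 10,736 shared
orthogroups split into disjoint metazoan/bilaterian sets); and the
architecture cascade isolates the clades with planted effects — e.g.
Kirrel's longer acoelomorph exons put Acoelomorpha in its own bracket.

The same operations are scriptable via the CLI:

```
acoelgen simulate all --seed 1 --out fixtures/
acoelgen stats assembly fixtures/assembly.fasta
acoelgen decontam --fasta fixtures/assembly.fasta --hits fixtures/contig_hits.tsv \
    --taxonomy fixtures/taxonomy.tsv --out-prefix dec
acoelgen gene-content --orthogroups fixtures/orthogroups.tsv --clades fixtures/clades.tsv
acoelgen report qc_genomeA.json qc_genomeB.json   # side-by-side table
```

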