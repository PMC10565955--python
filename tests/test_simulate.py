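import numpy as np
import pytest

from acoelgenomics import simulate as sim
from acoelgenomics.assembly import summarize_assembly
from acoelgenomics.types import Assembly


def test_same_seed_gives_identical_assembly_bytes():
    a1, c1, m1 = sim.simulate_assembly(sim.AssemblySim(n_contigs=30), 1)
    a2, c2, m2 = sim.simulate_assembly(sim.AssemblySim(n_contigs=30), 1)
    assert [c.seq for c in a1] == [c.seq for c in a2]
    assert c1.rows == c2.rows
    assert m1.contigs == m2.contigs


def test_different_seed_differs():
    a1, _, _ = sim.simulate_assembly(sim.AssemblySim(n_contigs=10), 1)
    a2, _, _ = sim.simulate_assembly(sim.AssemblySim(n_contigs=10), 2)
    assert [c.seq for c in a1] != [c.seq for c in a2]


def test_manifest_lists_configured_contig_count():
    _, _, man = sim.simulate_assembly(sim.AssemblySim(n_contigs=100), 5)
    assert len(man.contigs) == 100
    assert man.totals["assembly"]["n_contigs"] == 100


def test_infeasible_config_is_hard_error():
    with pytest.raises(ValueError):
        sim.simulate_assembly(sim.AssemblySim(masked_fraction=1.5), 1)
    with pytest.raises(ValueError):
        sim.simulate_assembly(sim.AssemblySim(n_contigs=0), 1)


def test_assembly_summary_equals_manifest_prediction(rng):
    a, _, man = sim.simulate_assembly(sim.AssemblySim(n_contigs=60), rng)
    s = summarize_assembly(a)
    t = man.totals["assembly"]
    assert (s.total_length, s.n_contigs) == (t["total_length"], t["n_contigs"])
    assert s.n_count == t["n_count"]
    assert s.masked_count == t["masked_bp"]
    for c in a:
        info = man.contigs[c.id]
        assert len(c) == info["length"]
        assert c.seq.count("N") + c.seq.count("n") == info["n_count"]


def test_single_exon_config_yields_no_introns(rng):
    a, _, _ = sim.simulate_assembly(sim.AssemblySim(n_contigs=15), rng)
    ann, _, _, man = sim.simulate_annotation(
        a, sim.AnnotationSim(exon_count_mean=1.0), rng
    )
    assert all(g.rep.n_exons == 1 for g in ann)
    assert man.totals["annotation"]["intron_lengths_n"] == 0


def test_planted_gene_architecture_recovered(rng):
    from acoelgenomics.architecture import extract_architecture

    a, _, _ = sim.simulate_assembly(
        sim.AssemblySim(n_contigs=5, min_length=20_000), rng
    )
    planted = [{"family": "Eya", "n_exons": 2, "exon_lengths": [90, 90]}]
    ann, prots, a2, man = sim.simulate_annotation(
        a, sim.AnnotationSim(genes_per_contig_mean=0.0), rng, planted=planted
    )
    ids = {g["gene_id"]: g["family"] for g in man.genes}
    recs, _ = extract_architecture(ann, prots, ids, "sp", "Cnidaria")
    assert (recs[0].n_exons, recs[0].mean_exon_length) == (2, 90.0)
    assert recs[0].protein_length == 60


def test_unplaceable_planted_gene_is_hard_error(rng):
    a, _, _ = sim.simulate_assembly(
        sim.AssemblySim(n_contigs=3, min_length=1_000,
                        length_log_mean=6.9, length_log_sigma=0.01), rng
    )
    planted = [{"family": "ZO1", "n_exons": 50, "exon_lengths": [900] * 50}]
    with pytest.raises(RuntimeError, match="too short"):
        sim.simulate_annotation(
            a, sim.AnnotationSim(genes_per_contig_mean=0.0), rng,
            planted=planted,
        )


def test_proteins_are_translations_of_embedded_cds(rng):
    from Bio.Seq import Seq

    a, _, _ = sim.simulate_assembly(sim.AssemblySim(n_contigs=10), rng)
    ann, prots, a2, _ = sim.simulate_annotation(a, sim.AnnotationSim(), rng)
    seqs = {c.id: c.seq for c in a2}
    for g in list(ann)[:25]:
        t = g.rep
        genomic = "".join(
            seqs[g.contig_id][e.start - 1 : e.end] for e in t.exons
        ).upper()
        cds = genomic if t.strand == "+" else str(Seq(genomic).reverse_complement())
        assert str(Seq(cds).translate()) == prots[t.id]
        assert "*" not in prots[t.id]


def test_orthogroup_design_realized_exactly(rng):
    design = {("Cnidaria",): 8, ("Acoelomorpha", "Protostomia"): 6}
    table, clades, _, man = sim.simulate_orthogroups(
        sim.OrthogroupSim(class_counts=design, within_focal=None), rng
    )
    assert len(table) == 14
    assert man.totals["orthogroups"]["class_counts"] == {
        "Cnidaria": 8, "Acoelomorpha;Protostomia": 6
    }


def test_orthogroup_class_with_no_species_is_hard_error():
    cfg = sim.OrthogroupSim(
        species={"Cnidaria": []},
        class_counts={("Cnidaria",): 1},
        within_focal=None,
    )
    with pytest.raises(ValueError, match="no species"):
        sim.simulate_orthogroups(cfg, 1)


def test_within_focal_mismatch_is_hard_error():
    cfg = sim.OrthogroupSim(
        class_counts={("Acoelomorpha",): 10},
        within_focal=(5, 4, 2),  # sums to 11, not 10
    )
    with pytest.raises(ValueError, match="within_focal"):
        sim.simulate_orthogroups(cfg, 1)


def test_orthogroups_deterministic_under_seed():
    t1, _, g1, _ = sim.simulate_orthogroups(
        sim.OrthogroupSim(class_counts={("Cnidaria", "Protostomia"): 20},
                          within_focal=None), 9)
    t2, _, g2, _ = sim.simulate_orthogroups(
        sim.OrthogroupSim(class_counts={("Cnidaria", "Protostomia"): 20},
                          within_focal=None), 9)
    assert t1.counts == t2.counts and g1 == g2


def test_contig_hits_respect_planted_taxa(rng):
    _, _, man = sim.simulate_assembly(
        sim.AssemblySim(n_contigs=40, contamination_fraction=0.5), rng
    )
    hits, tax = sim.simulate_hits(man, sim.HitSim(cross_hit_p=0.0), rng)
    from acoelgenomics.decontam import assign_taxa

    calls, _ = assign_taxa(hits, tax)
    for cid, call in calls.items():
        assert call.name == man.contigs[cid]["taxon_phylum"]


def test_panel_hits_planted_absence_has_no_passing_hit(rng):
    cfg = sim.PanelSim()
    hits, qlen, qmap, man = sim.simulate_panel_hits(cfg, rng)
    for sp, rows in hits.items():
        clade = cfg.species[sp]
        for h in rows:
            fam = qmap[h.query_id]
            if (fam, clade) in cfg.absences:
                passes = (h.evalue <= 1e-5
                          and h.query_span() / qlen[h.query_id] >= 0.5)
                assert not passes
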