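import numpy as np
import pytest

from acoelgenomics import simulate as sim
from acoelgenomics.types import (
    AnnotationSet,
    GeneModel,
    Interval,
    OrthogroupTable,
    CladeAssignment,
    Transcript,
)

CLADES = ("Acoelomorpha", "Cnidaria", "Deuterostomia", "Protostomia")


def make_gene(gid, contig, exons, cds=None, strand="+", tx_suffix=".t1"):
    tx = Transcript(
        gid + tx_suffix,
        exons=[Interval(s, e) for s, e in exons],
        cds=[Interval(s, e) for s, e in (cds if cds is not None else exons)],
        strand=strand,
    )
    return GeneModel(gid, contig, [tx], tx.id)


def make_annotation(genes, universe=None):
    return AnnotationSet(list(genes), contig_universe=universe)


def random_orthogroup_table(rng, n_og=200, presence_p=0.35):
    """Random presence/absence table over the default 18-species panel."""
    species = [sp for sps in sim.DEFAULT_SPECIES.values() for sp in sps]
    counts = {}
    for i in range(n_og):
        row = {
            sp: int(rng.integers(1, 4))
            for sp in species
            if rng.random() < presence_p
        }
        if not row:
            row = {species[int(rng.integers(0, len(species)))]: 1}
        counts[f"OG{i:04d}"] = row
    clade_map = {
        sp: clade for clade, sps in sim.DEFAULT_SPECIES.items() for sp in sps
    }
    return (
        OrthogroupTable(counts=counts, species=species),
        CladeAssignment(clade=clade_map),
    )


@pytest.fixture(scope="session")
def paper_design_partition():
    """The default 15-class orthogroup design, realized and partitioned."""
    from acoelgenomics.gene_content import partition_by_clade

    table, clades, _, manifest = sim.simulate_orthogroups(sim.OrthogroupSim(), 1)
    return table, clades, partition_by_clade(table, clades), manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
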