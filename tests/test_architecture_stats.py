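import math

import numpy as np
import pytest
from scipy import stats

from acoelgenomics import simulate as sim
from acoelgenomics.architecture import (
    ABSENT,
    ANNOTATED,
    GENBANK,
    NO_DATA,
    ArchitectureRecord,
    build_presence_matrix,
    compare_clades,
    dunn_test,
    extract_architecture,
    fragment_filter,
    run_panel_comparison,
)
from acoelgenomics.types import HitRecord
from conftest import make_annotation, make_gene


def rec(clade, value, family="F", metric="mean_exon_length", species="sp", i=[0]):
    i[0] += 1
    kwargs = dict(protein_length=500, n_exons=3, mean_exon_length=200.0)
    kwargs[metric] = value
    return ArchitectureRecord(
        species=species, clade=clade, family=family, gene_id=f"g{i[0]}", **kwargs
    )


# ---------------------------------------------------------------------------
# Presence matrix


def phit(query, evalue=1e-30, span=300, qlen=400):
    return HitRecord(
        query_id=query, subject_id="p", percent_identity=80.0, evalue=evalue,
        bitscore=500.0, subject_taxid=1001, aln_length=span, qstart=1, qend=span,
    )


def test_presence_states():
    qmap = {"Nephrin_q": "Nephrin", "Osr_q": "Osr"}
    qlen = {"Nephrin_q": 400, "Osr_q": 400}
    hits = {
        "sp1": [phit("Nephrin_q")],                      # Osr absent
        "sp2": [phit("Osr_q", evalue=1e-3)],             # fails e-value
        "sp3": None,                                     # no proteome
    }
    m = build_presence_matrix(
        hits, qlen, qmap, families=["Nephrin", "Osr"],
        genbank_override={("Osr", "sp2")},
    )
    assert m.state("Nephrin", "sp1") == ANNOTATED
    assert m.state("Osr", "sp1") == ABSENT
    assert m.state("Osr", "sp2") == GENBANK
    assert m.state("Osr", "sp3") == NO_DATA


def test_presence_requires_query_coverage():
    qmap = {"Eya_q": "Eya"}
    hits = {"sp": [phit("Eya_q", span=100)]}  # 100/400 = 25% < 50%
    m = build_presence_matrix(hits, {"Eya_q": 400}, qmap, families=["Eya"])
    assert m.state("Eya", "sp") == ABSENT


def test_planted_absences_recovered_exactly(rng):
    cfg = sim.PanelSim()
    hits, qlen, qmap, man = sim.simulate_panel_hits(cfg, rng)
    m = build_presence_matrix(hits, qlen, qmap)
    for info in man.panel.values():
        expect = ANNOTATED if info["present"] else ABSENT
        assert m.state(info["family"], info["species"]) == expect


# ---------------------------------------------------------------------------
# Metric extraction


def test_extract_architecture_two_exons():
    ann = make_annotation([make_gene("g1", "c1", [(1, 90), (101, 190)])])
    recs, warn = extract_architecture(
        ann, {"g1.t1": "M" * 60}, {"g1": "Eya"}, "sp", "Cnidaria"
    )
    assert warn == []
    r = recs[0]
    assert (r.n_exons, r.mean_exon_length, r.protein_length) == (2, 90.0, 60)


def test_extract_architecture_single_exon_and_missing_protein():
    ann = make_annotation([make_gene("g1", "c1", [(1, 300)])])
    recs, warn = extract_architecture(ann, {}, {"g1": "Osr"}, "sp", "Cnidaria")
    assert recs[0].n_exons == 1 and recs[0].mean_exon_length == 300.0
    assert recs[0].protein_length is None
    assert any("no protein" in w for _, w in warn)


def test_extract_architecture_unknown_gene_warns():
    ann = make_annotation([make_gene("g1", "c1", [(1, 30)])])
    recs, warn = extract_architecture(ann, {}, {"ghost": "Eya"}, "sp", "Cnidaria")
    assert recs == [] and warn[0][0] == "ghost"


# ---------------------------------------------------------------------------
# Fragment filter


def _len_rec(family, length, i=[0]):
    i[0] += 1
    return ArchitectureRecord("sp", "X", family, f"f{i[0]}", length, 2, 100.0)


def test_fragment_filter_worked_example():
    recs = [_len_rec("A", x) for x in (100, 100, 100, 40)]
    kept, removed = fragment_filter(recs)
    # mean 85 -> threshold 42.5: only the 40-aa copy goes
    assert [r.protein_length for r in removed] == [40]
    assert len(kept) == 3


def test_fragment_filter_equal_lengths_removes_nothing():
    recs = [_len_rec("A", 200) for _ in range(5)]
    kept, removed = fragment_filter(recs)
    assert removed == [] and len(kept) == 5


def test_fragment_filter_threshold_is_single_pass(rng):
    """Matches a brute-force application of the rule; per family, pooled
    mean computed once before any removal."""
    for _ in range(20):
        recs = []
        for fam in "ABC":
            for _ in range(int(rng.integers(2, 12))):
                recs.append(_len_rec(fam, int(rng.integers(20, 1500))))
        kept, removed = fragment_filter(recs)
        by_fam = {}
        for r in recs:
            by_fam.setdefault(r.family, []).append(r.protein_length)
        thr = {f: 0.5 * np.mean(v) for f, v in by_fam.items()}
        expect_removed = {id(r) for r in recs if r.protein_length < thr[r.family]}
        assert {id(r) for r in removed} == expect_removed


# ---------------------------------------------------------------------------
# Dunn test


def naive_midranks(values):
    """O(n^2) midrank oracle, independent of scipy.rankdata."""
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        ties = sum(1 for w in values if w == v)
        out.append(less + (ties + 1) / 2.0)
    return out


def brute_force_dunn(groups):
    names = sorted(groups)
    values = [x for g in names for x in groups[g]]
    n = len(values)
    ranks = naive_midranks(values)
    mr = {}
    off = 0
    for g in names:
        k = len(groups[g])
        mr[g] = sum(ranks[off:off + k]) / k
        off += k
    from collections import Counter
    tie = sum(t**3 - t for t in Counter(values).values()) / (12.0 * (n - 1))
    out = {}
    m = len(names) * (len(names) - 1) // 2
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = math.sqrt((n * (n + 1) / 12.0 - tie)
                           * (1 / len(groups[a]) + 1 / len(groups[b])))
            z = (mr[a] - mr[b]) / se
            p = min(1.0, 2 * stats.norm.sf(abs(z)) * m)
            out[(a, b)] = (z, p)
    return out


def test_dunn_matches_brute_force_with_ties(rng):
    for _ in range(25):
        groups = {
            name: rng.integers(0, 8, size=int(rng.integers(3, 10))).astype(float)
            for name in ["w", "x", "y", "z"][: int(rng.integers(2, 5))]
        }
        got = dunn_test(groups)
        want = brute_force_dunn({k: list(v) for k, v in groups.items()})
        for pair in want:
            assert got[pair][0] == pytest.approx(want[pair][0], abs=1e-10)
            assert got[pair][1] == pytest.approx(want[pair][1], abs=1e-10)


def test_dunn_antisymmetric_under_group_swap(rng):
    a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
    z1 = dunn_test({"a": a, "b": b})[("a", "b")][0]
    z2 = dunn_test({"a": b, "b": a})[("a", "b")][0]
    assert z1 == pytest.approx(-z2)


def test_dunn_no_ties_means_zero_tie_correction(rng):
    vals = rng.permutation(30).astype(float)  # all distinct
    groups = {"a": vals[:10], "b": vals[10:20], "c": vals[20:]}
    got = dunn_test(groups, adjust="none")
    n = 30
    mr = {g: stats.rankdata(vals)[0] for g in []}  # unused
    base = n * (n + 1) / 12.0
    ranks = stats.rankdata(vals)
    mra = ranks[:10].mean(); mrb = ranks[10:20].mean()
    z_expect = (mra - mrb) / math.sqrt(base * (1 / 10 + 1 / 10))
    assert got[("a", "b")][0] == pytest.approx(z_expect)


# ---------------------------------------------------------------------------
# Cascade


def test_identical_groups_not_significant():
    recs = [rec(c, v) for c in ("A", "B") for v in (1.0, 2.0, 3.0)]
    o = compare_clades(recs, "F", "mean_exon_length")
    assert not o.significant
    assert o.brackets == [["A", "B"]]


def test_shifted_clade_isolated_in_anova_branch():
    rng = np.random.default_rng(42)
    recs = []
    for clade in ("A", "B", "C", "D"):
        shift = 100.0 if clade == "D" else 0.0  # 10 SD at sd=10
        for v in rng.normal(500 + shift, 10, 20):
            recs.append(rec(clade, float(v)))
    o = compare_clades(recs, "F", "mean_exon_length")
    assert o.omnibus == "ANOVA" and o.normality_pass and o.homoscedasticity_pass
    assert o.significant
    assert ["D"] in o.brackets
    assert all("D" not in b for b in o.brackets if b != ["D"])


def test_pairwise_only_run_when_omnibus_significant():
    recs = [rec(c, v) for c in ("A", "B") for v in (1.0, 2.0, 3.0)]
    o = compare_clades(recs, "F", "mean_exon_length")
    assert o.pairwise == {}


def test_bonferroni_p_at_least_raw_and_capped(rng):
    recs = []
    for clade in ("A", "B", "C"):
        shift = {"A": 0, "B": 5, "C": 30}[clade]
        for v in rng.normal(100 + shift, 10, 15):
            recs.append(rec(clade, float(v)))
    o = compare_clades(recs, "F", "mean_exon_length")
    if o.significant and o.omnibus == "ANOVA":
        m = len(o.pairwise)
        for (a, b), padj in o.pairwise.items():
            raw = stats.ttest_ind(
                [r.mean_exon_length for r in recs if r.clade == a],
                [r.mean_exon_length for r in recs if r.clade == b],
            ).pvalue
            assert padj == pytest.approx(min(1.0, raw * m))
            assert padj >= raw - 1e-12
    assert all(0 <= p <= 1 for p in o.pairwise.values())


def test_kw_branch_invariant_under_monotone_transform(rng):
    recs, recs_t = [], []
    for clade in ("A", "B", "C"):
        vals = rng.lognormal(3 + (clade == "C"), 0.6, 12)
        for v in vals:
            recs.append(rec(clade, float(v)))
            recs_t.append(rec(clade, float(math.log(v))))
    o1 = compare_clades(recs, "F", "mean_exon_length")
    o2 = compare_clades(recs_t, "F", "mean_exon_length")
    if o1.omnibus == "Kruskal-Wallis" and o2.omnibus == "Kruskal-Wallis":
        assert o1.omnibus_p == pytest.approx(o2.omnibus_p)


def test_small_groups_force_nonparametric_branch():
    recs = [rec(c, v) for c in ("A", "B") for v in (1.0, 2.5)]  # n=2 < 3
    o = compare_clades(recs, "F", "mean_exon_length")
    assert o.omnibus == "Kruskal-Wallis" and not o.normality_pass


def test_constant_data_is_degenerate_not_significant():
    recs = [rec(c, 5.0) for c in ("A", "B") for _ in range(4)]
    o = compare_clades(recs, "F", "mean_exon_length")
    assert o.degenerate and not o.significant


def test_fewer_than_two_groups_is_hard_error():
    recs = [rec("A", v) for v in (1.0, 2.0, 3.0)]
    with pytest.raises(ValueError):
        compare_clades(recs, "F", "mean_exon_length")


def test_anova_branch_frequency_on_normal_data():
    """On normal homoscedastic data the parametric branch is chosen about
    (1-alpha)^(k+1) of the time (k Shapiro gates + Bartlett)."""
    rng = np.random.default_rng(7)
    n_rep, k = 400, 4
    chosen = 0
    for _ in range(n_rep):
        recs = [rec(c, float(v)) for c in "ABCD"
                for v in rng.normal(100, 10, 15)]
        chosen += compare_clades(recs, "F", "mean_exon_length").omnibus == "ANOVA"
    expect = 0.95 ** (k + 1)
    se = math.sqrt(expect * (1 - expect) / n_rep)
    assert chosen / n_rep >= expect - 4 * se


# ---------------------------------------------------------------------------
# Panel runner


def test_family_with_two_clades_compared_over_two():
    rng = np.random.default_rng(3)
    recs = []
    for clade in ("Deuterostomia", "Protostomia"):
        for v in rng.normal(300 + 80 * (clade == "Deuterostomia"), 15, 8):
            recs.append(rec(clade, float(v), family="Osr"))
    outcomes, skipped = run_panel_comparison(recs)
    osr = [o for o in outcomes if o.family == "Osr"]
    assert all(set(o.group_sizes) == {"Deuterostomia", "Protostomia"}
               for o in osr)
    assert skipped == []


def test_single_clade_family_skipped_with_reason():
    recs = [rec("Cnidaria", v, family="Six1") for v in (1.0, 2.0, 3.0)]
    outcomes, skipped = run_panel_comparison(recs)
    assert outcomes == []
    assert any(fam == "Six1" for fam, _, _ in skipped)


def test_empty_records_give_empty_outcome_list():
    assert run_panel_comparison([]) == ([], [])


def test_planted_effects_detected_at_fixed_seed():
    """Families with planted clade shifts flag significant; unshifted
    families mostly do not."""
    rng = np.random.default_rng(11)
    recs = []
    for fam, shift in (("Kirrel", 200.0), ("Eya", 0.0)):
        for clade in ("Acoelomorpha", "Deuterostomia", "Protostomia"):
            mu = 300 + (shift if clade == "Acoelomorpha" else 0.0)
            for v in rng.normal(mu, 25, 12):
                recs.append(rec(clade, float(v), family=fam))
    outcomes, _ = run_panel_comparison(recs)
    by = {(o.family, o.metric): o for o in outcomes}
    assert by[("Kirrel", "mean_exon_length")].significant
    assert not by[("Eya", "mean_exon_length")].significant
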