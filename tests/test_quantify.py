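"""Exon-union gene models, gene counting, RPKM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xenorna.classify import AlignmentRecord, ReadClass, classify_set
from xenorna.genemodel import (
    GeneModel,
    MergedGeneModel,
    merge_exon_groups,
    read_gtf,
    write_gtf,
)
from xenorna.quantify import (
    CountAudit,
    CountMatrix,
    build_count_matrix,
    compute_rpkm,
    count_to_genes,
)
from xenorna.sim.counts import simulate_gene_models


def brute_force_union(model: GeneModel, max_coord: int = 12_000):
    """Per-base set-union oracle for the composite length."""
    covered = np.zeros(max_coord, dtype=bool)
    for s, e in model.all_exons():
        covered[s:e] = True
    length = int(covered.sum())
    groups = []
    pos = 0
    while pos < max_coord:
        if covered[pos]:
            start = pos
            while pos < max_coord and covered[pos]:
                pos += 1
            groups.append((start, pos))
        else:
            pos += 1
    return groups, length


def test_single_exon():
    m = merge_exon_groups(GeneModel("g", transcripts={"t": [(0, 100)]}))
    assert m.merged_groups == [(0, 100)] and m.composite_length == 100


def test_identical_transcripts_idempotent():
    exons = [(0, 100), (200, 300)]
    one = merge_exon_groups(GeneModel("g", transcripts={"t1": exons}))
    two = merge_exon_groups(GeneModel("g", transcripts={"t1": exons, "t2": exons}))
    assert one.merged_groups == two.merged_groups
    again = merge_exon_groups(GeneModel("g", transcripts={"m": one.merged_groups}))
    assert again.merged_groups == one.merged_groups


def test_overlapping_exons_merge():
    m = merge_exon_groups(
        GeneModel("g", transcripts={"t": [(0, 100), (50, 150), (200, 250)]})
    )
    assert m.merged_groups == [(0, 150), (200, 250)]
    assert m.composite_length == 200


def test_zero_length_exon_rejected():
    with pytest.raises(ValueError):
        GeneModel("g", transcripts={"t": [(10, 10)]})


def test_merge_matches_brute_force_on_random_models():
    for model in simulate_gene_models(300, seed=21):
        merged = merge_exon_groups(model)
        groups, length = brute_force_union(model)
        assert merged.merged_groups == groups
        assert merged.composite_length == length


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 80)).map(
            lambda t: (t[0], t[0] + t[1])
        ),
        min_size=1,
        max_size=20,
    )
)
def test_merge_union_property(exons):
    model = GeneModel("g", transcripts={"t": exons})
    merged = merge_exon_groups(model)
    groups, length = brute_force_union(model, max_coord=600)
    assert merged.merged_groups == groups and merged.composite_length == length


def test_gtf_roundtrip(tmp_path):
    models = simulate_gene_models(20, seed=3)
    path = str(tmp_path / "genes.gtf")
    write_gtf(models, path)
    back = {m.gene_id: m for m in read_gtf(path)}
    assert set(back) == {m.gene_id for m in models}
    for m in models:
        loaded = back[m.gene_id]
        for tid, exons in m.transcripts.items():
            assert sorted(loaded.transcripts[tid]) == sorted(exons)
        assert merge_exon_groups(loaded).composite_length == merge_exon_groups(m).composite_length


# ------------------------------------------------------------------ counting


def _aln(rid, mate, tid, species="A"):
    return AlignmentRecord(rid, mate, species, tid, 0, 42)


TX2GENE = {"t1": "g1", "t2": "g1", "t3": "g2", "t_ig": None}


def test_single_unique_pair_counts_once():
    assignments = {"r1": ReadClass.A_UNIQUE}
    counts, audit = count_to_genes(
        assignments, [_aln("r1", 1, "t1"), _aln("r1", 2, "t2")], TX2GENE, "A"
    )
    assert counts["g1"] == 1 and counts["g2"] == 0
    assert audit.n_counted == 1 and audit.n_gene_ambiguous == 0


def test_pair_hitting_two_genes_is_gene_ambiguous():
    assignments = {"r1": ReadClass.A_UNIQUE}
    counts, audit = count_to_genes(
        assignments, [_aln("r1", 1, "t1"), _aln("r1", 2, "t3")], TX2GENE, "A"
    )
    assert counts.sum() == 0
    assert audit.n_gene_ambiguous == 1


def test_intergenic_and_nontarget_pairs():
    assignments = {"r1": ReadClass.A_UNIQUE, "r2": ReadClass.AMBIGUOUS}
    counts, audit = count_to_genes(
        assignments, [_aln("r1", 1, "t_ig"), _aln("r2", 1, "t1")], TX2GENE, "A"
    )
    assert counts.sum() == 0
    assert audit.n_intergenic == 1 and audit.n_assigned == 1


def test_unknown_transcript_is_an_error():
    assignments = {"r1": ReadClass.A_UNIQUE}
    with pytest.raises(KeyError, match="mystery"):
        count_to_genes(assignments, [_aln("r1", 1, "mystery")], TX2GENE, "A")


def test_counting_conserves_reads_on_simulation(small_refpair, small_readset):
    """counted + gene-ambiguous + intergenic = species-assigned total."""
    rs = small_readset
    assignments, stats = classify_set(rs.alignments_A, rs.alignments_B, n_total=rs.n_pairs)
    tx2gene = {tid: f"gene_{tid}" for tid, _ in small_refpair.transcripts_A}
    counts, audit = count_to_genes(assignments, rs.alignments_A, tx2gene, "A")
    assert audit.n_assigned == stats.n_A
    assert audit.n_counted + audit.n_gene_ambiguous + audit.n_intergenic == audit.n_assigned
    assert counts.sum() == audit.n_counted


# ------------------------------------------------------------------ RPKM


def _matrix(c, totals):
    counts = pd.DataFrame(c, index=[f"g{i}" for i in range(len(c))],
                          columns=[f"s{j}" for j in range(len(totals))])
    return CountMatrix("A", counts, pd.Series(totals, index=counts.columns))


def test_rpkm_closed_form_and_zero():
    cm = _matrix([[10], [0]], [1_000_000])
    rpkm = compute_rpkm(cm, {"g0": 1000, "g1": 500})
    assert rpkm.loc["g0", "s0"] == pytest.approx(10.0)
    assert rpkm.loc["g1", "s0"] == 0.0


def test_rpkm_joint_scale_invariance():
    rng = np.random.default_rng(0)
    c = rng.integers(0, 200, size=(30, 4))
    totals = c.sum(axis=0) + rng.integers(100, 500, 4)
    lengths = {f"g{i}": int(rng.integers(200, 5000)) for i in range(30)}
    a = compute_rpkm(_matrix(c, totals), lengths)
    b = compute_rpkm(_matrix(2 * c, 2 * totals), lengths)
    assert np.allclose(a.to_numpy(), b.to_numpy())
    # inversely proportional to composite length
    half = compute_rpkm(_matrix(c, totals), {g: 2 * l for g, l in lengths.items()})
    assert np.allclose(half.to_numpy(), a.to_numpy() / 2)


def test_rpkm_errors():
    with pytest.raises(ValueError, match="no assigned reads"):
        compute_rpkm(_matrix([[0]], [0]), {"g0": 100})
    with pytest.raises(KeyError):
        compute_rpkm(_matrix([[1]], [10]), {})
    with pytest.raises(ValueError):
        compute_rpkm(_matrix([[1]], [10]), {"g0": 0})


def test_count_matrix_validation():
    with pytest.raises(ValueError, match="exceed"):
        _matrix([[10]], [5])
    built = build_count_matrix("A", {"s0": (pd.Series({"g0": 3}), CountAudit(5, 3, 1, 1))})
    assert built.totals["s0"] == 5
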