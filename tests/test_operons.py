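"""Operon calling, equivalence criteria, breakpoint overlap, contingency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scramblekit import (
    EquivalenceCriteria,
    GeneModel,
    call_operons,
    operon_equivalent,
    operon_size_by_breakpoint,
    operonic_status_test,
    segment,
    shared_operons,
)
from scramblekit.io_formats import OrthologMap, ValidationError
from scramblekit.operons import Operon, breakpoint_overlap
import pandas as pd

from conftest import make_aln


def genes_on(chrom, spans_strands, prefix="g"):
    return [
        GeneModel(f"{prefix}{i}", chrom, s, e, st)
        for i, (s, e, st) in enumerate(spans_strands)
    ]


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------


def test_gap_at_most_500_merges():
    ops = call_operons(genes_on("c1", [(100, 500, "+"), (900, 1200, "+")]))
    assert len(ops) == 1 and ops[0].gene_ids == ["g0", "g1"]
    assert (ops[0].start, ops[0].end) == (100, 1200)


@pytest.mark.parametrize(
    "gap,n_operons", [(500, 1), (501, 0)], ids=["gap-500-merges", "gap-501-splits"]
)
def test_gap_boundary(gap, n_operons):
    ops = call_operons(genes_on("c1", [(0, 100, "+"), (100 + gap, 300 + gap, "+")]))
    assert len(ops) == n_operons


def test_strand_change_never_merges():
    ops = call_operons(genes_on("c1", [(0, 100, "+"), (100, 200, "-")]))
    assert ops == []


def test_overlapping_same_strand_genes_merge_as_gap_zero():
    ops = call_operons(genes_on("c1", [(0, 100, "+"), (80, 200, "+")]))
    assert len(ops) == 1


def test_singletons_are_not_operons():
    ops = call_operons(genes_on("c1", [(0, 100, "+"), (5000, 5100, "+")]))
    assert ops == []


def test_calling_invariant_under_coordinate_mirror():
    """Mirroring the chromosome and flipping strands yields the same operons."""
    spans = [(0, 100, "+"), (300, 500, "+"), (700, 900, "-"), (1000, 1200, "-")]
    genes = genes_on("c1", spans)
    L = 2000
    mirrored = [
        GeneModel(g.gene_id, "c1", L - g.end, L - g.start,
                  "-" if g.strand == "+" else "+")
        for g in genes
    ]
    sets_fwd = sorted(tuple(sorted(o.gene_ids)) for o in call_operons(genes))
    sets_rev = sorted(tuple(sorted(o.gene_ids)) for o in call_operons(mirrored))
    assert sets_fwd == sets_rev and len(sets_fwd) == 2


# ---------------------------------------------------------------------------
# Equivalence
# ---------------------------------------------------------------------------


def op(gene_ids, size_start=0):
    return Operon("op", "c1", "+", list(gene_ids), size_start, size_start + 100)


ASSIGN_1 = {"a1": "A", "a2": "B", "a3": "C"}


def crit(kind):
    return EquivalenceCriteria("HOG", kind)


@pytest.mark.parametrize(
    "other,expected",
    [({"x1": "A", "x2": "B", "x3": "C"}, True),   # ABC
     ({"x1": "X", "x2": "B", "x3": "C"}, True),   # XBC
     ({"x1": "A", "x2": "X", "x3": "C"}, True),   # AXC
     ({"x1": "A", "x2": "B", "x3": "X"}, True),   # ABX
     ({"x1": "X", "x2": "Y", "x3": "C"}, False)], # two substitutions
    ids=["ABC", "XBC", "AXC", "ABX", "XYC"],
)
def test_inexact_allows_one_substitution_at_size_three(other, expected):
    got = operon_equivalent(
        op(["a1", "a2", "a3"]), op(list(other)), (ASSIGN_1, other), crit("inexact")
    )
    assert got is expected


def test_exact_requires_identical_multisets():
    assert operon_equivalent(
        op(["a1", "a2", "a3"]), op(["x1", "x2", "x3"]),
        (ASSIGN_1, {"x1": "A", "x2": "B", "x3": "C"}), crit("exact")
    )
    assert not operon_equivalent(
        op(["a1", "a2", "a3"]), op(["x1", "x2", "x3"]),
        (ASSIGN_1, {"x1": "A", "x2": "B", "x3": "X"}), crit("exact")
    )


def test_size_two_operons_never_match_inexactly():
    a = {"a1": "A", "a2": "B"}
    b = {"x1": "A", "x2": "X"}
    assert not operon_equivalent(op(["a1", "a2"]), op(["x1", "x2"]), (a, b), crit("inexact"))


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    ogs1=st.lists(st.sampled_from("ABCDX"), min_size=2, max_size=5),
    ogs2=st.lists(st.sampled_from("ABCDX"), min_size=2, max_size=5),
    kind=st.sampled_from(["same", "permuted", "independent"]),
)
def test_exact_implies_inexact(ogs1, ogs2, kind):
    if kind == "same":
        ogs2 = list(ogs1)
    elif kind == "permuted":
        ogs2 = list(reversed(ogs1))
    a = {f"a{i}": og for i, og in enumerate(ogs1)}
    b = {f"b{i}": og for i, og in enumerate(ogs2)}
    o1, o2 = op(list(a)), op(list(b))
    if operon_equivalent(o1, o2, (a, b), crit("exact")):
        assert operon_equivalent(o1, o2, (a, b), crit("inexact"))


def test_unassigned_genes_match_nothing():
    a = {"a1": "A", "a2": "B"}  # a3 unassigned
    b = {"x1": "A", "x2": "B", "x3": "C"}
    assert not operon_equivalent(
        op(["a1", "a2", "a3"]), op(["x1", "x2", "x3"]), (a, b), crit("exact")
    )
    # inexact still works: the unassigned gene is the one differing gene
    assert operon_equivalent(
        op(["a1", "a2", "a3"]), op(["x1", "x2", "x3"]), (a, b), crit("inexact")
    )


# ---------------------------------------------------------------------------
# Sharing across genomes
# ---------------------------------------------------------------------------


def omap_identical(genomes, n_ops, size=2):
    rows = []
    for g in genomes:
        for i in range(n_ops * size):
            rows.append(
                {"genome_id": g, "gene_id": f"{g}.g{i}",
                 "hog_id": f"H{i}", "og_id": f"O{i}"}
            )
    return OrthologMap(pd.DataFrame(rows))


def ops_for(genome, n_ops, size=2):
    return [
        Operon(f"{genome}.op{k}", "c1", "+",
               [f"{genome}.g{k * size + j}" for j in range(size)],
               1000 * k, 1000 * k + 500)
        for k in range(n_ops)
    ]


def test_identical_genomes_share_everything():
    genomes = ["A", "B", "C"]
    omap = omap_identical(genomes, 4)
    counts = shared_operons({g: ops_for(g, 4) for g in genomes}, omap, reference="A")
    assert counts == {frozenset({"B", "C"}): 4}


def test_disjoint_orthogroups_share_nothing():
    rows = []
    for g, offset in (("A", 0), ("B", 100)):
        for i in range(4):
            rows.append(
                {"genome_id": g, "gene_id": f"{g}.g{i}",
                 "hog_id": f"H{offset + i}", "og_id": f"O{offset + i}"}
            )
    omap = OrthologMap(pd.DataFrame(rows))
    counts = shared_operons(
        {"A": ops_for("A", 2), "B": ops_for("B", 2)}, omap, reference="A"
    )
    assert counts == {frozenset(): 2}


def test_subset_counts_sum_to_reference_operon_count(small_sim):
    from scramblekit import call_operons, map_genes
    from scramblekit.synthetic_data import build_ortholog_map

    ga, gb = small_sim["A"], small_sim["B"]
    omap = build_ortholog_map([ga, gb])
    op_sets = {g.name: call_operons(map_genes(g)) for g in (ga, gb)}
    counts = shared_operons(op_sets, omap, reference=ga.name)
    assert sum(counts.values()) == len(op_sets[ga.name])


def test_sharing_conclusions_stable_across_criteria():
    """Fully conserved operons are shared and fully scrambled ones are not,
    under every combination of gene/operon equivalence criteria."""
    genomes = ["A", "B"]
    omap = omap_identical(genomes, 3, size=3)
    ops_a = ops_for("A", 3, size=3)
    conserved_b = ops_for("B", 3, size=3)
    # scrambled: genes regrouped across operons so no multiset matches
    scrambled_b = [
        Operon(f"B.s{k}", "c1", "+",
               [f"B.g{(3 * k + 4 * j) % 9}" for j in range(3)], k * 100, k * 100 + 50)
        for k in range(3)
    ]
    for gene_eq in ("HOG", "OG"):
        for op_eq in ("exact", "inexact"):
            c = EquivalenceCriteria(gene_eq, op_eq)
            shared = shared_operons({"A": ops_a, "B": conserved_b}, omap, c, "A")
            assert shared == {frozenset({"B"}): 3}
            unshared = shared_operons({"A": ops_a, "B": scrambled_b}, omap, c, "A")
            assert unshared.get(frozenset(), 0) == 3


# ---------------------------------------------------------------------------
# Breakpoint overlap
# ---------------------------------------------------------------------------


@pytest.fixture
def seg_with_breakpoints():
    # breakpoint [30,40) and a zero-width one at 15
    aln = make_aln(
        [
            ("t1", 0, 15, "q1", 0, 15, "+"),
            ("t1", 15, 30, "q1", 20, 35, "-"),
        ],
        {"t1": 40},
        {"q1": 40},
    )
    return segment(aln)


def test_element_covering_breakpoint_counted(seg_with_breakpoints):
    table = breakpoint_overlap({"gene": [("t1", 28, 38)]}, seg_with_breakpoints)
    assert table.loc[0, "n_overlapping"] == 1


def test_zero_width_breakpoint_must_be_strictly_inside(seg_with_breakpoints):
    elements = {
        "at_end": [("t1", 5, 15)],      # zero-width bp at its end: not cut
        "at_start": [("t1", 15, 25)],   # at its start: not cut
        "across": [("t1", 10, 20)],     # strictly inside: cut
    }
    table = breakpoint_overlap(elements, seg_with_breakpoints).set_index("element_class")
    assert table.loc["at_end", "n_overlapping"] == 0
    assert table.loc["at_start", "n_overlapping"] == 0
    assert table.loc["across", "n_overlapping"] == 1


def test_chromosome_mismatch_rejected(seg_with_breakpoints):
    with pytest.raises(ValidationError, match="absent"):
        breakpoint_overlap({"gene": [("nope", 0, 10)]}, seg_with_breakpoints)


def test_planted_overlap_proportion_recovered():
    """Half the elements straddle breakpoints by construction."""
    aln = make_aln(
        [("t1", 0, 500, "q1", 0, 500, "+"), ("t1", 600, 1000, "q1", 700, 1100, "-")],
        {"t1": 1000}, {"q1": 2000},
    )
    seg = segment(aln)  # breakpoint [500,600)
    elements = {"e": [("t1", 450, 550), ("t1", 0, 100), ("t1", 550, 650), ("t1", 700, 800)]}
    table = breakpoint_overlap(elements, seg)
    assert table.loc[0, "proportion"] == 0.5


# ---------------------------------------------------------------------------
# Operonic-status contingency
# ---------------------------------------------------------------------------


def test_hand_computed_chi_squared():
    # counts (both, A only, B only, neither) = (2500, 500, 500, 6500);
    # marginals 0.3/0.3 give expectations (900, 2100, 2100, 4900) and
    # chi2 = 1600^2 * (1/900 + 1/2100 + 1/2100 + 1/4900) = 5804.98866...
    pairs, opa, opb = [], set(), set()
    k = 0
    for n, ina, inb in ((2500, 1, 1), (500, 1, 0), (500, 0, 1), (6500, 0, 0)):
        for _ in range(n):
            a, b = f"a{k}", f"b{k}"
            k += 1
            pairs.append((a, b))
            if ina:
                opa.add(a)
            if inb:
                opb.add(b)
    res = operonic_status_test(pairs, opa, opb)
    assert res.counts == {"both": 2500, "a_only": 500, "b_only": 500, "neither": 6500}
    assert res.df == 3
    assert res.chi2 == pytest.approx(5804.988662, abs=1e-5)
    assert res.p < 1e-100


def test_positive_association_detected():
    pairs = [(f"a{i}", f"b{i}") for i in range(100)]
    opa = {f"a{i}" for i in range(50)}
    opb = {f"b{i}" for i in range(50)}  # perfectly correlated
    res = operonic_status_test(pairs, opa, opb)
    assert res.chi2 > 0
    assert res.counts["both"] > res.expected["both"]


def test_degenerate_marginal_rejected():
    pairs = [("a1", "b1"), ("a2", "b2")]
    with pytest.raises(ValidationError, match="degenerate"):
        operonic_status_test(pairs, set(), {"b1"})


# ---------------------------------------------------------------------------
# Operon size by breakpoint status
# ---------------------------------------------------------------------------


def test_all_operons_overlapping_reports_missing_test(seg_with_breakpoints):
    ops = [Operon("o1", "t1", "+", ["g1", "g2"], 28, 38)]
    out = operon_size_by_breakpoint(ops, seg_with_breakpoints)
    assert out["p_value"] is None and "empty" in out["note"]


def test_planted_size_bias_detected(seg_with_breakpoints):
    rng = np.random.default_rng(37)
    ops = []
    for i in range(200):
        overlapping = i % 2 == 0
        size = int(rng.poisson(2)) + (4 if overlapping else 2)
        span = (30, 40) if overlapping else (0, 10)
        ops.append(Operon(f"o{i}", "t1", "+", [f"g{i}.{j}" for j in range(size)], *span))
    out = operon_size_by_breakpoint(ops, seg_with_breakpoints)
    assert out["p_value"] < 1e-6
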