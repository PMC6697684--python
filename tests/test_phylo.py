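"""Distances, neighbour joining, bootstrap, rooting and monophyly."""

import math

import numpy as np
import pytest
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from cytophylo import (
    DistanceMatrix,
    bootstrap_support,
    is_monophyletic,
    k2p_distance,
    nj_tree,
    p_distance,
    read_newick,
    root_with_outgroup,
    write_newick,
)
from cytophylo.phylo import tree_bipartitions


def aln(**seqs):
    return MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    )


def random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree as (splits->length, pendant lengths,
    distance matrix); built independently of the NJ code by sequential
    taxon insertion on an explicit edge list."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # edge list on a node graph: start from a 3-star
    next_node = [n_taxa]  # internal node ids from n_taxa upwards
    edges = {}  # (u,v) sorted tuple -> length

    def add_edge(u, v, ln):
        edges[tuple(sorted((u, v)))] = ln

    def del_edge(u, v):
        return edges.pop(tuple(sorted((u, v))))

    c = next_node[0]
    next_node[0] += 1
    for i in range(3):
        add_edge(i, c, rng.uniform(0.1, 1.0))
    for i in range(3, n_taxa):
        u, v = list(edges)[rng.integers(len(edges))]
        ln = del_edge(u, v)
        w = next_node[0]
        next_node[0] += 1
        split = rng.uniform(0.25, 0.75)
        add_edge(u, w, ln * split)
        add_edge(v, w, ln * (1 - split))
        add_edge(i, w, rng.uniform(0.1, 1.0))

    # path distances by BFS over the edge list
    import collections

    adj = collections.defaultdict(list)
    for (u, v), ln in edges.items():
        adj[u].append((v, ln))
        adj[v].append((u, ln))

    def dists_from(src):
        seen = {src: 0.0}
        dq = collections.deque([src])
        while dq:
            x = dq.popleft()
            for y, ln in adj[x]:
                if y not in seen:
                    seen[y] = seen[x] + ln
                    dq.append(y)
        return seen

    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        di = dists_from(i)
        for j in range(n_taxa):
            d[i, j] = di[j]
    np.fill_diagonal(d, 0.0)

    # splits with lengths: for each internal edge, leaf set on one side
    splits = {}
    for (u, v), ln in edges.items():
        if u < n_taxa or v < n_taxa:  # pendant
            leaf = min(u, v)
            splits[frozenset([labels[leaf]])] = ln
            continue
        # remove edge, collect leaves on u's side
        comp = set()
        dq = [u]
        seen = {u, v}
        while dq:
            x = dq.pop()
            comp.add(x)
            for y, _ in adj[x]:
                if y not in seen and tuple(sorted((x, y))) != tuple(sorted((u, v))):
                    seen.add(y)
                    dq.append(y)
        side = frozenset(labels[x] for x in comp if x < n_taxa)
        splits[side] = ln
    return labels, d, splits


def nj_splits_with_lengths(tree):
    """Map each split (pendant: single label; internal: side set not
    containing the alphabetically first taxon) to its branch length."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref, full = leaves[0], set(leaves)
    out = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.is_leaf():
            out[frozenset([nd.taxon.label])] = nd.edge.length
            continue
        side = {l.taxon.label for l in nd.leaf_iter()}
        if ref in side:
            side = full - side
        if 0 < len(side) < len(full):
            out[frozenset(side)] = nd.edge.length
    return out


def test_p_distance_values():
    d = p_distance(aln(a="ACGT", b="ACGT"))
    assert d[("a", "b")] == 0.0
    d = p_distance(aln(a="ACGT", b="ACGA"))
    assert d[("a", "b")] == pytest.approx(0.25)


def test_deletion_schemes_differ_only_with_gaps():
    gapless = aln(a="ACGT", b="ACGA", c="ACGG")
    assert np.allclose(
        p_distance(gapless, "pairwise").values,
        p_distance(gapless, "complete").values,
    )
    gapped = aln(a="ACGT", b="ACGA", c="-CGG")
    pw = p_distance(gapped, "pairwise")
    comp = p_distance(gapped, "complete")
    assert pw[("a", "b")] != comp[("a", "b")]  # 1/4 vs 1/3


def test_k2p_closed_form():
    # 100 sites, 10 transitions, 5 transversions: P=0.1, Q=0.05
    s1 = "A" * 100
    s2 = "G" * 10 + "C" * 5 + "A" * 85
    d = k2p_distance(aln(a=s1, b=s2))
    expected = -0.5 * math.log(1 - 2 * 0.1 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
    assert d[("a", "b")] == pytest.approx(expected)
    assert d[("a", "b")] == pytest.approx(0.1701811, abs=1e-6)


def test_k2p_dominates_p_distance():
    rng = np.random.default_rng(11)
    seqs = {
        f"t{i}": "".join(rng.choice(list("ACGT"), 200)) for i in range(5)
    }
    a = aln(**seqs)
    # distances may be saturated on random sequences; flag as inf
    dk = k2p_distance(a, on_saturation="inf")
    dp = p_distance(a)
    assert (dk.values >= dp.values - 1e-12).all()


def test_k2p_saturation_handling():
    pair = aln(a="ACAC" * 20, b="GTGT" * 20)  # all sites differ
    with pytest.raises(ValueError, match="saturated"):
        k2p_distance(pair)
    d = k2p_distance(pair, on_saturation="inf")
    assert math.isinf(d[("a", "b")])


def test_nj_three_taxa_closed_form():
    d = DistanceMatrix(["A", "B", "C"], np.array(
        [[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]
    ))
    tree = nj_tree(d)
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)


def test_nj_recovers_four_taxon_additive_tree():
    # quartet ((A:1,B:2):1,(C:3,D:1)); path distances below
    taxa = ["A", "B", "C", "D"]
    d = DistanceMatrix(taxa, np.array(
        [
            [0.0, 3.0, 5.0, 3.0],
            [3.0, 0.0, 6.0, 4.0],
            [5.0, 6.0, 0.0, 4.0],
            [3.0, 4.0, 4.0, 0.0],
        ]
    ))
    tree = nj_tree(d)
    splits = nj_splits_with_lengths(tree)
    assert frozenset(["C", "D"]) in splits
    assert splits[frozenset(["C", "D"])] == pytest.approx(1.0)
    for taxon, ln in (("A", 1.0), ("B", 2.0), ("C", 3.0), ("D", 1.0)):
        assert splits[frozenset([taxon])] == pytest.approx(ln)


@pytest.mark.parametrize("n_taxa", [4, 5, 6])
def test_nj_exact_on_random_additive_matrices(n_taxa):
    rng = np.random.default_rng(100 + n_taxa)
    for _ in range(10):
        labels, d, true_splits = random_additive_tree(n_taxa, rng)
        tree = nj_tree(DistanceMatrix(labels, d))
        got = nj_splits_with_lengths(tree)
        # same normalization for the true splits
        ref = sorted(labels)[0]
        full = set(labels)
        norm = {}
        for side, ln in true_splits.items():
            if len(side) > 1 and ref in side:
                side = frozenset(full - side)
            norm[side] = ln
        assert set(got) == set(norm)
        for side in norm:
            assert got[side] == pytest.approx(norm[side], abs=1e-9)


def test_nj_topology_matches_skbio():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(21)
    labels, d, _ = random_additive_tree(7, rng)
    d += rng.uniform(0, 0.01, d.shape)  # perturb off additivity
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    ours = nj_tree(DistanceMatrix(labels, d))
    theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))

    def skbio_splits(t):
        leaves = sorted(n.name for n in t.tips())
        ref, full = leaves[0], set(leaves)
        out = set()
        for node in t.non_tips(include_self=False):
            side = {t2.name for t2 in node.tips()}
            if ref in side:
                side = full - side
            if 1 < len(side) < len(full) - 1:
                out.add(frozenset(side))
        return out

    assert tree_bipartitions(ours) == skbio_splits(theirs)


def test_nj_asymmetric_matrix_rejected():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float
        ))


def test_nj_negative_branch_lengths_clamped():
    # matrix engineered to produce a negative NJ branch estimate
    d = DistanceMatrix(["a", "b", "c", "d"], np.array(
        [
            [0.0, 0.1, 0.4, 0.45],
            [0.1, 0.0, 0.45, 0.4],
            [0.4, 0.45, 0.0, 0.1],
            [0.45, 0.4, 0.1, 0.0],
        ]
    ))
    tree = nj_tree(d)
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            assert nd.edge.length >= 0.0


def test_bootstrap_supports_are_reproducible_and_bounded():
    rng = np.random.default_rng(3)
    base = list("ACGT" * 25)
    seqs = {}
    for i in range(6):
        s = base.copy()
        if i < 3:
            s[0] = s[1] = s[2] = "T" if s[0] != "T" else "C"
        seqs[f"x{i}"] = "".join(s)
    a = aln(**seqs)
    t1 = bootstrap_support(a, n_reps=100, seed=42)
    t2 = bootstrap_support(a, n_reps=100, seed=42)
    assert write_newick(t1) == write_newick(t2)
    for nd in t1.preorder_node_iter():
        if nd.label is not None:
            assert 0.0 <= float(nd.label) <= 100.0


def test_bootstrap_strong_signal_full_support():
    # two clearly separated groups, many supporting columns, no homoplasy
    g1 = "A" * 30 + "C" * 170
    g2 = "G" * 30 + "C" * 170
    a = aln(p1=g1, p2=g1, p3=g1, q1=g2, q2=g2, q3=g2)
    tree = bootstrap_support(a, n_reps=100, seed=0)
    for nd in tree.preorder_node_iter():
        if nd.label is not None:
            assert float(nd.label) == pytest.approx(100.0)


def test_rooting_on_outgroup():
    d = DistanceMatrix(["A", "B", "C"], np.array(
        [[0.0, 0.2, 1.0], [0.2, 0.0, 1.0], [1.0, 1.0, 0.0]]
    ))
    rooted = root_with_outgroup(nj_tree(d), "C")
    assert rooted.is_rooted
    assert is_monophyletic(rooted, {"A", "B"})
    with pytest.raises(ValueError, match="not among leaves"):
        root_with_outgroup(nj_tree(d), "Z")


def test_rooting_preserves_bipartitions():
    rng = np.random.default_rng(5)
    labels, d, _ = random_additive_tree(6, rng)
    tree = nj_tree(DistanceMatrix(labels, d))
    rooted = root_with_outgroup(tree, labels[0])
    assert tree_bipartitions(rooted) == tree_bipartitions(tree)


def test_monophyly_queries():
    tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    tree.is_rooted = True
    assert is_monophyletic(tree, {"A"})
    assert is_monophyletic(tree, {"A", "B", "C", "D"})
    assert is_monophyletic(tree, {"A", "B"})
    assert not is_monophyletic(tree, {"A", "C"})
    with pytest.raises(ValueError, match="not in tree"):
        is_monophyletic(tree, {"A", "Z"})


def test_newick_round_trip():
    rng = np.random.default_rng(8)
    labels, d, _ = random_additive_tree(6, rng)
    tree = nj_tree(DistanceMatrix(labels, d))
    # attach fake supports to exercise label round-tripping
    for i, nd in enumerate(tree.preorder_internal_node_iter()):
        if nd.parent_node is not None:
            nd.label = str(60 + i)
    s = write_newick(tree)
    back = read_newick(s)
    assert tree_bipartitions(back) == tree_bipartitions(tree)
    orig = nj_splits_with_lengths(tree)
    rt = nj_splits_with_lengths(back)
    for side, ln in orig.items():
        assert rt[side] == pytest.approx(ln, abs=1e-6)
    back_labels = {nd.label for nd in back.preorder_internal_node_iter() if nd.label}
    tree_labels = {nd.label for nd in tree.preorder_internal_node_iter() if nd.label}
    assert back_labels == tree_labels


def test_distance_matrix_phylip_round_trip(tmp_path):
    d = DistanceMatrix(["a", "b", "c"], np.array(
        [[0.0, 0.5, 0.25], [0.5, 0.0, 0.125], [0.25, 0.125, 0.0]]
    ))
    path = tmp_path / "dm.phy"
    d.write_phylip(path)
    back = DistanceMatrix.read_phylip(path)
    assert back.taxa == d.taxa
    assert np.allclose(back.values, d.values, atol=1e-6)
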