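"""Distance-based phylogenetics: p/K2P distances, neighbour joining,
nonparametric bootstrap, outgroup rooting and monophyly checks.

Trees are dendropy ``Tree`` objects (Newick I/O, rerooting and MRCA
queries come with the container); the neighbour-joining agglomeration,
the distance estimators and the bootstrap are implemented here.

Neighbour joining follows the Saitou-Nei Q-criterion with two
deterministic conventions: ties in Q are broken by the lexicographically
smallest pair of cluster labels, and negative branch lengths are clamped
to zero (the tree is then flagged via ``tree.clamped_negative_lengths``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import dendropy

__all__ = [
    "DistanceMatrix",
    "alignment_to_array",
    "p_distance",
    "k2p_distance",
    "nj_tree",
    "bootstrap_support",
    "root_with_outgroup",
    "is_monophyletic",
    "tree_bipartitions",
    "write_newick",
    "read_newick",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINES = (0, 2)  # A, G


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-distance matrix over labelled taxa."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    def __getitem__(self, pair):
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])

    def write_phylip(self, path) -> None:
        """PHYLIP square format (relaxed labels)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for label, row in zip(self.taxa, self.values):
                fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read_phylip(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            tokens = fh.read().split()
        n = int(tokens[0])
        taxa, rows, pos = [], [], 1
        for _ in range(n):
            taxa.append(tokens[pos])
            rows.append([float(t) for t in tokens[pos + 1 : pos + 1 + n]])
            pos += 1 + n
        return cls(taxa, np.array(rows))


def alignment_to_array(alignment) -> tuple[list[str], np.ndarray]:
    """Encode an alignment as (labels, int matrix); A,C,G,T -> 0..3, else -1."""
    labels = [rec.id for rec in alignment]
    rows = [str(rec.seq).upper() for rec in alignment]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("ragged alignment")
    arr = np.full((len(rows), len(rows[0])), -1, dtype=np.int8)
    for i, r in enumerate(rows):
        arr[i] = [_CODE.get(c, -1) for c in r]
    return labels, arr


def _deletion_mask(arr: np.ndarray, deletion: str) -> np.ndarray | None:
    if deletion == "complete":
        return (arr >= 0).all(axis=0)
    if deletion == "pairwise":
        return None
    raise ValueError("deletion must be 'complete' or 'pairwise'")


def _pair_counts(a: np.ndarray, b: np.ndarray, global_mask) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) for one sequence pair."""
    mask = (a >= 0) & (b >= 0) if global_mask is None else global_mask
    aa, bb = a[mask], b[mask]
    diff = aa != bb
    n = int(mask.sum())
    if diff.any():
        pur_a = np.isin(aa[diff], _PURINES)
        pur_b = np.isin(bb[diff], _PURINES)
        ts = int((pur_a == pur_b).sum())
        tv = int(diff.sum()) - ts
    else:
        ts = tv = 0
    return n, ts, tv


def _distances_from_encoded(
    labels: list[str],
    arr: np.ndarray,
    kind: str,
    deletion: str,
    on_saturation: str = "error",
) -> DistanceMatrix:
    gmask = _deletion_mask(arr, deletion)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m, ts, tv = _pair_counts(arr[i], arr[j], gmask)
        if m == 0:
            raise ValueError(f"no comparable sites between {labels[i]} and {labels[j]}")
        if kind == "p":
            d[i, j] = d[j, i] = (ts + tv) / m
            continue
        p, q = ts / m, tv / m
        w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
        if w1 <= 0 or w2 <= 0:
            if on_saturation == "inf":
                d[i, j] = d[j, i] = math.inf
                continue
            raise ValueError(f"saturated pair ({labels[i]}, {labels[j]}): P={p}, Q={q}")
        d[i, j] = d[j, i] = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DistanceMatrix(labels, d)


def p_distance(alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing sites among pairwise-comparable sites."""
    labels, arr = alignment_to_array(alignment)
    return _distances_from_encoded(labels, arr, "p", deletion)


def k2p_distance(
    alignment, deletion: str = "pairwise", on_saturation: str = "error"
) -> DistanceMatrix:
    """Kimura two-parameter distance.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P and Q the transition
    and transversion proportions.  A non-positive log argument means the
    pair is saturated: raise (default) or return inf per ``on_saturation``
    ("error" | "inf").
    """
    labels, arr = alignment_to_array(alignment)
    return _distances_from_encoded(labels, arr, "k2p", deletion, on_saturation)


def _nj_merge_order(dist: np.ndarray, labels: list[str]):
    """Saitou-Nei agglomeration; yields merges, mutates nothing external."""
    # Work on lists; labels here are cluster labels (lexicographic tie-break).
    d = dist.copy()
    active = list(range(len(labels)))
    merges = []  # (i, j, li, lj) as positions into current active list
    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # tie-break: lexicographically smallest sorted label pair
        best = None
        ii, jj = np.where(q <= qmin + 1e-12)
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            key = tuple(sorted((labels[active[a]], labels[active[b]])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        li = 0.5 * sub[a, b] + (r[a] - r[b]) / (2.0 * (n - 2))
        lj = sub[a, b] - li
        # distances from the new cluster u to every remaining cluster
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        u = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[u, :-1] = new_row
        d[:-1, u] = new_row
        labels.append(min(labels[i], labels[j]))
        merges.append((i, j, li, lj, u))
        active = [x for x in active if x not in (i, j)] + [u]
    # final three (or fewer) clusters resolved by the three-point formulas
    return merges, active, d


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Neighbour-joining tree (unrooted; trifurcating root node).

    Recovers topology and branch lengths exactly on additive matrices.
    Negative branch-length estimates are clamped to zero and the tree is
    flagged (``tree.clamped_negative_lengths``).
    """
    taxa_labels = list(dist.taxa)
    if len(taxa_labels) < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    ns = dendropy.TaxonNamespace(taxa_labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    clamped = False

    def _mk_edge_len(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return float(x)

    nodes: dict[int, dendropy.Node] = {}
    for k, lab in enumerate(taxa_labels):
        nd = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes[k] = nd

    merges, active, d = _nj_merge_order(dist.values, list(taxa_labels))
    for i, j, li, lj, u in merges:
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = _mk_edge_len(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = _mk_edge_len(lj)
        nodes[u] = parent

    root = tree.seed_node
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
        lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
        lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
        for k, lk in zip((a, b, c), (la, lb, lc)):
            root.add_child(nodes[k])
            nodes[k].edge.length = _mk_edge_len(lk)
    else:  # exactly 2 active clusters can only arise from... n>=3 keeps 3+
        a, b = active
        root.add_child(nodes[a])
        nodes[a].edge.length = _mk_edge_len(d[a, b] / 2)
        root.add_child(nodes[b])
        nodes[b].edge.length = _mk_edge_len(d[a, b] / 2)
    tree.is_rooted = False
    tree.clamped_negative_lengths = clamped
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as leaf-label sets on the side away from
    the alphabetically first taxon (a rooted/unrooted-stable encoding)."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    full = set(leaves)
    splits = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = {l.taxon.label for l in nd.leaf_iter()}
        if ref in side:
            side = full - side
        if 1 < len(side) < len(full) - 1:
            splits.add(frozenset(side))
    return splits


def _resample_alignment(arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cols = rng.integers(0, arr.shape[1], size=arr.shape[1])
    return arr[:, cols]


def _distance_from_array(
    labels, arr, distance_kind: str, deletion: str
) -> DistanceMatrix:
    if distance_kind not in ("p", "k2p"):
        raise ValueError("distance_kind must be 'p' or 'k2p'")
    return _distances_from_encoded(labels, arr, distance_kind, deletion, "inf")


def bootstrap_support(
    alignment,
    n_reps: int = 1000,
    seed: int = 0,
    distance_kind: str = "k2p",
    deletion: str = "pairwise",
) -> dendropy.Tree:
    """Full-data NJ tree with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement per replicate
    (replicate r draws from a generator seeded ``seed + r``, so the
    replicate stream is deterministic and order-independent); the support
    of each bipartition of the full-data tree is the percentage of
    replicate NJ trees containing it, written to the internal node labels.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels, arr = alignment_to_array(alignment)
    full_tree = nj_tree(_distance_from_array(labels, arr, distance_kind, deletion))
    counts: dict[frozenset[str], int] = {s: 0 for s in tree_bipartitions(full_tree)}
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        rep_arr = _resample_alignment(arr, rng)
        rep_tree = nj_tree(_distance_from_array(labels, rep_arr, distance_kind, deletion))
        for s in tree_bipartitions(rep_tree):
            if s in counts:
                counts[s] += 1

    leaves = sorted(labels)
    ref, full = leaves[0], set(leaves)
    for nd in full_tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = {l.taxon.label for l in nd.leaf_iter()}
        if ref in side:
            side = full - side
        if 1 < len(side) < len(full) - 1:
            support = 100.0 * counts[frozenset(side)] / n_reps
            nd.label = f"{support:g}"
    full_tree.bootstrap_reps = n_reps
    return full_tree


def _support_by_split(tree: dendropy.Tree) -> dict[frozenset[str], str]:
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref, full = leaves[0], set(leaves)
    out = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None or nd.label is None:
            continue
        side = {l.taxon.label for l in nd.leaf_iter()}
        if ref in side:
            side = full - side
        out[frozenset(side)] = nd.label
    return out


def root_with_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root a copy of the tree at the midpoint of the outgroup pendant edge.

    Support values are per-bipartition, not per-node, so internal node
    labels are re-assigned after rerooting by matching each node's
    bipartition against the unrooted tree's supports.
    """
    supports = _support_by_split(tree)
    rooted = tree.clone(depth=1)
    matches = [
        l for l in rooted.leaf_node_iter() if l.taxon.label == outgroup_label
    ]
    if not matches:
        raise ValueError(f"outgroup {outgroup_label!r} not among leaves")
    leaf = matches[0]
    elen = leaf.edge.length if leaf.edge.length is not None else 0.0
    rooted.reroot_at_edge(
        leaf.edge, length1=elen / 2.0, length2=elen / 2.0, update_bipartitions=False
    )
    rooted.is_rooted = True
    leaves = sorted(l.taxon.label for l in rooted.leaf_node_iter())
    ref, full = leaves[0], set(leaves)
    for nd in rooted.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = {l.taxon.label for l in nd.leaf_iter()}
        if ref in side:
            side = full - side
        nd.label = supports.get(frozenset(side))
    return rooted


def is_monophyletic(tree: dendropy.Tree, taxa: set[str]) -> bool:
    """True iff ``taxa`` is exactly the leaf set of some clade of a rooted tree."""
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = set(taxa) - leaf_labels
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if len(taxa) in (1, len(leaf_labels)):
        return True
    mrca = tree.mrca(taxon_labels=list(taxa))
    clade = {l.taxon.label for l in mrca.leaf_iter()}
    return clade == set(taxa)


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Newick with bootstrap supports as internal node labels, 6-decimal
    branch lengths; returns the string, optionally writing it to a file."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string or file path (internal labels kept as supports)."""
    import os

    if os.path.exists(source):
        return dendropy.Tree.get(path=source, schema="newick")
    return dendropy.Tree.get(data=source, schema="newick")
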