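"""Distance phylogenetics and tanglegram entanglement.

Used to compare the evolutionary course of the housekeeping markers
(rpoB + groEL concatenation) with the riboflavin-associated genes
(ribU + ribCF): neighbor-joining trees with bootstrap support, and a
quantitative entanglement score for the facing pair of dendrograms.

Trees are :class:`skbio.TreeNode` objects throughout, so newick I/O and
standard tree manipulation come for free.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "EntanglementScore",
    "p_distance",
    "jc_distance",
    "concatenate_alignments",
    "nj_tree",
    "bootstrap_support",
    "entanglement",
    "tree_bipartitions",
]

Alignment = Sequence[tuple[str, str]]

GAP_CHARS = frozenset("-.")


def _check_alignment(alignment: Alignment) -> None:
    if len(alignment) < 2:
        raise ValueError("alignment needs at least two sequences")
    lengths = {len(s) for _, s in alignment}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths {sorted(lengths)}")


def p_distance(alignment: Alignment) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gapped sites.

    For each pair the distance is the fraction of differing sites among
    the sites where neither sequence carries a gap. A pair with no
    comparable site at all is an error rather than a silent zero.
    """
    _check_alignment(alignment)
    ids = [name for name, _ in alignment]
    seqs = [seq.upper() for _, seq in alignment]
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        comparable = diffs = 0
        for a, b in zip(seqs[i], seqs[j]):
            if a in GAP_CHARS or b in GAP_CHARS:
                continue
            comparable += 1
            if a != b:
                diffs += 1
        if comparable == 0:
            raise ValueError(f"no comparable sites between {ids[i]} and {ids[j]}")
        d[i, j] = d[j, i] = diffs / comparable
    return DistanceMatrix(d, ids)


def jc_distance(alignment: Alignment) -> DistanceMatrix:
    """Jukes-Cantor corrected distances, d = -3/4 ln(1 - 4p/3)."""
    pd = p_distance(alignment)
    data = pd.data.copy()
    if (data >= 0.75).any():
        raise ValueError("p-distance >= 0.75; Jukes-Cantor correction undefined")
    with np.errstate(divide="ignore"):
        corrected = -0.75 * np.log1p(-4.0 * data / 3.0)
    np.fill_diagonal(corrected, 0.0)
    return DistanceMatrix(corrected, pd.ids)


def concatenate_alignments(*alignments: Alignment) -> list[tuple[str, str]]:
    """End-to-end concatenation of per-gene alignments.

    Taxa missing from one gene are gap-filled for that block, so the
    pairwise-deletion distance simply ignores the missing stretch.
    """
    taxa: list[str] = []
    for aln in alignments:
        for name, _ in aln:
            if name not in taxa:
                taxa.append(name)
    blocks = []
    for aln in alignments:
        _check_alignment(aln)
        length = len(aln[0][1])
        lookup = dict(aln)
        blocks.append({t: lookup.get(t, "-" * length) for t in taxa})
    return [(t, "".join(block[t] for block in blocks)) for t in taxa]


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining (Saitou-Nei) on a distance matrix.

    Agglomerates by the Q-criterion with deterministic tie-breaking on
    the lexicographically lowest label pair; branch lengths follow the
    standard NJ formulas, with negative estimates clamped to zero (a
    warning is emitted). Returns an unrooted tree represented with a
    trifurcating root.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = {
        (a, b): float(dm[a, b]) for a in ids for b in ids if a != b
    }
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in ids}
    # sort key per working node: smallest leaf label underneath
    active = sorted(ids)
    clamped = False

    def dist(a: str, b: str) -> float:
        return d[(a, b)]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (n - 2) * dist(a, b) - r[a] - r[b]
            key = (q, min(a, b), max(a, b))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        la = 0.5 * dist(a, b) + (r[a] - r[b]) / (2 * (n - 2))
        lb = dist(a, b) - la
        if la < 0 or lb < 0:
            clamped = True
        la, lb = max(la, 0.0), max(lb, 0.0)
        u = min(a, b)  # merged node inherits the smaller label for ties
        new_node = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].length, nodes[b].length = la, lb
        new_d = {}
        for k in active:
            if k in (a, b):
                continue
            new_d[k] = 0.5 * (dist(a, k) + dist(b, k) - dist(a, b))
        active = sorted(k for k in active if k not in (a, b))
        for k in active:
            d[(u, k)] = d[(k, u)] = new_d[k]
        nodes[u] = new_node
        active = sorted(active + [u])
    a, b, c = active
    xa = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    xb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    xc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    if min(xa, xb, xc) < 0:
        clamped = True
    for t, x in zip((a, b, c), (xa, xb, xc)):
        nodes[t].length = max(x, 0.0)
    if clamped:
        warnings.warn(
            "negative neighbor-joining branch length(s) clamped to 0",
            stacklevel=2,
        )
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree.

    Each internal edge is represented canonically by the smaller of the
    two leaf sets it induces (ties broken by sorted labels), so rooted
    and unrooted renderings of the same topology compare equal.
    """
    all_leaves = frozenset(t.name for t in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canonical = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        parts.add(canonical)
    return parts


def bootstrap_support(
    alignment: Alignment,
    tree_builder: Callable[[Alignment], TreeNode] | None = None,
    n_replicates: int = 100,
    seed: int | None = None,
) -> TreeNode:
    """Bootstrap supports by alignment-column resampling.

    Builds the reference tree on the full alignment, then resamples
    columns with replacement ``n_replicates`` times; each internal
    node's ``support`` is the percentage of replicate trees containing
    its bipartition. Reproducible under a fixed ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    _check_alignment(alignment)
    if tree_builder is None:
        tree_builder = lambda aln: nj_tree(p_distance(aln))  # noqa: E731
    rng = np.random.default_rng(seed)
    names = [n for n, _ in alignment]
    seqs = [s for _, s in alignment]
    length = len(seqs[0])
    reference = tree_builder(alignment)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        replicate = [
            (name, "".join(seq[c] for c in cols))
            for name, seq in zip(names, seqs)
        ]
        try:
            rep_tree = tree_builder(replicate)
        except ValueError:
            continue  # e.g. a pair with no comparable resampled sites
        for part in tree_bipartitions(rep_tree):
            counts[part] = counts.get(part, 0) + 1
    all_leaves = frozenset(names)
    for node in reference.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            node.support = None
            continue
        canonical = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        node.support = 100.0 * counts.get(canonical, 0) / n_replicates
    return reference


@dataclass
class EntanglementScore:
    """Leaf-order discordance between two facing dendrograms.

    ``score`` is in [0, 1]: the mean absolute rank displacement between
    the two optimized leaf orders, divided by the maximum achievable
    mean displacement for that leaf count. 0 means the trees can be
    drawn with identical leaf orders.
    """

    score: float
    order1: tuple[str, ...]
    order2: tuple[str, ...]


def _internal_nodes(tree: TreeNode) -> list[TreeNode]:
    return [n for n in tree.traverse() if not n.is_tip()]


def _leaf_order(tree: TreeNode, flipped: frozenset[int]) -> tuple[str, ...]:
    out: list[str] = []

    def walk(node: TreeNode) -> None:
        if node.is_tip():
            out.append(node.name)
            return
        children = list(node.children)
        if id(node) in flipped:
            children = children[::-1]
        for child in children:
            walk(child)

    walk(tree)
    return tuple(out)


def _max_mean_displacement(n: int) -> float:
    # attained by the reversal permutation
    return n / 2 if n % 2 == 0 else (n * n - 1) / (2 * n)


def _displacement(order1: Sequence[str], order2: Sequence[str]) -> float:
    rank2 = {name: i for i, name in enumerate(order2)}
    return float(np.mean([abs(i - rank2[name]) for i, name in enumerate(order1)]))


def entanglement(
    t1: TreeNode, t2: TreeNode, *, exact_limit: int = 16
) -> EntanglementScore:
    """Entanglement of two trees over the same leaf set.

    Minimizes mean rank displacement over child-order flips of internal
    nodes: exhaustively when the combined internal-node count is at most
    ``exact_limit``, otherwise by repeated greedy one-node flip sweeps
    over each tree until no flip improves. Deterministic and seed-free.
    """
    leaves1 = {t.name for t in t1.tips()}
    leaves2 = {t.name for t in t2.tips()}
    if leaves1 != leaves2:
        raise ValueError("trees have different leaf sets")
    n = len(leaves1)
    if n < 2:
        return EntanglementScore(0.0, _leaf_order(t1, frozenset()), _leaf_order(t2, frozenset()))
    norm = _max_mean_displacement(n)
    int1, int2 = _internal_nodes(t1), _internal_nodes(t2)

    if len(int1) + len(int2) <= exact_limit:
        orders1 = {
            _leaf_order(t1, frozenset(id(nd) for nd, f in zip(int1, flips) if f))
            for flips in itertools.product((False, True), repeat=len(int1))
        }
        orders2 = {
            _leaf_order(t2, frozenset(id(nd) for nd, f in zip(int2, flips) if f))
            for flips in itertools.product((False, True), repeat=len(int2))
        }
        best = None
        for o1 in sorted(orders1):
            for o2 in sorted(orders2):
                disp = _displacement(o1, o2)
                if best is None or disp < best[0]:
                    best = (disp, o1, o2)
        disp, o1, o2 = best
        return EntanglementScore(disp / norm, o1, o2)

    flips1: set[int] = set()
    flips2: set[int] = set()
    current = _displacement(
        _leaf_order(t1, frozenset(flips1)), _leaf_order(t2, frozenset(flips2))
    )
    for _ in range(20):
        improved = False
        for tree, ints, flips in ((t1, int1, flips1), (t2, int2, flips2)):
            for node in ints:
                flips.symmetric_difference_update({id(node)})
                trial = _displacement(
                    _leaf_order(t1, frozenset(flips1)),
                    _leaf_order(t2, frozenset(flips2)),
                )
                if trial < current - 1e-12:
                    current = trial
                    improved = True
                else:
                    flips.symmetric_difference_update({id(node)})
        if not improved:
            break
    return EntanglementScore(
        current / norm,
        _leaf_order(t1, frozenset(flips1)),
        _leaf_order(t2, frozenset(flips2)),
    )
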