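"""Independent reference computations used to check the package.

Everything here is deliberately naive and structurally different from the
implementation: matrix exponentials by scaled Taylor series, cladogenetic
scenario sets by explicit listing, and the DEC likelihood by full
enumeration over internal-node state assignments.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def series_expm(Q: np.ndarray, t: float, terms: int = 40) -> np.ndarray:
    """exp(Q t) by scaling-and-squaring of a truncated Taylor series."""
    norm = np.abs(Q).max() * t
    n_sq = max(0, int(math.ceil(math.log2(norm))) + 4) if norm > 1e-300 else 0
    A = Q * (t / 2 ** n_sq)
    S = np.eye(len(Q))
    term = np.eye(len(Q))
    for k in range(1, terms):
        term = term @ A / k
        S = S + term
    for _ in range(n_sq):
        S = S @ S
    return S


def naive_scenarios(state: int) -> list[tuple[int, int]]:
    """Ordered daughter-range pairs for a parent range, equal weights."""
    bits = [1 << i for i in range(state.bit_length()) if state >> i & 1]
    if len(bits) == 1:
        return [(state, state)]
    pairs = set()
    for a in bits:
        rest = state & ~a
        pairs.update({(a, state), (state, a), (a, rest), (rest, a)})
    return sorted(pairs)


def naive_dec_q(d: float, e: float, k: int) -> np.ndarray:
    """Unconstrained DEC generator written out longhand."""
    S = 1 << k
    Q = np.zeros((S, S))
    for s in range(1, S):
        occupied = [i for i in range(k) if s >> i & 1]
        for j in range(k):
            if not s >> j & 1:
                Q[s, s | (1 << j)] += d * len(occupied)
        for i in occupied:
            Q[s, s & ~(1 << i)] += e
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def dec_enumeration(chron, ranges, d: float, e: float, k: int):
    """DEC likelihood and node marginals by exhaustive state enumeration.

    Sums, over every joint assignment of a non-null range to every internal
    node, the product of the root weight, the per-node cladogenetic factor
    (an explicit loop over scenarios), and the per-edge series-expm
    transition entries.  Unconstrained model only.  Returns
    ``(loglik, marginals)`` with marginals keyed by node.
    """
    S = 1 << k
    Q = naive_dec_q(d, e, k)
    P = {}
    for node in chron.tree.preorder_node_iter():
        if node is not chron.root:
            P[node] = series_expm(Q, node.edge.length).tolist()
    tip_state = {
        leaf: ranges.bitmask(leaf.taxon.label)
        for leaf in chron.tree.leaf_node_iter()
    }
    internal = [
        n for n in chron.tree.preorder_node_iter() if not n.is_leaf()
    ]
    nonnull = list(range(1, S))
    root_w = 1.0 / len(nonnull)
    total = 0.0
    marg = {v: np.zeros(S) for v in internal}
    for assign in product(nonnull, repeat=len(internal)):
        amap = dict(zip(internal, assign))
        term = root_w
        for v in internal:
            sv = amap[v]
            c1, c2 = v.child_nodes()
            s1 = amap[c1] if not c1.is_leaf() else tip_state[c1]
            s2 = amap[c2] if not c2.is_leaf() else tip_state[c2]
            scen = naive_scenarios(sv)
            w = 1.0 / len(scen)
            p1, p2 = P[c1], P[c2]
            f = 0.0
            for left, right in scen:
                f += w * p1[left][s1] * p2[right][s2]
            term *= f
            if term == 0.0:
                break
        total += term
        for v in internal:
            marg[v][amap[v]] += term
    marginals = {v: m / total for v, m in marg.items()}
    return math.log(total), marginals


def brute_force_mrca(chron, labels):
    """MRCA by intersecting explicit ancestor chains."""
    common = None
    for label in labels:
        node = chron.leaf(label)
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        chain = set(chain)
        common = chain if common is None else common & chain
    return max(common, key=lambda n: len(list(n.ancestor_iter())))


def moment_skewness(x) -> float:
    """g1 from first principles: explicit central moments."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    return m3 / m2 ** 1.5


def subtree_length(node) -> float:
    """Total edge length below a node, by independent recursion."""
    return sum(
        child.edge.length + subtree_length(child)
        for child in node.child_nodes()
    )
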