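"""Expression phylograms: 1 - Spearman distances, neighbor-joining, and
gene-bootstrap branch support.

The NJ agglomeration is deterministic: on exactly equal Q values the
lowest-index pair is joined, and negative branch lengths are clamped to
zero with the deficit moved to the sibling edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "NJTree",
    "PhylogramResult",
    "expression_distance",
    "neighbor_joining",
    "bootstrap_support",
]


@dataclass
class DistanceMatrix:
    values: pd.DataFrame
    metric: str = "one-minus-spearman"

    def __post_init__(self):
        v = self.values.to_numpy(float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")

    @property
    def taxa(self):
        return list(self.values.columns)


def expression_distance(e: ExpressionMatrix) -> DistanceMatrix:
    """d_ij = 1 - Spearman rank correlation of the two species' expression
    profiles (average ranks on ties); values lie in [0, 2]."""
    v = e.values
    if v.shape[1] < 3 or v.shape[0] < 2:
        raise ValueError("need at least 3 species and 2 genes")
    sd = v.std(axis=0, ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"constant expression column(s): {flat}; "
                         "Spearman correlation undefined")
    rho = stats.spearmanr(v.to_numpy(float)).statistic
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(pd.DataFrame(d, index=v.columns, columns=v.columns))


class _Node:
    __slots__ = ("label", "children", "tips", "support")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []   # list of (node, branch_length)
        self.tips = (frozenset([label]) if label is not None
                     else frozenset().union(*(c.tips for c, _ in self.children)))
        self.support = None

    def newick(self, with_support=False) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick(with_support)}:{bl:.10g}"
                         for c, bl in self.children)
        lab = ""
        if with_support and self.support is not None:
            lab = f"{self.support:.3f}"
        return f"({inner}){lab}"


@dataclass
class NJTree:
    """Unrooted NJ tree: a center node with >= 3 children."""

    center: _Node
    taxa: list[str]

    def newick(self, with_support: bool = False) -> str:
        return self.center.newick(with_support) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Internal-edge bipartitions, each canonicalized as the side not
        containing the first taxon."""
        full = frozenset(self.taxa)
        first = self.taxa[0]
        out = set()

        def visit(node):
            for child, _ in node.children:
                side = child.tips
                if 1 < len(side) < len(full) - 1:
                    out.add(side if first not in side else full - side)
                visit(child)

        visit(self.center)
        return out

    def internal_nodes(self):
        nodes = []

        def visit(node):
            for child, _ in node.children:
                if child.children:
                    nodes.append(child)
                visit(child)

        visit(self.center)
        return nodes


def neighbor_joining(d: DistanceMatrix) -> NJTree:
    """Saitou-Nei neighbor joining with the Q-matrix criterion and
    closed-form branch lengths."""
    D = d.values.to_numpy(float).copy()
    taxa = d.taxa
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [_Node(label=t) for t in taxa]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best, bi, bj = np.inf, -1, -1
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best - 1e-12:   # strict improvement: lowest-index tie-break
                    best, bi, bj = q, i, j
        li = 0.5 * D[bi, bj] + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = D[bi, bj] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = _Node(children=[(nodes[bi], li), (nodes[bj], lj)])
        dk = 0.5 * (D[bi, :] + D[bj, :] - D[bi, bj])
        keep = [k for k in range(m) if k not in (bi, bj)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dk[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
    # connect the last three through the central node (three-point formula)
    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    center = _Node(children=[(a, la), (b, lb), (c, lc)])
    return NJTree(center=center, taxa=taxa)


@dataclass
class PhylogramResult:
    tree: NJTree
    supports: dict   # bipartition (frozenset) -> support in [0, 1]
    B: int
    newick: str
    outgroup: str | None = None


def bootstrap_support(e: ExpressionMatrix, B: int = 1000, seed: int = 0,
                      outgroup: str | None = None) -> PhylogramResult:
    """NJ phylogram with gene-bootstrap branch support.

    Genes are resampled with replacement ``B`` times; the support of an
    internal edge is the fraction of replicate trees containing the same
    bipartition (branch lengths ignored).  Optionally rooted on a named
    outgroup for display.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if outgroup is not None and outgroup not in e.values.columns:
        raise ValueError(f"outgroup {outgroup!r} not among species")
    base = neighbor_joining(expression_distance(e))
    obs = base.bipartitions()
    counts = {b: 0 for b in obs}
    rng = np.random.default_rng(seed)
    g = e.values.shape[0]
    for _ in range(B):
        idx = rng.integers(0, g, size=g)
        rep = ExpressionMatrix(e.values.iloc[idx], stage=e.stage)
        reps = neighbor_joining(expression_distance(rep)).bipartitions()
        for b in obs:
            if b in reps:
                counts[b] += 1
    supports = {b: counts[b] / B for b in obs}
    # annotate internal nodes for newick output
    full = frozenset(base.taxa)
    first = base.taxa[0]
    for node in base.internal_nodes():
        side = node.tips
        key = side if first not in side else full - side
        if key in supports:
            node.support = supports[key]
    nwk = base.newick(with_support=True)
    if outgroup is not None:
        nwk = _root_on_outgroup(nwk, outgroup)
    return PhylogramResult(tree=base, supports=supports, B=B, newick=nwk,
                           outgroup=outgroup)


def _root_on_outgroup(newick: str, outgroup: str) -> str:
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick",
                          preserve_underscores=True)
    og = t.find_node_with_taxon_label(outgroup)
    t.reroot_at_edge(og.edge, update_bipartitions=False)
    return t.as_string(schema="newick", suppress_rooting=True).strip()
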