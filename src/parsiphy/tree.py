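"""Phylogenetic tree model, newick/NEXUS I/O and bipartition algebra.

Trees are node-based and may be rooted or unrooted; an unrooted tree is stored
anchored at an arbitrary internal node and all topology comparisons go through
canonical bipartition sets, which are anchor-independent.  Newick and NEXUS
serialization is delegated to dendropy; child order is canonicalized
(lexicographically by smallest descendant leaf) so output is byte-stable.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "TreeNode",
    "PhyloTree",
    "Bipartition",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "reroot_on_outgroup",
]


class TreeNode:
    __slots__ = ("label", "children", "parent", "length", "support", "annotations")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length
        self.support: float | None = None
        self.annotations: dict = {}

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def min_leaf(self) -> str:
        return min(n.label for n in self.leaves())


class PhyloTree:
    """A rooted or unrooted tree over uniquely labelled leaves."""

    def __init__(self, root: TreeNode, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        labels = [n.label for n in root.leaves()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        if any(lbl is None for lbl in labels):
            raise ValueError("unlabelled leaf")

    # -- basics -----------------------------------------------------------
    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(n.label for n in self.root.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def nodes(self) -> Iterator[TreeNode]:
        return self.root.walk()

    def postorder(self) -> list[TreeNode]:
        out = list(self.root.walk())
        out.reverse()
        return out

    def copy(self) -> "PhyloTree":
        def clone(n: TreeNode) -> TreeNode:
            c = TreeNode(n.label, n.length)
            c.support = n.support
            c.annotations = dict(n.annotations)
            for k in n.children:
                c.add(clone(k))
            return c

        return PhyloTree(clone(self.root), self.rooted)

    def canonicalize(self) -> "PhyloTree":
        """Sort children by smallest descendant leaf, in place; returns self."""
        order: dict[TreeNode, str] = {}
        for n in self.postorder():
            order[n] = n.label if n.is_leaf else min(order[c] for c in n.children)
        for n in self.nodes():
            n.children.sort(key=order.__getitem__)
        return self

    def find_clade(self, leaves: Iterable[str]) -> TreeNode | None:
        """Node whose descendant leaf set equals ``leaves`` exactly, if any."""
        target = frozenset(leaves)
        below: dict[TreeNode, frozenset[str]] = {}
        for n in self.postorder():
            below[n] = (
                frozenset({n.label})
                if n.is_leaf
                else frozenset().union(*(below[c] for c in n.children))
            )
            if below[n] == target:
                return n
        return None

    def __repr__(self) -> str:
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind}, {self.n_leaves} leaves>"


class Bipartition:
    """A canonical leaf split over a fixed taxon universe.

    The stored side is the smaller half (ties broken by lexicographically
    smallest member) so a split and its complement compare equal.  Trivial
    splits (singleton or full set) are rejected.
    """

    __slots__ = ("side", "universe")

    def __init__(self, side: Iterable[str], universe: Iterable[str]):
        side = frozenset(side)
        universe = frozenset(universe)
        if not side <= universe:
            raise ValueError("split side is not a subset of the universe")
        comp = universe - side
        if not side or not comp:
            raise ValueError("trivial split: one side is empty")
        if len(side) > len(comp) or (len(side) == len(comp) and min(side) > min(comp)):
            side = comp
        self.side = side
        self.universe = universe

    @property
    def complement(self) -> frozenset[str]:
        return self.universe - self.side

    def is_trivial(self) -> bool:
        return len(self.side) <= 1 or len(self.complement) <= 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self.side == other.side and self.universe == other.universe

    def __hash__(self) -> int:
        return hash((self.side, self.universe))

    def __repr__(self) -> str:
        inner = ",".join(sorted(self.side))
        return f"Bipartition({{{inner}}} | {len(self.complement)} others)"


# ---------------------------------------------------------------------------
# newick / NEXUS I/O (via dendropy)


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def conv(dnode) -> TreeNode:
        label = None
        if dnode.is_leaf():
            label = (dnode.taxon.label if dnode.taxon else dnode.label) or None
            if label is not None:
                label = label.replace(" ", "_")
        node = TreeNode(label, dnode.edge.length)
        if not dnode.is_leaf() and dnode.label is not None:
            try:
                node.support = float(dnode.label)
            except ValueError:
                node.annotations["label"] = dnode.label
        for ch in dnode.child_nodes():
            node.add(conv(ch))
        return node

    root = conv(dtree.seed_node)
    rooted = dtree.is_rooted if dtree.is_rooted is not None else len(root.children) == 2
    return PhyloTree(root, rooted=bool(rooted))


def _to_dendropy(tree: PhyloTree) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=ns)

    def build(node: TreeNode, dnode) -> None:
        for ch in node.children:
            dch = dnode.new_child()
            dch.edge.length = ch.length
            if ch.is_leaf:
                dch.taxon = ns.require_taxon(label=ch.label)
            else:
                if ch.support is not None:
                    sup = float(ch.support)
                    dch.label = str(int(sup)) if sup.is_integer() else str(sup)
                elif "label" in ch.annotations:
                    dch.label = ch.annotations["label"]
                build(ch, dch)

    dtree.seed_node.clear_child_nodes()
    build(tree.root, dtree.seed_node)
    dtree.is_rooted = tree.rooted
    return dtree


def parse_newick(text: str, universe: Iterable[str] | None = None) -> PhyloTree:
    """Parse a newick string (or the first tree of a NEXUS TREES block)."""
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    dtree = dendropy.Tree.get(
        data=text, schema=schema, suppress_internal_node_taxa=True
    )
    tree = _from_dendropy(dtree)
    if universe is not None:
        extra = tree.taxa - frozenset(universe)
        if extra:
            raise ValueError(f"leaf labels outside taxon universe: {sorted(extra)}")
    return tree


def write_newick(tree: PhyloTree, schema: str = "newick") -> str:
    """Canonical newick (or single-tree NEXUS) text; supports become labels."""
    dtree = _to_dendropy(tree.copy().canonicalize())
    txt = dtree.as_string(
        schema=schema,
        suppress_rooting=(schema == "newick"),
        unquoted_underscores=True,
    )
    return txt if schema == "nexus" else txt.strip() + "\n"


# ---------------------------------------------------------------------------
# bipartition algebra


def bipartitions(tree: PhyloTree) -> set[Bipartition]:
    """Non-trivial splits, one per internal edge (anchor/root independent)."""
    universe = tree.taxa
    below: dict[TreeNode, frozenset[str]] = {}
    out: set[Bipartition] = set()
    for n in tree.postorder():
        below[n] = (
            frozenset({n.label})
            if n.is_leaf
            else frozenset().union(*(below[c] for c in n.children))
        )
        if n is tree.root or n.is_leaf:
            continue
        side = below[n]
        if 1 < len(side) < len(universe) - 1:
            out.add(Bipartition(side, universe))
    return out


def to_undirected(tree: PhyloTree):
    """Undirected adjacency view: (adj, labels); a degree-2 root is suppressed."""
    adj: dict[int, set[int]] = {}
    labels: dict[int, str] = {}
    ids: dict[int, TreeNode] = {}

    def nid(n: TreeNode) -> int:
        ids[id(n)] = n
        return id(n)

    for n in tree.nodes():
        adj.setdefault(nid(n), set())
        if n.is_leaf:
            labels[nid(n)] = n.label
        for c in n.children:
            adj.setdefault(nid(c), set())
            adj[nid(n)].add(nid(c))
            adj[nid(c)].add(nid(n))
    r = id(tree.root)
    if len(adj[r]) == 2:
        u, v = adj[r]
        adj[u].discard(r)
        adj[v].discard(r)
        adj[u].add(v)
        adj[v].add(u)
        del adj[r]
    return adj, labels


def _grow(adj, labels, node: int, avoid: int) -> TreeNode:
    """Build the rooted subtree hanging off ``node``, looking away from ``avoid``."""
    t = TreeNode(labels.get(node))
    for nb in adj[node]:
        if nb != avoid:
            t.add(_grow(adj, labels, nb, node))
    return t


def reroot_on_outgroup(tree: PhyloTree, outgroup: Iterable[str]) -> PhyloTree:
    """Root an (un)rooted tree so the root separates outgroup from ingroup.

    If no single edge cleanly separates the outgroup, the edge minimizing the
    number of misplaced taxa is used and a warning is issued.  The unrooted
    bipartition set is unchanged by rooting.
    """
    outgroup = frozenset(tree_resolve(tree, outgroup))
    if not outgroup or not outgroup < tree.taxa:
        raise ValueError("outgroup must be a non-empty proper subset of the leaves")
    adj, labels = to_undirected(tree)

    # leaf set on the ``u`` side of each directed edge (u, v)
    def side_leaves(u: int, v: int, memo={}) -> frozenset[str]:
        out: set[str] = set()
        stack = [(u, v)]
        while stack:
            x, av = stack.pop()
            if x in labels:
                out.add(labels[x])
            for nb in adj[x]:
                if nb != av:
                    stack.append((nb, x))
        return frozenset(out)

    edges = {(u, v) for u in adj for v in adj[u] if u < v}
    best, best_score = None, None
    for u, v in edges:
        lu = side_leaves(u, v)
        score = min(len(lu ^ outgroup), len((tree.taxa - lu) ^ outgroup))
        if best_score is None or score < best_score:
            best, best_score = (u, v), score
    if best_score > 0:
        warnings.warn(
            f"outgroup is not monophyletic on any edge; rooting with "
            f"{best_score} misplaced taxa",
            stacklevel=2,
        )
    u, v = best
    root = TreeNode()
    su = _grow(adj, labels, u, v)
    sv = _grow(adj, labels, v, u)
    # outgroup side first, for stable reading
    if not frozenset(l.label for l in su.leaves()) & outgroup:
        su, sv = sv, su
    root.add(su)
    root.add(sv)
    return PhyloTree(root, rooted=True).canonicalize()


def tree_resolve(tree: PhyloTree, names: Iterable[str]) -> list[str]:
    """Resolve names against tree leaves, tolerating space/underscore variants."""
    from .matrix import resolve_taxon_name

    taxa = tree.taxa
    out = []
    for name in names:
        cand = resolve_taxon_name(name)
        if cand not in taxa:
            raise KeyError(f"taxon {name!r} not in tree")
        out.append(cand)
    return out
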