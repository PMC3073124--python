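"""Consensus trees and Bremer (decay) support.

Strict consensus keeps exactly the splits present in every input tree;
majority rule keeps those above a frequency threshold (> 0.5 guarantees
pairwise compatibility).  Both are built from canonical bipartition sets.

The Bremer index of a clade is the extra length needed before trees lacking
the clade appear: (shortest tree without the clade) - (overall minimum).  Two
estimators are provided: a converse-constraint heuristic search (trees
containing the clade are rejected during swapping) and, for small problems, a
complete suboptimal sweep via branch and bound, which is exact.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import pandas as pd

from .matrix import CharacterMatrix
from .search import SearchConfig, SearchResult, branch_and_bound, heuristic_search
from .tree import Bipartition, PhyloTree, TreeNode, bipartitions

__all__ = [
    "strict_consensus",
    "majority_rule",
    "bremer_support",
    "build_tree_from_splits",
]


def _check_universe(trees: Sequence[PhyloTree]) -> frozenset[str]:
    if not trees:
        raise ValueError("empty tree set")
    universe = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != universe:
            raise ValueError("trees have mismatched leaf sets")
    return universe


def build_tree_from_splits(
    splits: Iterable[Bipartition],
    universe: frozenset[str],
    frequencies: dict[Bipartition, float] | None = None,
) -> PhyloTree:
    """Assemble the (unrooted) tree containing a compatible split set."""
    anchor = min(universe)
    # represent each split by the side away from the anchor; these are nested
    sides = [
        ((bp.side if anchor not in bp.side else bp.complement), bp)
        for bp in splits
    ]
    sides.sort(key=lambda p: (-len(p[0]), tuple(sorted(p[0]))))
    root = TreeNode()
    node_of: dict[frozenset[str], TreeNode] = {}
    containers: list[tuple[frozenset[str], TreeNode]] = []
    for side, bp in sides:
        node = TreeNode()
        if frequencies is not None:
            node.support = frequencies[bp]
        parent = root
        best_size = None
        for other, onode in containers:
            if side <= other and (best_size is None or len(other) < best_size):
                parent, best_size = onode, len(other)
        parent.add(node)
        node_of[side] = node
        containers.append((side, node))
    for leaf in sorted(universe):
        parent = root
        best_size = None
        for side, node in containers:
            if leaf in side and (best_size is None or len(side) < best_size):
                parent, best_size = node, len(side)
        parent.add(TreeNode(leaf))
    return PhyloTree(root, rooted=False).canonicalize()


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree whose splits are exactly those shared by every input tree."""
    universe = _check_universe(trees)
    common = set(bipartitions(trees[0]))
    for t in trees[1:]:
        common &= bipartitions(t)
    return build_tree_from_splits(common, universe)


def majority_rule(trees: Sequence[PhyloTree], threshold: float = 0.5) -> PhyloTree:
    """Splits occurring in more than ``threshold`` of the trees, annotated
    with their frequencies as node support."""
    if not threshold >= 0.5:
        raise ValueError("threshold must be >= 0.5 for a compatible consensus")
    universe = _check_universe(trees)
    counts: Counter[Bipartition] = Counter()
    for t in trees:
        counts.update(bipartitions(t))
    keep = {bp: c / len(trees) for bp, c in counts.items() if c / len(trees) > threshold}
    return build_tree_from_splits(keep.keys(), universe, frequencies=keep)


# ---------------------------------------------------------------------------
# Bremer support


def _sweep_decay(
    m: CharacterMatrix, best_length: int, clade: Bipartition, max_slack: int = 12
) -> int:
    """Exact decay via complete enumeration of near-optimal trees (small n)."""
    for j in range(1, max_slack + 1):
        result = branch_and_bound(m, slack=j)
        lengths = result.replicate_log[0]["lengths"]
        best_without = None
        for L, tree in zip(lengths, result.trees):
            if clade not in bipartitions(tree):
                if best_without is None or L < best_without:
                    best_without = L
        if best_without is not None:
            return int(best_without - best_length)
    raise RuntimeError(f"decay exceeds the sweep limit of {max_slack}")


def bremer_support(
    m: CharacterMatrix,
    result: SearchResult,
    clades: Sequence[Bipartition] | None = None,
    method: str = "converse-constraint",
    cfg: SearchConfig | None = None,
) -> pd.DataFrame:
    """Decay index per clade of the strict consensus of ``result.trees``.

    Returns a table with one row per clade: its leaf list, the Bremer value,
    its occurrence frequency in the retained optimal trees, and whether the
    value is exact (complete sweep) or a heuristic upper estimate.
    """
    if method not in ("converse-constraint", "suboptimal-sweep"):
        raise ValueError(f"unknown Bremer method {method!r}")
    consensus = strict_consensus(result.trees)
    consensus_splits = bipartitions(consensus)
    if clades is None:
        clades = sorted(consensus_splits, key=lambda bp: sorted(bp.side))
    rows = []
    for clade in clades:
        in_any = any(clade in bipartitions(t) for t in result.trees)
        if not in_any:
            raise ValueError(f"clade {sorted(clade.side)} absent from every retained tree")
        freq = sum(clade in bipartitions(t) for t in result.trees) / len(result.trees)
        if method == "suboptimal-sweep":
            k = _sweep_decay(m, result.best_length, clade)
            exact = True
        else:
            sub_cfg = cfg or SearchConfig(replicates=3, seed=result.config.seed if result.config else 0)
            constrained = heuristic_search(m, sub_cfg, forbid=clade, collect=False)
            k = int(constrained.best_length - result.best_length)
            exact = False
        rows.append(
            {
                "clade": ",".join(sorted(clade.side)),
                "size": len(clade.side),
                "bremer": k,
                "frequency": freq,
                "exact": exact,
            }
        )
    return pd.DataFrame(rows)
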