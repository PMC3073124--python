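"""Synthetic morphological matrices with known generating history.

The generator emulates the statistical shape of a discrete morphology study:
unordered k-state characters (k <= 4) evolved on a known tree, plus the three
corruption modes real matrices show -- missing cells ('?'), inapplicable
cells ('-') and occasional polymorphic cells.  Each character starts from a
uniform root state and accrues a Poisson number of changes placed uniformly
over branches (change placement deliberately ignores branch lengths: morphology
step counts, not rates, are what the downstream analysis consumes); every
change picks a uniformly random different state.  The true per-branch change
log is returned so mapping and recovery can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import CellKind, CharacterMatrix, StateCell
from .tree import PhyloTree, TreeNode

__all__ = ["SimConfig", "simulate_tree", "simulate_matrix", "TrueChange"]


@dataclass(frozen=True)
class SimConfig:
    n_taxa: int = 8
    n_char: int = 50
    states_per_char: int = 3
    tree_model: str = "yule"  # or 'uniform'
    expected_changes: float = 1.0  # Poisson mean per character over the tree
    missing_frac: float = 0.0
    inapplicable_frac: float = 0.0
    polymorphic_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3 or self.n_char < 1:
            raise ValueError("need n_taxa >= 3 and n_char >= 1")
        if not 2 <= self.states_per_char <= 4:
            raise ValueError("states_per_char must be between 2 and 4")
        fracs = (self.missing_frac, self.inapplicable_frac, self.polymorphic_frac)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("corruption fractions must lie in [0,1] and sum <= 1")
        if self.tree_model not in ("yule", "uniform"):
            raise ValueError("tree_model must be 'yule' or 'uniform'")


@dataclass(frozen=True)
class TrueChange:
    char_index: int  # 1-based
    clade: frozenset[str]  # leaves below the branch carrying the change
    from_state: int
    to_state: int


def simulate_tree(cfg: SimConfig) -> PhyloTree:
    """Random rooted binary tree over taxa t1..tN.

    'yule' splits a uniformly chosen extant tip at each step (the discrete
    Yule/pure-birth topology process); 'uniform' draws uniformly from all
    labelled rooted topologies by random edge insertion.
    """
    rng = np.random.default_rng(cfg.seed)
    names = [f"t{i + 1}" for i in range(cfg.n_taxa)]
    if cfg.tree_model == "yule":
        root = TreeNode()
        first, second = TreeNode(names[0]), TreeNode(names[1])
        root.add(first)
        root.add(second)
        tips = [first, second]
        for name in names[2:]:
            tip = tips[rng.integers(len(tips))]
            tip.children = []
            left, right = TreeNode(tip.label), TreeNode(name)
            tip.label = None
            tip.add(left)
            tip.add(right)
            tips.remove(tip)
            tips += [left, right]
        return PhyloTree(root, rooted=True).canonicalize()
    # uniform: insert each new tip on a uniformly chosen edge
    root = TreeNode()
    root.add(TreeNode(names[0]))
    root.add(TreeNode(names[1]))
    for name in names[2:]:
        edges = [n for n in root.walk() if n.parent is not None]
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = TreeNode()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        mid.add(TreeNode(name))
    return PhyloTree(root, rooted=True).canonicalize()


def simulate_matrix(
    tree: PhyloTree, cfg: SimConfig
) -> tuple[CharacterMatrix, list[TrueChange]]:
    """Evolve characters on ``tree`` and corrupt cells per the config."""
    rng = np.random.default_rng(cfg.seed + 1)
    k = cfg.states_per_char
    taxa = sorted(tree.taxa)
    nodes = list(tree.nodes())  # preorder: parents first
    branches = [n for n in nodes if n.parent is not None]
    below: dict[int, frozenset[str]] = {}
    for n in tree.postorder():
        below[id(n)] = (
            frozenset({n.label})
            if n.is_leaf
            else frozenset().union(*(below[id(c)] for c in n.children))
        )

    columns = np.zeros((len(taxa), cfg.n_char), dtype=np.int64)
    log: list[TrueChange] = []
    tindex = {t: i for i, t in enumerate(taxa)}
    for j in range(cfg.n_char):
        state: dict[int, int] = {id(tree.root): int(rng.integers(k))}
        n_changes = rng.poisson(cfg.expected_changes)
        hit = [int(rng.integers(len(branches))) for _ in range(n_changes)]
        changes_on: dict[int, list[int]] = {}
        for b in hit:
            changes_on.setdefault(b, []).append(b)
        for bi, node in enumerate(branches):
            s = state[id(node.parent)]
            for _ in changes_on.get(bi, ()):
                new = int(rng.integers(k - 1))
                new = new if new < s else new + 1
                log.append(
                    TrueChange(j + 1, below[id(node)], s, new)
                )
                s = new
            state[id(node)] = s
        for leaf in tree.root.leaves():
            columns[tindex[leaf.label], j] = state[id(leaf)]

    cells: list[list[StateCell]] = []
    u = rng.random((len(taxa), cfg.n_char))
    for i, taxon in enumerate(taxa):
        row = []
        for j in range(cfg.n_char):
            draw = u[i, j]
            if draw < cfg.missing_frac:
                row.append(StateCell(CellKind.MISSING, raw="?"))
            elif draw < cfg.missing_frac + cfg.inapplicable_frac:
                row.append(StateCell(CellKind.INAPPLICABLE, raw="-"))
            elif draw < cfg.missing_frac + cfg.inapplicable_frac + cfg.polymorphic_frac:
                true = int(columns[i, j])
                other = int(rng.integers(k - 1))
                other = other if other < true else other + 1
                pair = frozenset({true, other})
                row.append(StateCell(CellKind.POLYMORPHIC, pair))
            else:
                row.append(StateCell.determinate(int(columns[i, j])))
        cells.append(row)
    matrix = CharacterMatrix(taxa, cells, provenance=f"simulated(seed={cfg.seed})")
    return matrix, log
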