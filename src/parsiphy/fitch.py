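"""Fitch optimization for unordered multistate characters.

State sets are bitmasks (uint8; state *s* is bit ``1 << s``), so the Fitch
combine step is an AND, falling back to OR (one extra step) when the
intersection is empty.  The bit-parallel implementation vectorizes the combine
across all characters with numpy; a scalar per-character implementation over
Python sets serves as the reference the fast path must reproduce exactly.

Per-character bounds under unordered costs:

* ``m_i`` -- minimum conceivable steps: (number of distinct determinate states
  observed) - 1, floored at 0;
* ``g_i`` -- maximum steps on any tree (attained on the star tree): number of
  taxa with a determinate cell minus the count of the most frequent state.

Ensemble statistics over a tree of total length S: ``CI = M/S`` and
``RI = (G-S)/(G-M)`` with ``M = sum m_i`` and ``G = sum g_i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .matrix import CellKind, CharacterMatrix, informative_characters
from .tree import PhyloTree, to_undirected

__all__ = [
    "FitchScore",
    "EnsembleIndices",
    "fitch_length",
    "fitch_length_scalar",
    "char_bounds",
    "ensemble_indices",
    "ancestral_state_sets",
    "character_score_table",
    "round3",
]


def round3(x: float) -> float:
    """Half-up rounding to 3 decimals (reporting precision)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FitchScore:
    total: int
    per_char: np.ndarray  # int64[n_char]


@dataclass(frozen=True)
class EnsembleIndices:
    S: int
    M: int
    G: int
    ci: float | None
    ri: float | None
    rc: float | None
    variant: str  # 'all' or 'informative'
    ci_defined: bool
    ri_defined: bool


# ---------------------------------------------------------------------------
# tree length


def _adjacency(tree: PhyloTree | tuple, taxa: list[str]):
    """Normalize input to (adj: dict[int, list[int]], leaf_row: dict[int, int])."""
    if isinstance(tree, PhyloTree):
        missing = tree.taxa - set(taxa)
        if missing:
            raise KeyError(f"tree leaves without a matrix row: {sorted(missing)}")
        adj, labels = to_undirected(tree)
        row = {nid: taxa.index(lbl) for nid, lbl in labels.items()}
        return {k: list(v) for k, v in adj.items()}, row
    adj, row = tree
    return adj, row


def fitch_length(
    tree: PhyloTree,
    m: CharacterMatrix,
    X: np.ndarray | None = None,
) -> FitchScore:
    """Minimum unordered state changes of every character on ``tree``.

    The length is a property of the unrooted topology: rooted and unrooted
    versions of the same tree score identically.  ``X`` may carry precomputed
    effective state sets (e.g. under a non-default gap policy).
    """
    if X is None:
        X = m.state_sets()
    adj, row = _adjacency(tree, m.taxa)
    if len(adj) == 1:  # single leaf
        return FitchScore(0, np.zeros(m.n_char, dtype=np.int64))

    anchor = next(nid for nid in adj if nid in row)
    root = adj[anchor][0]
    parent = {root: anchor}
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for w in adj[v]:
            if w != parent[v]:
                parent[w] = v
                stack.append(w)

    steps = np.zeros(X.shape[1], dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    for v in reversed(order):
        kids = [w for w in adj[v] if w != parent[v]]
        s = X[row[v]] if v in row else None
        for k in kids:
            if s is None:
                s = sets[k]
                continue
            inter = s & sets[k]
            empty = inter == 0
            steps += empty
            s = np.where(empty, s | sets[k], inter)
        sets[v] = s
    inter = sets[root] & X[row[anchor]]
    steps = steps + (inter == 0)
    return FitchScore(int(steps.sum()), steps)


def fitch_length_scalar(tree: PhyloTree, m: CharacterMatrix) -> FitchScore:
    """Reference implementation: per-character Fitch over Python sets."""
    adj, row = _adjacency(tree, m.taxa)
    n_char = m.n_char
    if len(adj) == 1:
        return FitchScore(0, np.zeros(n_char, dtype=np.int64))
    X = m.state_sets()
    leafsets = {
        nid: [
            {s for s in range(8) if X[r, j] >> s & 1} for j in range(n_char)
        ]
        for nid, r in row.items()
    }
    anchor = next(nid for nid in adj if nid in row)
    root = adj[anchor][0]
    parent = {root: anchor}
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for w in adj[v]:
            if w != parent[v]:
                parent[w] = v
                stack.append(w)
    per_char = np.zeros(n_char, dtype=np.int64)
    for j in range(n_char):
        sets: dict[int, set] = {}
        for v in reversed(order):
            kids = [w for w in adj[v] if w != parent[v]]
            s = set(leafsets[v][j]) if v in leafsets else None
            for k in kids:
                if s is None:
                    s = sets[k]
                    continue
                inter = s & sets[k]
                if inter:
                    s = inter
                else:
                    per_char[j] += 1
                    s = s | sets[k]
            sets[v] = s
        if not sets[root] & leafsets[anchor][j]:
            per_char[j] += 1
    return FitchScore(int(per_char.sum()), per_char)


# ---------------------------------------------------------------------------
# bounds and ensemble indices


def char_bounds(m: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-character (min steps m_i, star-tree max steps g_i).

    Ambiguous/missing/inapplicable cells contribute to neither tally; a column
    with no determinate observation has m_i = g_i = 0.
    """
    mins = np.zeros(m.n_char, dtype=np.int64)
    maxs = np.zeros(m.n_char, dtype=np.int64)
    for j in range(m.n_char):
        counts: dict[int, int] = {}
        for row in m.cells:
            if row[j].kind is CellKind.DETERMINATE:
                (s,) = row[j].states
                counts[s] = counts.get(s, 0) + 1
        if counts:
            mins[j] = len(counts) - 1
            maxs[j] = sum(counts.values()) - max(counts.values())
    return mins, maxs


def ensemble_indices(
    S: int, m: CharacterMatrix, variant: str = "all"
) -> EnsembleIndices:
    """Ensemble CI/RI/RC at observed total length ``S``.

    ``variant='all'`` sums bounds over every character (the convention that
    reproduces the packaged study's printed values); ``variant='informative'``
    restricts M and G — and the share of S attributable to uninformative
    characters — to parsimony-informative characters.  For the informative
    variant S must be the per-character total over informative characters
    (pass the full-matrix S only with variant='all').
    """
    mins, maxs = char_bounds(m)
    if variant == "all":
        M, G = int(mins.sum()), int(maxs.sum())
    elif variant == "informative":
        idx = np.array(informative_characters(m), dtype=int) - 1
        M, G = int(mins[idx].sum()), int(maxs[idx].sum())
    else:
        raise ValueError("variant must be 'all' or 'informative'")
    ci_defined = S > 0
    ci = M / S if ci_defined else 1.0
    ri_defined = G != M
    ri = (G - S) / (G - M) if ri_defined else None
    rc = ci * ri if (ci is not None and ri is not None) else None
    return EnsembleIndices(
        S=S, M=M, G=G, ci=ci, ri=ri, rc=rc,
        variant=variant, ci_defined=ci_defined, ri_defined=ri_defined,
    )


# ---------------------------------------------------------------------------
# ancestral state sets (rooted reconstruction machinery)


@dataclass(frozen=True)
class AncestralStates:
    """Fitch preliminary (down-pass) and final (MPR up-pass) sets per node."""

    prelim: dict[int, frozenset[int]]  # keyed by id(node)
    final: dict[int, frozenset[int]]


def ancestral_state_sets(
    tree: PhyloTree, m: CharacterMatrix, char_index: int
) -> AncestralStates:
    """State-set reconstruction for one 1-based character on a rooted tree.

    Leaves carry their effective state sets.  The up-pass applies the
    standard most-parsimonious-reconstruction finalization; at polytomies each
    child is finalized independently against the parent's final set.
    """
    if not tree.rooted:
        raise ValueError("ancestral reconstruction requires a rooted tree")
    j = char_index - 1
    X = m.state_sets()
    bits = lambda mask: frozenset(s for s in range(8) if mask >> s & 1)

    prelim: dict[int, frozenset[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            prelim[id(node)] = bits(X[m.taxa.index(node.label), j])
            continue
        s = None
        for c in node.children:
            cs = prelim[id(c)]
            if s is None:
                s = cs
            else:
                s = (s & cs) or (s | cs)
        prelim[id(node)] = s

    final: dict[int, frozenset[int]] = {id(tree.root): prelim[id(tree.root)]}
    for node in tree.nodes():
        fu = final[id(node)]
        for c in node.children:
            pv = prelim[id(c)]
            if c.is_leaf:
                final[id(c)] = (pv & fu) or pv
            elif fu <= pv:
                final[id(c)] = fu
            else:
                kid_sets = [prelim[id(k)] for k in c.children]
                inter_all = frozenset.intersection(*kid_sets)
                union_all = frozenset.union(*kid_sets)
                if inter_all:
                    final[id(c)] = pv | (fu & union_all)
                else:
                    final[id(c)] = pv | fu
    return AncestralStates(prelim=prelim, final=final)


# ---------------------------------------------------------------------------
# reporting


def character_score_table(tree: PhyloTree, m: CharacterMatrix) -> pd.DataFrame:
    """Per-character score table: index, name, s, m, g, ci, ri."""
    score = fitch_length(tree, m)
    mins, maxs = char_bounds(m)
    names = (
        [d.name for d in m.defs]
        if m.defs is not None
        else [f"char{j + 1}" for j in range(m.n_char)]
    )
    s = score.per_char
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(s > 0, mins / np.maximum(s, 1), np.nan)
        denom = maxs - mins
        ri = np.where(denom > 0, (maxs - s) / np.maximum(denom, 1), np.nan)
    return pd.DataFrame(
        {
            "char_index": np.arange(1, m.n_char + 1),
            "name": names,
            "steps": s,
            "min_steps": mins,
            "max_steps": maxs,
            "ci": ci,
            "ri": ri,
        }
    )
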