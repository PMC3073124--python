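"""Character-state mapping onto trees: synapomorphies, ACCTRAN/DELTRAN,
homoplasy flags and zero-length-branch collapsing.

The machinery is a unit-cost Sankoff dynamic program (states are cheap: at
most five per character, the four symbols plus an optional gap state).  For a
node ``v`` with parent ``p`` it yields

* ``down[v][s]``  -- minimum steps within the subtree of ``v`` given state s;
* ``A[v][s]``     -- minimum steps in the rest of the tree given ``p`` = s;

so the minimum length forcing states (s_p, s_v) across the branch is
``A[v][s_p] + [s_p != s_v] + down[v][s_v]``.  This answers, exactly, whether a
branch carries a change in *some* most-parsimonious reconstruction (its
minimum length over MPRs) or in *every* one (unambiguous changes), and drives
the PAUP-like collapsing of branches whose minimum length is zero.

ACCTRAN resolves ties toward the root (prefers making the change on the
current branch), DELTRAN toward the tips (prefers keeping the parent state);
both are exact backtraces of the DP, so each character maps exactly its Fitch
step count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitch import char_bounds, fitch_length
from .matrix import CharacterMatrix
from .tree import Bipartition, PhyloTree, TreeNode

__all__ = [
    "SynapomorphyEntry",
    "SynapomorphyMap",
    "map_synapomorphies",
    "clade_diagnostics",
    "collapse_zero_length_branches",
]

_K = 5  # bitmask width: states 0-3 plus the optional extra gap state
_INF = np.int32(1 << 20)


@dataclass(frozen=True)
class SynapomorphyEntry:
    clade: frozenset[str]  # leaves below the branch the change sits on
    char_index: int  # 1-based
    char_name: str
    from_state: int
    to_state: int
    resolution: str  # 'acctran' | 'deltran' | 'unambiguous'
    homoplastic: bool


@dataclass
class SynapomorphyMap:
    entries: list[SynapomorphyEntry]
    resolution: str
    tree: PhyloTree
    per_char_steps: np.ndarray
    homoplastic_chars: frozenset[int]

    @property
    def total_changes(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "clade": ",".join(sorted(e.clade)),
                    "char_index": e.char_index,
                    "char_name": e.char_name,
                    "change": f"{e.from_state}->{e.to_state}",
                    "resolution": e.resolution,
                    "homoplastic": e.homoplastic,
                }
                for e in self.entries
            ]
        )


# ---------------------------------------------------------------------------
# Sankoff tables


def _sankoff_tables(tree: PhyloTree, m: CharacterMatrix, X: np.ndarray | None = None):
    if X is None:
        X = m.state_sets()
    nodes = tree.postorder()  # children precede parents
    idx = {id(n): i for i, n in enumerate(nodes)}
    C = m.n_char
    down = np.full((len(nodes), C, _K), _INF, dtype=np.int32)
    row_of = {t: i for i, t in enumerate(m.taxa)}
    for i, node in enumerate(nodes):
        if node.is_leaf:
            mask = X[row_of[node.label]]
            for s in range(_K):
                allowed = (mask >> s) & 1 == 1
                down[i, allowed, s] = 0
        else:
            acc = np.zeros((C, _K), dtype=np.int64)
            for c in node.children:
                d = down[idx[id(c)]]
                mn = d.min(axis=1, keepdims=True)
                acc += np.minimum(d, mn + 1)
            down[i] = np.minimum(acc, _INF)
    A = np.zeros((len(nodes), C, _K), dtype=np.int32)
    up = np.zeros((len(nodes), C, _K), dtype=np.int32)
    for node in tree.nodes():  # preorder: parents precede children
        i = idx[id(node)]
        for c in node.children:
            j = idx[id(c)]
            out = up[i].astype(np.int64).copy()
            for sib in node.children:
                if sib is c:
                    continue
                d = down[idx[id(sib)]]
                mn = d.min(axis=1, keepdims=True)
                out += np.minimum(d, mn + 1)
            out = np.minimum(out, _INF)
            A[j] = out
            mnA = out.min(axis=1, keepdims=True)
            up[j] = np.minimum(out, mnA + 1)
    return nodes, idx, down, A


def _branch_change_bounds(tree: PhyloTree, m: CharacterMatrix, X=None):
    """Per non-root node: per-character (min, max possible) changes on the
    branch above it, over all most-parsimonious reconstructions."""
    nodes, idx, down, A = _sankoff_tables(tree, m, X)
    root_i = idx[id(tree.root)]
    tstar = down[root_i].min(axis=1)  # (C,)
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    eye = np.eye(_K, dtype=np.int32)
    for node in tree.nodes():
        if node.parent is None:
            continue
        j = idx[id(node)]
        a, d = A[j].astype(np.int64), down[j].astype(np.int64)
        zero_possible = (a + d).min(axis=1) == tstar
        pair = a[:, :, None] + d[:, None, :] + (1 - eye)[None, :, :]
        change_possible = pair.min(axis=(1, 2)) == tstar
        min_changes = (~zero_possible).astype(np.int64)
        max_changes = change_possible.astype(np.int64)
        out[id(node)] = (min_changes, max_changes)
    return out


# ---------------------------------------------------------------------------
# assignments


def _backtrace(tree, m, X, prefer_change: bool):
    """Exact DP backtrace; ties resolved toward change (ACCTRAN) or stasis
    (DELTRAN).  Returns {id(node): state array (C,)}."""
    nodes, idx, down, _A = _sankoff_tables(tree, m, X)
    C = m.n_char
    states: dict[int, np.ndarray] = {}
    root_i = idx[id(tree.root)]
    states[id(tree.root)] = down[root_i].argmin(axis=1)
    cols = np.arange(C)
    for node in tree.nodes():
        sp = states[id(node)]
        for c in node.children:
            d = down[idx[id(c)]].astype(np.int64)
            stay = d[cols, sp]
            dm = d.copy()
            dm[cols, sp] = _INF
            change = dm.min(axis=1) + 1
            chstate = dm.argmin(axis=1)
            if prefer_change:
                take = change <= stay
            else:
                take = change < stay
            states[id(c)] = np.where(take, chstate, sp)
    return states


def map_synapomorphies(
    tree: PhyloTree,
    m: CharacterMatrix,
    resolution: str = "acctran",
    X: np.ndarray | None = None,
) -> SynapomorphyMap:
    """Assign character-state changes to branches of a rooted tree.

    ``resolution`` is ``'acctran'`` (changes pushed rootward, favouring
    reversal), ``'deltran'`` (tipward, favouring parallelism) or
    ``'unambiguous'`` (only branches that change in every most-parsimonious
    reconstruction; states reported from the ACCTRAN resolution).  Characters
    whose observed steps exceed their conceivable minimum are flagged
    homoplastic.
    """
    if not tree.rooted:
        raise ValueError("synapomorphy mapping requires a rooted tree")
    if resolution not in ("acctran", "deltran", "unambiguous"):
        raise ValueError(f"unknown resolution {resolution!r}")
    if any(len(n.children) > 2 for n in tree.nodes()) and resolution != "unambiguous":
        warnings.warn(
            "tree contains polytomies; changes are mapped on the polytomous "
            "branches as given",
            stacklevel=2,
        )
    if X is None:
        X = m.state_sets()
    score = fitch_length(tree, m, X=X)
    mins, _ = char_bounds(m)
    homoplastic = frozenset(
        int(j + 1) for j in range(m.n_char) if score.per_char[j] > mins[j]
    )
    names = (
        {d.index: d.name for d in m.defs}
        if m.defs is not None
        else {j + 1: f"char{j + 1}" for j in range(m.n_char)}
    )

    states = _backtrace(tree, m, X, prefer_change=(resolution != "deltran"))
    forced = (
        _branch_change_bounds(tree, m, X) if resolution == "unambiguous" else None
    )

    below: dict[int, frozenset[str]] = {}
    for n in tree.postorder():
        below[id(n)] = (
            frozenset({n.label})
            if n.is_leaf
            else frozenset().union(*(below[id(c)] for c in n.children))
        )

    entries: list[SynapomorphyEntry] = []
    for node in tree.nodes():
        for c in node.children:
            sp, sv = states[id(node)], states[id(c)]
            for j in range(m.n_char):
                if sp[j] == sv[j]:
                    continue
                if forced is not None and not forced[id(c)][0][j]:
                    continue  # branch can be changeless in some MPR
                entries.append(
                    SynapomorphyEntry(
                        clade=below[id(c)],
                        char_index=j + 1,
                        char_name=names[j + 1],
                        from_state=int(sp[j]),
                        to_state=int(sv[j]),
                        resolution=resolution,
                        homoplastic=(j + 1) in homoplastic,
                    )
                )
    return SynapomorphyMap(
        entries=entries,
        resolution=resolution,
        tree=tree,
        per_char_steps=score.per_char,
        homoplastic_chars=homoplastic,
    )


def clade_diagnostics(
    smap: SynapomorphyMap, clade: Bipartition | frozenset[str]
) -> list[SynapomorphyEntry]:
    """Stem-branch changes diagnosing a clade of the mapped tree."""
    side = clade.side if isinstance(clade, Bipartition) else frozenset(clade)
    if smap.tree.find_clade(side) is None:
        raise KeyError(f"clade {sorted(side)} not present in the mapped tree")
    return [e for e in smap.entries if e.clade == side]


# ---------------------------------------------------------------------------
# collapsing


def collapse_zero_length_branches(
    tree: PhyloTree, m: CharacterMatrix, criterion: str = "min", X=None
) -> PhyloTree:
    """Collapse internal branches whose length can (min) or must (max) be 0.

    ``criterion='min'`` collapses a branch when some most-parsimonious
    reconstruction puts no change on it (PAUP-like default); ``'max'``
    collapses only branches that are changeless in every reconstruction.
    """
    if criterion not in ("min", "max"):
        raise ValueError("criterion must be 'min' or 'max'")
    work = tree.copy()
    bounds = _branch_change_bounds(work, m, X)
    which = 0 if criterion == "min" else 1
    for node in list(work.nodes()):
        if node.parent is None or node.is_leaf:
            continue
        mn, mx = bounds[id(node)]
        ref = mn if which == 0 else mx
        if int(ref.sum()) == 0:
            parent = node.parent
            i = parent.children.index(node)
            parent.children[i : i + 1] = node.children
            for c in node.children:
                c.parent = parent
    return work.canonicalize()
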