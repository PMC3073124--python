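"""Most-parsimonious tree search.

Three layers:

* :func:`stepwise_addition` -- greedy seeded random-addition starting trees;
* :func:`heuristic_search`  -- NNI/SPR/TBR branch swapping with replicates,
  plateau drift over equal-length trees (tabu on canonical topologies) and a
  retained-tree buffer of distinct optimal topologies;
* :func:`branch_and_bound`  -- provably complete search for small taxon sets,
  optionally keeping all trees within ``slack`` steps of the optimum (used by
  the decay-index sweep).

Plateau drift exists because strict descent TBR reliably sticks a few steps
above the optimum on real morphological matrices: the equal-length plateaus
are large and must be crossed, which mirrors how PAUP*'s swapping over all
retained trees behaves in practice.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .matrix import CharacterMatrix
from .tree import Bipartition, PhyloTree, TreeNode, to_undirected

__all__ = [
    "SearchConfig",
    "SearchResult",
    "FlatTree",
    "stepwise_addition",
    "heuristic_search",
    "branch_and_bound",
]

BNB_GUARD = 12  # branch_and_bound refuses larger problems


@dataclass
class SearchConfig:
    replicates: int = 10
    seed: int = 0
    swap: str = "tbr"  # 'nni' | 'spr' | 'tbr'
    maxtrees: int = 200
    auto_grow: bool = False
    collapse_policy: str = "collapse-zero-length-min"  # or 'none', '...-max'
    steepest_descent: bool = False
    patience: int = 1500  # plateau-drift steps without improvement before giving up

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.maxtrees < 1:
            raise ValueError("replicates and maxtrees must be >= 1")
        if self.swap not in ("nni", "spr", "tbr"):
            raise ValueError(f"unknown swap mode {self.swap!r}")


@dataclass
class SearchResult:
    best_length: int
    trees: list[PhyloTree]  # retained topologies after the collapse policy
    hit_maxtrees: bool
    replicate_log: list[dict]
    config: SearchConfig | None = None
    n_distinct_binary: int = 0
    binary_trees: list[PhyloTree] = field(default_factory=list)  # uncollapsed


# ---------------------------------------------------------------------------
# flat tree representation


class FlatTree:
    """Unrooted binary tree as neighbour tables over 2n-2 node slots."""

    __slots__ = ("n", "nbr", "deg", "next_internal")

    def __init__(self, n: int):
        if n < 3:
            raise ValueError("need at least 3 taxa")
        N = 2 * n - 2
        self.n = n
        self.nbr = np.full((N, 3), -1, dtype=np.int32)
        self.deg = np.zeros(N, dtype=np.int32)
        self.next_internal = n

    @classmethod
    def star3(cls, n: int, a: int, b: int, c: int) -> "FlatTree":
        t = cls(n)
        hub = t.next_internal
        t.next_internal += 1
        for leaf in (a, b, c):
            t.add_edge(hub, leaf)
        return t

    def copy(self) -> "FlatTree":
        t = FlatTree.__new__(FlatTree)
        t.n = self.n
        t.nbr = self.nbr.copy()
        t.deg = self.deg.copy()
        t.next_internal = self.next_internal
        return t

    def add_edge(self, a: int, b: int) -> None:
        self.nbr[a, self.deg[a]] = b
        self.deg[a] += 1
        self.nbr[b, self.deg[b]] = a
        self.deg[b] += 1

    def remove_edge(self, a: int, b: int) -> None:
        for x, y in ((a, b), (b, a)):
            row = self.nbr[x]
            for t in range(self.deg[x]):
                if row[t] == y:
                    row[t] = row[self.deg[x] - 1]
                    row[self.deg[x] - 1] = -1
                    self.deg[x] -= 1
                    break
            else:
                raise ValueError(f"edge {a}-{b} not present")

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for a in range(self.nbr.shape[0]):
            for t in range(self.deg[a]):
                b = self.nbr[a, t]
                if a < b:
                    out.append((a, int(b)))
        return out

    def attach_leaf(self, leaf: int, edge: tuple[int, int]) -> None:
        """Insert ``leaf`` by subdividing ``edge`` with a fresh internal node."""
        u, v = edge
        w = self.next_internal
        self.next_internal += 1
        self.remove_edge(u, v)
        self.add_edge(w, u)
        self.add_edge(w, v)
        self.add_edge(w, leaf)

    def apply_tbr(self, move: tuple[int, int, int, int, int, int]) -> None:
        """Apply a TBR move recorded by the scan kernel (see _kernels)."""
        a, b, u1, v1, u2, v2 = move
        self.remove_edge(a, b)
        for x, u, v in ((a, u1, v1), (b, u2, v2)):
            if x >= self.n:
                p, q = (int(self.nbr[x, t]) for t in range(2))
                self.remove_edge(x, p)
                self.remove_edge(x, q)
                self.add_edge(p, q)
                self.remove_edge(u, v)
                self.add_edge(x, u)
                self.add_edge(x, v)
        self.add_edge(a, b)

    def length(self, X: np.ndarray) -> int:
        return int(_kernels.tree_length(self.nbr, self.deg, self.n, X))

    # -- topology bookkeeping --------------------------------------------
    def _below_masks(self):
        anchor = next(v for v in range(self.n) if self.deg[v] > 0)
        root = int(self.nbr[anchor, 0])
        parent = {root: anchor}
        order = [root]
        stack = [root]
        while stack:
            v = stack.pop()
            for t in range(self.deg[v]):
                w = int(self.nbr[v, t])
                if w != parent[v]:
                    parent[w] = v
                    order.append(w)
                    stack.append(w)
        below: dict[int, int] = {}
        for v in reversed(order):
            if v < self.n:
                below[v] = 1 << v
            else:
                acc = 0
                for t in range(self.deg[v]):
                    w = int(self.nbr[v, t])
                    if w != parent[v]:
                        acc |= below[w]
                below[v] = acc
        return anchor, below, parent, order

    def topology_key(self) -> frozenset[int]:
        """Canonical split set: leaf bitmasks of the side away from the anchor."""
        anchor, below, parent, order = self._below_masks()
        present = 0
        for v in range(self.n):
            if self.deg[v] > 0:
                present |= 1 << v
        keys = set()
        for v in order:
            if v >= self.n:
                mask = below[v]
                nbits = mask.bit_count()
                if 2 <= nbits <= present.bit_count() - 2:
                    keys.add(mask)
        return frozenset(keys)

    def contains_split(self, mask: int) -> bool:
        anchor, below, parent, order = self._below_masks()
        present = 0
        for v in range(self.n):
            if self.deg[v] > 0:
                present |= 1 << v
        target = mask if not (mask >> anchor) & 1 else present ^ mask
        return any(below[v] == target for v in order if v >= self.n)

    # -- conversions ------------------------------------------------------
    def to_phylo(self, taxa: list[str]) -> PhyloTree:
        anchor, below, parent, order = self._below_masks()
        nodes: dict[int, TreeNode] = {}
        root_id = int(self.nbr[anchor, 0])
        for v in order:
            nodes[v] = TreeNode(taxa[v] if v < self.n else None)
        for v in order:
            if v != root_id:
                nodes[parent[v]].add(nodes[v])
        nodes[root_id].add(TreeNode(taxa[anchor]))
        return PhyloTree(nodes[root_id], rooted=False).canonicalize()

    @classmethod
    def from_phylo(cls, tree: PhyloTree, taxa: list[str]) -> "FlatTree":
        adj, labels = to_undirected(tree)
        index = {lbl: i for i, lbl in enumerate(taxa)}
        n = len(taxa)
        t = cls(n)
        ids: dict[int, int] = {}
        for nid in adj:
            if nid in labels:
                ids[nid] = index[labels[nid]]
            else:
                ids[nid] = t.next_internal
                t.next_internal += 1
        for nid, nbs in adj.items():
            for other in nbs:
                if nid < other:
                    t.add_edge(ids[nid], ids[other])
        return t


def split_mask(side: frozenset[str], taxa: list[str]) -> int:
    mask = 0
    for name in side:
        mask |= 1 << taxa.index(name)
    return mask


# ---------------------------------------------------------------------------
# stepwise addition


def stepwise_addition(
    m: CharacterMatrix,
    seed: int = 0,
    order: str = "random",
    X: np.ndarray | None = None,
    return_flat: bool = False,
):
    """Greedy insertion of taxa at the attachment edge of minimum length.

    ``order='random'`` shuffles the addition sequence with the seed;
    ``order='as-is'`` keeps matrix order.  Ties between equally good
    attachment edges are broken uniformly from the seeded stream, so identical
    seeds give identical trees.
    """
    if m.n_taxa < 3:
        raise ValueError("stepwise addition needs at least 3 taxa")
    if X is None:
        X = m.state_sets()
    rng = random.Random(seed)
    seq = list(range(m.n_taxa))
    if order == "random":
        rng.shuffle(seq)
    elif order != "as-is":
        raise ValueError("order must be 'random' or 'as-is'")
    ft = FlatTree.star3(m.n_taxa, *seq[:3])
    N = ft.nbr.shape[0]
    out_u = np.empty(2 * N, dtype=np.int32)
    out_v = np.empty(2 * N, dtype=np.int32)
    out_s = np.empty(2 * N, dtype=np.int64)
    for leaf in seq[3:]:
        E, _ = _kernels.attach_scores(
            ft.nbr, ft.deg, ft.n, X, leaf, out_u, out_v, out_s
        )
        best = out_s[:E].min()
        cands = [
            (int(out_u[i]), int(out_v[i])) for i in range(E) if out_s[i] == best
        ]
        ft.attach_leaf(leaf, rng.choice(cands))
    return ft if return_flat else ft.to_phylo(m.taxa)


# ---------------------------------------------------------------------------
# heuristic search (drift TBR/SPR, NNI)


def _scan(ft, X, cur_best, mode, collect_all, rng, cap_imp=16, cap_eq=128):
    edges = ft.edges()
    rng.shuffle(edges)
    ea = np.array([e[0] for e in edges], dtype=np.int32)
    eb = np.array([e[1] for e in edges], dtype=np.int32)
    out_imp = np.empty((cap_imp, 7), dtype=np.int32)
    out_eq = np.empty((cap_eq, 7), dtype=np.int32)
    n_imp, n_eq = _kernels.tbr_scan(
        ft.nbr, ft.deg, ft.n, X, ea, eb, cur_best, mode, collect_all,
        out_imp, out_eq, rng.randrange(2**31),
    )
    eq = out_eq[:n_eq].copy()
    perm = list(range(len(eq)))
    rng.shuffle(perm)
    return out_imp[:n_imp].copy(), eq[perm]


def _nni_descend(ft, X, rng):
    """Plain first-improvement NNI descent (no plateau drift)."""
    best = ft.length(X)
    improved = True
    while improved:
        improved = False
        edges = [e for e in ft.edges() if e[0] >= ft.n and e[1] >= ft.n]
        rng.shuffle(edges)
        for a, b in edges:
            a_nb = [int(w) for w in ft.nbr[a, : ft.deg[a]] if w != b]
            b_nb = [int(w) for w in ft.nbr[b, : ft.deg[b]] if w != a]
            for x in a_nb:
                for y in b_nb:
                    t = ft.copy()
                    t.remove_edge(a, x)
                    t.remove_edge(b, y)
                    t.add_edge(a, y)
                    t.add_edge(b, x)
                    L = t.length(X)
                    if L < best:
                        ft, best, improved = t, L, True
                        break
                if improved:
                    break
            if improved:
                break
    return best, ft


def _drift_descend(ft, X, cfg, rng, forbid_mask=None):
    """Descend by branch swapping; drift across equal-length plateaus.

    Accepts the first improving move (or the best of the scan under steepest
    descent); when none exists, steps to a random not-yet-visited equal-length
    topology.  Gives up after ``cfg.patience`` consecutive sideways steps.
    With ``forbid_mask`` set, any move creating that split is rejected
    (converse-constraint searching).
    """
    mode = 1 if cfg.swap == "spr" else 0
    best = ft.length(X)
    if forbid_mask is not None and ft.contains_split(forbid_mask):
        raise ValueError("start tree violates the constraint")
    best_tree = ft.copy()
    visited = {ft.topology_key()}
    stale = 0
    steps = 0
    while stale < cfg.patience:
        constrained = forbid_mask is not None
        collect_all = 1 if (constrained or cfg.steepest_descent) else 0
        imp, eq = _scan(ft, X, best, mode, collect_all, rng,
                        cap_imp=64 if collect_all else 4,
                        cap_eq=128)
        steps += 1
        accepted = False
        if len(imp):
            cand = imp[np.argsort(imp[:, 6], kind="stable")]
            for row in cand:
                t = ft.copy()
                t.apply_tbr(tuple(int(x) for x in row[:6]))
                if constrained and t.contains_split(forbid_mask):
                    continue
                ft, best = t, int(row[6])
                best_tree = ft.copy()
                visited = {ft.topology_key()}
                stale = 0
                accepted = True
                break
        if accepted:
            continue
        moved = False
        for row in eq:
            t = ft.copy()
            t.apply_tbr(tuple(int(x) for x in row[:6]))
            if constrained and t.contains_split(forbid_mask):
                continue
            key = t.topology_key()
            if key not in visited:
                visited.add(key)
                ft = t
                stale += 1
                moved = True
                break
        if not moved:
            stale += 1  # rescan with a fresh edge order next round
    return best, best_tree, steps


def _collect_plateau(ft_list, X, best, cfg, rng, forbid_mask=None):
    """Grow the retained-tree buffer by swapping on retained optimal trees.

    Returns (pool dict key->FlatTree, hit_cap, improved_tree_or_None).
    """
    mode = 1 if cfg.swap == "spr" else 0
    pool = {}
    queue = []
    for ft in ft_list:
        key = ft.topology_key()
        if key not in pool:
            pool[key] = ft
            queue.append(ft)
    hit = False
    while queue:
        ft = queue.pop(0)
        imp, eq = _scan(ft, X, best, mode, 1, rng, cap_imp=4, cap_eq=512)
        for row in imp:
            t = ft.copy()
            t.apply_tbr(tuple(int(x) for x in row[:6]))
            if forbid_mask is not None and t.contains_split(forbid_mask):
                continue
            return pool, hit, t  # better tree found: caller restarts
        for row in eq:
            if len(pool) >= cfg.maxtrees and not cfg.auto_grow:
                hit = True
                break
            t = ft.copy()
            t.apply_tbr(tuple(int(x) for x in row[:6]))
            if forbid_mask is not None and t.contains_split(forbid_mask):
                continue
            key = t.topology_key()
            if key not in pool:
                pool[key] = t
                queue.append(t)
        if hit:
            break
    return pool, hit, None


def _repair_forbidden(ft: FlatTree, mask: int, X, rng) -> FlatTree:
    """Break a forbidden split with nearest-neighbour swaps until absent."""
    for _ in range(ft.n):
        if not ft.contains_split(mask):
            return ft
        anchor, below, parent, order = ft._below_masks()
        present = 0
        for v in range(ft.n):
            if ft.deg[v] > 0:
                present |= 1 << v
        target = mask if not (mask >> anchor) & 1 else present ^ mask
        v = next(v for v in order if v >= ft.n and below[v] == target)
        p = parent[v]
        x = next(int(w) for w in ft.nbr[v, : ft.deg[v]] if w != p)
        y = next(int(w) for w in ft.nbr[p, : ft.deg[p]] if w != v and w != parent.get(p, -1))
        if y == -1 or y == x:
            y = parent.get(p, int(ft.nbr[p, 0]))
        ft.remove_edge(v, x)
        ft.remove_edge(p, y)
        ft.add_edge(v, y)
        ft.add_edge(p, x)
    raise RuntimeError("could not break the forbidden clade in the start tree")


def heuristic_search(
    m: CharacterMatrix,
    cfg: SearchConfig | None = None,
    forbid: Bipartition | None = None,
    X: np.ndarray | None = None,
    collect: bool = True,
) -> SearchResult:
    """Replicated random-addition branch swapping; pools optimal topologies.

    ``forbid`` runs a converse-constraint search: only trees *lacking* that
    bipartition are considered, which is how decay indices are estimated.
    """
    cfg = cfg or SearchConfig()
    if X is None:
        X = m.state_sets()
    rng = random.Random(cfg.seed)
    forbid_mask = (
        split_mask(forbid.side, m.taxa) if forbid is not None else None
    )
    best_overall: int | None = None
    best_trees: list[FlatTree] = []
    log: list[dict] = []
    for rep in range(cfg.replicates):
        rep_seed = rng.randrange(2**31)
        ft = stepwise_addition(m, seed=rep_seed, X=X, return_flat=True)
        if forbid_mask is not None:
            ft = _repair_forbidden(ft, forbid_mask, X, rng)
        start_len = ft.length(X)
        if cfg.swap == "nni":
            if forbid_mask is not None:
                raise ValueError("constrained search requires spr or tbr swapping")
            best, ft_best = _nni_descend(ft, X, rng)
            steps = 0
        else:
            best, ft_best, steps = _drift_descend(ft, X, cfg, rng, forbid_mask)
        log.append(
            {
                "replicate": rep,
                "seed": rep_seed,
                "start_length": int(start_len),
                "final_length": int(best),
                "scans": steps,
            }
        )
        if best_overall is None or best < best_overall:
            best_overall = best
            best_trees = [ft_best]
        elif best == best_overall:
            best_trees.append(ft_best)

    hit = False
    if collect and cfg.swap != "nni":
        while True:
            pool, hit, better = _collect_plateau(
                best_trees, X, best_overall, cfg, rng, forbid_mask
            )
            if better is None:
                break
            # swapping on retained trees found a shorter tree: restart pooling
            b, bt, _ = _drift_descend(better, X, cfg, rng, forbid_mask)
            best_overall, best_trees = b, [bt]
        flats = list(pool.values())
    else:
        seen = set()
        flats = []
        for ft in best_trees:
            k = ft.topology_key()
            if k not in seen:
                seen.add(k)
                flats.append(ft)

    trees, binary = _finalize_trees(flats, m, cfg)
    return SearchResult(
        best_length=int(best_overall),
        trees=trees,
        hit_maxtrees=hit,
        replicate_log=log,
        config=cfg,
        n_distinct_binary=len(flats),
        binary_trees=binary,
    )


def _finalize_trees(
    flats: list[FlatTree], m: CharacterMatrix, cfg: SearchConfig
) -> tuple[list[PhyloTree], list[PhyloTree]]:
    """Convert retained topologies to PhyloTree, applying the collapse policy."""
    binary = [ft.to_phylo(m.taxa) for ft in flats]
    trees = binary
    if cfg.collapse_policy != "none":
        from .mapping import collapse_zero_length_branches

        criterion = "min" if cfg.collapse_policy.endswith("min") else "max"
        collapsed = []
        seen = set()
        for t in binary:
            ct = collapse_zero_length_branches(t, m, criterion=criterion)
            from .tree import bipartitions

            key = frozenset(bp.side for bp in bipartitions(ct))
            if key not in seen:
                seen.add(key)
                collapsed.append(ct)
        trees = collapsed
    return trees, binary


# ---------------------------------------------------------------------------
# branch and bound (exact)


def branch_and_bound(
    m: CharacterMatrix,
    slack: int = 0,
    guard: int = BNB_GUARD,
    cfg: SearchConfig | None = None,
) -> SearchResult:
    """All optimal topologies (and any within ``slack`` steps) by exact search.

    Depth-first taxon insertion with lower-bound pruning: partial-tree length
    plus, per character, the number of states present only among taxa not yet
    inserted (each such state must cost at least one further step).
    """
    n = m.n_taxa
    if n > guard:
        raise ValueError(
            f"branch_and_bound is guarded to <= {guard} taxa "
            f"({n} given); use heuristic_search"
        )
    cfg = cfg or SearchConfig(replicates=1)
    X = m.state_sets()
    C = m.n_char
    det = np.zeros((n, C), dtype=np.uint8)  # determinate-only masks for the bound
    from .matrix import CellKind

    for i, row in enumerate(m.cells):
        for j, cell in enumerate(row):
            if cell.kind is CellKind.DETERMINATE:
                det[i, j] = sum(1 << s for s in cell.states)

    order = list(range(n))
    # future-state bound per depth: states appearing only after depth k
    bound_add = np.zeros(n + 1, dtype=np.int64)
    for k in range(n + 1):
        included = np.bitwise_or.reduce(det[order[:k]], axis=0) if k else np.zeros(C, np.uint8)
        remaining = (
            np.bitwise_or.reduce(det[order[k:]], axis=0) if k < n else np.zeros(C, np.uint8)
        )
        novel = remaining & ~included
        bound_add[k] = sum(int(x).bit_count() for x in novel)

    if n == 3:
        ft = FlatTree.star3(n, *order[:3])
        L = ft.length(X)
        return SearchResult(L, [ft.to_phylo(m.taxa)], False, [], cfg, 1)

    best = [np.iinfo(np.int64).max]
    kept: list[tuple[int, FlatTree]] = []
    N = 2 * n - 2
    out_u = np.empty(2 * N, dtype=np.int32)
    out_v = np.empty(2 * N, dtype=np.int32)
    out_s = np.empty(2 * N, dtype=np.int64)

    def recurse(ft: FlatTree, k: int) -> None:
        leaf = order[k]
        E, _ = _kernels.attach_scores(
            ft.nbr, ft.deg, ft.n, X, leaf, out_u, out_v, out_s
        )
        options = sorted(
            ((int(out_s[i]), int(out_u[i]), int(out_v[i])) for i in range(E))
        )
        for L, u, v in options:
            if L + bound_add[k + 1] > best[0] + slack:
                continue
            t = ft.copy()
            t.attach_leaf(leaf, (u, v))
            if k + 1 == n:
                if L < best[0]:
                    best[0] = L
                    kept[:] = [(Lk, tk) for Lk, tk in kept if Lk <= best[0] + slack]
                kept.append((L, t))
            else:
                recurse(t, k + 1)

    recurse(FlatTree.star3(n, *order[:3]), 3)
    kept_final = [(L, t) for L, t in kept if L <= best[0] + slack]
    kept_final.sort(key=lambda p: p[0])
    if slack == 0:
        trees, binary = _finalize_trees([t for _, t in kept_final], m, cfg)
    else:
        binary = [t.to_phylo(m.taxa) for _, t in kept_final]
        trees = binary
    return SearchResult(
        best_length=int(best[0]),
        trees=trees,
        hit_maxtrees=False,
        replicate_log=[{"lengths": [L for L, _ in kept_final]}],
        config=cfg,
        n_distinct_binary=len(kept_final),
        binary_trees=binary,
    )
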