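"""Shared fixtures and independent oracle helpers.

The expensive searches on the packaged matrix run once per session and are
shared by the pipeline and acceptance tests.  Oracle helpers (topology
enumeration, exhaustive assignment scoring) are deliberately written from
first principles, independent of the package's search/scoring internals.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import parsiphy as pp
from parsiphy.search import SearchConfig, heuristic_search
from parsiphy.tree import PhyloTree, TreeNode


# ---------------------------------------------------------------------------
# light helpers


def make_matrix(rows: dict[str, str]) -> pp.CharacterMatrix:
    text = "\n".join(f"{k} {v}" for k, v in rows.items())
    return pp.parse_matrix(text, dialect="bespoke")


def random_matrix(rng, n_taxa, n_char, k=3, missing=0.0):
    """Plain random (not tree-generated) matrix for oracle tests."""
    rows = {}
    for i in range(n_taxa):
        syms = []
        for _ in range(n_char):
            if rng.random() < missing:
                syms.append("?")
            else:
                syms.append(str(rng.randrange(k)))
        rows[f"t{i + 1}"] = "".join(syms)
    return make_matrix(rows)


# ---------------------------------------------------------------------------
# oracle: enumerate all unrooted binary topologies


def enumerate_topologies(taxa: list[str]):
    """Yield every unrooted binary topology over ``taxa`` (1, 3, 15, 105...)."""
    n = len(taxa)
    assert n >= 3
    # edge lists over nodes: leaves 0..n-1, internals n, n+1, ...
    def insert_all(edges, next_internal, leaf):
        for i, (u, v) in enumerate(edges):
            new = [e for j, e in enumerate(edges) if j != i]
            w = next_internal
            yield new + [(u, w), (v, w), (leaf, w)], w + 1

    stack = [([(0, n), (1, n), (2, n)], n + 1, 3)]
    while stack:
        edges, nxt, k = stack.pop()
        if k == n:
            yield _edges_to_tree(edges, taxa)
            continue
        for new_edges, new_nxt in insert_all(edges, nxt, k):
            stack.append((new_edges, new_nxt, k + 1))


def _edges_to_tree(edges, taxa):
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    n = len(taxa)

    def grow(node, avoid):
        t = TreeNode(taxa[node] if node < n else None)
        for nb in adj[node]:
            if nb != avoid:
                t.add(grow(nb, node))
        return t

    root_leaf = 0
    hub = adj[0][0]
    root = grow(hub, 0)
    root.add(TreeNode(taxa[0]))
    return PhyloTree(root, rooted=False)


def exhaustive_min_steps(
    tree: PhyloTree, m: pp.CharacterMatrix, n_states: int = 4
) -> np.ndarray:
    """Per-character minimum steps by brute force over internal labelings.

    Enumerates every assignment of states to internal nodes (vectorized over
    assignments and characters) and takes the cheapest; independent of the
    package's Fitch machinery.
    """
    X = m.state_sets()
    nodes = list(tree.nodes())
    internal = [nd for nd in nodes if not nd.is_leaf]
    leaves = [nd for nd in nodes if nd.is_leaf]
    idx = {id(nd): i for i, nd in enumerate(internal)}
    A = np.array(
        list(itertools.product(range(n_states), repeat=len(internal))),
        dtype=np.int8,
    )  # (n_assignments, n_internal)
    cost = np.zeros(len(A), dtype=np.int64)
    for nd in internal:
        if nd.parent is not None:
            cost += A[:, idx[id(nd)]] != A[:, idx[id(nd.parent)]]
    total = np.repeat(cost[:, None], m.n_char, axis=1)
    for nd in leaves:
        mask = X[m.taxa.index(nd.label)]  # (C,) uint8 bitmasks
        par = A[:, idx[id(nd.parent)]]  # (S,)
        total += ((mask[None, :] >> par[:, None]) & 1) == 0
    return total.min(axis=0)


# ---------------------------------------------------------------------------
# session-scoped searches on the packaged matrix


@pytest.fixture(scope="session")
def packaged():
    return pp.load_packaged_matrix()


@pytest.fixture(scope="session")
def groups():
    return pp.taxon_groups()


@pytest.fixture(scope="session")
def analysis1_search(packaged):
    """Heuristic search on the full 78-taxon matrix (fixed seed)."""
    cfg = SearchConfig(replicates=3, seed=11, maxtrees=60)
    return heuristic_search(packaged, cfg)


@pytest.fixture(scope="session")
def arminid_matrix(packaged, groups):
    return pp.subset_matrix(packaged, groups["arminidae"])


@pytest.fixture(scope="session")
def analysis2_search(arminid_matrix):
    """Heuristic search on the 55-taxon arminid submatrix (fixed seed)."""
    cfg = SearchConfig(replicates=4, seed=7, maxtrees=60)
    return heuristic_search(arminid_matrix, cfg)
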