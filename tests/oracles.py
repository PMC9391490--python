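"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: ancestral states
are computed from the Brownian-motion covariance matrix by direct GLS
linear algebra, and permutation p-values by literal enumeration with
numpy's correlation routine.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np


def _ancestor_path(node: dendropy.Node) -> list[dendropy.Node]:
    path = [node]
    while path[-1].parent_node is not None:
        path.append(path[-1].parent_node)
    return path


def _pairwise_distance(a: dendropy.Node, b: dendropy.Node) -> float:
    depth = {}
    for n in (a, b):
        d = 0.0
        cur = n
        while cur.parent_node is not None:
            d += cur.edge.length
            cur = cur.parent_node
        depth[n] = d
    anc_a = set(id(x) for x in _ancestor_path(a))
    cur, d_b = b, 0.0
    while id(cur) not in anc_a:
        d_b += cur.edge.length
        cur = cur.parent_node
    common = cur
    d_a = 0.0
    cur = a
    while cur is not common:
        d_a += cur.edge.length
        cur = cur.parent_node
    return d_a + d_b


def gls_ancestral_states(
    tree: dendropy.Tree, tip_values: dict[str, float]
) -> dict[str, float]:
    """ML ancestral states by the GLS closed form on the re-rooted BM
    covariance matrix: for node u, V_u[i,j] = shared path length from u,
    and a_hat(u) = (1' V_u^-1 y) / (1' V_u^-1 1)."""
    leaves = list(tree.leaf_node_iter())
    y = np.array([tip_values[lf.taxon.label] for lf in leaves])
    d_leaf = np.array(
        [[_pairwise_distance(a, b) for b in leaves] for a in leaves]
    )
    states: dict[str, float] = {}
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    for idx, node in enumerate(tree.preorder_node_iter()):
        if node.is_leaf():
            continue
        d_u = np.array([_pairwise_distance(node, lf) for lf in leaves])
        V = (d_u[:, None] + d_u[None, :] - d_leaf) / 2.0
        np.fill_diagonal(V, d_u)
        one = np.ones_like(y)
        Vi_y = np.linalg.solve(V, y)
        Vi_1 = np.linalg.solve(V, one)
        label = node.label if node.label else f"N{idx}"
        states[label] = float(one @ Vi_y / (one @ Vi_1))
    return states


def random_binary_tree(
    n_tips: int, rng: np.random.Generator
) -> tuple[dendropy.Tree, dict[str, float]]:
    """Random binary topology with random positive branch lengths and
    random tip values, built by repeated pair-joining."""
    labels = [f"t{i}" for i in range(n_tips)]
    clades = [(lab, None) for lab in labels]
    newicks = {lab: lab for lab in labels}
    items = list(labels)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a, b = items[j], items[i]  # pop higher index first
        items.pop(j)
        items.pop(i)
        la, lb = rng.uniform(0.2, 3.0), rng.uniform(0.2, 3.0)
        merged = f"({newicks[a]}:{la:.6f},{newicks[b]}:{lb:.6f})"
        key = f"{a}|{b}"
        newicks[key] = merged
        items.append(key)
    tree = dendropy.Tree.get(data=newicks[items[0]] + ";", schema="newick")
    tips = {lab: float(rng.normal(0.0, 5.0)) for lab in labels}
    return tree, tips


def brute_force_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exhaustive permutation p-value for the Pearson r of (x, y)."""
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    n = len(y)
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(np.corrcoef(x, y[list(perm)])[0, 1])
        hits += r >= r_obs - 1e-12
        total += 1
    return hits / total
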