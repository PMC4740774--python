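"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive: exhaustive enumeration over internal
state assignments for parsimony lengths, exhaustive multiset permutations for
exact p-values, and path-length sums for additive distances.  None of it
shares code with the package.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from skbio import TreeNode

from sympy.utilities.iterables import multiset_permutations


def brute_force_steps(tree: TreeNode, tip_states: dict[str, int | None], k: int) -> int:
    """Minimum change count by enumerating every internal-node assignment.

    A tip with a missing state can always adopt its parent's state, so it
    never contributes a step and is excluded from the enumeration.
    """
    internals = [n for n in tree.postorder(include_self=True) if not n.is_tip()]
    idx = {id(n): i for i, n in enumerate(internals)}
    internal_edges = []  # (child index, parent index)
    tip_edges = []  # (tip state, parent index)
    for node in tree.traverse(include_self=False):
        pi = idx[id(node.parent)]
        if node.is_tip():
            st = tip_states.get(node.name)
            if st is not None:
                tip_edges.append((st, pi))
        else:
            internal_edges.append((idx[id(node)], pi))
    best = np.inf
    for assign in product(range(k), repeat=len(internals)):
        steps = sum(1 for ci, pi in internal_edges if assign[ci] != assign[pi])
        steps += sum(1 for st, pi in tip_edges if st != assign[pi])
        if steps < best:
            best = steps
    return int(best)


def exact_permutation_p(
    tree: TreeNode, scored_tips: list[str], states: list[int], k: int
) -> tuple[float, int]:
    """Exact one-sided p over all distinct assignments of the state multiset.

    p = fraction of assignments whose step count is <= the observed count
    (equivalently whose RI is >= the observed RI, since M and G are fixed).
    """
    obs = brute_force_steps(
        tree, dict(zip(scored_tips, states)), k
    )
    counts = []
    for perm in multiset_permutations(states):
        counts.append(brute_force_steps(tree, dict(zip(scored_tips, perm)), k))
    counts = np.array(counts)
    return float((counts <= obs).mean()), len(counts)


def random_tree(
    rng: np.random.Generator,
    tip_names: list[str],
    allow_polytomies: bool = True,
    with_lengths: bool = False,
) -> TreeNode:
    """Random topology over the given tips by repeated random joins."""
    nodes = [TreeNode(name=n) for n in tip_names]
    while len(nodes) > 1:
        max_join = min(3 if allow_polytomies else 2, len(nodes))
        size = int(rng.integers(2, max_join + 1)) if max_join > 2 else 2
        picks = sorted(rng.choice(len(nodes), size=size, replace=False))
        parent = TreeNode()
        for i in picks:
            child = nodes[i]
            if with_lengths:
                child.length = float(rng.uniform(0.5, 2.0))
            parent.append(child)
        nodes = [n for i, n in enumerate(nodes) if i not in set(picks)]
        nodes.append(parent)
    return nodes[0]


def random_character(
    rng: np.random.Generator,
    tip_names: list[str],
    k: int,
    missing_prob: float = 0.0,
) -> dict[str, int | None]:
    """Random k-state character, re-drawn until >=2 tips are scored."""
    while True:
        out: dict[str, int | None] = {}
        for t in tip_names:
            out[t] = None if rng.random() < missing_prob else int(rng.integers(k))
        if sum(v is not None for v in out.values()) >= 2:
            return out


def additive_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Tip-tip path-length distances of a tree with branch lengths."""
    dm = tree.tip_tip_distances()
    return list(dm.ids), np.asarray(dm.data, dtype=float)
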