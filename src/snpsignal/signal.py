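"""Phylogenetic signal of categorical characters: parsimony steps, retention
index, and a tip-shuffling randomization test.

For a categorical character scored on the tips of a tree, let

* ``S`` — the minimum number of unordered state changes the tree requires
  (Fitch parsimony length),
* ``M`` — the minimum achievable on *any* tree: (number of distinct observed
  states) − 1,
* ``G`` — the maximum: the parsimony length on a star tree, i.e. (number of
  scored tips) − (count of the modal state).

The retention index is ``RI = (G − S) / (G − M)``, defined when ``G > M``:
1 means the character is perfectly congruent with the tree, 0 means maximal
homoplasy.  Significance is assessed by permuting the observed states across
the scored tips (missing tips stay missing, so ``M`` and ``G`` are constant
and only ``S`` varies), recomputing RI on the same tree, and reporting the
one-sided add-one Monte-Carlo p-value

    p = (1 + #{null RI >= observed RI}) / (1 + n_reps).

Step counting uses dynamic programming over state sets (Sankoff with 0/1
costs), which is exact for arbitrary polytomies; naive set-based Fitch is
only exact on binary trees.  Tips with a missing state are assigned a
zero-cost vector over all states, so they never force a step.  All
statistics are invariant to the root placement and to tip storage order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .metadata import SampleMetadata

logger = logging.getLogger(__name__)

_INF = np.float64(1e18)


@dataclass
class TipCharacter:
    """A categorical character on tree tips: tip label -> state or None."""

    name: str
    tip_states: dict[str, str | None]

    @classmethod
    def from_metadata(cls, metadata: SampleMetadata, variable: str) -> "TipCharacter":
        return cls(variable, metadata.states(variable))


@dataclass
class SignalResult:
    """Observed and null retention index of one character on one tree."""

    variable: str
    tree_id: str
    n_scored: int
    S: int
    M: int
    G: int
    RI: float
    n_reps: int
    null_RIs: np.ndarray = field(repr=False)
    p_value: float
    seed: int


class UninformativeCharacterError(ValueError):
    """Raised when RI is undefined (G == M): the character is either
    invariant on the scored tips or every scored tip has its own state."""


def _scored_tips(
    tree: TreeNode, character: TipCharacter
) -> tuple[list[str], list[str]]:
    """Tip labels with a non-missing state, and the sorted distinct states."""
    states = character.tip_states
    # sorted so permutation draws are invariant to tip storage order and root
    scored = sorted(
        t.name for t in tree.tips() if states.get(t.name) is not None
    )
    if not scored:
        raise ValueError(
            f"character {character.name!r} has no scored tips on the tree"
        )
    levels = sorted({states[t] for t in scored})
    return scored, levels


def _postorder_plan(
    tree: TreeNode,
) -> tuple[list[str | None], list[list[int]], int]:
    """Flatten the tree to a postorder schedule for the DP.

    Returns (tip name per node or None for internals, child indices per
    node, index of the root node).
    """
    order = list(tree.postorder(include_self=True))
    index = {id(n): i for i, n in enumerate(order)}
    names: list[str | None] = []
    children: list[list[int]] = []
    for n in order:
        names.append(n.name if n.is_tip() else None)
        children.append([index[id(c)] for c in n.children])
    return names, children, index[id(order[-1])]


def _sankoff_batch(
    tree: TreeNode,
    tip_codes: dict[str, np.ndarray],
    k: int,
) -> np.ndarray:
    """Minimum change counts for a batch of characters on one tree.

    ``tip_codes`` maps a tip label to an ``(R,)`` array of state indices in
    ``[0, k)``; tips absent from the map (or coded ``-1``) are treated as
    missing for every replicate.  Returns an ``(R,)`` array of step counts.

    With unit substitution costs, the child contribution to a parent state
    ``s`` simplifies to ``min(cost[s], min(cost) + 1)``, so each node is a
    couple of vectorized array operations.
    """
    R = next(iter(tip_codes.values())).shape[0]
    names, children, root = _postorder_plan(tree)
    costs: list[np.ndarray | None] = [None] * len(names)
    for i, name in enumerate(names):
        if not children[i]:  # tip
            codes = tip_codes.get(name)  # type: ignore[arg-type]
            c = np.zeros((R, k))
            if codes is not None:
                rows = np.flatnonzero(codes >= 0)
                c[rows, :] = _INF
                c[rows, codes[rows]] = 0.0
            costs[i] = c
        else:
            total = np.zeros((R, k))
            for ci in children[i]:
                cc = costs[ci]
                total += np.minimum(cc, cc.min(axis=1, keepdims=True) + 1.0)
                costs[ci] = None  # free memory
            costs[i] = total
    return costs[root].min(axis=1)


def fitch_steps(tree: TreeNode, character: TipCharacter) -> int:
    """Minimum number of unordered state changes of ``character`` on ``tree``.

    Missing tips carry the full state set and contribute no forced steps.
    Exact on polytomies (dynamic programming over assignments).
    """
    scored, levels = _scored_tips(tree, character)
    level_of = {s: i for i, s in enumerate(levels)}
    codes = {
        t: np.array([level_of[character.tip_states[t]]]) for t in scored
    }
    return int(_sankoff_batch(tree, codes, len(levels))[0])


def step_bounds(tree: TreeNode, character: TipCharacter) -> tuple[int, int]:
    """(M, G): minimum and maximum possible step counts over all trees.

    ``M`` = distinct observed states − 1.  ``G`` = scored tips − modal state
    count (the parsimony length on a star tree; ties in the modal state do
    not change G).  Both ignore missing tips.
    """
    scored, levels = _scored_tips(tree, character)
    counts = pd.Series([character.tip_states[t] for t in scored]).value_counts()
    return len(levels) - 1, len(scored) - int(counts.iloc[0])


def retention_index(tree: TreeNode, character: TipCharacter) -> float:
    """RI = (G − S)/(G − M); raises :class:`UninformativeCharacterError`
    when G == M (RI undefined)."""
    S = fitch_steps(tree, character)
    M, G = step_bounds(tree, character)
    if G == M:
        raise UninformativeCharacterError(
            f"character {character.name!r} is uninformative on this tree "
            f"(M == G == {M}); retention index undefined"
        )
    return (G - S) / (G - M)


def randomization_test(
    tree: TreeNode,
    character: TipCharacter,
    n_reps: int = 9999,
    seed: int | None = None,
    tree_id: str = "global",
) -> SignalResult:
    """Permutation test of whether RI exceeds that of randomized data.

    Each replicate shuffles the observed state multiset uniformly across the
    scored tips (missingness pattern preserved) and recomputes RI on the same
    tree.  Because M and G are fixed under this null, ``null RI >= observed
    RI`` is evaluated exactly as ``null S <= observed S`` on integer step
    counts — no floating-point ties.  The add-one correction keeps p in
    (0, 1].  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for a reproducible test")
    scored, levels = _scored_tips(tree, character)
    level_of = {s: i for i, s in enumerate(levels)}
    k = len(levels)
    obs = np.array([level_of[character.tip_states[t]] for t in scored])
    M, G = step_bounds(tree, character)
    if G == M:
        raise UninformativeCharacterError(
            f"character {character.name!r} is uninformative; cannot test"
        )
    S_obs = fitch_steps(tree, character)

    rng = np.random.default_rng(seed)
    # column j of perms holds the state of scored tip j in every replicate
    perms = np.empty((n_reps, len(scored)), dtype=np.int64)
    for r in range(n_reps):
        perms[r] = rng.permutation(obs)
    tip_codes = {t: perms[:, j] for j, t in enumerate(scored)}
    null_S = _sankoff_batch(tree, tip_codes, k).astype(np.int64)

    null_RIs = (G - null_S) / (G - M)
    n_ge = int((null_S <= S_obs).sum())
    p = (1 + n_ge) / (1 + n_reps)
    return SignalResult(
        variable=character.name,
        tree_id=tree_id,
        n_scored=len(scored),
        S=S_obs,
        M=M,
        G=G,
        RI=(G - S_obs) / (G - M),
        n_reps=n_reps,
        null_RIs=null_RIs,
        p_value=p,
        seed=seed,
    )


def run_signal_suite(
    trees: dict[str, TreeNode],
    metadata: SampleMetadata,
    variables: list[str],
    n_reps: int = 9999,
    seed: int | None = None,
) -> list[SignalResult]:
    """Randomization test for every (tree, variable) pair with a defined RI.

    Sub-seeds are derived deterministically from the master seed per pair,
    so adding or removing pairs does not perturb the others.  Pairs whose
    character is uninformative on that tree (or absent from its tips) are
    skipped with a logged reason.
    """
    if seed is None:
        raise ValueError("a master seed is required")
    for v in variables:
        if v not in metadata.variables:
            raise KeyError(f"variable {v!r} not in metadata")
    results: list[SignalResult] = []
    pairs = [(tid, v) for tid in trees for v in variables]
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    for (tree_id, var), child in zip(pairs, children):
        sub_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        if var in metadata.multilabel:
            logger.info(
                "skipping %s on tree %s: multi-label variables are not a "
                "single-state character",
                var,
                tree_id,
            )
            continue
        character = TipCharacter.from_metadata(metadata, var)
        try:
            results.append(
                randomization_test(
                    trees[tree_id], character, n_reps, sub_seed, tree_id=tree_id
                )
            )
        except (UninformativeCharacterError, ValueError) as exc:
            logger.info("skipping %s on tree %s: %s", var, tree_id, exc)
    return results


def results_table(
    results: list[SignalResult], bh_adjust: bool = True
) -> pd.DataFrame:
    """Tabulate results; optional Benjamini–Hochberg column alongside raw p
    (never replacing it)."""
    rows = [
        {
            "variable": r.variable,
            "tree_id": r.tree_id,
            "n_scored": r.n_scored,
            "S": r.S,
            "M": r.M,
            "G": r.G,
            "RI": r.RI,
            "n_reps": r.n_reps,
            "p_value": r.p_value,
            "seed": r.seed,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if bh_adjust and len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
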