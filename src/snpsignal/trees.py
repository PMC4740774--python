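"""Distance-based tree building from genotype matrices, plus Newick I/O.

Trees are held as :class:`skbio.TreeNode` objects.  They are stored with an
arbitrary deterministic root purely for representation — every downstream
signal statistic is root-invariant — and polytomies are permitted.

The default construction is classical neighbor-joining (Saitou–Nei) on
Hamming distances with pairwise deletion of missing calls.  The tree method
is a package choice: the retention-index machinery accepts any externally
built tree supplied as Newick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .matrix import (
    MISSING,
    GenotypeMatrix,
    drop_uninformative,
    filter_by_completeness,
    subset_samples,
)
from .metadata import SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Pairwise sample distances with pairwise-deletion bookkeeping.

    ``d`` is symmetric with zero diagonal; ``n_comparable[i, j]`` counts the
    variants at which both samples have a call.
    """

    sample_ids: list[str]
    d: np.ndarray
    n_comparable: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.d.shape != (n, n) or self.n_comparable.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distances must be symmetric with zero diagonal")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )


def hamming_distances(
    matrix: GenotypeMatrix, normalize: bool = True
) -> DistanceMatrix:
    """Pairwise Hamming distances between sample genotype vectors.

    For each pair, the distance counts variants at which both calls are
    present and the codes differ; variants missing in either sample are
    deleted pairwise.  With ``normalize`` the count is divided by the number
    of comparable variants, giving a per-site mismatch proportion.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples for distances")
    calls = matrix.calls
    present = calls != MISSING
    n = matrix.n_samples
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = present[i] & present[i + 1 :]
        diff = (calls[i] != calls[i + 1 :]) & both
        comp[i, i + 1 :] = both.sum(axis=1)
        d[i, i + 1 :] = diff.sum(axis=1)
    comp += comp.T
    d += d.T
    np.fill_diagonal(comp, matrix.n_variants)
    zero = np.argwhere((comp == 0) & ~np.eye(n, dtype=bool))
    if zero.size:
        i, j = zero[0]
        raise ValueError(
            f"no comparable variants between samples "
            f"{matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r}; "
            "matrix too sparse for pairwise distances"
        )
    if normalize:
        off = ~np.eye(n, dtype=bool)
        d[off] = d[off] / comp[off]
    return DistanceMatrix(list(matrix.sample_ids), d, comp)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor-joining (Saitou–Nei Q-criterion).

    Produces an unrooted binary tree represented with a trifurcating root at
    the final join.  Ties in Q are broken toward the lowest (row, column)
    index pair, so the result is deterministic in the input taxon order.
    Negative branch-length estimates are clamped to zero with the total
    deficit logged; the topology is unaffected.
    """
    if len(dm.sample_ids) < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")
    D = dm.d.astype(float).copy()
    nodes = [TreeNode(name=s) for s in dm.sample_ids]
    clamped = 0.0

    def _blen(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        rowsum = D.sum(axis=1)
        Q = (r - 2) * D - rowsum[:, None] - rowsum[None, :]
        iu = np.triu_indices(r, k=1)
        flat = Q[iu]
        best = int(np.argmin(flat))  # first minimum = lowest-index pair
        i, j = int(iu[0][best]), int(iu[1][best])
        vi = 0.5 * D[i, j] + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        vj = D[i, j] - vi
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = _blen(vi)
        b.length = _blen(vj)
        parent.extend([a, b])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], dnew[keep]])
        last = np.append(dnew[keep], 0.0)
        D = np.hstack([D, last[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = _blen(0.5 * (dab + dac - dbc))
    b.length = _blen(0.5 * (dab + dbc - dac))
    c.length = _blen(0.5 * (dac + dbc - dab))
    root = TreeNode()
    root.extend([a, b, c])
    if clamped > 0:
        logger.info("clamped negative NJ branch lengths; total deficit %.4g", clamped)
    return root


def read_newick(path) -> TreeNode:
    """Read a Newick tree; validates unique, non-empty tip labels and
    non-negative branch lengths."""
    tree = TreeNode.read(str(path))
    _validate(tree)
    return tree


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    tree = TreeNode.read([text])
    _validate(tree)
    return tree


def _validate(tree: TreeNode) -> None:
    names = [t.name for t in tree.tips()]
    if any(n is None or n == "" for n in names):
        raise ValueError("tree has unnamed tips")
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate tip labels: {dups}")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length at {node.name!r}")


def write_newick(tree: TreeNode, path) -> None:
    """Write Newick, quoting labels where the dialect requires it."""
    tree.write(str(path))


def build_stratified_trees(
    matrix: GenotypeMatrix,
    metadata: SampleMetadata,
    strat_var: str,
    min_call_fraction: float = 0.9,
    min_stratum_size: int = 4,
    normalize: bool = True,
) -> dict[str, TreeNode]:
    """One tree per level of ``strat_var``, re-running the full chain.

    For each level: subset samples, re-apply the completeness filter on the
    subset, drop uninformative variants, compute Hamming distances and build
    the NJ tree.  Levels with fewer than ``min_stratum_size`` samples are
    skipped with a warning.  A sample carrying several labels of a
    multi-label variable appears in every matching stratum.
    """
    trees: dict[str, TreeNode] = {}
    for level in metadata.levels(strat_var):
        try:
            sub_m, sub_meta = subset_samples(
                matrix, metadata, strat_var, level, min_samples=min_stratum_size
            )
        except ValueError as exc:
            logger.warning("skipping stratum %s=%s: %s", strat_var, level, exc)
            continue
        filtered, report = filter_by_completeness(sub_m, min_call_fraction)
        informative = drop_uninformative(filtered)
        logger.info(
            "stratum %s=%s: %d samples, %d/%d variants kept, %d informative",
            strat_var,
            level,
            sub_m.n_samples,
            report.n_variants_kept,
            report.n_variants_in,
            informative.n_variants,
        )
        if informative.n_variants == 0:
            logger.warning(
                "skipping stratum %s=%s: no informative variants", strat_var, level
            )
            continue
        trees[level] = neighbor_joining(hamming_distances(informative, normalize))
    if not trees:
        raise ValueError(f"no usable stratum for variable {strat_var!r}")
    return trees
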