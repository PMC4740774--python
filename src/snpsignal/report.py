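"""Static figures and tables for a signal analysis run."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from skbio import TreeNode

from .metadata import SampleMetadata
from .signal import SignalResult


def _layout(tree: TreeNode) -> dict[int, tuple[float, float]]:
    """Rectangular layout: x = cumulative branch length (unit edges when
    lengths are absent), y = tip rank / mean of children."""
    pos: dict[int, tuple[float, float]] = {}
    y = 0.0
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            pos[id(node)] = (0.0, y)
            y += 1.0
        else:
            ys = [pos[id(c)][1] for c in node.children]
            pos[id(node)] = (0.0, float(np.mean(ys)))
    for node in tree.preorder(include_self=True):
        if node.parent is None:
            x = 0.0
        else:
            x = pos[id(node.parent)][0] + (
                node.length if node.length is not None else 1.0
            )
        pos[id(node)] = (x, pos[id(node)][1])
    return pos


def plot_tree(
    tree: TreeNode,
    tip_states: dict[str, str | None],
    title: str,
    path: Path,
) -> None:
    """Draw the tree with tips colored by a categorical character."""
    pos = _layout(tree)
    levels = sorted({s for s in tip_states.values() if s is not None})
    cmap = plt.get_cmap("tab10")
    color_of = {lv: cmap(i % 10) for i, lv in enumerate(levels)}
    n_tips = tree.count(tips=True)
    fig, ax = plt.subplots(figsize=(7, max(3, 0.22 * n_tips)))
    for node in tree.traverse(include_self=True):
        x, ynode = pos[id(node)]
        if node.parent is not None:
            xp, yp = pos[id(node.parent)]
            ax.plot([xp, xp, x], [yp, ynode, ynode], color="0.3", lw=0.8)
        if node.is_tip():
            state = tip_states.get(node.name)
            ax.plot(
                [x],
                [ynode],
                "o",
                ms=5,
                color=color_of.get(state, "0.7"),
            )
            ax.text(x, ynode, f"  {node.name}", va="center", fontsize=6)
    handles = [
        plt.Line2D([], [], marker="o", ls="", color=color_of[lv], label=lv)
        for lv in levels
    ]
    if handles:
        ax.legend(handles=handles, fontsize=7, loc="best")
    ax.set_title(title, fontsize=9)
    ax.set_yticks([])
    ax.set_xlabel("distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_null_histogram(result: SignalResult, path: Path) -> None:
    """Null RI distribution with the observed RI marked."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(result.null_RIs, bins=30, color="0.6", edgecolor="white")
    ax.axvline(result.RI, color="crimson", lw=1.5)
    ax.set_title(
        f"{result.variable} on {result.tree_id}: RI={result.RI:.4f}, "
        f"p={result.p_value:.4g}",
        fontsize=9,
    )
    ax.set_xlabel("retention index under tip shuffling")
    ax.set_ylabel("replicates")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_report(
    results: list[SignalResult],
    trees: dict[str, TreeNode],
    metadata: SampleMetadata,
    outdir: Path,
) -> list[Path]:
    """Per-tree plots colored by each tested variable plus null histograms
    and the null samples as TSV.  Returns the files written."""
    if not results:
        raise ValueError("no results to render")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for r in results:
        tree = trees[r.tree_id]
        stem = f"{r.tree_id}__{r.variable}".replace("/", "_")
        tree_png = outdir / f"tree_{stem}.png"
        plot_tree(
            tree,
            metadata.states(r.variable),
            f"{r.tree_id} tree, tips by {r.variable}",
            tree_png,
        )
        hist_png = outdir / f"null_{stem}.png"
        plot_null_histogram(r, hist_png)
        null_tsv = outdir / f"null_{stem}.tsv"
        pd.DataFrame({"null_RI": r.null_RIs}).to_csv(
            null_tsv, sep="\t", index=False, float_format="%.10g"
        )
        written += [tree_png, hist_png, null_tsv]
    return written
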