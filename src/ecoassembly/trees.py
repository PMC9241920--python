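"""Phylogeny handling: Newick I/O and patristic distances.

Trees are scikit-bio ``TreeNode`` objects; this module only adds the
small conveniences the assembly null models need (aligned patristic
distance matrices, validation against an OTU table's taxon set).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import skbio

__all__ = ["read_newick", "write_newick", "patristic_distances"]


def read_newick(path: str | Path, missing_lengths: str = "error") -> skbio.TreeNode:
    """Read a rooted Newick tree.

    ``missing_lengths`` controls branches without a length: "error"
    rejects the tree, "zero" treats them as length 0.
    """
    if missing_lengths not in ("error", "zero"):
        raise ValueError(f"unknown missing_lengths policy {missing_lengths!r}")
    tree = skbio.TreeNode.read(str(path), convert_underscores=False)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if missing_lengths == "error":
                name = node.name or "<internal>"
                raise ValueError(f"branch above {name!r} has no length")
            node.length = 0.0
        elif node.length < 0:
            raise ValueError(f"negative branch length above {node.name!r}")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate tip labels in tree")
    return tree


def write_newick(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path))


def patristic_distances(
    tree: skbio.TreeNode, taxa: list[str] | None = None
) -> pd.DataFrame:
    """Tip-to-tip (patristic) distance matrix, optionally aligned to and
    restricted to ``taxa``; raises naming any taxon absent from the tree."""
    dm = tree.tip_tip_distances()
    df = pd.DataFrame(np.asarray(dm.data), index=list(dm.ids), columns=list(dm.ids))
    if taxa is not None:
        missing = [t for t in taxa if t not in df.index]
        if missing:
            raise KeyError(f"taxa missing from tree: {missing}")
        df = df.loc[list(taxa), list(taxa)]
    return df
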