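"""Phylogeny handling: newick I/O, rooting, tip pruning, cophenetic distances
and per-branch abundance aggregation.

Trees are represented as :class:`skbio.TreeNode` objects.  Every operation
here treats the tree as rooted; branch lengths are patristic distances in
substitutions/site (or whatever unit the upstream tree inference produced).

The :class:`BranchTable` is the workhorse for UniFrac-family metrics: it
flattens the tree into an array of branches (every non-root node), each with
its length and the abundance of its descendant tips in every sample, so that
the generalized UniFrac ratio can be evaluated with plain array arithmetic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._errors import TreeError, ParseError

__all__ = [
    "read_newick",
    "write_newick",
    "root_at_mrca",
    "prune_long_tips",
    "cophenetic",
    "BranchTable",
    "branch_abundances",
    "tip_heights",
]


def read_newick(path) -> TreeNode:
    """Read a newick tree from ``path`` and validate tip-label uniqueness."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise ParseError(f"could not parse newick file {path}: {exc}") from exc
    _validate(tree)
    return tree


def parse_newick(text: str) -> TreeNode:
    """Parse a newick string (convenience wrapper around :func:`read_newick`)."""
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:
        raise ParseError(f"could not parse newick string: {exc}") from exc
    _validate(tree)
    return tree


def _validate(tree: TreeNode) -> None:
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ParseError(f"duplicate tip labels: {dupes}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and not np.isfinite(node.length):
            raise TreeError(f"non-finite branch length at {node.name!r}")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def root_at_mrca(tree: TreeNode, tip_subset) -> TreeNode:
    """Re-root ``tree`` on the branch subtending the MRCA of ``tip_subset``.

    The new root is placed at the midpoint of that branch, so total tree
    length is conserved.  Re-rooting at the MRCA of all tips (i.e. the
    current root) is refused as ambiguous.
    """
    tip_subset = list(tip_subset)
    if not tip_subset:
        raise TreeError("tip_subset is empty")
    tip_names = {t.name for t in tree.tips()}
    unknown = sorted(set(tip_subset) - tip_names)
    if unknown:
        raise TreeError(f"tips not in tree: {unknown}")
    if set(tip_subset) == tip_names:
        raise TreeError(
            "tip_subset covers every tip; its MRCA is the current root and "
            "re-rooting is ambiguous"
        )
    mrca = tree.lca(tip_subset)
    if mrca.is_root():
        raise TreeError(
            "MRCA of the subset is already the root; re-rooting is ambiguous"
        )
    if mrca.is_tip():
        # Rooting on a pendant branch is well-defined: split it in half.
        pass
    return tree.root_at(mrca, above=True, reset=True)


def tip_heights(tree: TreeNode) -> pd.Series:
    """Root-to-tip path length for every tip (a.k.a. node height of the tip)."""
    heights = {}
    for tip in tree.tips():
        h = 0.0
        node = tip
        while node.parent is not None:
            h += node.length or 0.0
            node = node.parent
        heights[tip.name] = h
    return pd.Series(heights, name="height")


def prune_long_tips(tree: TreeNode, max_height: float = 2.0):
    """Drop tips whose root-to-tip path length exceeds ``max_height``.

    Mirrors the common QC step of removing anomalous long-branch tips after
    rooting.  Degree-2 nodes created by the removal are collapsed with branch
    lengths summed.  Returns ``(pruned_tree, removed_tip_names)``.
    """
    heights = tip_heights(tree)
    removed = sorted(heights.index[heights > max_height])
    if not removed:
        return tree.copy(), []
    keep = [n for n in heights.index if n not in set(removed)]
    if len(keep) < 2:
        raise TreeError(
            f"pruning at max_height={max_height} would leave {len(keep)} tip(s)"
        )
    pruned = tree.shear(keep)
    return pruned, removed


def cophenetic(tree: TreeNode) -> pd.DataFrame:
    """Pairwise tip-to-tip patristic distance matrix as a DataFrame."""
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    return pd.DataFrame(dm.data, index=ids, columns=ids)


@dataclass
class BranchTable:
    """Flattened tree: per-branch lengths and per-sample descendant abundance.

    Attributes
    ----------
    lengths : (n_branches,) float array of branch lengths.
    abundances : (n_branches, n_samples) float array; entry (i, s) is the
        total abundance in sample s over the tips descending from branch i.
    sample_ids : column labels of the abundance matrix.
    tip_sets : list of frozensets of descendant tip names per branch.
    mode : 'relative' or 'absolute', inherited from the abundance matrix.
    """

    lengths: np.ndarray
    abundances: np.ndarray
    sample_ids: list
    tip_sets: list = field(repr=False)
    mode: str = "relative"

    @property
    def n_branches(self) -> int:
        return len(self.lengths)

    def column(self, sample_id) -> np.ndarray:
        return self.abundances[:, self.sample_ids.index(sample_id)]


def branch_abundances(tree: TreeNode, abund) -> BranchTable:
    """Aggregate an abundance matrix (taxa x samples) onto every branch.

    ``abund`` may be an :class:`~limnoecol.features.AbundanceMatrix` or a
    plain DataFrame indexed by tip label.  Tips absent from the matrix are
    treated as zero; matrix taxa with nonzero abundance that are not tips of
    the tree are an error.  The root carries no branch and is excluded.
    """
    mode = getattr(abund, "mode", "relative")
    values = getattr(abund, "values_df", None)
    if values is None:
        values = abund
    tip_names = {t.name for t in tree.tips()}
    extra = values.index.difference(tip_names)
    if len(extra):
        bad = values.loc[extra]
        nonzero = sorted(bad.index[(bad != 0).any(axis=1)])
        if nonzero:
            raise TreeError(
                f"taxa with nonzero abundance missing from tree: {nonzero[:10]}"
            )
    n_samples = values.shape[1]
    arr = values.to_numpy(dtype=float)
    row_of = {name: i for i, name in enumerate(values.index)}

    lengths, rows, tip_sets = [], [], []
    # single post-order pass: children are finalized before their parent
    agg: dict[int, np.ndarray] = {}
    tips_below: dict[int, frozenset] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = row_of.get(node.name)
            vec = arr[i] if i is not None else np.zeros(n_samples)
            agg[id(node)] = vec
            tips_below[id(node)] = frozenset([node.name])
        else:
            vec = np.zeros(n_samples)
            ts = frozenset()
            for child in node.children:
                vec = vec + agg[id(child)]
                ts = ts | tips_below[id(child)]
            agg[id(node)] = vec
            tips_below[id(node)] = ts
        if node.parent is not None:  # root excluded from the branch set
            lengths.append(node.length if node.length is not None else 0.0)
            rows.append(agg[id(node)])
            tip_sets.append(tips_below[id(node)])

    return BranchTable(
        lengths=np.asarray(lengths, dtype=float),
        abundances=np.vstack(rows) if rows else np.zeros((0, n_samples)),
        sample_ids=list(values.columns),
        tip_sets=tip_sets,
        mode=mode,
    )
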