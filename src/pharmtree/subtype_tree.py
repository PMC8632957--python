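"""Sensitivity labelling and recursive drug-response partition trees.

Each drug gets a binary tree over its assayed cell lines.  Cells below the
drug's screening ceiling are "sensitive", all others "resistant".  A node is
split by sorting its cells by ln-IC50 and scanning every contiguous division
with at least three cells on each side; the division with the smallest
two-sided Mann-Whitney U p-value wins.  Recursion stops when a node is
smaller than six cells, is homogeneous in sensitivity label, or no division
reaches p < 0.05.  Leaves, read left to right, are the pharmacological
subtypes C1..Ck ordered from most sensitive to most resistant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ResponseMatrix, ValidationError

SENSITIVE = "sensitive"
RESISTANT = "resistant"
MIXED = "mixed"
MISSING = "missing"

#: raw two-sided p-value below which a division is accepted
DEFAULT_ALPHA = 0.05
#: nodes smaller than this are terminal
MIN_NODE_SIZE = 6
#: smallest admissible child node
MIN_CHILD_SIZE = 3
#: pooled sample size up to which the exact U null distribution is used
#: (requires tie-free data); larger nodes fall back to the tie-corrected
#: normal approximation without continuity correction
DEFAULT_EXACT_MAX_N = 40


class EmptyTreeError(ValidationError):
    """Raised when a drug has no assayed cells to build a tree from."""


def label_sensitivity(ln_ic50: float | None, max_conc: float) -> str:
    """Label one response: sensitive iff ln_ic50 < ln(max_conc), else resistant.

    A missing (None/NaN) response maps to "missing".  The boundary value
    ln_ic50 == ln(max_conc) is resistant (strict inequality).
    """
    if max_conc <= 0 or not math.isfinite(max_conc):
        raise ValidationError(f"max_conc must be positive and finite, got {max_conc!r}")
    if ln_ic50 is None or (isinstance(ln_ic50, float) and math.isnan(ln_ic50)):
        return MISSING
    ln_ic50 = float(ln_ic50)
    if not math.isfinite(ln_ic50):
        raise ValidationError(f"non-finite ln_ic50 value {ln_ic50!r}")
    return SENSITIVE if ln_ic50 < math.log(max_conc) else RESISTANT


def sensitivity_labels(responses: ResponseMatrix, drug: str) -> pd.Series:
    """Per-cell sensitive/resistant labels over the cells assayed for `drug`."""
    values = responses.drug_response(drug)
    threshold = math.log(float(responses.max_conc[drug]))
    return pd.Series(
        np.where(values.to_numpy() < threshold, SENSITIVE, RESISTANT),
        index=values.index,
        name=drug,
    )


def enumerate_divisions(n_s: int) -> list[int]:
    """Left-block sizes of the admissible contiguous divisions of n_s cells.

    Both children need at least MIN_CHILD_SIZE cells, giving sizes
    3..n_s-3 (n_s - 5 divisions).  Below six cells the node is unsplittable.
    """
    if n_s < MIN_NODE_SIZE:
        return []
    return list(range(MIN_CHILD_SIZE, n_s - MIN_CHILD_SIZE + 1))


@dataclass(eq=True)
class TreeNode:
    """One node of a subtype tree.

    `cells` are stored in increasing ln-IC50 order (ties broken by cell ID),
    so the leftmost leaf is the most sensitive subtype.  Internal nodes carry
    the accepted split p-value; leaves carry a response class.
    """

    cells: tuple[str, ...]
    split_p: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    response_class: str | None = None

    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None


@dataclass(eq=True)
class SubtypeTree:
    """Per-drug binary partition tree; leaves are subtypes C1..Ck."""

    drug: str
    root: TreeNode

    @property
    def leaves(self) -> list[TreeNode]:
        """Leaves in in-order (left subtree first): C1 is most sensitive."""
        return list(_iter_leaves(self.root))

    @property
    def k(self) -> int:
        return len(self.leaves)

    def leaf_of(self) -> dict[str, int]:
        """Map each cell to the 0-based index of its leaf."""
        out: dict[str, int] = {}
        for idx, leaf in enumerate(self.leaves):
            for cell in leaf.cells:
                out[cell] = idx
        return out


def _iter_leaves(node: TreeNode) -> Iterator[TreeNode]:
    if node.is_leaf:
        yield node
    else:
        yield from _iter_leaves(node.left)
        yield from _iter_leaves(node.right)


def sort_by_response(values: pd.Series) -> list[str]:
    """Cell IDs sorted by ascending ln-IC50, ties broken by cell ID."""
    return sorted(values.index, key=lambda c: (values[c], c))


def _mw_pvalue(x: np.ndarray, y: np.ndarray, exact_max_n: int) -> float:
    """Two-sided Mann-Whitney p between two blocks of responses."""
    pooled = np.concatenate([x, y])
    uniq = np.unique(pooled)
    if uniq.size == 1:  # fully tied: no evidence either way
        return 1.0
    has_ties = uniq.size < pooled.size
    method = "exact" if (not has_ties and pooled.size <= exact_max_n) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    p = float(res.pvalue)
    if not math.isfinite(p):  # degenerate variance under heavy ties
        return 1.0
    return min(p, 1.0)


def best_split(
    values: pd.Series,
    alpha: float = DEFAULT_ALPHA,
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> tuple[list[str], list[str], float] | None:
    """Best contiguous division of cells sorted by response, or None.

    Scans all admissible left sizes, computing the two-sided Mann-Whitney U
    p-value between the left (more sensitive) and right blocks.  Returns the
    division with minimal p; ties broken towards the most balanced division,
    then the smaller left block.  Returns None when the node is unsplittable
    or the minimum p is >= alpha.
    """
    if values.isna().any():
        missing = list(values.index[values.isna()])
        raise ValidationError(f"missing response for cells {missing}")
    n = len(values)
    divisions = enumerate_divisions(n)
    if not divisions:
        return None
    order = sort_by_response(values)
    arr = values.loc[order].to_numpy(dtype=float)
    best: tuple[float, int, int] | None = None
    for k in divisions:
        p = _mw_pvalue(arr[:k], arr[k:], exact_max_n)
        key = (p, abs(n - 2 * k), k)
        if best is None or key < best:
            best = key
    p, _, k = best
    if p >= alpha:
        return None
    return order[:k], order[k:], p


def classify_leaf(leaf: "TreeNode | Iterable[str]", labels: pd.Series) -> str:
    """sensitive / resistant / mixed, from the leaf's cell labels."""
    cells = list(leaf.cells) if isinstance(leaf, TreeNode) else list(leaf)
    seen = set(labels.loc[cells])
    if seen == {SENSITIVE}:
        return SENSITIVE
    if seen == {RESISTANT}:
        return RESISTANT
    return MIXED


def grow_tree(
    drug: str,
    responses: ResponseMatrix,
    alpha: float = DEFAULT_ALPHA,
    min_node: int = MIN_NODE_SIZE,
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> SubtypeTree:
    """Grow the pharmacological subtype tree for one drug.

    Depth-first recursion: a node becomes a leaf when it has fewer than
    `min_node` cells, all its cells share one sensitivity label, or no
    division reaches p < alpha; otherwise the best division is accepted and
    both children are grown (left first).
    """
    values = responses.drug_response(drug)
    if values.empty:
        raise EmptyTreeError(f"no assayed cells for drug {drug!r}")
    labels = sensitivity_labels(responses, drug)

    def build(cell_ids: list[str]) -> TreeNode:
        sub = values.loc[cell_ids]
        cells = tuple(sort_by_response(sub))
        if len(cells) < min_node or len(set(labels.loc[list(cells)])) == 1:
            return TreeNode(cells=cells, response_class=classify_leaf(cells, labels))
        found = best_split(sub, alpha=alpha, exact_max_n=exact_max_n)
        if found is None:
            return TreeNode(cells=cells, response_class=classify_leaf(cells, labels))
        left_ids, right_ids, p = found
        return TreeNode(
            cells=cells, split_p=p, left=build(left_ids), right=build(right_ids)
        )

    return SubtypeTree(drug=drug, root=build(list(values.index)))


def subtype_count(tree: SubtypeTree) -> int:
    """Number of pharmacological subtypes (leaves) of a tree."""
    return tree.k
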