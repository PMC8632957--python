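"""Downstream cohort statistics.

Hierarchical clustering of similarity matrices with Fisher-exact phenotype
enrichment, per-cancer subtype-count (treatment heterogeneity) profiles,
Kolmogorov-Smirnov comparisons of those distributions, and hypergeometric
enrichment of a histology inside a subtype.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io_formats import ResponseMatrix, ValidationError
from .subtype_tree import EmptyTreeError, SubtypeTree, TreeNode, grow_tree

#: a histology is profiled only when its mean assayed cells per drug exceeds this
MIN_MEAN_CELLS = 35.0


@dataclass
class ClusterAssignment:
    items: list[str]
    labels: np.ndarray  # one integer label per item
    k: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.items, name="cluster")


@dataclass
class EnrichmentResult:
    cluster: int
    phenotype: str
    p: float
    direction: str  # over | under


@dataclass
class CancerProfile:
    """Subtype-count distribution for one histology."""

    cancer: str
    eligible: bool
    mean_cells_per_drug: float
    subtype_counts: dict[int, int] = field(default_factory=dict)

    @property
    def total_trees(self) -> int:
        return sum(self.subtype_counts.values())


def cluster_items(
    similarity: pd.DataFrame,
    k: int,
    method: str = "ward",
    height: float | None = None,
) -> ClusterAssignment:
    """Agglomerative clustering of similarity-matrix rows.

    Rows are embedded as vectors and clustered on Euclidean distances with
    the given linkage; the dendrogram is cut to exactly `k` clusters (or at
    an absolute `height` if one is given).  Deterministic for fixed input.
    """
    items = list(similarity.index)
    n = len(items)
    if height is None and k < 2:
        raise ValidationError("need k >= 2 clusters")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of items ({n})")
    X = similarity.fillna(0.0).to_numpy(dtype=float)
    if not np.allclose(X, X.T, atol=1e-8):
        raise ValidationError("similarity matrix must be symmetric")
    d = pdist(X, metric="euclidean")
    Z = linkage(d, method=method)
    if height is not None:
        labels = fcluster(Z, t=height, criterion="distance")
    else:
        labels = fcluster(Z, t=k, criterion="maxclust")
    realised = len(set(labels))
    if height is None and realised < k:
        warnings.warn(
            f"degenerate clustering: only {realised} distinct clusters for k={k}"
        )
    return ClusterAssignment(items=items, labels=np.asarray(labels), k=realised)


def cluster_phenotype_enrichment(
    assignment: ClusterAssignment, phenotypes: pd.Series
) -> list[EnrichmentResult]:
    """Two-sided Fisher exact test per (cluster, phenotype) 2x2 table."""
    missing = [i for i in assignment.items if i not in phenotypes.index]
    if missing:
        raise ValidationError(f"items without phenotype label: {missing}")
    labels = assignment.as_series()
    ph = phenotypes.loc[assignment.items]
    clusters = sorted(set(labels))
    if len(clusters) < 2:
        return []
    results: list[EnrichmentResult] = []
    n = len(labels)
    for cl in clusters:
        in_cl = labels == cl
        for name in sorted(set(ph)):
            has = ph == name
            a = int((in_cl & has).sum())
            b = int((in_cl & ~has).sum())
            c = int((~in_cl & has).sum())
            d = n - a - b - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            in_rate = a / max(a + b, 1)
            out_rate = c / max(c + d, 1)
            results.append(
                EnrichmentResult(
                    cluster=int(cl),
                    phenotype=str(name),
                    p=float(p),
                    direction="over" if in_rate >= out_rate else "under",
                )
            )
    return results


def heterogeneity_profile(
    responses: ResponseMatrix,
    min_mean_cells: float = MIN_MEAN_CELLS,
    cancers: Iterable[str] | None = None,
    **tree_kwargs,
) -> dict[str, CancerProfile]:
    """Per-cancer subtype-count distributions from histology-restricted trees.

    For each histology, trees are grown per drug using only that histology's
    cells; the profile maps leaf counts to the number of drugs realising
    them.  A cancer is flagged eligible when its mean assayed cells per drug
    (over drugs with at least one assayed cell) exceeds `min_mean_cells`.
    """
    if cancers is None:
        cancers = sorted(set(responses.histology))
    out: dict[str, CancerProfile] = {}
    for cancer in cancers:
        cells = responses.histology.index[responses.histology == cancer]
        if len(cells) == 0:
            out[cancer] = CancerProfile(cancer, False, 0.0)
            continue
        sub_ln = responses.ln_ic50.loc[cells]
        counts_per_drug = sub_ln.notna().sum(axis=0)
        assayed_drugs = counts_per_drug.index[counts_per_drug > 0]
        if len(assayed_drugs) == 0:
            out[cancer] = CancerProfile(cancer, False, 0.0)
            continue
        mean_cells = float(counts_per_drug.loc[assayed_drugs].mean())
        sub = ResponseMatrix(
            ln_ic50=sub_ln[list(assayed_drugs)],
            max_conc=responses.max_conc.loc[list(assayed_drugs)],
            histology=responses.histology.loc[cells],
        )
        counter: Counter[int] = Counter()
        for drug in assayed_drugs:
            try:
                tree = grow_tree(drug, sub, **tree_kwargs)
            except EmptyTreeError:
                continue
            counter[tree.k] += 1
        out[cancer] = CancerProfile(
            cancer=cancer,
            eligible=mean_cells > min_mean_cells,
            mean_cells_per_drug=mean_cells,
            subtype_counts=dict(sorted(counter.items())),
        )
    return out


def ks_compare(dist_a: Sequence[float], dist_b: Sequence[float]) -> float:
    """Two-sample two-sided Kolmogorov-Smirnov p-value."""
    a = np.asarray(list(dist_a), dtype=float)
    b = np.asarray(list(dist_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("ks_compare requires two non-empty samples")
    return float(stats.ks_2samp(a, b, alternative="two-sided").pvalue)


def subtype_enrichment(
    leaf: "TreeNode | Iterable[str]", cancer: str, histology: pd.Series
) -> float:
    """Upper-tail hypergeometric p for over-representation of one histology
    in a subtype, against the universe of all labelled cells."""
    cells = list(leaf.cells) if isinstance(leaf, TreeNode) else list(leaf)
    if not cells:
        raise ValidationError("leaf is empty")
    missing = [c for c in cells if c not in histology.index]
    if missing:
        raise ValidationError(f"leaf cells outside the universe: {missing}")
    M = len(histology)
    K = int((histology == cancer).sum())
    if K == 0:
        raise ValidationError(f"histology {cancer!r} absent from the universe")
    n = len(cells)
    x = int((histology.loc[cells] == cancer).sum())
    return float(stats.hypergeom.sf(x - 1, M, K, n))
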