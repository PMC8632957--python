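"""Gene-drug connection tests, FDR control, and the association network.

Genomic alterations are tested against a drug's subtypes with a chi-squared
test on the 2 x K table of altered/unaltered counts over the non-mixed
leaves; expression with an equal-variance t test between the cells of
sensitive-class leaves and resistant-class leaves.  P-values are adjusted
per drug and modality with Benjamini-Hochberg; records are retained at
q < 0.1, and expression records additionally need a Pearson correlation
between ln-IC50 and expression (over the sensitive pool) stronger than 0.3
with sign consistent with the direction label.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    AlterationMatrix,
    ExpressionMatrix,
    ResponseMatrix,
    ValidationError,
)
from .subtype_tree import MIXED, RESISTANT, SENSITIVE, SubtypeTree, sensitivity_labels

GENOMIC = "genomic"
EXPRESSION = "expression"

DEFAULT_FDR = 0.1
DEFAULT_PCC = 0.3
#: genes altered in fewer analysed cells than this are skipped (degenerate tables)
MIN_ALTERED = 3
#: minimum cells per response-class pool for the expression t test
MIN_POOL = 3


@dataclass(frozen=True)
class ConnectionRecord:
    """One gene-drug association surviving the modality filters."""

    gene: str
    drug: str
    modality: str  # genomic | expression
    p: float
    q_fdr: float
    direction: str  # sensitive | resistant
    pcc: float | None = None  # expression modality only


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _class_pools(tree: SubtypeTree) -> tuple[list, list[str], list[str]]:
    """Non-mixed leaves and the cells pooled by leaf response class."""
    non_mixed = [leaf for leaf in tree.leaves if leaf.response_class != MIXED]
    sens = [c for leaf in non_mixed if leaf.response_class == SENSITIVE for c in leaf.cells]
    resist = [c for leaf in non_mixed if leaf.response_class == RESISTANT for c in leaf.cells]
    return non_mixed, sens, resist


def genomic_connection_test(
    status: pd.Series,
    tree: SubtypeTree,
    min_altered: int = MIN_ALTERED,
) -> tuple[float, str] | None:
    """Chi-squared test of one gene's alteration across non-mixed leaves.

    Returns (p, direction) or None when not testable: fewer than two
    non-mixed leaves with analysable cells, too few altered cells, a
    zero-variance gene, or an empty sensitive/resistant pool.  When the two
    pool frequencies tie exactly the p-value is still reported but the
    direction is None (the record can never be retained).
    """
    non_mixed, sens, resist = _class_pools(tree)
    if len(non_mixed) < 2:
        return None
    cells_per_leaf = [
        [c for c in leaf.cells if c in status.index] for leaf in non_mixed
    ]
    cells_per_leaf = [cells for cells in cells_per_leaf if cells]
    if len(cells_per_leaf) < 2:
        return None
    altered = np.array([int(status.loc[cells].sum()) for cells in cells_per_leaf])
    totals = np.array([len(cells) for cells in cells_per_leaf])
    if altered.sum() < min_altered:
        return None
    if (totals - altered).sum() == 0:  # altered everywhere: zero variance
        return None
    table = np.vstack([altered, totals - altered])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    sens = [c for c in sens if c in status.index]
    resist = [c for c in resist if c in status.index]
    if not sens or not resist:
        return None
    freq_s = float(status.loc[sens].mean())
    freq_r = float(status.loc[resist].mean())
    if freq_s == freq_r:
        return float(p), None
    direction = SENSITIVE if freq_s > freq_r else RESISTANT
    return float(p), direction


def expression_connection_test(
    expr: pd.Series,
    tree: SubtypeTree,
    ln_ic50: pd.Series,
    min_pool: int = MIN_POOL,
) -> tuple[float, str, float] | None:
    """t test of one gene's expression between the class pools, plus PCC.

    Returns (p, direction, pcc) where pcc is the Pearson correlation between
    ln-IC50 and expression over the sensitive-class cells (NaN when not
    computable), or None when not testable.
    """
    _, sens, resist = _class_pools(tree)
    sens = [c for c in sens if c in expr.index and c in ln_ic50.index]
    resist = [c for c in resist if c in expr.index and c in ln_ic50.index]
    if len(sens) < min_pool or len(resist) < min_pool:
        return None
    xs = expr.loc[sens].to_numpy(dtype=float)
    xr = expr.loc[resist].to_numpy(dtype=float)
    if xs.std(ddof=1) == 0.0 or xr.std(ddof=1) == 0.0:
        return None
    _, p = stats.ttest_ind(xs, xr, equal_var=True)
    if not math.isfinite(p):
        return None
    mean_s, mean_r = float(xs.mean()), float(xr.mean())
    if mean_s == mean_r:
        return None
    direction = SENSITIVE if mean_s > mean_r else RESISTANT
    ic = ln_ic50.loc[sens].to_numpy(dtype=float)
    if len(sens) >= 2 and ic.std() > 0 and xs.std() > 0:
        pcc = float(stats.pearsonr(ic, xs).statistic)
    else:
        pcc = float("nan")
    return float(p), direction, pcc


def passes_pcc(direction: str, pcc: float, threshold: float = DEFAULT_PCC) -> bool:
    """Strict |PCC| > threshold with sign consistent with the direction.

    A sensitive connection means expression rises as ln-IC50 falls, i.e.
    PCC(ln-IC50, expression) < -threshold; a resistant connection needs
    PCC > +threshold.
    """
    if pcc is None or not math.isfinite(pcc):
        return False
    return pcc < -threshold if direction == SENSITIVE else pcc > threshold


def connect_drug(
    drug: str,
    tree: SubtypeTree,
    responses: ResponseMatrix,
    alterations: AlterationMatrix | None = None,
    expression: ExpressionMatrix | None = None,
    fdr: float = DEFAULT_FDR,
    pcc_threshold: float = DEFAULT_PCC,
    gene_list: "set[str] | None" = None,
) -> list[ConnectionRecord]:
    """All retained gene connections for one drug.

    BH adjustment is applied per drug within each modality.  `gene_list`
    (e.g. core cancer pathway genes) restricts the expression modality.
    """
    records: list[ConnectionRecord] = []

    if alterations is not None:
        tested: list[tuple[str, float, str]] = []
        for gene in alterations.genes:
            res = genomic_connection_test(alterations.status.loc[gene], tree)
            if res is not None and res[1] is not None:
                tested.append((gene, res[0], res[1]))
        if tested:
            qs = bh_adjust([t[1] for t in tested])
            for (gene, p, direction), q in zip(tested, qs):
                if q < fdr:
                    records.append(
                        ConnectionRecord(gene, drug, GENOMIC, p, float(q), direction)
                    )

    if expression is not None:
        ln = responses.drug_response(drug)
        genes = expression.genes
        if gene_list is not None:
            genes = [g for g in genes if g in gene_list]
        tested_e: list[tuple[str, float, str, float]] = []
        for gene in genes:
            res = expression_connection_test(expression.expr.loc[gene], tree, ln)
            if res is not None:
                tested_e.append((gene, *res))
        if tested_e:
            qs = bh_adjust([t[1] for t in tested_e])
            for (gene, p, direction, pcc), q in zip(tested_e, qs):
                if q < fdr and passes_pcc(direction, pcc, pcc_threshold):
                    records.append(
                        ConnectionRecord(gene, drug, EXPRESSION, p, float(q), direction, pcc)
                    )

    return records


def connect_all(
    trees: Mapping[str, SubtypeTree],
    responses: ResponseMatrix,
    alterations: AlterationMatrix | None = None,
    expression: ExpressionMatrix | None = None,
    fdr: float = DEFAULT_FDR,
    pcc_threshold: float = DEFAULT_PCC,
    gene_list: "set[str] | None" = None,
) -> list[ConnectionRecord]:
    records: list[ConnectionRecord] = []
    for drug in sorted(trees):
        records.extend(
            connect_drug(
                drug,
                trees[drug],
                responses,
                alterations=alterations,
                expression=expression,
                fdr=fdr,
                pcc_threshold=pcc_threshold,
                gene_list=gene_list,
            )
        )
    return records


@dataclass
class ConnectionNetwork:
    """Bipartite gene-drug network with degree indices."""

    graph: nx.Graph
    records: list[ConnectionRecord]
    gene_degree: pd.Series
    drug_degree: pd.Series


def build_network(
    records: Sequence[ConnectionRecord],
) -> ConnectionNetwork:
    """Assemble the bipartite network; duplicate (gene, drug, modality) edges
    are dropped with a warning."""
    seen: set[tuple[str, str, str]] = set()
    kept: list[ConnectionRecord] = []
    for r in records:
        key = (r.gene, r.drug, r.modality)
        if key in seen:
            warnings.warn(f"duplicate connection record {key} dropped")
            continue
        seen.add(key)
        kept.append(r)
    g = nx.Graph()
    gene_counts: dict[str, int] = {}
    drug_counts: dict[str, int] = {}
    for r in kept:
        g.add_node(r.gene, bipartite="gene")
        g.add_node(r.drug, bipartite="drug")
        g.add_edge(
            r.gene, r.drug, modality=r.modality, direction=r.direction,
            p=r.p, q_fdr=r.q_fdr,
        )
        gene_counts[r.gene] = gene_counts.get(r.gene, 0) + 1
        drug_counts[r.drug] = drug_counts.get(r.drug, 0) + 1
    gene_degree = pd.Series(gene_counts, dtype=int).sort_values(ascending=False)
    drug_degree = pd.Series(drug_counts, dtype=int).sort_values(ascending=False)
    return ConnectionNetwork(
        graph=g, records=kept, gene_degree=gene_degree, drug_degree=drug_degree
    )


def gene_list_enrichment(
    network: ConnectionNetwork,
    gene_list: "set[str]",
    top_k: int,
    universe_size: int,
    alternative: str = "greater",
) -> float:
    """Fisher exact p for enrichment of `gene_list` among the top-k hub genes.

    The 2 x 2 table counts list membership inside and outside the top-k genes
    against a background universe of `universe_size` genes.
    """
    if top_k <= 0 or universe_size < top_k:
        raise ValidationError("need 0 < top_k <= universe_size")
    ranked = sorted(
        network.gene_degree.items(), key=lambda item: (-item[1], item[0])
    )
    top = {gene for gene, _ in ranked[:top_k]}
    a = len(top & gene_list)
    b = top_k - a
    c = len(gene_list) - a
    d = universe_size - top_k - c
    if d < 0:
        raise ValidationError("gene list larger than the stated universe")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(p)
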