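"""Pair-concordance matrices and the derived cell-cell / drug-drug similarity.

For each drug, a symmetric matrix scores every assayed cell pair: +1 when the
two cells share a leaf and are both sensitive, -1 when they share a leaf and
are both resistant, 0 otherwise.  Cell similarity averages |score| over the
drugs in which both cells were assayed; drug similarity is a Tanimoto-style
ratio between two drugs' concordance matrices restricted to shared cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_formats import ValidationError
from .subtype_tree import RESISTANT, SENSITIVE, SubtypeTree


class UndefinedSimilarityError(ValidationError):
    """Raised when a similarity score has no defined value (too few shared cells)."""


@dataclass
class PairConcordanceMatrix:
    """Per-drug symmetric cell-pair concordance scores in {-1, 0, 1}."""

    drug: str
    cells: list[str]
    D: np.ndarray  # m x m int8, zero diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.cells, columns=self.cells)


@dataclass
class CellSimilarityMatrix:
    """Cell-cell similarity S in [0, 1] and per-pair co-assay counts q.

    S[i, j] is defined only where q[i, j] >= 1; undefined entries are NaN in
    memory (serialised as 0 with a flag downstream).  The pair score is
    defined for i != j only; the diagonal of S is fixed at 1 (self
    similarity) so row vectors of identically-responding cells coincide, and
    the diagonal of q at 0.
    """

    S: pd.DataFrame
    q: pd.DataFrame


@dataclass
class DrugSimilarityScore:
    drug_a: str
    drug_b: str
    value: float
    m: int  # number of shared assayed cells
    undefined: bool = False


def pair_concordance(tree: SubtypeTree, labels: pd.Series) -> PairConcordanceMatrix:
    """Score every cell pair of one drug's tree.

    +1: same leaf, both sensitive; -1: same leaf, both resistant; 0 otherwise
    (different leaves, discordant labels, or i == j).
    """
    cells = sorted(tree.root.cells)
    missing = [c for c in cells if c not in labels.index]
    if missing:
        raise ValidationError(f"cells without sensitivity label: {missing}")
    leaf_of = tree.leaf_of()
    leaf_idx = np.array([leaf_of[c] for c in cells])
    lab = labels.loc[cells].to_numpy()
    same_leaf = leaf_idx[:, None] == leaf_idx[None, :]
    sens = lab == SENSITIVE
    resist = lab == RESISTANT
    D = np.zeros((len(cells), len(cells)), dtype=np.int8)
    D[same_leaf & sens[:, None] & sens[None, :]] = 1
    D[same_leaf & resist[:, None] & resist[None, :]] = -1
    np.fill_diagonal(D, 0)
    return PairConcordanceMatrix(drug=tree.drug, cells=cells, D=D)


def cell_similarity(concordances: Sequence[PairConcordanceMatrix]) -> CellSimilarityMatrix:
    """Average |concordance| per cell pair over co-assayed drugs.

    q counts only drugs in which BOTH cells of a pair were assayed; pairs
    with q == 0 are undefined (NaN).
    """
    if not concordances:
        raise ValidationError("cell_similarity requires at least one concordance matrix")
    all_cells = sorted(set().union(*(pc.cells for pc in concordances)))
    pos = {c: i for i, c in enumerate(all_cells)}
    n = len(all_cells)
    num = np.zeros((n, n), dtype=float)
    q = np.zeros((n, n), dtype=int)
    for pc in concordances:
        idx = np.array([pos[c] for c in pc.cells])
        num[np.ix_(idx, idx)] += np.abs(pc.D)
        q[np.ix_(idx, idx)] += 1
    np.fill_diagonal(q, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(q > 0, num / np.maximum(q, 1), np.nan)
    np.fill_diagonal(S, 1.0)
    off = ~np.eye(n, dtype=bool)
    if not (q[off] > 0).any():
        warnings.warn("no cell pair shares an assayed drug; all similarities undefined")
    return CellSimilarityMatrix(
        S=pd.DataFrame(S, index=all_cells, columns=all_cells),
        q=pd.DataFrame(q, index=all_cells, columns=all_cells),
    )


def drug_similarity(
    Da: PairConcordanceMatrix, Db: PairConcordanceMatrix
) -> DrugSimilarityScore:
    """Tanimoto-style similarity of two drugs' concordance matrices.

    Sums run over ordered off-diagonal pairs of the shared cell set; the
    double counting cancels in the ratio.  A zero denominator yields value 0
    flagged undefined.  Negative values are possible and retained.
    """
    shared = sorted(set(Da.cells) & set(Db.cells))
    if len(shared) < 2:
        raise UndefinedSimilarityError(
            f"drugs {Da.drug!r} and {Db.drug!r} share fewer than 2 assayed cells"
        )
    A = Da.to_frame().loc[shared, shared].to_numpy(dtype=float)
    B = Db.to_frame().loc[shared, shared].to_numpy(dtype=float)
    num = float((A * B).sum())
    den = float((A * A).sum() + (B * B).sum() - num)
    if den == 0.0:
        return DrugSimilarityScore(Da.drug, Db.drug, 0.0, len(shared), undefined=True)
    return DrugSimilarityScore(Da.drug, Db.drug, num / den, len(shared))


def drug_similarity_table(
    concordances: Sequence[PairConcordanceMatrix],
) -> pd.DataFrame:
    """Long-format pairwise drug similarity (drug_a, drug_b, value, m, undefined)."""
    rows = []
    for i, Da in enumerate(concordances):
        for Db in concordances[i + 1 :]:
            try:
                s = drug_similarity(Da, Db)
            except UndefinedSimilarityError:
                s = DrugSimilarityScore(
                    Da.drug, Db.drug, 0.0, len(set(Da.cells) & set(Db.cells)), True
                )
            rows.append(
                {
                    "drug_a": s.drug_a,
                    "drug_b": s.drug_b,
                    "value": s.value,
                    "m": s.m,
                    "undefined": s.undefined,
                }
            )
    return pd.DataFrame(rows, columns=["drug_a", "drug_b", "value", "m", "undefined"])


def drug_similarity_matrix(
    concordances: Sequence[PairConcordanceMatrix],
) -> pd.DataFrame:
    """Square symmetric drug similarity matrix (undefined pairs as 0)."""
    drugs = [pc.drug for pc in concordances]
    mat = pd.DataFrame(np.ones((len(drugs), len(drugs))), index=drugs, columns=drugs)
    by_drug = {pc.drug: pc for pc in concordances}
    for d in drugs:
        s = drug_similarity(by_drug[d], by_drug[d])
        mat.loc[d, d] = s.value
    table = drug_similarity_table(concordances)
    for row in table.itertuples(index=False):
        mat.loc[row.drug_a, row.drug_b] = row.value
        mat.loc[row.drug_b, row.drug_a] = row.value
    return mat


def similarity_to_distance(sim: "CellSimilarityMatrix | pd.DataFrame") -> pd.DataFrame:
    """Euclidean distances between similarity-matrix rows (undefined -> 0)."""
    S = sim.S if isinstance(sim, CellSimilarityMatrix) else sim
    X = S.fillna(0.0).to_numpy(dtype=float)
    D = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(D, index=S.index, columns=S.columns)
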