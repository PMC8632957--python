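"""Seeded synthetic pharmacogenomic cohorts with planted structure.

Each drug's ln-IC50 values are drawn from a mixture of normal components
straddling the screening ceiling (the planted subtype groups); alteration
status is Bernoulli with group-specific frequencies for effect genes;
expression is a linear function of ln-IC50 plus noise for effect genes and
pure noise for null genes.  A single seed reproduces everything via named
sub-streams, and the planted truth is returned for recovery scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .connections import ConnectionRecord, EXPRESSION, GENOMIC
from .io_formats import (
    AlterationMatrix,
    ExpressionMatrix,
    ResponseMatrix,
    ValidationError,
)
from .subtype_tree import RESISTANT, SENSITIVE, SubtypeTree

#: ceilings drawn log-uniformly from this range (uM) when none is given,
#: matching the typical screening range of large cell-line panels
CEILING_RANGE = (0.08, 20.0)

# fixed spawn order of the per-component random streams
_STREAMS = ("histology", "membership", "response", "missing", "alteration", "expression")


@dataclass(frozen=True)
class GenomicEffect:
    """Planted alteration-frequency profile over one drug's groups."""

    gene: str
    drug: str
    group_freqs: tuple[float, ...]


@dataclass(frozen=True)
class ExpressionEffect:
    """Planted linear expression/ln-IC50 relation for one drug."""

    gene: str
    drug: str
    slope: float
    noise_sd: float = 0.5
    intercept: float = 0.0


@dataclass
class SyntheticConfig:
    n_cells: int = 60
    n_drugs: int = 1
    group_means: tuple[float, ...] = (-6.0, -1.0, 4.0)  # ln(uM), ascending
    group_sds: "tuple[float, ...] | float" = 0.5
    group_weights: tuple[float, ...] | None = None  # default uniform
    max_conc: "float | tuple[float, ...] | None" = 1.0  # uM; None -> random draw
    histology_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"CANA": 0.5, "CANB": 0.5}
    )
    genomic_effects: tuple[GenomicEffect, ...] = ()
    expression_effects: tuple[ExpressionEffect, ...] = ()
    n_null_genes: int = 0
    background_alteration_freq: float = 0.2
    null_expression_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_drugs < 1:
            raise ValidationError("need at least one cell and one drug")
        means = tuple(float(m) for m in self.group_means)
        if list(means) != sorted(means):
            raise ValidationError("group_means must be ascending")
        self.group_means = means
        g = len(means)
        sds = self.group_sds
        if isinstance(sds, (int, float)):
            sds = (float(sds),) * g
        if len(sds) != g or any(s <= 0 for s in sds):
            raise ValidationError("group_sds must be positive, one per group")
        self.group_sds = tuple(float(s) for s in sds)
        if self.group_weights is None:
            self.group_weights = (1.0 / g,) * g
        if len(self.group_weights) != g:
            raise ValidationError("group_weights must match the number of groups")
        total = sum(self.group_weights)
        self.group_weights = tuple(w / total for w in self.group_weights)
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.background_alteration_freq <= 1.0):
            raise ValidationError("background_alteration_freq must be in [0, 1]")
        for eff in self.genomic_effects:
            if len(eff.group_freqs) != g:
                raise ValidationError(
                    f"genomic effect for {eff.gene!r} needs {g} group frequencies"
                )
            if any(not 0.0 <= f <= 1.0 for f in eff.group_freqs):
                raise ValidationError("alteration frequencies must lie in [0, 1]")

    @property
    def n_groups(self) -> int:
        return len(self.group_means)


@dataclass(frozen=True)
class PlantedConnection:
    gene: str
    drug: str
    modality: str
    direction: str


@dataclass
class SyntheticTruth:
    """Planted group memberships and planted gene effects."""

    groups: pd.DataFrame  # cells x drugs, integer group index
    histology: pd.Series
    connections: tuple[PlantedConnection, ...]


def _resolve_ceilings(config: SyntheticConfig, drugs: list[str], rng) -> pd.Series:
    mc = config.max_conc
    if mc is None:
        lo, hi = np.log(CEILING_RANGE)
        return pd.Series(np.exp(rng.uniform(lo, hi, len(drugs))), index=drugs)
    if isinstance(mc, (int, float)):
        return pd.Series(float(mc), index=drugs)
    if len(mc) != len(drugs):
        raise ValidationError("max_conc tuple must have one entry per drug")
    return pd.Series([float(v) for v in mc], index=drugs)


def _planted_direction(config: SyntheticConfig, eff: GenomicEffect, ceiling: float) -> str | None:
    threshold = math.log(ceiling)
    sens = [g for g, m in enumerate(config.group_means) if m < threshold]
    resist = [g for g in range(config.n_groups) if g not in sens]
    if not sens or not resist:
        return None
    f_s = float(np.mean([eff.group_freqs[g] for g in sens]))
    f_r = float(np.mean([eff.group_freqs[g] for g in resist]))
    if f_s == f_r:
        return None
    return SENSITIVE if f_s > f_r else RESISTANT


def generate(
    config: SyntheticConfig,
) -> tuple[ResponseMatrix, AlterationMatrix, ExpressionMatrix, SyntheticTruth]:
    """Draw one cohort; fully reproducible from config.seed."""
    streams = dict(
        zip(_STREAMS, map(np.random.default_rng, np.random.SeedSequence(config.seed).spawn(len(_STREAMS))))
    )
    cells = [f"CL{i:04d}" for i in range(config.n_cells)]
    drugs = [f"D{j:03d}" for j in range(config.n_drugs)]

    hist_labels = sorted(config.histology_proportions)
    probs = np.array([config.histology_proportions[h] for h in hist_labels], dtype=float)
    probs = probs / probs.sum()
    histology = pd.Series(
        streams["histology"].choice(hist_labels, size=config.n_cells, p=probs),
        index=cells,
    )

    groups = pd.DataFrame(
        streams["membership"].choice(
            config.n_groups, size=(config.n_cells, config.n_drugs),
            p=config.group_weights,
        ),
        index=cells,
        columns=drugs,
    )

    means = np.asarray(config.group_means)
    sds = np.asarray(config.group_sds)
    g = groups.to_numpy()
    ln = streams["response"].normal(means[g], sds[g])
    if config.missing_rate > 0:
        mask = streams["missing"].random(ln.shape) < config.missing_rate
        ln = np.where(mask, np.nan, ln)
    ln_df = pd.DataFrame(ln, index=cells, columns=drugs)
    max_conc = _resolve_ceilings(config, drugs, streams["response"])
    responses = ResponseMatrix(ln_ic50=ln_df, max_conc=max_conc, histology=histology)

    effect_alt_genes = sorted({e.gene for e in config.genomic_effects})
    effect_expr_genes = sorted({e.gene for e in config.expression_effects})
    null_genes = [f"NULL{i:04d}" for i in range(config.n_null_genes)]

    alt_rng = streams["alteration"]
    alt_rows: dict[str, np.ndarray] = {}
    for gene in effect_alt_genes + null_genes:
        effs = [e for e in config.genomic_effects if e.gene == gene]
        if effs:
            eff = effs[0]  # frequencies follow the gene's first planted drug
            freqs = np.asarray(eff.group_freqs)[groups[eff.drug].to_numpy()]
        else:
            freqs = np.full(config.n_cells, config.background_alteration_freq)
        alt_rows[gene] = (alt_rng.random(config.n_cells) < freqs).astype(np.int8)
    alterations = AlterationMatrix(
        status=pd.DataFrame(alt_rows, index=cells).T
        if alt_rows
        else pd.DataFrame(
            np.zeros((1, config.n_cells), dtype=np.int8), index=["NULL0000"], columns=cells
        )
    )

    expr_rng = streams["expression"]
    expr_rows: dict[str, np.ndarray] = {}
    for gene in effect_expr_genes + null_genes:
        effs = [e for e in config.expression_effects if e.gene == gene]
        if effs:
            eff = effs[0]
            base = ln_df[eff.drug].to_numpy()
            base = np.where(np.isnan(base), np.nanmean(base), base)
            expr_rows[gene] = (
                eff.slope * base
                + eff.intercept
                + expr_rng.normal(0.0, eff.noise_sd, config.n_cells)
            )
        else:
            expr_rows[gene] = expr_rng.normal(
                0.0, config.null_expression_sd, config.n_cells
            )
    expression = ExpressionMatrix(
        expr=pd.DataFrame(expr_rows, index=cells).T
        if expr_rows
        else pd.DataFrame(
            np.zeros((1, config.n_cells)), index=["NULL0000"], columns=cells
        )
    )

    planted: list[PlantedConnection] = []
    for eff in config.genomic_effects:
        direction = _planted_direction(config, eff, float(max_conc[eff.drug]))
        if direction is not None:
            planted.append(PlantedConnection(eff.gene, eff.drug, GENOMIC, direction))
    for eff in config.expression_effects:
        direction = SENSITIVE if eff.slope < 0 else RESISTANT
        planted.append(PlantedConnection(eff.gene, eff.drug, EXPRESSION, direction))

    truth = SyntheticTruth(
        groups=groups, histology=histology, connections=tuple(planted)
    )
    return responses, alterations, expression, truth


@dataclass
class RecoveryReport:
    ari: dict[str, float]
    precision: float | None = None
    recall: float | None = None
    direction_accuracy: float | None = None


def evaluate_recovery(
    truth: SyntheticTruth,
    trees: Mapping[str, SubtypeTree],
    records: Sequence[ConnectionRecord] | None = None,
) -> RecoveryReport:
    """Score leaf partitions against planted groups and, optionally,
    connection records against planted connections."""
    ari: dict[str, float] = {}
    for drug, tree in trees.items():
        if drug not in truth.groups.columns:
            raise ValidationError(f"drug {drug!r} absent from planted truth")
        cells = list(tree.root.cells)
        missing = [c for c in cells if c not in truth.groups.index]
        if missing:
            raise ValidationError(f"cells absent from planted truth: {missing}")
        planted = truth.groups.loc[cells, drug].to_numpy()
        leaf_of = tree.leaf_of()
        found = np.array([leaf_of[c] for c in cells])
        ari[drug] = float(adjusted_rand_score(planted, found))

    precision = recall = direction_accuracy = None
    if records is not None:
        predicted = {(r.gene, r.drug, r.modality): r.direction for r in records}
        planted_map = {
            (c.gene, c.drug, c.modality): c.direction for c in truth.connections
        }
        tp = set(predicted) & set(planted_map)
        precision = len(tp) / len(predicted) if predicted else None
        recall = len(tp) / len(planted_map) if planted_map else None
        if tp:
            direction_accuracy = sum(
                predicted[k] == planted_map[k] for k in tp
            ) / len(tp)
    return RecoveryReport(
        ari=ari, precision=precision, recall=recall,
        direction_accuracy=direction_accuracy,
    )
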