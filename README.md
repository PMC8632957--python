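# pharmtree

Therapeutic-response re-classification of tumour cell lines from large
drug screens.

For every drug, cell lines are labelled **sensitive** when their ln-IC50 lies
below the natural log of the drug's maximum screened concentration, otherwise
**resistant**.  A *pharmacological subtype tree* is grown by recursively
splitting the cells sorted by ln-IC50 at the contiguous division with the
smallest two-sided Mann-Whitney U p-value (divisions leave at least three
cells per side; nodes below six cells, label-homogeneous nodes, or nodes with
no division at p < 0.05 become leaves).  The leaves, left to right, are the
subtypes C1..Ck from most sensitive to most resistant.  On top of the trees,
the package provides:

- **Pair concordance / similarity** — per-drug cell-pair scores in
  {-1, 0, +1} (same leaf + both sensitive / both resistant / otherwise),
  aggregated into cell-cell similarity (mean |score| over co-assayed drugs)
  and a Tanimoto-style drug-drug similarity over shared cells.
- **Gene-drug connections** — chi-squared tests of binary alterations across
  the non-mixed leaves and equal-variance t tests of expression between the
  sensitive- and resistant-class cell pools, Benjamini-Hochberg adjusted per
  drug (q < 0.1), with a Pearson-correlation filter (|PCC| > 0.3, sign
  consistent with the direction label) for expression; retained records form
  a bipartite gene-drug network with degree rankings and gene-list
  enrichment.
- **Cohort statistics** — hierarchical clustering of similarity matrices
  with Fisher-exact phenotype enrichment, per-cancer subtype-count
  (heterogeneity) profiles, Kolmogorov-Smirnov comparisons, and
  hypergeometric enrichment of a histology inside a subtype.
- **Synthetic cohorts** — seeded cohorts with planted subtype groups,
  alteration frequencies and expression effects, plus recovery scoring
  (adjusted Rand index, connection precision/recall).

## Command line

All stages share one entry point:

```sh
pharmtree simulate  --seed 7 --out sim/                 # synthetic cohort
pharmtree fit-trees --responses sim/responses.tsv --out trees/
pharmtree similarity --trees trees/ --responses sim/responses.tsv --out sim_out/
pharmtree connect   --trees trees/ --responses sim/responses.tsv \
                    --alterations sim/alterations.tsv \
                    --expression sim/expression.tsv --out conn/
pharmtree cluster   --similarity sim_out/cell_similarity.tsv --k 4 --out clus/
pharmtree run       --config pipeline.yaml --out run/    # all stages + manifest
```

`pharmtree run` reads a YAML config (`responses`, optional `alterations`,
`expression`, `gene_list`, thresholds `split_alpha`, `fdr`, `pcc`,
`min_node`, cluster counts, `seed`), writes every stage output plus a
`manifest.json` with SHA-256 hashes for exact re-runs, and uses exit codes
0 (success), 2 (validation error), 3 (stage failure).

## File formats

Everything is plain text: the response table is long-format TSV/CSV
(`cell, drug, ln_ic50, max_conc[, histology]`; GDSC-style headers such as
`CELL_LINE_NAME`/`LN_IC50` are also accepted, and cells labelled
`UNCLASSIFIED` are dropped on read); alteration and expression matrices are
gene-rows x cell-columns tables; trees are nested JSON records carrying each
node's cells, split p-value and leaf response class; similarity and
connection tables are TSV.

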