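# tscoex

Tissue-specificity scoring and cross-biotype co-expression networks for
multi-tissue RNA expression data.

Given a sample-level expression matrix (rows = miRNAs / lncRNAs / mRNAs,
columns = samples), a sample→tissue map and an annotation table, the
pipeline:

1. removes pseudogene-flagged RNAs,
2. collapses samples to per-tissue median expression,
3. drops RNAs whose tissue-median vector is all zeros,
4. scores each RNA's tissue specificity with a Gini index over its
   tissue-median vector, classifies it as tissue-specific (GI ≥ 0.85),
   nonspecific (GI ≤ 0.15) or intermediate, and assigns each
   tissue-specific RNA to its maximal-median tissue,
5. builds, per tissue, an undirected co-expression network between
   tissue-specific RNAs of *different* biotypes using sample-level
   Pearson correlation with a strict |r| > 0.7 cutoff.

A synthetic-data module generates datasets with planted housekeeping /
tissue-specific / intermediate roles and latent-factor co-expression so
the whole pipeline is testable offline, and packaged fixtures transcribe
the published per-tissue reference tables for verification.

## CLI

```sh
# generate a synthetic dataset (+ truth + ready-to-use run config)
tscoex simulate --seed 42 --out-dir sim/

# run the full pipeline
tscoex run --config sim/config.yaml

# print the summary tables of a finished run
tscoex summarize --results sim/results

# recompute all packaged reference-table totals
tscoex verify-fixtures
```

Run outputs: `specificity.tsv` (per-RNA score/class/tissue),
`edges.tsv` (canonical edge list), `ts_counts_per_tissue.tsv`,
`interactions_per_tissue.tsv` (em-dash for tissues where no cross-class
pair is even possible), `run_summary.json` and the resolved config.
Exit code 2 signals a validation error, 3 an I/O error.

## Library use

```python
import tscoex

matrix, truth = tscoex.generate(tscoex.GeneratorParams(seed=42))
matrix = tscoex.filter_pseudogenes(matrix)
tm = tscoex.drop_zero_median(tscoex.tissue_medians(matrix))
calls = tscoex.run_specificity(tm)
nets = tscoex.build_all_networks(matrix, calls, truth.params.tissue_names())
report = tscoex.recovery_report(calls, nets.values(), truth)
```

## Notes

- Input formats: TSV (`rna_id` + one column per sample) or GCT v1.2;
  2-column sample map; 3-column annotation (`rna_id`, `biotype`,
  `is_pseudogene`).
- The interaction reference table's printed grand total exceeds the sum
  of its own per-tissue cells by 4; `verify-fixtures` reports both values
  and flags the discrepancy as expected rather than failing.
- Correlation thresholding is strict (|r| exactly at the threshold is not
  an edge); within-class pairs can be enabled via `allowed_pairs`.
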