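# tissuerank

Tools for integrating heterogeneous microarray expression profiles into a
single compendium and ranking genes by tissue-selective expression.

The pipeline has two halves:

1. **Integration** — per-group invariant-set normalization against a
   baseline array of median overall intensity, optional model-based
   probe-set summarization with detection calls and outlier-array
   exclusion (arrays flagged in >15% of probe sets are dropped), and a
   global median transformation so every profile shares median 1.00.
2. **Selectivity ranking** — for a target tissue, samples split into an
   experiment set (Ne) and control set (Nc). A sample shows *significant
   expression* when the detection call is Present and the value is at
   least a threshold θ. Candidates need Se ≥ *min* significant experiment
   samples and at most *max* significant controls, and are ranked by

   ```
   score1 = log10(((Se + 0.1)/Ne) / ((Sc + 0.1)/Nc))
   score2 = log10(Ee / Ec)          # Ee: mean over significant experiment
   score  = w1*score1 + w2*score2   # Ec: mean of top-Se control values
   ```

   Significance comes from jointly permuting each probe set's
   (value, call) pairs across samples and counting permutations whose
   score reaches the observed one.

## CLI

```
tissuerank simulate  --seed 1 --out-dir sim            # synthetic compendium + truth
tissuerank normalize group1.tsv group2.tsv             # invariant-set normalization
tissuerank integrate --values g1.tsv --calls c1.tsv \
                     --annotations ann.tsv --out-dir comp
tissuerank rank      --values comp/values.tsv --calls comp/calls.tsv \
                     --annotations comp/annotations.tsv \
                     --tissue liver --theta 1.0 --min 23 --max 29 --out ranked.tsv
tissuerank permute   ... --n-perm 10000 --seed 1 --out ranked_p.tsv
```

`--min`/`--max` accept absolute counts or percentages of the respective
set size (`--min 20%`). All file formats are plain TSV: matrices with a
sample-id header row and probe-id first column, calls over `P`/`M`/`A`,
and annotations with columns `sample_id  tissue  group  study`.

## Layout

- `src/tissuerank/core_model.py` — domain types, TSV I/O, validation,
  tissue partitioning
- `src/tissuerank/normalization.py` — baseline selection, invariant-set
  search, monotone normalization curves
- `src/tissuerank/summarization.py` — multiplicative probe-set model,
  Wilcoxon detection calls, outlier-array flagging
- `src/tissuerank/integration.py` — median transformation and group merge
- `src/tissuerank/selectivity.py` — scoring, ranking, permutation p-values
- `src/tissuerank/synthetic_data.py` — seeded generators with ground truth
- `src/tissuerank/cli.py` — command-line entry points
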