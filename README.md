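# molenrich

Ontology-based over-representation analysis for small-molecule sets against a
ChEBI-style chemical ontology, with graph pruning of the result.

Three analysis modes:

- **plain** — a one-sided binomial tail test per ontology class hit by the
  sample, with Benjamini–Hochberg FDR correction;
- **weighted** — SaddleSum-style significance of the weight accumulated by
  each class (Lugannani–Rice saddlepoint tail on the empirical cumulant
  generating function of the submitted weight list; exact tail counts for
  classes with 1 or 2 sample members);
- **fragment** — weighted analysis restricted to the structural branch, with
  a pruning strategy that never removes terminal molecule leaves or roots.

The ontology is read from an OBO flat file (`is_a`, `has_part`, `has_role`
relations; InChI strings mark fully specified molecules). Results come back
as a ranked table and as a pruned result graph built from `is_a`/`has_part`
edges, compacted by five pruning operators (zero-degree vertex, root
children, molecule leaves, high-p-value branch, linear branch collapser)
composed into pre-loop / loop-to-fixpoint / final strategies.

## CLI

```bash
# generate a synthetic ontology + sample (no external download needed)
molenrich fixtures --classes 200 --molecules 100 --mode plain --seed 1 --out fx/

# run an analysis
molenrich run --ontology fx/ontology.obo --input fx/sample.tsv \
    --mode plain --branch all --alpha 0.05 \
    --formats tsv,graphml,sif,node_link_json --out results/

# sanity-check inputs without analysing
molenrich validate --ontology fx/ontology.obo --input fx/sample.tsv
```

`run` writes `table.tsv` (columns `class_id name k n K N p_raw p_adj
sample_pct fold`) plus the requested network files. Input samples are one
identifier per line (`1234` or `CHEBI:1234`), optionally with a
tab-separated weight in [0, 1] for weighted/fragment mode.

## Library

```python
from molenrich import parse_obo, validate_input, run_analysis, AnalysisConfig

graph = parse_obo("chebi_like.obo")
sample = validate_input(open("ids.txt").readlines())
rows, result_graph, report = run_analysis(graph, sample, AnalysisConfig(mode="plain"))
```

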