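# dreambench

A challenge-assessment toolkit for reverse-engineering contests in systems
biology: it scores ranked edge-list network predictions, withheld-measurement
predictions, rank-matrix expression predictions and measurement-to-species
assignment tables against gold standards, builds empirical null
distributions with stretched-exponential tail extrapolation, runs the
null-mutant z-score network inference baseline, aggregates many submissions
into a rank-sum consensus, and analyses community-level behaviour
(edge identifiability, systematic false positives). A small ODE-based
simulator generates all fixtures (networks, wild-type / knockdown /
knockout steady states, time courses) in the challenge file formats, so no
external data is required.

## Modules

| module                | what it does |
|-----------------------|--------------|
| `formats`             | domain types + TSV readers/writers; all validation |
| `assignment_score`    | exact enumeration scoring of assignment tables; binomial community p-values |
| `response_score`      | variance-normalized squared prediction error; column-resampling null |
| `expression_score`    | Spearman profile scoring (exact permutation null for n ≤ 9); geometric-mean summaries |
| `network_score`       | ROC / precision-recall of ranked edge lists; analytic truncated-list completion; empirical nulls |
| `null_models`         | two-sided stretched-exponential histogram fits and tail p-values |
| `zscore_inference`    | null-mutant z-score edge ranking from a knockout strain panel |
| `consensus_community` | rank-sum consensus; identifiability histograms; shortcut/co-regulation topology classification; KS and Fisher tests |
| `insilico_sim`        | seeded acyclic network generator + ODE strain/trajectory simulator |
| `cli`                 | `dream-bench` entry point wiring everything together |

## CLI

```bash
# simulate a 10-gene data bundle, infer a network, score it
dream-bench simulate --preset size10 --seed 1 --out bundle/
dream-bench infer-zscore --data bundle/ --out edges.tsv
dream-bench score-network --pred edges.tsv --gold bundle/gold_standard.tsv \
    --null-reps 100000 --seed 0 --out report.json

# other scoring modes
dream-bench score-assignment --submitted sub.tsv --gold gold.tsv
dream-bench score-expression --pred pred.tsv --gold gold.tsv
dream-bench score-response --pred pred.tsv --truth truth.tsv --train train.tsv \
    --sigma-tech 300 --cv 0.8 --null-reps 100000 --seed 0

# community analyses
dream-bench consensus --pred a.tsv --pred b.tsv --out consensus.tsv
dream-bench community --pred a.tsv --pred b.tsv --gold gold.tsv \
    --cutoff-mult 2 --top-fraction 0.01 --seed 0
dream-bench null-fit --sample metric_values.txt
```

All stochastic subcommands take `--seed` and are reproducible under it.
A YAML config mirroring every flag can be supplied with
`--config conf.yaml`. Exit codes: 0 success, 2 validation error, 64 usage
error. P-values print at two significant figures ("0*" marks values below
numeric precision); JSON reports keep full precision.

## File formats

Tab-separated UTF-8, `#` comment lines ignored:

- prediction list: `source<TAB>target[<TAB>confidence]`, one edge per line,
  ranked best first; confidences must be non-increasing,
- gold network: `source<TAB>target<TAB>1` (optional explicit `0` rows;
  a `# nodes: ...` directive preserves isolated nodes),
- measurement table: header of analyte names after the condition column;
  `NA` / `NaN` / empty cells mark withheld prediction targets,
- rank matrix: genes × time points, each column a permutation of 1..G,
- assignment table: `measurement<TAB>species`, injective.

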