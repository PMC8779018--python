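# fungirec

Post-network toolkit for citizen-science species recognition. It covers the
probability-space half of a fine-grained recognition service — everything that
happens *after* an image classifier has produced per-species posteriors:

- **Prior-shift correction** (`fungirec.prior_shift`) — re-express posteriors
  trained under one class prior under a different deployment prior (including
  the uniform-prior special case), with the ratio computed in log space.
- **Metadata fusion** (`fungirec.metadata_fusion`) — fit species-given-metadata
  frequency tables (habitat, substrate, month) from training labels and fuse
  them with image posteriors under a conditional-independence assumption;
  optional direct joint estimation for type pairs with enough support.
- **Test-time augmentation & ensembling** (`fungirec.tta`) — the 14-view crop
  scheme (full image, 80% central, 60% central + four 60% corner crops, each
  mirrored), pixel realization of fractional crops, and `sum`/`mode` pooling
  across views or ensemble members.
- **Evaluation** (`fungirec.evaluation`) — top-k accuracy, mean per-class
  accuracy, rank-share statistics, error-reduction arithmetic, and the
  per-species ⌈90%⌉ stratified split.
- **Simulator** (`fungirec.simulator`) — a fully discrete generative model
  (long-tailed species prior, per-species visual-token and metadata channels)
  whose exact Bayes posteriors are enumerable. It doubles as the test oracle:
  the prior-shift and fusion code must reproduce brute-force enumeration to
  1e-9 on it.
- **IO / pipeline / CLI** (`fungirec.io`, `fungirec.pipeline`, `fungirec.cli`)
  — CSV/JSON interchange formats and a single `fungirec` executable.

## CLI

One executable, `fungirec`, with subcommands:

```bash
fungirec adjust-priors --posteriors post.csv --train-prior train.json --uniform --out adjusted.csv
fungirec fuse-metadata --posteriors post.csv --metadata meta.csv \
    --train-labels labels.csv --types habitat,substrate,month --out fused.csv
fungirec pool --inputs view1.csv --inputs view2.csv --method sum --out pooled.csv
fungirec tta-specs --out specs.json
fungirec evaluate --posteriors post.csv --truth labels.csv --ks 1,3,5 --report report.json
fungirec split --truth labels.csv --fraction 0.9 --out-train train.csv --out-test test.csv
fungirec simulate --out-dir runs/demo
fungirec run --config pipeline.yaml       # multi-stage chain, type-checked up front
```

File formats: posterior matrices are CSV with an `observation_id` first column
and one column per species; priors are JSON species→probability maps; metadata
is CSV with `observation_id,habitat,substrate,month` (empty cell = missing).

A pipeline config is YAML/JSON:

```yaml
seed: 1
out_dir: runs/demo
stages:
  - stage: simulate
    params: {k: 50, v: 200, n: 10000, test_exponent: 0.2, which_prior: test}
  - stage: adjust-priors
  - stage: evaluate
```

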