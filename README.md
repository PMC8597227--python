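# eoesgc

Prediction of miRNA–disease associations by combining similarity-network
construction, link-based embedding on a coupled heterogeneous graph, and
simplified graph-convolution feature propagation with an MLP link scorer.

The pipeline has four stages:

1. **Similarity networks** (`eoesgc.similarity`, `eoesgc.pipeline`) — two
   ontology-DAG semantic similarity models for diseases (depth-decay and
   rarity weighting), Gaussian interaction-profile (GIP) kernels for both
   node types, miRNA functional similarity via associated-disease sets,
   convex integration (`alpha`) and hard thresholding (`h`).
2. **Coupled-graph embedding** (`eoesgc.graph`, `eoesgc.eoe`) — miRNA and
   disease similarity sub-networks joined by association edges; embeddings
   plus a harmony matrix trained with a six-term positive/negative
   log-loss (linked nodes pulled together, unlinked pushed apart).
3. **Simplified graph convolution + scorer** (`eoesgc.sgc`) — embeddings
   mapped to a shared Z-dimensional space, propagated by
   `S = D^{-1/2}(A+I)D^{-1/2}` applied `K` hops per layer with no
   inter-layer nonlinearity, then pair scoring through a two-layer MLP
   trained end-to-end on cross-entropy.
4. **Evaluation** (`eoesgc.evaluation`) — 1:`ratio` negative sampling,
   stratified k-fold cross-validation with leak-free per-fold adjacency
   masking, AUC/AUPR/F1, dimension sweeps, and per-disease top-k
   candidate ranking.

All training is plain NumPy with hand-derived gradients (checked against
finite differences in the test suite) and an Adam update, so runs are
bit-reproducible per seed. `eoesgc.synthetic` generates random
multi-rooted ontology DAGs and planted-block association matrices so the
whole pipeline is testable offline.

## CLI

```bash
# synthetic fixture bundle (presets: tiny, bench, paper-scale)
eoesgc simulate --preset tiny --seed 1 --out fixtures/

# similarity matrices (MS/DS plus intermediates)
eoesgc similarity --associations fixtures/associations.tsv \
    --ontology fixtures/ontology.tsv --disease-map fixtures/disease_map.tsv \
    --alpha 0.5 --h 0.5 --out-dir sims/

# coupled-graph embedding stage on its own
eoesgc train-eoe --graph-dir sims/ --epochs 200 --seed 1 --out eoe_state/

# full model on all data, then candidate ranking
eoesgc train --similarity-dir sims/ --seed 1 --out model/
eoesgc predict --model model/ --disease disease_0000 --top 20

# cross-validation and dimension sweep
eoesgc evaluate --similarity-dir sims/ --folds 5 --seed 1 --out report.json
eoesgc sweep --similarity-dir sims/ --dims 16,32,64 --seed 1
```

A YAML config (see `eoesgc.io.RunConfig` for the schema and defaults;
unknown keys are rejected) can be passed to `train`, `evaluate` and
`sweep` via `--config`.

### Real data

Given user-supplied associations (TSV: `mirna`, `disease`) and an
ontology (edge TSV: `child_term`, `parent_term`; mapping TSV:
`disease_name`, `term_id`), the same commands run at full scale
(≈500×400 is minutes on one CPU). No download or name normalization is
performed.

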