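# respnet

Minimum-cost-flow inference of sparse signaling/regulatory subnetworks that
connect a **source set** of proteins to a **target set** of genes, proteins or
microRNAs over a typed molecular interactome — plus construction of
tissue-specific interactomes from raw RNA-seq counts, and set algebra for
comparing predicted subnetworks across tissues or runs.

## How it works

- **Typed interactome.** Nodes are `(identifier, kind)` pairs with kind in
  `{PROTEIN, GENE, MIRNA}`; a gene and its protein product are distinct nodes.
  Edges are undirected PPIs (weight in (0,1]) or directed regulatory
  interactions (TF→gene, TF→microRNA, microRNA→gene), which default to
  weight 1. Genes are pure regulatory sinks, so any pathway reaching a gene
  target necessarily ends with a regulatory interaction.
- **Flow inference.** Each edge of weight *w* becomes an arc of unit cost
  −ln *w* (PPIs become two antiparallel arcs). A super-source feeds the
  sources, a super-sink drains the targets, and the LP minimizes total
  cost minus γ × (routed flow), solved with HiGHS via `scipy.optimize.linprog`.
  Larger γ admits more, lower-probability paths. Edges with positive optimal
  flow form the predicted subnetwork; nodes that are neither sources nor
  targets are the "connecting" predictions. Optional degree-matched
  randomizations give empirical per-node p-values.
- **Tissue interactomes.** Raw counts are prefiltered (> 5 reads in ≥ 10
  samples), TMM-normalized to cpm (edgeR-compatible: upper-quartile reference,
  doubly trimmed inverse-variance-weighted mean of log-ratios), and genes are
  called expressed per tissue (cpm ≥ 8 in ≥ 10 samples, median cpm ≥ 8). A
  PPI survives in a tissue iff both partners are expressed; microRNA and
  regulatory edges are never filtered.
- **Layers.** Subnetworks can be combined with union / intersection /
  difference / XOR at edge granularity, with per-layer flow values kept side
  by side.
- **Synthetic benchmarks.** `respnet.synth` generates interactomes with
  planted high-weight pathways among noise PPIs, and GTEx-like
  negative-binomial count matrices with known per-tissue expressed sets, so
  the whole pipeline is testable offline.

## CLI

```sh
# synthetic fixtures
respnet synth net --seed 7 --out demo/net
respnet synth counts --seed 7 --out demo/cnt

# merge / validate / annotate interaction tables
respnet interactome merge --in a.tsv --in b.tsv --out merged.tsv
respnet interactome validate --in merged.tsv
respnet interactome annotate --in merged.tsv --annotations ann.tsv --out net.json

# tissue-specific interactome from counts
respnet tissue build --counts demo/cnt/counts.tsv --tissues demo/cnt/tissues.tsv \
    --global-net merged.tsv --tissue-name tissueA --out tissueA.tsv

# flow inference
respnet run --net demo/net/net.tsv --sources demo/net/sources.txt \
    --targets demo/net/targets.txt --gamma 10 --out sub.tsv --json sub.json \
    --randomizations 100 --seed 1

# compare subnetworks
respnet layers combine --a subA.json --b subB.json --op xor --out cmp.json
```

Exit codes: 0 success, 2 usage, 3 validation/format error, 4 solver failure.

### File formats (all plain TSV/JSON)

- Interaction table: header `a_id a_kind b_id b_kind etype weight`
  (optional `provenance`); blank regulatory weights fill to 1.0; duplicate
  edges keep the maximum weight.
- Counts: first column `gene_id`, one column per sample; separate two-column
  sample→tissue TSV.
- Node sets: one id per line, optional tab-separated weight.
- Annotations: `node_id field value` with field in
  `disease | drug_target | variability` (variability in [0,100]).
- Subnetwork JSON embeds the full config snapshot (γ, ε, solver, build tag)
  needed to regenerate the run; the TSV adds `flow` and endpoint-role columns.

## Notes & caveats

- Identifiers are taken verbatim; ID conversion/mapping is out of scope.
- PPI reliability weights are expected as input; `logistic_weight` offers a
  documented non-canonical fallback from publication counts.
- Tie-breaking between equal-cost LP optima is solver-dependent; runs are
  deterministic per solver build (solver name recorded in output config).
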