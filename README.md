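# coexshift

Differential coexpression analysis across a two-condition boundary (e.g.
prenatal vs. postnatal development): module detection on the adjacency
*difference* network, permutation significance of module rewiring,
module-wise gene-set enrichment with resampling nulls, and
condition-specific network edge extraction — plus a synthetic-data
generator that plants known rewired modules so every stage can be validated
against ground truth.

## What it does

Given a genes × samples expression TSV and sample metadata (region, age,
window ∈ {prenatal, postnatal}):

1. **profiles** — gene-variance filter, PCA with Kruskal–Wallis factor
   association, per-(region, window) average expression profiles, and
   average-linkage clustering of the 1 − R profile distances.
2. **structure** — one gene–gene Pearson matrix per (region, window)
   stratum, entry-wise 1 − R comparison of whole coexpression matrices,
   UPGMA clustering and top-split extraction.
3. **diffcoex** — per-window correlation matrices; adjacency difference
   `d = (½·|sign(c₁)c₁² − sign(c₂)c₂²|)^(β/2)` with β = 6; scale-free fit
   index; topological overlap; adaptive tree cut (minimum module size 100);
   eigengene merging at r > 0.9; per-module change in average correlation
   with a 1000-permutation label-shuffling significance test.
4. **enrich** — Z-score term enrichment against 10 000 equally-sized random
   gene samples (BH FDR < 0.05 and observed − expected > 1), hypergeometric
   alternative, TF-motif exclusivity permutation test, overlap counts, and
   a Welch-t differential-expression screen with targeted term queries.
5. **rewire** — classify module gene pairs at |window-specific| R > 0.95
   into prenatal-only / postnatal-only / constant edges, per-condition
   degree summaries, GraphML/TSV export.

## CLI

```bash
# generate a synthetic dataset with planted gain/loss/swap modules
coexshift simulate --config sim.yaml --seed 1 --out data/

# run everything (flags override config values)
coexshift all --expression data/expression.tsv --metadata data/metadata.tsv \
    --go-gmt data/annotations.gmt --tf-gmt data/annotations.gmt \
    --out results/ --seed 1
```

Subcommands `profiles`, `structure`, `diffcoex`, `enrich`, `rewire` run
individual stages.  A YAML config (`coexshift all --config run.yaml`) may set
any `RunConfig` field; defaults are the study parameters (β = 6, minimum
module size 100, merge r = 0.9, edge threshold 0.95, 1000/10 000/10 000
permutations, α = 0.05).  Every run writes a `manifest.json` with parameter
values, library versions and SHA-256 checksums of all outputs; reruns with
the same seed are byte-identical.

## Acceptance

Acceptance is property-based (exact oracle equivalence of the numerical
primitives, planted-module recovery, null calibration, structure-split
recovery, exclusivity separation, enrichment-null convergence) and lives in
`tests/test_acceptance.py`.  The report script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs a seeded end-to-end smoke and writes the (empty) target report.

## Layout

- `src/coexshift/io.py` — expression/metadata/GMT I/O, variance filter, sample splits
- `src/coexshift/simulate.py` — latent-factor generator with planted rewiring + annotations
- `src/coexshift/compare.py` — PCA, Kruskal–Wallis, profile/structure clustering
- `src/coexshift/diffcoex.py` — adjacency difference, TOM, tree cut, eigengenes, permutation tests
- `src/coexshift/enrich.py` — Z-score/hypergeometric enrichment, exclusivity, DE
- `src/coexshift/graph.py` — condition-specific edge classification and export
- `src/coexshift/pipeline.py`, `src/coexshift/cli.py` — orchestration and CLI
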