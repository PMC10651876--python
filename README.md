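# heptadnet

Regulatory-architecture analysis for sorted human hematopoietic stem and
progenitor cell (HSPC) subsets. Blood stem cells are governed by a heptad of
transcription factors — FLI1, ERG, GATA2, RUNX1, TAL1, LYL1, LMO2 — that bind
regulatory elements combinatorially, and the specific factor combinations,
promoter–enhancer loops, and DNA motif grammars differ between stem
(HSC-MPP), common myeloid (CMP), granulocyte–macrophage (GMP) and
megakaryocyte–erythroid (MEP) progenitors. `heptadnet` packages that analysis
as a tested, reusable pipeline for anyone working with per-factor ChIP peak
calls, HiChIP loop calls, ATAC regions and signal tracks:

- **Combinatorial co-occupancy** — merge all factors' peaks of a cell type
  into a region universe, assign each region its *exact* bound factor subset
  S, and score every subset against a genome-randomization null:
  z(S) = (obs(S) − μ₀(S)) / σ₀(S), where μ₀, σ₀ come from re-placing every
  peak uniformly on its own chromosome (length preserved) over N seeded
  randomizations.
- **Promoter–enhancer networks** — filter loops at FDR ≤ 0.01, classify
  anchors as promoter (strand-oriented TSS window) or enhancer, gate
  P–E loops on accessible chromatin at the distal anchor, and name elements
  by their kb offset from the TSS along the direction of transcription
  (e.g. `ERG+85`). Regions link to genes directly (10 kb promoter window) or
  indirectly via significant loops.
- **Chromatin landscape** — mean per-bp signal matrices over accessible
  regions, kNN-graph Louvain clustering with a 2D embedding, pairwise
  log2 fold-change overlays, k-means promoter/enhancer profiles, and a
  moderated-t differential-enrichment stage producing DEH
  (differentially-enriched-for-heptad) region sets.
- **Motif-grammar classification** — per-region consensus-motif counts
  (min–max normalized to [0, 1]), one gradient-boosted binary classifier per
  cell type vs background, held-out ROC/AUROC, and exact additive (TreeSHAP)
  per-motif attribution; trained models score external region cohorts.
- **Synthetic studies with ground truth** — a generator that emulates the
  shape of such a study (genome, genes, planted factor combinations, loops,
  signal archetypes, motif grammars) so every stage is testable offline,
  plus dedicated calibration scenarios.

## Worked example

Simulate a small study and score factor combinations in MEP:

```bash
heptadnet simulate --config sim_small.yaml --out demo_bundle --seed 7
# wrote bundle to demo_bundle (155 truth regions)

heptadnet cobind --peaks-manifest manifest.tsv \
    --chrom-sizes demo_bundle/genome.chrom.sizes \
    --cell-type MEP --n-rand 1000 --seed 7 --out cobind.MEP.tsv
```

which prints the five most significant multi-factor combinations:

```
                             subset  size  observed  null_mean  null_sd        z
               GATA2+LYL1+TAL1+LMO2     4        25      0.000 0.000000      inf
ERG+GATA2+LYL1+RUNX1+TAL1+LMO2+FLI1     7        20      0.000 0.000000      inf
                          ERG+RUNX1     2         1      0.710 0.831018 0.348970
                         RUNX1+FLI1     2         1      0.714 0.876911 0.326145
                           ERG+LYL1     2         1      0.861 0.920068 0.151076
```

Reading this: the generator planted 25 MEP-specific regions bound by the
GATA2+TAL1+LYL1+LMO2 combination and 20 core regions bound by all seven
factors. Both combinations are recovered exactly, and since uniform random
placement essentially never stacks four or seven distinct factors on one
region, their null spread is zero — an infinite-z sentinel meaning
"never seen under the null". Incidental pairwise overlaps (`ERG+RUNX1`, …)
sit within the null's reach (z ≈ 0.3), exactly as they should.

The one-command end-to-end run — simulate, then every stage, then assert
that all planted structure is recovered:

```bash
heptadnet demo --out demo_run --seed 7
# conservation: ok        planted_cobinding: ok   planted_recovery: ok
# null_calibration: ok    loop_recovery: ok       deh: ok
# landscape: ok           select_specific: ok     classifier: ok
```

Other subcommands: `annotate-peaks`, `build-network`, `landscape`, `deh`,
`select-specific`, `pe-profiles`, `motif-model train|attribute|score`, and
`run` (whole pipeline from one YAML config, with a reproducibility
manifest).

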