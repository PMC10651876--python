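# Methods

This note documents the models and procedures implemented in `heptadnet`,
the parameter defaults and why they were chosen, the numerical conventions,
and what the synthetic-data generator does and does not emulate.

## Coordinates and the interval engine

All coordinates are 0-based half-open (BED convention); GTF input is
converted on read. Overlap tests are strictly half-open — intervals sharing
only a boundary do not overlap — and default to a 1 bp minimum intersection
(`min_bp`), the weakest defensible criterion; it is configurable everywhere
because published peak-intersection analyses rarely state theirs. Merging,
by contrast, joins book-ended intervals: merged regions are maximal
contiguous coverage runs (the `bedtools merge` convention), which keeps the
region universe identical to what a per-base coverage bitmap would produce.
Strand is metadata only; it affects TSS placement and element naming, never
interval arithmetic, since ChIP/ATAC peaks are unstranded.

The engine is a single lexsort, a running-maximum sweep to find region
breaks, and `bitwise_or.reduceat` to accumulate per-region factor sets. This
is what makes the randomization null affordable: one merge+assign pass over
~14,000 peaks costs ~2 ms, so 1,000 genome randomizations run in seconds on
one CPU.

## Combinatorial co-occupancy

For one cell type, the universe is the merge of all factors' peaks; each
region is assigned the **exact** subset of factors with an overlapping peak
(exclusive counting — a partition, so subset counts always sum to the
universe size). Exclusive counting is the convention under which the
full-factor combination can dominate while individual pairs stay modest; an
inclusive mode (each region counted for every sub-combination of its bound
set, computed by a superset-sum transform) is available behind a flag.

The null re-places every peak independently and uniformly on its own
chromosome with its length preserved; factors are shuffled independently
and shuffled peaks may overlap. z(S) = (obs − mean)/sd with the sample sd
over `n_randomizations` (default 1,000) iterations. A circular-shift mode
(one offset per factor per chromosome, preserving intra-factor spacing) is
the alternative null. Degenerate cases: sd = 0 with obs = mean gives z = 0;
sd = 0 with obs ≠ mean gives a signed infinite sentinel with a warning —
"never seen under the null". Calibration summaries are computed over
subsets with finite defined z. On uniform-random input the multi-factor
z-scores are centered (|mean| ≤ 0.2) with unit-scale spread, which is the
Monte-Carlo sanity check shipped in the test suite.

Single-factor regions (exact assignment = one factor) are retained and
flagged; they feed the cross-cell-type priming analysis. Adding PU.1 or any
eighth factor is the same computation with another label.

## Promoter–enhancer networks

Loops are kept at q ≤ `fdr_max` (default 0.01, boundary inclusive as
printed in loop-caller output). An anchor is a promoter anchor iff it
overlaps the strand-oriented window 10 kb upstream to 2 kb downstream of
any TSS; 10 kb matches the gene-linking window used throughout, 2 kb is the
conventional downstream bound (both configurable). P–E loops record the
distal anchor and are gated on ≥ 1 accessible (ATAC) interval there.
Anchors overlapping two genes' promoter windows link to both — no
nearest-gene tie-break; deduplication is the caller's concern.

Element ids are `GENE±kb`: the signed distance from element midpoint to
TSS, in kb rounded half away from zero, oriented so downstream of
transcription is positive (strand flip negates the sign). Sub-kb precision
(`TAL1+0.5`) is opt-in.

Per-gene networks collect the promoter window, distal anchors of gated P–E
loops in any cell type, and anchors reachable from those by one E–E loop
(depth 1, flagged indirect — deeper enhancer-community closure is left to
the caller because published analyses rarely state a closure depth). Each
element carries, per cell type, the number of factors with an overlapping
peak and whether it loops directly to the promoter — the inputs of the
standard dot-plot summary.

Region→gene linking: direct iff the region overlaps the promoter window;
indirect iff it overlaps one anchor of a significant loop whose other
anchor overlaps a promoter window; unlinked regions are reported.

## Chromatin landscape

Signal matrices hold mean per-bp coverage per region per (track, cell)
pair, computed by exact step-function integration of bedGraph input;
uncovered positions count as zero. Log normalization is log2(x+1).

Clustering builds a symmetrized kNN graph (Euclidean, k = 15) on the
log-normalized matrix and runs Louvain community detection. The default
resolution is 0.5: Louvain can never merge disconnected kNN components at
any resolution, but at resolution 1 it tends to subdivide large homogeneous
components (the modularity resolution limit), so the default targets the
coarse signal-archetype structure this stage is used for; raise it for
finer substructure. The 2D embedding (PCA by default, UMAP on request) is
visualization-only — no downstream logic reads it. Labels are deterministic
given the seed (igraph draws from Python's seeded RNG).

Pairwise log2 fold changes use a pseudocount (default 1) on raw coverage
and are exactly antisymmetric in the two cell types.

Cell-type-specific region selection requires accessibility LFC ≥ `lfc_min`
(default 1.0) against **every** other cell type and ≥
`occupancy_min_factors` (default 2) factors with a peak in the target cell
type. Neither threshold has a canonical published value; both are flags and
the selection returns a per-region justification table.

### Differential enrichment (DEH stand-in)

The differential stage is a deliberately simple, fully documented stand-in
for a dedicated differential-binding package; externally computed DEH BED
files can be supplied to bypass it. Per candidate region (pre-filtered to
≥ 2 bound factors), summed factor signal is compared between two cell types
across replicate tracks with a **moderated t-test** on log2(x+1) signal:
per-region pooled variances are shrunk toward an inverse-chi-square prior
fitted by the standard method of moments on log variances, and the
statistic is referred to a t distribution with the combined degrees of
freedom. This empirical-Bayes treatment is what the field's
differential-binding tools do internally at small replicate counts; with 3
replicates per group a plain Welch t (df ≈ 4) or a rank-sum test (minimum
two-sided p = 0.1 at 3 vs 3) cannot clear FDR control at realistic region
counts. Mann–Whitney and plain Welch remain as options, and with a single
replicate per group the fallback is a robust z on the log2 difference
(centered by the median, scaled by 1.4826·MAD across regions).
Benjamini–Hochberg adjustment, keep at adjusted p < 0.05, direction
recorded. On null simulations (3 replicates, 2,000 regions) the fraction of
regions called is ≈ 0; on 4-fold planted enrichment power is ≈ 0.9.

k-means promoter–enhancer profiles concatenate the promoter and enhancer
signal vectors per pair; k = 4 by default (the standard C1–C4 reading:
promoter-enriched / enhancer-enriched / both / neither), k-means++
initialization, 10 restarts, labels renumbered by decreasing promoter-mean
signal so C1 is always the promoter-enriched profile.

## Motif-grammar classification

Features are double-strand IUPAC consensus-motif counts per region
(overlapping matches all counted; coincident forward/reverse hits
deduplicated; N in the sequence never matches), min–max normalized to
[0, 1] per motif. Normalization constants are frozen at training time and
reused — with clipping to [0, 1] — when scoring new regions; constant
columns map to 0. The default library is the four core consensi (ETS GGAA,
GATA GATA, E-box CANNTG, RUNX TGTGGT — the canonical RUNX core, since the
relevant publications name the motif without printing a string) plus
extended consensi and decoys; any external name/consensus list is accepted.
Consensus matching, not PWM scanning, is implemented and labeled as such.

One binary gradient-boosted model per cell type (target vs background)
rather than one multiclass model, matching how per-cell-type ROC panels are
reported. Background regions are accessible regions not in any cell-type-
specific set, sampled 1:1 with positives. Defaults: depth 4, 200 rounds,
learning rate 0.1, early stopping on an internal validation fold,
histogram trees on one thread — deterministic given the seed. Performance
is held-out ROC/AUROC on a stratified split (default 25 % test).

Attribution uses the exact tree-path additive decomposition (TreeSHAP) as
implemented by XGBoost's `pred_contribs`: per region, per-motif
contributions plus the base value equal the model margin to 1e-6. Motifs
are ranked by mean |contribution|. Cohort scoring featurizes new regions
with the stored constants and reports per-region probabilities under each
cell-type model; the cohort call is the model with the highest median
probability. One caveat shipped as a design rule: when one library motif
nests inside another (GATA inside AGATAA), their counts are strongly
correlated and attribution spreads across both; the separable-grammar
reference scenario therefore uses a non-nested library.

## Synthetic data: what it emulates, and what it does not

The generator emits a complete study bundle — FASTA genome, chrom.sizes,
GTF gene models, per-factor×cell-type narrowPeak files, per-cell ATAC BED,
FDR-annotated BEDPE loops, bedGraph signal tracks, replicate tracks for the
differential stage — plus a TruthTable of everything planted. Reference
conditions (defaults, chosen once as a desk-scale emulation of a sorted-
HSPC study):

- genome: 2 chromosomes × 10 Mb, i.i.d. uniform ACGT; 40 genes.
- 80 **core** regions bound by all seven factors in every cell type, plus
  cell-type-specific regions with lineage-flavoured subsets (150 stem-like
  ERG/FLI1/RUNX1 regions in HSC-MPP, 100 CMP, 150 GMP, 150 MEP with
  GATA2/TAL1/LYL1/LMO2) — mirroring the qualitative structure of heptad
  occupancy across the differentiation axis.
- peaks: width ~N(400, 80²) bp, jittered ±20 %, centered near the region
  midpoint; 300 uniform background peaks per factor per cell type.
- loops: 5 kb anchors (HiChIP-bin-like) from element midpoint to nearest
  TSS with probability 0.8; planted q ~ U(10⁻⁶, 0.005), decoy q ~
  U(0.05, 1) — well separated from the 0.01 threshold. Planted regions stay
  ≥ 15 kb from any TSS so distal anchors cannot straddle promoter windows.
- signal: multiplicative log-normal noise (σ = 0.4) on a unit baseline,
  archetype amplitudes 3–8× for active/bivalent promoter, CTCF and
  enhancer classes; replicate tracks of summed factor signal for the
  differential stage.
- motif grammars per cell type (planted by substitution on a random
  strand), mixing a rare 6-mer with a common short motif so bundle
  classifiers are strong but not trivially perfect.
- determinism: one RNG stream per output concern derived from the master
  seed, so the same seed yields byte-identical files and adding one output
  never perturbs the others.

Not modelled: reads, fragment-length and GC effects, mappability, chromatin
contact matrices, realistic genomic sequence composition, or inter-factor
signal correlation beyond the planted structure. Recovery rates on this
generator therefore demonstrate algorithmic correctness and calibration,
not expected performance on real libraries. Effect sizes are documented
choices, not calibrated to any deposited dataset.

Scaled scenarios used by the tests and the acceptance script (problem
sizes chosen as the package's reference conditions): 500 random instances
for interval-oracle agreement; 7 × 2,000 uniform peaks on 10 Mb with 1,000
randomizations for null calibration; 200 planted full-complement regions
for co-binding recovery; 2,000 regions × 3 replicates for differential
error/power; 5,000 regions × 4 archetypes for clustering; 1,000 + 1,000
sequences for the separable-grammar classifier.

## Known limitations

- The randomization null is uniform within chromosomes; it is not matched
  for GC, accessibility or distance-to-TSS, so absolute z magnitudes are
  not comparable across datasets with different region composition.
- Exclusive subset counts are sensitive to peak-calling stringency: a
  missed peak moves a region to a smaller subset rather than removing it.
- The moderated-t differential stage assumes roughly homoscedastic
  log-signal noise across regions; strong mean–variance trends would call
  for a count-model treatment.
- Attribution is computed per model; contributions are not comparable in
  scale across cell-type models with different class balance.
- E–E network expansion stops at depth 1; enhancer communities beyond that
  are reported only through the loops themselves.
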