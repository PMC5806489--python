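# Methods

## The valley model

A DNA methylation valley (DMV) is operationalized, as in the mouse-tissue
methylome literature, by a two-stage scan over a binned methylome:

1. **Binning.** Per-CpG calls (methylated count m, total count t per site,
   strand-merged) are aggregated into fixed 1-kb bins. A bin's methylation
   is Σm / Σt over its CpGs — the coverage-weighted "methylated CpG versus
   total CpG" estimator, not the mean of per-site ratios (a flag switches
   to the unweighted form for sensitivity analyses). Bins with no CpG or
   with Σt < 5 are *missing*; the ≥ 5 summed-coverage filter is stated in
   the source protocol for its 200-bp QC bins and is applied here to the
   1-kb caller track as well, so single poorly covered CpGs cannot seed
   valleys.
2. **Scan and merge.** A 5-kb window slides in 1-kb steps (window and step
   must be bin multiples). A window *qualifies* when it has ≥ 3 of 5
   covered bins and the unweighted mean of its covered bin values is
   strictly < 0.15. Overlapping and book-ended qualifying windows merge;
   each valley runs from the start of its first qualifying window to the
   end of its last, so every call is ≥ 5 kb by construction. Windows with
   fewer covered bins are skipped — they neither qualify nor split a
   valley — which is this package's resolution of the protocol's silence
   on missing data: CpG deserts are tolerated inside a valley but cannot
   create one. Chromosome tails shorter than one window are never scanned.
   Whether the original merge accepted book-ended windows is unstated
   upstream; both behaviours exist behind `merge_bookended` (default: on).

The reported per-valley mean methylation is coverage-weighted over the
valley's covered bins.

## Classification

Tissue-specific differentially methylated regions (tsDMRs) are an input,
pre-filtered to length strictly > 2 kb. A valley is **dynamic** iff it
fully contains a tsDMR or > 50% of its bp is covered by the (union-merged)
tsDMR set; both cutoffs are read as strict inequalities. Non-dynamic
valleys are **group I**.

Per-lineage summaries use unweighted means over a lineage's samples
(expression) and coverage-weighted means over a valley's CpGs
(methylation). A gene is **dynamically expressed** when its peak lineage
FPKM ≥ 2, the mean of the remaining lineages is ≤ 2 and the peak is ≥ 3×
that mean. Genes are attached to valleys by TSS-in-valley (`max_dist=0`
default — valleys are promoter-anchored); the boundary is half-open, so a
TSS at the valley end coordinate is outside.

For a dynamic valley with a dynamic gene, the Pearson correlation r between
the four lineage methylation means and the four lineage FPKM means decides:
r < 0 → **group II**, r > 0 → **group III**. With n = 4 points only the
sign is meaningful; |r| is reported as evidence and no p-value is computed.
Dynamic valleys with no dynamic gene, an undefined or zero r, or
conflicting top genes stay **dynamic-unassigned** rather than being forced
into II/III — the upstream protocol's group counts imply such valleys were
folded somewhere unstated, and an explicit label is the honest option.
When several associated genes are dynamic, the gene with the largest |r|
decides; if the largest |r| is tied the valley is assigned only when the
tied correlations agree in sign (a same-sign tie yields the same label
either way), otherwise it is unassigned.

## Annotation and quantification

- **Chromatin state** is any-overlap (≥ 1 bp) with H3K4me3 / H3K27me3
  peaks: {K4-only, K27-only, K4+K27, none}; overlap with an EED (PRC2)
  peak flags a valley as Polycomb-bound.
- **KO − WT change.** Each region is partitioned into CGI and non-CGI
  parts (the parts tile the region exactly; the CGI set is union-merged
  first). Δm = m(KO) − m(WT) is computed coverage-weighted on the whole
  region and on each part; a region is *hypermethylated* when
  Δm ≥ 0.1. The 0.1 cutoff is this package's default — the source reports
  "shows hypermethylation" without a numeric threshold — and is a plain
  keyword argument.
- **Meta-profiles.** Region bodies are rescaled to 20 bins; flanks are
  absolute-bp bins (default 20 kb in 1-kb bins), since valleys have
  heterogeneous lengths. A site's position is its interval midpoint, and
  density is sites per kb averaged over regions. The flank size and body
  bin count are explicit configuration, not a claim about any published
  profile.
- **Random controls.** For each draw every region length is placed
  uniformly on the genome — chromosome chosen proportionally to the number
  of valid start positions — with rejection sampling against an optional
  exclusion set. The control length multiset equals the region lengths and
  everything is reproducible from the seed. The enrichment p-value is
  (1 + #{controls ≥ observed}) / (1 + n): add-one smoothed, never
  anti-conservative, in (0, 1].
- **Stratified score comparison** pools the two region sets, cuts the
  pooled CG-density distribution into quantile strata, and reports
  n/median/quartiles per stratum and set; empty strata are reported with
  n = 0.
- **Normalization.** RPKM = count / ((width/1000)·(total/10⁶)). The
  genome-wide Z-score uses the *population* SD (divide by n; the upstream
  text does not specify) over covered bins by default, all bins by flag.
  Quantile normalization maps each column onto the mean sorted profile,
  averaging the reference over tied ranks, then log2(x + 1).

## The synthetic world

The generator emulates the structure the analysis assumes, not real
sequence. Defaults (all in `SimulationConfig`, units in bp/FPKM):

| parameter | default | rationale |
| --- | --- | --- |
| genome | 2 × 5 Mb | large enough for ~50 valleys plus background at desk scale |
| valleys | 50, lengths 5–40 kb on the 1-kb grid, ≥ 10 kb apart | the observed valley length range; grid alignment makes recovery tests measure the caller, not sub-bin placement; separation ≥ one window keeps valleys resolvable |
| group proportions | 0.70 / 0.20 / 0.10 | mirrors the strong predominance of constant valleys upstream (1580/132/34 rescaled to desk size) |
| background methylation | Beta(8, 2) per site (mean 0.8) | typical somatic genome-wide level with realistic site scatter |
| valley / CGI methylation | 0.05 / 0.02 | deep hypomethylation; islands slightly lower |
| dynamic high level | 0.35 | the "methylated" state of tsDMR blocks in non-peak lineages — far enough from 0.05 for a clean correlation sign, low enough to stay biologically valley-like |
| CpG spacing | geometric, mean 100 (12 in islands) | ~1 CpG/100 bp genome average; ~8× island densification |
| coverage | Poisson(30) per site per lineage; zero-coverage sites dropped | a standard deep WGBS depth; dropping empty sites creates the missing-bin cases the caller must handle |
| lineages | blood, endoderm, mesoderm, ectoderm; 2 samples each | the four-lineage design of the tissue panel |
| dynamic genes | peak FPKM U(6, 30), others U(0, 1.5); constant genes flat U(0.5, 4); log-normal σ = 0.1 sample noise | dynamic genes satisfy the expression rule by construction with margin; flat genes always violate it |
| KO gain | +0.3 on non-CGI parts of group I/III valleys | a strong Polycomb-loss effect, clearly above the 0.1 call threshold |
| TF sites | 2·10⁻⁴/bp background, 3× inside valleys | detectable but not overwhelming enrichment |

Each valley carries a CpG island near its 5′ end (≈ 15% of its length,
500–2000 bp) and — if dynamic — a tsDMR spanning from 35% of its length to
200 bp before its end: always fully contained, always > 2 kb, covering
> half the valley. Dynamic methylation applies to tsDMR CpGs outside the
island; islands stay at 0.02 everywhere, which is what confines the KO
gain and the lineage dynamics to non-CGI parts. Group II valleys are
unmethylated in the lineage where their gene peaks and at 0.35 elsewhere;
group III is the mirror image. Decoy tsDMRs (outside valleys, plus short
< 2 kb fragments) ensure the dynamic rule is doing real work.

Randomness comes from one root seed split into fixed named substreams
(layout, CpGs, methylation, per-lineage coverage, expression, KO,
features), so regenerating one component never shifts another.

**What a green test does not establish.** The generator has no sequence
composition, no bisulfite conversion error, no mapping bias, no copy-number
or batch structure, and its valleys have sharp grid-aligned edges; recovery
and accuracy numbers on it bound the *algorithmic* behaviour of the
pipeline, not its performance on real methylomes.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere internally; the Bismark-style
  CpG report reader treats input positions as 1-based (flag-controlled) and
  folds minus-strand G counts onto the plus-strand C.
- Strict `< 0.15` taken literally; the caller and its enumeration oracle
  compute window means with the same summation so threshold ties cannot
  diverge.
- Missing means are NaN and propagate explicitly: an uncovered region in
  the KO analysis is reported NaN and logged, never silently dropped.
- Empty inputs are legal throughout: a `max_meth=0` pipeline run succeeds
  with empty tables.
- Constant vectors make the correlation undefined (flagged NaN, valley
  unassigned) rather than ±1; a constant signal track makes the Z-score an
  error.

## Known limitations

- The caller is a thresholded scan, by design; no HMM/changepoint
  segmentation and no alternative "canyon" definitions.
- tsDMRs and super-enhancers are inputs, never called.
- Non-CpG (CHH/CHG) contexts, smoothing and imputation are out of scope.
- The meta-profile clips nothing at chromosome ends; flank bins that fall
  off the genome simply count zero sites, which slightly deflates flank
  densities for regions within one flank of an end.
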