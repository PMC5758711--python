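# Methods

## Coordinate and calling conventions

All genomic intervals are 0-based, half-open. A region's anchor is its
centre, `floor((start + end) / 2)`, which is deterministic for odd widths.
Two intervals overlap when they share at least one base pair
(`a.end > b.start and b.end > a.start`).

Differential-expression calls use a single log2 threshold (default 0.5)
with **strict** inequalities: a contrast of exactly ±0.5 is *unchanged*.
Knockdown sensitivity applies the same magnitude threshold to the
`stim_sirna − stim_mock` contrast in the direction opposing the
stimulation change. An alternative interpretation — requiring the
knockdown arm to return to within the threshold of the mock baseline —
is available as `mode="toward_baseline"`; the fixed-magnitude opposing
shift is the default because it reuses the screen's only stated
threshold without introducing a second convention. The CSC/NCSC
compartment call reuses the same threshold on `csc_log2 − ncsc_log2`;
it is a parameter, not a separate constant.

Reversibility percentages are rounded half-up to one decimal using exact
decimal arithmetic (so 1459/3502 → 41.7%, 790/3351 → 23.6%); a direction
with zero probes reports NaN rather than 0.

## Region annotation

* **Tag filter.** Regions need ≥ 12.2 normalized reads (inclusive), on a
  reads-per-10-million scale; the value is a plain parameter.
* **Nearest TSS.** Same-chromosome only; cross-chromosome distance is
  undefined and regions on gene-free chromosomes carry the sentinel
  `no_gene`, excluded from distance statistics. Distance ties break to
  the lexicographically smallest gene id, which makes the assignment a
  pure function of the inputs. Signed distance is negative when the
  centre lies upstream of the TSS *on the gene's strand*.
* **Features.** The promoter window is symmetric and strict
  (centre < 1 kb from a TSS) and outranks any overlapping track feature;
  remaining labels are resolved by the fixed priority
  5utr > 3utr > exon > intron > tts > ncRNA > pseudo > rRNA, defaulting
  to intergenic. The feature track is a typed BED; gene-model
  construction from GTF is out of scope.
* **Chromatin states.** Maximal base-pair overlap wins; exact ties go to
  the leftmost segment; overlapping segments in the input are rejected.
* **Metaprofiles.** Strand-oriented windows of ±1500 bp around each TSS,
  100 bp bins (30 bins), per-base coverage summed per bin, averaged over
  genes. Minus-strand windows are reversed so bin 0 is always the most
  upstream. Windows leaving the chromosome are skipped with a warning.

## Target classification and exact tests

A gene is a **direct** target iff it is knockdown-sensitive and its
minimal centre-to-TSS distance is ≤ 5000 bp (inclusive); sensitive genes
without such a region are **indirect**; insensitive genes are
**untargeted**. The three classes partition the gene universe.

`fisher_exact_2x2` implements the conventional two-sided test: the sum
of hypergeometric point probabilities (same margins) not exceeding the
observed table's probability, with a 1e-7 relative tolerance on the
comparison to absorb floating ties. It is computed in exact integer /
rational arithmetic and only converted to float at the end; a zero
margin returns p = 1 by convention with a warning. Gene-set enrichment
is the upper-tail hypergeometric `P[X ≥ overlap]`; Benjamini–Hochberg
adjusted values are reported *alongside* raw p-values, never substituted
for them.

## Co-binding

Chains of transitively overlapping regions (from either factor) merge
into one region spanning their union; the standardized window is exactly
`width` bp (default 300) centred on the floor of the merged midpoint,
clipped at zero with a warning if necessary. Tag counting over the
window either apportions region tag counts by base-pair overlap fraction
(deterministic and conservative) or sums a coverage track. Correlation
is the plain Pearson product-moment on untransformed counts within the
standardized windows (original merged spans available behind
`use_standardized=False`); fewer than 3 regions or a constant vector
yields an undefined marker, never 0.

## Signal metrics

Peptide-array positives are signals ≥ mean + k·SD (k = 2) where mean and
SD are taken over **all** peptides on the array; SD is the population SD
(divide by n), with the sample-SD alternative behind a flag — the
positivity rule's source does not specify which. A zero-dispersion array
calls nothing positive and sets a degenerate flag. TNFI/TCFI is the
masked intensity sum minus a supplied scalar background times mask area;
the background estimate is produced upstream (the synthetic generator
uses the constant level outside the cell mask). No default kinase
consensus motif is shipped: motif patterns are user-supplied in a small
DSL (`[ST]x[KR]`: character classes, `x` wildcard). Phenotype
partitioning puts boundary values in the moderate band: 1 iff value >
hi, 3 iff value < lo, else 2; the package exposes the circulating-tumour-
cell thresholds (1100/500 for the phospho-form, 1500/600 for the total
protein) as named constants.

## Synthetic study design

One root seed feeds named substreams (genome, expression, peaks, states,
peptides, images), so adding a generator never perturbs another's draws
and identical config + seed reproduces byte-identical outputs.

Defaults emulate the statistical structure of the real study at a
desk-scale problem size of 1000 genes on two 2 Mb chromosomes (chosen to
keep the default suite fast while leaving hundreds of genes per class):

* 18% of genes induced, 17% repressed on stimulation; 41.7% of induced
  and 23.6% of repressed genes knockdown-sensitive — the study's
  reported reversibility rates used as planting probabilities.
* log2 effects ~ Normal(2.0, 0.3), per-arm Gaussian noise SD 0.1. The
  source study reports no effect-size distribution, so these are tunable
  defaults, not calibrated to the deposited data; effect 2.0 with noise
  0.1 gives near-perfect separation at the 0.5 threshold, which is the
  intended regime for recovery tests.
* 600 factor-A peaks of 300 bp; 60% placed Normal(0, 500 bp) around the
  TSSs of a sampled half of the sensitive genes, the rest uniform. A 5%
  fraction of the uniform peaks are sub-threshold decoys with tags drawn
  strictly below 12.2 (real peaks are at/above 13), exercising the tag
  filter without ambiguity. Planted *direct* flags are recorded from the
  realized placement: sensitive genes whose minimal kept-peak distance
  is ≤ 5 kb — so background peaks landing near a sensitive TSS are part
  of the truth, and the zero-noise pipeline must recover the set exactly.
* Factor-B peaks co-bind factor A with probability 0.6 at promoter-
  proximal peaks and 0.05 elsewhere; co-bound tag pairs draw from a
  bivariate normal whose correlation rises from 0.05 (distal) through
  0.35 (promoter) to 0.8 (promoters of sensitive genes), reproducing the
  nested-subset correlation increase qualitatively. Background factor-B
  peaks are placed with rejection against any factor-A overlap so that
  co-binding occurs *only* where planted (this is what makes
  `cobind_rate = 0` imply exactly zero overlapping pairs).
  `generate_cobound_tag_study` additionally builds isolated identical
  A/B interval pairs so the merge → standardize → count path returns
  each planted tag pair exactly — the clean instrument for correlation-
  recovery checks.
* Chromatin states tile each chromosome without gaps or overlaps from a
  fixed seven-label vocabulary; segments covering a sensitive TSS are
  biased toward `active_promoter`.
* Peptide arrays default to 201 peptides tiling an abstract protein
  (length 15, step 3) with 15 planted hits at signal 50 against
  background Normal(5, 1.5) — hits sit far above the mean + 2 SD
  threshold, so exact recovery is expected. Setting
  `hit_signal = background_mean` is an intentional confound under which
  recovery is *not* expected.
* Cell images are 64×64 grids with concentric disk cell/nuclear masks;
  within-mask pixels draw from a bivariate normal with the planted
  correlation (default 0.38) and constant background outside. ρ = 1
  makes channel B an exact affine image of channel A. Channels are not
  clipped at zero (means sit 4–5 SDs above it), preserving exact affine
  structure.

One probe per gene is simulated; the probe/gene distinction is kept in
the schemas but collapsed by default to make truth bookkeeping
unambiguous.

### What the simulator does not model

Raw reads, fragment-length effects, duplicate structure, probe-level
hybridization, mappability, copy-number variation, or correlated noise
across arms. Passing recovery tests therefore demonstrates the
*correctness of the calling and integration logic* under the planted
statistical structure — not robustness to the messiness of real ChIP-seq
or microarray data.

## Problem sizes and numerical checks

The test suite verifies the exact tests against exhaustive enumeration
(all 2×2 tables with total ≤ 30; all hypergeometric configurations with
universes ≤ 12 by literal draw counting), nearest-TSS search against an
all-pairs scan (50 instances of 1000×1000), and correlation recovery
against Fisher-z 99% sampling intervals at n = 500 regions / ≥ 10⁴
pixels. These sizes were chosen so the whole default suite runs in well
under a minute while the enumeration bounds stay airtight.

## Known limitations

* The genome-wide numbers of the motivating study (6487 regions, 368
  co-bound, the 0.04/0.14/0.64 correlation ladder, 63%/84% promoter
  fractions) depend on its deposited sequencing data and annotation
  versions; this package reproduces the *procedures* and demonstrates
  them on planted-truth data, not those exact values.
* Peak calling, read mapping, and normalization are out of scope: the
  pipeline consumes called regions with normalized tag counts.
* `nearest_tss` treats every gene as a single TSS; alternative
  transcripts must be expanded to one row each by the caller.
* Fisher p-values are exact but the BH column assumes independent or
  positively dependent tests, as usual.
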