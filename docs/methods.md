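# Methods

## Coordinate and data conventions

All intervals are held 0-based, half-open (BED convention); GFF3 input
(1-based, closed) is converted on ingestion. The TSS is the first
transcribed base (`start` for + genes, `end − 1` for − genes) and the TES
the last; promoter windows are TSS ± flank (default 3000 bp) clipped at
chromosome edges. Genes are single intervals — isoform structure is out
of scope. Coverage is rasterized onto fixed-width bins (default 50 bp) by
length-weighted averaging, with uncovered bases contributing zero; this
conserves total mass (Σ bin value × bin width = Σ interval value ×
length) exactly for bin-aligned intervals and to within one bin's worth
of mass otherwise. Gene order is input order throughout, which fixes
tie-breaking in the rank plot.

## Library normalization

Before any cross-condition comparison, each track's bin values are scaled
to sum to 10⁶ (counts per million bins; `library_total` becomes 10⁶ ×
bin width). This equal-depth scaling is the minimal assumption that makes
a +Dox/−Dox fold change meaningful; it does deflect fold changes slightly
when a large fraction of the library sits in regions that change (the
synthetic defaults show observed demethylation fold changes of ~0.25–0.3
for a planted plateau attenuation of 0.2), which is the familiar
composition effect of total-count normalization and is left visible
rather than corrected.

## Promoter occupancy and chromatin states

Occupancy is the per-base mean of normalized depth over the promoter
window (a sum option exists; the mean is robust to edge clipping). States
are called on the uninduced (−Dox) condition only: *Bivalent* iff both
H3K4me3 and H3K27me3 occupancy strictly exceed the state threshold
(default 20 in normalized units), *K4me3*/*K27me3* iff exactly one does,
*NoMark* otherwise. All thresholds in the package are strict
inequalities, read literally from their published forms (">20", "<0.5",
"<0.66"); boundary behavior is unit-tested.

Demethylation uses FC = (occ₊ + ε)/(occ₋ + ε) with a symmetric
pseudocount ε = 0.1 (normalized-depth units), so equal occupancies give
FC exactly 1 and the log2 fold change is always finite. At occupancies
≥ 1 the calls are insensitive to ε (moving ε to 0.01 shifts log₂FC by
< 0.15 on the synthetic fixture; regression-tested). Whether the
published analysis applied its fold-change filter to raw or
depth-normalized occupancy is not stated; normalized is implemented.

## Metagene profiles

Each gene contributes a fixed grid: upstream flank bins, a gene body
resampled to `body_bins` (default 100) by length-weighted per-base
averaging, and downstream flank bins; minus-strand genes are
orientation-flipped. Genes shorter than one base per body bin are dropped
with a warning. The gene-averaged profile is divided by the mean of the
gene-averaged per-base density over [TES, TES + 6 kb) on the oriented
axis — the normalization region extends 3 kb beyond the displayed flank
and is computed even though it is not displayed. Averaged-profile
normalization (rather than per-gene) is the implemented default since the
source procedure does not specify which; per-gene normalization can be
emulated by calling the profiler per gene. When the normalization region
has zero density the profiler raises and instructs the caller to disable
normalization (`--no-normalize`).

## Expression filters

Differential calls average replicates within a condition, apply the
expression floor to the larger of the two condition means (a gene silent
in one condition but induced in the other must stay eligible), and call
up at FC > 2 and down at FC < 0.5 with the same ε = 0.1 pseudocount.
Swapping conditions mirrors up- and down-calls exactly.

The replicate-aware upregulation filter computes
z = (mean_t − mean_r)/√(se_t² + se_r²) on log₂(FPKM + ε) and requires
both FC > threshold (4 or 10 in the motivating comparisons) and z > 4.
This is a plain two-sample z reimplementation of a web-service filter
whose exact statistic is unpublished; only the thresholds are faithful.
With zero spread in both conditions, z is defined as 0 when the means are
equal (no evidence) and ±∞ otherwise.

## Coupling statistics

The rank plot stably sorts all genes ascending by H3K27me3 log₂ fold
change and averages expression log₂ fold change in a sliding window
(default 1000 genes, step 1). Window means are exact — they equal
brute-force means, not an approximation. When the gene universe is
smaller than the window (as in desk-scale simulation), the pipeline
clamps the window to a quarter of the universe with a warning so the
curve retains shape resolution; callers who want the strict published
window must supply ≥ window-size genes.

PAGE: z = (S̄ₘ − μ)√m/σ with μ, σ the parent mean and sample standard
deviation (ddof = 1) and S̄ₘ the set mean; p from the standard normal
(two-sided by default; one-sided available). z is invariant under affine
transformation of the values. The normal approximation is accurate for
moderate m by the CLT; for sets drawn *without replacement* from a small
parent universe the finite-population factor (N − m)/(N − 1) makes the
test slightly conservative, so null calibration is checked at N = 2000,
m = 50 where that factor is ≈ 0.98. The primary framing takes the
demethylated genes as the set and expression log₂FC as the values (is
the demethylated set upregulated?); the reciprocal framing (upregulated
genes scored on H3K27me3 log₂FC) is also computed, since either reading
of "correlation between demethylation and upregulation" is defensible.

## Synthetic data generator

The generator plants exactly the structure the analysis assumes, with
defaults chosen as one fixed reference condition:

- **Geometry.** 400 genes on 2 chromosomes, lengths uniform 2–8 kb,
  ≥ 12 kb spacing (room for ±3 kb promoters and the TES + 6 kb
  normalization region), 9 kb edge margins; 50 bp bins.
- **States.** Bivalent/K4-only/K27-only/NoMark with proportions
  0.3/0.3/0.2/0.2. Demethylation is planted on bivalent promoters with
  probability 0.4 (optionally also on K27-only promoters, since the
  motivating experiment saw demethylation at both classes; off by
  default so the planted fraction is exactly π_bivalent·π_d).
- **Coverage.** Promoter signal is a flat-top plateau over TSS ± 2 kb
  with 500 bp linear shoulders — the simplest shape that exercises
  window clipping and body resampling. Levels are parametrized on the
  normalized scale: plateau target 45, background 2.5, so that marked
  promoters average ≈ 30 over the ±3 kb window (≈ 1.5× the state
  threshold of 20, ≈ 12× background) and unmarked promoters ≈ 2.5.
  Higher plateau-to-genome ratios are not reachable at desk scale: with
  per-million depth normalization the total mass is fixed, and ~200
  4 kb plateaus already hold ~70% of it. Demethylated promoters keep
  background but have the plateau enhancement multiplied by 0.2 in
  +Dox. Bin counts are negative binomial around the mean profile
  (dispersion 20; ∞ recovers Poisson), at ~5 background counts/bin.
- **Expression.** Baseline log₂ FPKM ~ N(3, 1.5²) (median ≈ 8 FPKM);
  +Dox = −Dox × 2^(δ·flag + η) with planted δ = 1.0 and condition noise
  η ~ N(0, 0.25²); two replicates per condition with N(0, 0.15²) log₂
  replicate noise.
- **Randomness.** One seed, fixed named substreams per component
  (placement, states, expression, each of the four tracks), so adding a
  track cannot perturb the others; a fixed seed gives byte-identical
  bundles.

What the generator does *not* emulate: read-level artifacts (mappability,
GC, fragment-length effects), realistic peak shapes, overlapping or
isoform-rich gene models, genome-scale gene counts, and biological
confounding between expression level and chromatin state. Passing
recovery tests therefore demonstrates the pipeline's correctness and
statistical calibration on data satisfying its assumptions — not
performance on real sequencing data.

## Problem sizes used in the checks

The bundled checks run at desk scale by design: recovery metrics average
ten 400-gene simulations; PAGE null calibration uses 2500 random sets of
50 genes from a 2000-gene universe; oracle-equivalence tests compare the
binned implementations against independent per-base brute-force
reimplementations on ≤ 5-gene toys at 10⁻⁹ relative tolerance. The
published genome-scale counts themselves (1907 bivalent genes, etc.) are
inputs to the summary arithmetic, not outputs reproducible without the
original sequencing data.

## Known limitations

- Total-count normalization only; no background-aware (e.g. SES) or
  spike-in scaling.
- The expression z-filter approximates an unpublished web-service
  statistic; only its thresholds are faithful.
- bedGraph round-trips are exact for bin-aligned files; an interval
  ending inside a trailing partial bin is diluted by the bin's covered
  fraction.
- No peak calling or HMM segmentation — state calls are threshold rules
  on window means, as in the source procedure.
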