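# Methods

## Data model and assumptions

A ChIP-exo library consists of uniquely mapped single-end reads whose 5′
ends mark λ-exonuclease stop sites. The package assumes: reads are
pre-aligned (uniqueness expressed as mapping quality, filtered at
`min_mapq`, default 20); clonal reads are genuine signal and are never
deduplicated; forward-strand stops lie at the left edge of a binding site
and reverse-strand stops at the right edge, so one forward border pairs
with one *downstream* reverse border; and site width is approximately
constant genome-wide, up to a small number of discrete modes (outer and
inner stop geometries).

Coordinates are 0-based half-open throughout. The 5′ end of a
forward-strand read is `start`; for a reverse-strand read it is `end − 1`
(its highest genomic coordinate). BED/bedGraph are written natively
0-based; SAM input is converted at the boundary by pysam. Coverage tracks
are stored sparsely (positions + values), so memory scales with covered
positions, not genome length.

## Normalization and bias correction

The size factor F_j = common_scale / T_j (common scale 10⁷) equalizes
replicate depth; after scaling, each replicate's total 5′-end mass equals
the common scale exactly.

Composition bias is estimated from singleton reads only, to exclude IP,
exonuclease and PCR selection. The weight W(h) = mean_n P̂_n(h) / P̂_0(h)
compares a k-mer's frequency at the read start (offset 0) with its mean
frequency over interior offsets 1..L−k; each interior offset is
normalized separately before averaging, and k-mers containing non-ACGT
bases are excluded from all tallies. Numerical guards, chosen because the
ratio is unbounded and undefined at P̂_0 = 0:

- W clamped to [0.1, 10];
- a k-mer never seen at offset 0 but present internally gets the upper
  clamp (it is depleted at starts);
- unseen or ambiguous start k-mers fall back to weight 1 at application
  time.

k defaults to 6 and is configurable in [4, 8]. The singleton overlap test
is strand-agnostic: any overlap disqualifies. Correction is **off by
default**: on unbiased data it only adds sampling noise from the finite
singleton pool, and its effect on the final pair catalog is small (the
pipeline test bounds the on/off catalog difference at 5% with 1 nt
endpoint slack). With modest singleton counts hexamer weights are noisy;
k = 4 is the practical choice below a few hundred thousand singletons.

## Consolidation

S_i = (1/n) Σ_j v_ij × H(p)/ln n, natural logarithm (the reference values
1.386 = ln 4 and 1.099 = ln 3 fix the base), 0·ln 0 ≡ 0. Properties used
as tests: the entropy weight is 1 iff all replicates agree and 0 iff one
replicate carries all signal; S_entropy ≤ S_AM pointwise; entropy/AM/GM
are scale-equivariant and SNR scale-invariant.

The proportions p_j are computed per position by default. A pooled
per-locus reading (one p vector from replicate totals over the locus) is
available via `pooled_proportions`; the per-position reading is the
default because it is the one that actually suppresses replicate-exclusive
positions. Edge cases: with a single replicate the entropy weight is
defined as 1 with a logged warning; SNR at zero spread is capped at
mean × 10³ (SNR is a benchmarking comparator, never the default); GM is 0
wherever any replicate is 0.

## Border detection

Candidate loci are maximal runs of combined forward+reverse consolidated
signal ≥ `min_signal` (default 5 normalized units), merged when closer
than `merge_gap` (default 100 bp). Background statistics (m, s) are
computed per strand over the locus extended by `bg_flank` (default
±500 bp), over **all** positions in that window including zeros and
including the candidate peaks themselves (conservative: peaks inflate s
and can only weaken their own significance). The window is treated as the
complete local background population, so s uses the population (1/N)
denominator. This mirrors a "local lambda" style background.

The pseudo p-value min(1, 1/k²) requires k > 1; s = 0 (no dispersion)
yields 1. These are distribution-free upper bounds, deliberately
conservative — a site has only two true borders, and excess candidates
would flood the matcher — and are reported raw, without multiple-testing
correction. Significant positions within 2 nt on a strand collapse to the
single maximum (leftmost on ties), giving single-nucleotide borders.
Default significance cutoff: pseudo p ≤ 0.05.

## Border matching

High-confidence sizes come from loci with exactly one significant border
per strand (unambiguous pairing), capped at 500 bp pre-fit. A C-component
1-D Gaussian mixture (default C = 2, since size distributions are often
bimodal) is fitted by EM: seeded data-point initialization, best of 8
restarts by final log-likelihood, convergence at Δlog-likelihood < 10⁻⁸,
component variances floored at 10⁻⁶ with a warning. μ_T and σ_T are the
mean and SD of the highest-mixing-weight component. Fewer than 20 sizes
is an error directing the user to set μ_T manually.

The kernel width K defaults to max(2 σ_T, 1) bp — 2 σ_T ties the penalty
to the observed size spread, and the 1 bp floor keeps the kernel finite
when the size distribution is nearly a point mass. Admissible pairs
require forward ≤ reverse and inclusive span d = reverse − forward + 1 ≤
max_span (default μ_T + 4 σ_T). The inclusive-span convention makes a
site whose borders sit on its first and last base have d equal to its
width. S_obs is the **sum** of the two border signals (additivity of
clonal-read evidence); preferences order candidate partners by descending
S_weighted, ties broken by smaller |d − μ_T| then smaller partner
coordinate; forward borders propose in Gale–Shapley (the proposer choice
fixes which stable matching is returned and is documented for
determinism). Pairs with Fisher-combined p ≤ 0.05 are reported.

## Synthetic data generator

Defaults are the package's reference study conditions: one 500 kb
chromosome, 200 non-overlapping planted sites of width 49 bp, 50 expected
clonal reads per border (Poisson), per-read stop jitter N(0, 1 nt)
rounded, 3 replicates at relative depths (1.0, 0.8, 1.2), 50 uniform
background reads per kb, 36 nt reads. 49 bp is the canonical outer-stop
CTCF-like geometry; a two-mode width option (e.g. 49/13 bp) mimics
outer/inner double stops. Read sequences are random ACGT with optional
start-k-mer enrichment for bias-correction tests; reads may extend past
the site, as real digestion stops at the protein, and are clamped to
chromosome bounds. Fixtures are written as BED6 or plain-text SAM (SAM
carries sequences, enabling bias estimation downstream).

What the generator does **not** emulate: real genomic sequence (no FASTA;
k-mer composition is i.i.d. outside the planted enrichment), mappability
structure, fragment-length variation, cross-linking asymmetries between
factors, or PCR duplication distinct from clonal stops. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not calibration on real libraries.

## Numerical and scale choices

Tests and the end-to-end acceptance check run at desk scale — a 500 kb
genome with 200 sites (~135 k reads over 3 replicates), finishing in
seconds — which preserves every per-locus quantity (border depth, local
background, size distribution) of a genome-scale run while keeping the
suite fast. bedGraph values are written losslessly (shortest exact float
representation), so composing the four stages through files is
byte-identical to the single-process pipeline. All randomness (simulator,
EM initialization) flows from one integer seed.

## Known limitations

- Chebyshev pseudo p-values are upper bounds, not calibrated p-values;
  they order candidates but should not be read as FDR.
- With few true sites relative to background (e.g. sparse simulations or
  shallow libraries), coincidental background pairs can dilute the size
  model; the dominant-component rule usually rejects them, but
  `--mu-t` allows a manual override, and raising `min_signal` removes the
  contamination at the source.
- Segmentation is threshold-based on normalized units; datasets with very
  different depth profiles may need `min_signal` adjusted.
- Single-replicate runs pass through without entropy denoising (weight
  fixed at 1, with a warning); the method's noise suppression requires
  replicates.
- No paired-end or spliced-alignment support; alignment itself is
  upstream.
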