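# Methods

## Coordinate and shape conventions

All coordinates are 0-based, half-open internally; text outputs destined
for browsers (pairs tables, site tables) are 1-based inclusive, while BED
and bedGraph keep 0-based half-open starts.  Chromosomes are circular by
default: genomic distance is `d(i, j) = min(|i−j|, N−|i−j|)` everywhere a
distance is needed, fragment and bin tilings wrap through the origin, and
intervals may wrap (recorded as `end > chrom_length`).  A contact matrix
over a chromosome of length L at bin size b has `ceil(L / b)` bins, the
last one short.

## Contact-map construction

Read pairs are assigned to restriction fragments (HpaII `C^CGG` by
default).  Two event classes are discarded as religation artifacts: both
mates on one fragment (self-circle), and mates on adjacent fragments with
inward-facing strands (the upstream mate on `+`, downstream on `−` — an
uncut or re-ligated junction).  No distance-based religation heuristics
beyond adjacency are applied.  Remaining pairs increment the symmetric
count matrix once per unordered bin pair.

**Balancing (SCN).**  Bins whose raw marginal is below 10% of the median
marginal are masked (rows/columns zeroed) before balancing; this is the
low-coverage filter, and the 10% value is a package choice.  Balancing
alternates L1 row and column normalization.  Although convergence is
declared when the coefficient of variation of the unmasked row sums drops
below `tol` (default 1e−6), iteration continues to the numerical fixed
point (entrywise change < 1e−15, capped at `max_iter` = 200 sweeps), which
is the unique balanced form `D·A·D` of a symmetric matrix.  At that point
the iterate is symmetric to machine precision; one final transpose-average
makes symmetry exact, and a global rescale sets unmasked row sums to 1.
Stopping at the fixed point rather than at the CV criterion is what makes
renormalization a strict no-op (drift < 1e−15 in practice) — a per-sweep
transpose-average, by contrast, converges to a slightly different
(non-Sinkhorn) fixed point and was rejected for that reason.

**Ratio maps.**  `log2(a/b)` entrywise where both maps are positive;
entries undefined in either map are excluded from the Gaussian smoothing
kernel and the kernel renormalized over defined entries (σ = 1 bin by
default; the smoothing is applied to the log2 field, wrapping on circular
maps).  Positive means more contacts in the numerator condition.

## Range of cis contacts

The per-locus contact range is measured on the balanced map in four steps:

1. Robust background: median and MAD over all unmasked entries,
   σ = 1.4826 · MAD (the Gaussian consistency factor).
2. Binarize at `value > median + k·σ`.  The multiplier defaults to
   k = 1.0 and is exposed as a flag; the robust statistics are fixed by the
   procedure but the multiplier is a package choice, and measured ranges
   depend on it.
3. Keep 8-connected components of ≥ 30 points (size filter first), then
   close the union with a diamond (Manhattan-ball) structuring element of
   radius 5 (61 points).  Closing treats off-matrix area as background for
   the dilation and foreground for the erosion, so border points are never
   eroded away; on circular maps both axes wrap instead.
4. At each bin i, walk the anti-diagonal (i+t, i−t), t = 0, ±1, …
   (wrapping when circular, truncating at edges otherwise) and count the
   maximal contiguous significant run containing t = 0; the width is odd
   by symmetry, zero when (i, i) itself is not significant.  The range in
   kb is `width × bin_size / 2` — the band is symmetric about the locus,
   so half the perpendicular width is the reach on each side.

Width is measured once per bin, not averaged over windows.  Region
summaries (median, quartiles) use linearly interpolated quantiles.

## Directional index and CID boundaries

For each bin the contact vector to the left (lags 1..K) is paired with the
vector to the right at matched lags (K = max_range / bin_size, default
100 kb / 5 kb = 20) and compared with a two-sided paired t-test on the
differences; df = valid lags − 1 (zero-variance or masked lags are dropped
pairwise).  Positive t means rightward contacts dominate.  Display values
truncate at |t| = 2, approximately the p = 0.05 critical value at 19 df.
No multiple-testing correction is applied.

By default the contact vectors are taken from the Pearson-correlation
matrix of the balanced map (each entry the correlation of two matrix rows,
masked bins dropped).  **Calibration caveat:** on the correlation matrix
the per-bin p-values are strongly anticonservative — correlation values at
neighbouring lags share the fluctuations of the central row, so the paired
differences are positively correlated across lags (mean off-diagonal
correlation ≈ 0.5 on homogeneous synthetic maps) and the null
false-positive rate at p < 0.05 is ≈ 0.67 rather than 0.05.  This is
structural to directional indices computed on correlation matrices, not a
defect of the t computation: the statistic is sign-balanced and
mirror-antisymmetric, and it remains an effective *ranking* score.
Passing a balanced `ContactMap` instead of a `CorrelationMap` computes the
DI on the normalized counts themselves, whose lag differences are
independent and whose p-values are well calibrated (measured null FPR
0.043–0.051 across seeds).  The calibration benchmark therefore runs in
raw-map mode; boundary calling uses the default correlation mode and
compensates by demanding consistency, not just significance.

A boundary between bins b−1 and b requires a sign change of t and, on each
side, `min_significant_flank` (default 3) consecutive bins all reaching
|t| ≥ t_crit(0.05, df).  Mid-domain sign changes (+ → − at domain centers)
have weak flanks and are filtered out by this rule.

## ChIP-seq enrichment and peaks

Enrichment at position x is `(IP(x)/ΣIP) / (input(x)/Σinput)`; zero-input
positions are undefined (NaN) and excluded, with kernel renormalization,
from the 50-kb centered circular sliding mean used for chromosome-scale
plots.  Peak calling operates on the *unsmoothed* enrichment track:
maximal runs with `value ≥ fold × background` (fold = 10) of length
≥ 30 bp, merged across the circular origin; the peak center is the run
midpoint.  The background defaults to the median of the defined
enrichment track — the procedure names a "background" without defining
one, and the median is robust to the peaks themselves; a constant
background can be supplied instead.  Calls are invariant under joint
rescaling of track and background.  Peak-center ± flank sequences are
exported as FASTA for external motif discovery (motif discovery itself is
out of scope).

## matS genomics

The packaged motif is the classical 13-bp palindromic consensus
`GTGACRNYGTCAC` in IUPAC exact-match mode (the consensus is its own
reverse complement, so forward and reverse scans coincide; double hits at
one window are reported once, on the forward strand).  PWM mode scores
both strands with a log-odds matrix against a threshold.  Scanning wraps
across the origin of circular genomes.  Because consensus variants differ
between studies, published per-species site counts are reproducible only
with the exact motif used there; the motif is therefore a required input
for any cross-study comparison, and all packaged statistics are exercised
on planted genomes where ground truth is known.

Ter delimitation: consecutive sites (circularly) closer than 100 kb
(end-to-start) belong to one cluster; the Ter domain is the cluster with
the longest first-site-to-last-site span — ties broken by site count,
then smaller start — so its flanking gaps are ≥ 100 kb by construction.
The span convention is site-to-site (not extended to gap midpoints).
Summary statistics: span in kb, site count, density = sites / span × 100
(undefined for a single-site domain), span as % of the chromosome, and
whether the domain contains *dif*.

Density profiles count sites in contiguous 100-kb windows with the
offset-0 window centered on *dif*; every site falls in exactly one window,
so counts sum to the site total.  Cross-species envelopes take per-offset
median and quartiles (linear interpolation), using whatever species cover
each offset.

## Synthetic data

The generators produce data with the structure the analyses assume, not
polymer-physics simulations.

**Contact maps.**  Expected counts for bins i, j at circular separation d:

    mu(i,j) = depth · [ exp(−d·b / min(λᵢ, λⱼ)) · Π(insulation) + f ]

with b the bin size, λ the per-bin contact decay length, the product over
insulation factors (0, 1] of CID boundaries crossed by the shorter arc
between i and j, and f the random-ligation noise floor
(`background_fraction`, default 0.01).  Counts are independent Poisson
draws per unordered pair, symmetric by construction.  Choices and their
reasons:

* Exponential decay rather than power-law: a single length λ maps
  directly onto the measured range of cis contacts, which is the statistic
  under study.
* `min(λᵢ, λⱼ)` couples loci, so a restricted (Ter) locus has short-range
  contacts with *all* partners — mirroring the observed absence of
  long-range contacts of Ter loci.
* The additive floor emulates inter-molecular ligation noise in real
  proximity-ligation libraries.  It is essential to the realism of the
  width statistic: the robust threshold `median + k·σ` is anchored by the
  background level of the map, and without a floor the threshold tracks
  the decay tail itself and the measured range is no longer monotone in λ.
  The floor is not attenuated by insulation factors (it is experimental,
  not chromosomal).
* Defaults are E. coli scale: 4.6 Mb, 5-kb bins, λ = 250 kb, a 4× λ
  reduction inside a declared Ter interval, depth 1000 expected counts at
  distance zero.

**ChIP experiments.**  Input is flat Poisson at `depth` reads/bp; IP
multiplies the rate by `enrichment_fold` (default 3, in the 2–4× band of
replication-following enrichment) inside a replicated interval minus a
Ter-excluded interval, plus optional planted plateaus (center, width,
fold) for the peak caller.

**Genomes and rearrangements.**  Planted motif instances (degenerate codes
sampled) are written onto a random background that is rejection-resampled
until it contains no spurious matches on either strand, so a scan recovers
exactly the planted sites.  `transpose_segment` performs literal string
cut-and-paste: the segment [a, b) is excised, the gap closes, and the
segment is reinserted (reverse-complemented if inverted) before the base
that originally sat at the insertion point; `liftover` /
`liftover_inverse` are the exact coordinate bijections, and features
relocate through them.  This is the in-silico analogue of the programmed
transpositions used to split Ter into Ter1/Ter2.

## Validation conditions (scripts/acceptance.py)

All problem sizes are package choices, fixed once:

* SCN balance: 50 maps, 200 bins (1 Mb), λ = 150 kb, depth 500; reports
  the worst row-sum CV and the worst entrywise change upon renormalizing.
* Width oracle: 40 random symmetric masks up to 50×50 (mixed
  circular/linear, random size filter and closing radius) compared
  bit-for-bit against naive BFS labeling, pointwise closing, and run
  enumeration; plus the analytic band case (|i−j| ≤ 10 bins → 27.5 kb).
* Decay-length recovery: λ ∈ {50, 100, 200, 400} kb, 3 seeds each, on a
  9.2-Mb circle — long enough that the λ = 400 kb band fits and the map
  median stays background-dominated, which the monotonicity of the
  statistic requires; Ter recovery: 12 runs at the 4.6-Mb default with a
  900-kb Ter at λ/4.
* DI: null FPR over 20 homogeneous 200-bin maps (raw-map mode; the
  correlation-mode FPR is reported alongside for transparency); boundary
  recall over 4 maps with three insulation-0.4 boundaries ≥ 40 bins apart.
* Peaks: 100 tracks (30 kb, 400 reads/bp) with three planted plateaus of
  15–20× and 30–80 bp; recall, precision, and calls on 100 tracks
  containing only sub-threshold plants (15× at 29 bp; 9.5× at 50 bp).
  Depth 400 keeps the per-position Poisson fluctuation of a 15× plateau
  ≈ 6σ clear of the 10× threshold, so exactness is expected, not lucky.
* Ter delimitation: 100 planted genomes (620 kb; clusters of 5–9 sites
  with 5–90-kb gaps; one distant decoy); exact cluster recovery and
  verified ≥ 100-kb flanking gaps.  The E. coli Ter-row arithmetic
  (31 sites / 1037 kb on 4641 kb → 2.99 per 100 kb, 22.3%) is recomputed
  from those printed inputs.
* Liftover: 1000 random rearrangements × 20 probed positions; plus marker
  relocation through literal string surgery.

## Known limitations

* The synthetic maps have exponential, not power-law, distance decay, no
  replication-associated secondary diagonal and no trans contacts;
  passing recovery tests shows the estimators are correct under the
  model's assumptions, not that real libraries satisfy them.
* The range statistic depends on the threshold multiplier k; comparisons
  across conditions should hold k fixed.
* Measured ranges saturate at the half-circumference of the chromosome;
  decay lengths whose significant band exceeds it are reported at the
  ceiling.
* The correlation-mode DI p-values are anticonservative (see above);
  treat them as scores unless raw-map mode is used.
* The matS scanner's exact-match mode does not model mismatch tolerance;
  use PWM mode with a threshold for degenerate discovery.
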