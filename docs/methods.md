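# Methods

## Genome and strain models

The genome model covers four chromosomes — chr1 (196 Mb, 2 copies; the
normalization reference), chr2 (153 Mb, 3 copies, centromere [52.2, 52.7) Mb),
chr3 (110 Mb, 2 copies) and chr24 (6 Mb, 4 copies) — with all geometry
configurable and further chromosomes addable by override. Coordinates are
0-based, half-open, in base pairs.

Strain karyotypes are lists of retained intervals per chromosome copy. The
p-arm truncation point is placed at centromere start − 0.2 Mb (the *EGFR*
integration site is described as ~0.2 Mb from the centromere) and the q-arm
truncation at the centromere end: the ~10 kb *TPK1* offset is below the 10-kb
bin resolution and is absorbed. The mini-chromosome is therefore exactly
[52.0, 52.7) Mb = 0.7 Mb, of which 0.5 Mb is centromere repeat. The two
mini-carrying architectures (`Chr2_1_1_mini`, `Chr2_1_p_q`) have identical
aggregate copy-number profiles and are indistinguishable by coverage; only
karyotyping separates them. Translocations, point mutations, LOH and
selection-marker genetics are out of scope.

## Segregation model

A cell is a state (copies, expressing). Each division, every copy replicates
into two sister chromatids which segregate independently of other copies:
faithful (one per daughter, probability 1 − p_ns − p_ll), nondisjunction (both
to one daughter, p_ns, daughter chosen uniformly), or anaphase-lag loss (one
chromatid lost, p_ll). GFP expression is inherited by chromatids; each
expressing copy is silenced permanently with probability p_silence per
division — silenced carriers score GFP-negative while retaining the DNA,
which is why reporter preselection cannot fully clear the negative fraction.
Copy number is tracked to k_max (default 4); outcomes beyond it are truncated
with a logged warning, so chromatid conservation holds exactly only when
2 × copies ≤ k_max.

The exact one-division distribution over unordered daughter-state pairs is
enumerated (convolution over copies, binomial silencing thinning) and cached;
population propagation is per-class multinomial sampling over these pairs
(vectorized across clones), with a deterministic expectation operator as its
twin. A mechanistic per-copy sampler (`sample_division`) is implemented
independently and tested against the enumeration. The per-daughter
probability of not inheriting from a one-copy mother is
r_eff = (p_ns + p_ll)/2, the quantity the retention model estimates.

Defaults: 3 divisions/day (8-h doubling). Long time-courses are kept at
≤ 10^6 cells by multivariate-hypergeometric subsampling at daily passages;
clone assays propagate exact class counts (a 2^21-cell clone is two integers)
and refuse > 60 generations, where 64-bit counts would overflow.

## Loss-rate estimation

* **Clone-median estimator.** Clones at exactly 100% GFP-negative are excluded
  by default (chromosome loss at day 0, before expansion); the median of the
  remaining per-clone negative fractions m gives r = 1 − (1 − m)^(1/n),
  n = round(days × divisions/day), f0 = 1. The median, not the mean, is used
  for robustness to the heavy right tail from early-division losses. CI by
  seeded nonparametric bootstrap over clones (2000 resamples, percentile,
  95%). An optional background mode subtracts a fixed day-0 negative fraction
  (silenced carriers); it is off by default, so silencing biases r upward —
  a limitation of the assay itself.
* **Time-course estimator.** Least squares on ln f = ln f0 + n ln(1 − r) with
  retained fraction f = 1 − GFP-negative fraction (double-GFP cells count as
  retaining; re-loss from two-copy cells is ignored, consistent with
  double-GFP fractions being much smaller than negative fractions). f0 is
  either pinned at the day-0 measurement or fitted as a free intercept.
  CI by seeded residual bootstrap. Complete loss (f_n = 0) returns r = 1 with
  a warning — the data only bound the rate.

**Median bias at low rates.** For a clone founded by a single cell, the
GFP-negative fraction is Σ_k N_k 2^−k, where N_k is the number of loss events
at generation k. Generations with expected event count below ~1 (for
r = 0.00143, generations 1–9) contribute r each to the *mean* — which equals
1 − (1 − r)^n exactly — but rarely to the *typical* clone, so the median sits
below the mean: simulated medians are ~2.13% where the mean is 2.96%
(n = 21), a −28% deficit that shrinks as n grows (−14% at n = 42) and
vanishes at high rates (at r = 0.0897, median ~85.6% vs mean 86.1%). The
clone-median estimator therefore under-reads low rates by the same factor and
never over-reads; tests assert exactly this behaviour. Estimates derived from
*observed* medians (the printed 2.96% → 0.14%/division) are unaffected — the
bias concerns forward simulation at a known rate, not the inversion.

## Coverage simulation

Expected count per bin = depth_per_copy × (copy-weighted covered fraction of
the bin) × mappability weight, with Poisson noise by default or
negative-binomial (variance μ + αμ²) optionally; real sequencing bias beyond
a weighted mask (GC content, mappability gradients) is not emulated, so
passing tests bound estimator behaviour under ideal count noise only.
Centromere intervals are masked (weight 0) by default, mimicking unmappable
repeat arrays — this is what places the detected q-side breakpoint at the
centromere's far edge (52.7 Mb) rather than inside it. Defaults: 10 kb bins,
10 reads/bin/copy (so chr1 bins average 20, control chr2 bins 30). Partial
bins at truncation points contribute their covered fraction. A read-position
sampler (uniform within retained copies, Poisson counts, mask thinning)
exercises the binning ingestion path and is cross-checked against the binned
expectation.

## Copy-number pipeline

Double normalization: bin counts ÷ mean chr1 bin count of the same sample,
then ÷ the control strain's ratio per bin. Bins where the control ratio falls
below 0.1 are masked. The per-bin score is kept as the raw ratio (so
self-normalization is exactly 1 per bin), but **chromosome-level means are
control-weighted** — the ratio of summed ratios, i.e. the whole-chromosome
read-count ratio. The plain mean of per-bin Poisson ratios is Jensen-biased
upward by ~E[Y]⁻¹ (measured 0.692 for a true 2/3 at these depths); the
weighted mean is unbiased and matches a read-count-based copy-number table.
Inferred copies = control_copies × mean score, quantized to the nearest whole
copy.

Segmentation is deterministic, in four stages:

1. median smoothing of the unmasked score subsequence (centered window,
   default 15 bins);
2. quantization to levels {k/control_copies : k = 0..control_copies+1} and
   merging of runs shorter than 3 bins;
3. per-run level re-estimation from the raw counts: each run's mean count is
   scored by Poisson likelihood against baselines level × control_copies ×
   (sample chr1 depth per copy), and a run survives only if its evidence
   beats the best neighboring level by ≥ 5 noiseless bins' worth
   (merge_margin). Per-bin score noise is dominated by the control
   denominator (a ratio of two ~Poisson(20–30) counts has sd ~0.2,
   right-skewed), which smoothing alone cannot suppress without destroying
   short features; validating levels against the counts removes
   denominator-driven runs exactly. The smallest feature that survives is
   ~merge_margin + 1 bins at a one-copy contrast;
4. maximum-likelihood boundary refinement: each boundary is relocated within
   ±25 unmasked bins by the prefix-sum argmax of per-bin log-likelihood
   evidence (Poisson on counts; squared error on scores when counts are
   unavailable). Candidates at the far edge of a masked gap receive a bonus
   of 0.8 noiseless bins of evidence: a repeat array is a far likelier
   breakpoint host than any single flanking bin, and without the bonus one
   noisy bin adjacent to the 0.5 Mb centromere mask relocates the q-side
   boundary by the whole gap 18% of the time (6% with it). The bonus is
   below one noiseless bin, so exact data always win.

Masked bins are bridged: segments extend through them and boundaries sit at
the first unmasked bin of a different level. Ties in quantization resolve to
the lower level; ties in the argmax to the leftmost candidate.

**Resolution limit.** Localizing a boundary between 2 and 3 copies at
10 reads/bin/copy is a changepoint between Poisson(20) and Poisson(30) bins.
The Bayes-optimal localizer (exact-rate ML) achieves P(|error| ≤ 1 bin) ≈ 87%
(Monte Carlo, 2×10^5 trials); our refinement operates at that limit (~85%
at the free 52.0 Mb boundary, ~90% at the mask-edge 52.7 Mb boundary).
Single-bin certainty would need roughly double the depth. Whole-chromosome
copy calls, by contrast, average ~15,000 bins and are essentially exact.

`detect_mini_segment` returns the interior segment whose level strictly
exceeds both flanks, nearest the centromere if several qualify.
`compare_strains` segments two score tracks independently and reports maximal
intervals of differing quantized level; regions of 1–2 bins arise from
independent boundary jitter of the two tracks and are ignored by downstream
selections, which take the longest loss region (incremental q-side loss) or
the region anchored at the chromosome's left end (p-arm loss).

## Interfaces

Counts round-trip through a TSV (chrom/start/end/count with a strain and
bin-size header comment); scores export as bedGraph (masked bins omitted) and
segments as BED4 with the level as name, both 0-based half-open. Assay TSVs:
clone_id/gfp_negative_fraction[/gfp_double_fraction] and
day/fraction_negative/fraction_single/fraction_double. Genome and karyotype
models round-trip through YAML. The `minichrom` CLI wraps simulation, CNV
calling and rate estimation; estimator classes follow the scikit-learn
protocol (`get_params`/`set_params`/`fit`, fitted attributes with trailing
underscores).

## Problem sizes

Default analyses are sized for seconds-scale runs: 3000-clone assays,
25-day time-courses at 10^5–10^6 cells, whole-genome tracks of ~47,000
10-kb bins, 100-replicate breakpoint studies. All stochastic entry points
take explicit seeds and are bitwise reproducible.
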