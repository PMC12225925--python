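# Methods

## The experimental design being modelled

Each trial pairs one treatment flower with a Paired Control — an identically
rigged flower, observed simultaneously, whose electrode is electrically
floating. One observer logs every honeybee landing at either flower over a
120-minute window, to the nearest minute. A treatment (50 Hz AC, +DC, or
−DC applied to a small spherical electrode 50 mm from the flower ring) is
repeated over eight such trials. The paired design absorbs site, weather and
seasonal variation; inference is within-pair.

## Paired permutation test

Statistic: `D = mean_i(control_i − treatment_i)` in landings, so a positive
D means suppression at the treatment flower. The default null is built by
**sign-flipping**: each resample independently swaps the two labels within
each pair (equivalently negates each paired difference) with probability ½
and recomputes D. For n pairs the signflip null has exactly 2ⁿ atoms and is
enumerated exhaustively on request (`exact=True`, n ≤ 20); at n = 8 the
smallest attainable two-sided p with no zero differences is 2/256. A
**full-relabel** scheme (re-partitioning all 2n counts into two groups of n,
ignoring the pairing) is retained as an option because "label permutation"
descriptions of such tests are ambiguous; it is never the default.

Two-sided p-value: the plain proportion of null statistics with
|D*| ≥ |D|, ties counted as exceedances, the observed arrangement *not*
appended to the null. This makes exact-vs-Monte-Carlo comparisons
well-defined (the MC p is an unbiased binomial estimate of the exact p) at
the cost that an MC p of exactly 0 is possible in principle; with the
identity sign pattern among 2ⁿ and 10⁴ draws this has negligible
probability at n = 8.

Null summaries: arithmetic mean, sample SD (ddof = 1), and the empirical
2.5th/97.5th percentiles with numpy's linear-interpolation convention. The
percentile band describes the null distribution (it brackets zero), not a
confidence interval for D.

Effect size: the default is `D / SD(null)`, a resampling-standardised
Cohen's d; this is the definition consistent with the printed
(difference, null SD, d) triplets of the study this pipeline reproduces.
The classical paired d, `mean(diff)/sd(diff)`, is available via
`kind="classical"`; every result records which was used.

Shapiro–Wilk (on paired differences) and Levene (across the two groups)
diagnostics are delegated to scipy and reported as advisory only — they
never gate the permutation test. Degenerate inputs (constant differences,
zero spread) are flagged in notes rather than raised.

`median_reduction` reports `100·(median(c) − median(t))/median(c)`, the
headline percent-reduction summary; it errors when the control median is
zero.

## Time-resolved analysis

Pooled landings (all trials of a treatment) are binned into 10-minute bins,
half-open `[a, a+10)` with the final bin closed at 120 so a landing logged
at exactly minute 120 lands in bin 12. Binning conserves counts exactly.

Percent-of-control per bin is `100·t_b/c_b`. A bin with `c_b = 0` has no
defined percentage — such bins occur in real pooled data — and is excluded
from means/SDs rather than treated as 0 or ∞. Summaries accept a 1-based
inclusive bin window (e.g. bins 3–12 for "the remainder of the trial" after
the first twenty minutes).

Rate of change: successive differences of percent-of-control between
consecutive *defined* bins, divided by the elapsed minutes between their
bin starts (10 min when no bin is skipped). The mean rate then telescopes
exactly to `(last − first) / elapsed minutes` whenever all bins in the
window are defined, which is the convention that reproduces a 40→75%
recovery over 110 elapsed minutes as ≈0.32 %/min. The SD of these per-step
rates is reported alongside; with skipped bins the steps span unequal
elapsed times and the telescoping identity no longer holds, so it is only
asserted on fully defined windows.

## Synthetic visitation generator

Control landings: homogeneous Poisson at `base_rate` λ (default 0.1/min,
i.e. 12 expected landings per 120-min trial, matching the 1–20 per-trial
count levels of the motivating experiments). Treatment landings:
inhomogeneous Poisson at `λ·s(t)`, realised by thinning a homogeneous
process at λ (exact, and stable under a fixed seed). Counts are the number
of generated events; only logged timestamps are rounded to the nearest
minute, so rounding can never merge events away.

Suppression trajectories `s(t) ∈ [0,1]`:

- exponential: `s(t) = s∞ + (s0 − s∞)·exp(−t/τ)`
- linear: `s(t) = s0 + (s∞ − s0)·t/T`
- constant: `s(t) = s0` (requires s0 = s∞)

Default presets (synthetic conventions calibrated to the observed
percent-of-control trajectories of each treatment class, not measured
values): AC 0.059→0.681 exponential with τ = 10 min (strong early
suppression, rapid partial rebound); +DC 0.40→0.75 linear; −DC 0.744
constant; NULL 1.0. The time-averaged suppression `(1/T)∫s dt` has the
closed forms used for parameter-recovery checks (`mean_suppression`).

Per-trial seeds derive from the study master seed via
`numpy.random.SeedSequence(seed).spawn(n_trials)` — trials are independent
but the whole study is bit-reproducible. The CLI fans a single master seed
out to per-stage seeds the same way.

What the generator does *not* emulate: overdispersion between trials
(counts are pure Poisson; real trials share weather and forager-density
drivers, so field data are likely overdispersed and the simulated power
estimates are optimistic), within-trial clustering of landings (bout
foraging), individual bee identity or learning, and covariates. Passing
tests therefore demonstrate the correctness and calibration of the
*pipeline* under its stated model, not properties of any field dataset.

## Field quantification and calibration

Point-source model: `E_RMS = V_RMS/r`, `V_RMS = Vpp/(2√2)` for a sinewave
(5 Vpp → 1.7678 V). Units are SI throughout the API (metres, volts, V/m);
millimetre lab figures are converted at the I/O boundary.

Baseline subtraction removes ambient mains pickup: stimulus-on minus
grounded-electrode control, element-wise on a shared distance grid;
negative differences are floored at 0 with a warning, since both operands
are noisy magnitudes and field magnitude cannot be negative.

Calibration lines: OLS of measured on modelled field, fitted separately in
a near band (60–300 mm) and a far band (360–600 mm); the measured/modelled
relationship is not globally linear but is strongly linear within each
band. No line exists in the 300–360 mm gap and queries there are an error
by design. Each electrometer's calibration factor is the band-line
prediction of the field at its anchor distance (70 mm near, 400 mm far)
divided by the mean potential it recorded with no plant present; applying
the factor back to that mean potential returns the anchor field exactly.

Waveform processing: a zero-phase (forward–backward) 4th-order Butterworth
low-pass at 30 Hz isolates a 20 Hz stimulus from 50 Hz mains noise, then
the RMS of the filtered trace is scaled by the calibration factor.
Forward–backward application squares the magnitude response: measured
passband gain at 20 Hz is ≈0.96 (within the ±5% tolerance the pipeline
asserts) and a 50 Hz tone of equal amplitude contributes <2% of its RMS.
Zero-phase filtering was chosen so the filter adds no delay or phase
distortion to the RMS estimate.

The nominal fair-weather atmospheric potential gradient context (~150 V/m,
emulated in the lab by a 60 V plate 0.4 m above ground) is documented
metadata only; it is not modelled.

## Transect mapping

Grids are horizontal distance (0–100 m in 5 m steps, one-sided, measured
from directly beneath the line) × height (0.225, 0.5, 1, 2 m). Nodes at or
above the instrument ceiling (2000 V/m) are stored at the ceiling with an
overrange flag: the map renders them at the ceiling as a floor-of-truth
rather than dropping or extrapolating them. Interpolation is bilinear on
the rectilinear grid (exact at nodes, no overshoot, linear field space —
log-space display is a plotting concern, not a data transform); any
interpolated point in a cell touching an overrange node is flagged
uncertain. No extrapolation outside the grid hull. The experimental-range
mask is the region where the interpolated field is ≤ a threshold (50 V/m
default), with its area fraction computed as the fraction of dense map
points — threshold-monotone by construction.

The synthetic transect fixture places a line source 10 m above the 0 m
mark with `E = A/r²` decay (A = 150 000 V·m²) plus additive Gaussian noise
floored at 0: with the default ceiling this both saturates under the line
and falls below 50 V/m near 100 m, spanning the regimes the mapping code
must handle. The quadratic decay exponent is a generator parameter, chosen
because a pure 1/r law cannot span a 2000 V/m ceiling and a ≤50 V/m far
field across this geometry.

## Problem sizes and numerical conventions

Statistical guarantees are checked at the design conditions: 8 pairs per
study, 1,000 study replicates for type-I error (measured rejection ≈0.04 at
α = 0.05 — conservative, as expected for a discrete null with 256 atoms and
ties) and for power (majority rejection under the default AC preset),
10,000 Monte-Carlo permutations where MC nulls are compared to exact
enumeration. Tie counting in p-values uses a 1e-9 magnitude tolerance so
float means of integer counts compare exactly. Percentiles, SDs (ddof = 1)
and OLS fits delegate to numpy/scipy.

## Known limitations

- Poisson dispersion only (see above); an overdispersed generator option
  would be the first extension for realistic power analysis.
- The permutation schemes implement both plausible readings of "label
  permutation" (within-pair vs pooled); which a given historical analysis
  used must be established against its deposited data before comparing null
  SDs.
- The calibration chain treats the plant's perturbation of the field as
  measured, not modelled; there is no electrostatics simulation.
- Rate-of-change SDs depend on the successive-difference convention; only
  the mean rate is pinned down by the telescoping identity.
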