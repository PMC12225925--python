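# beefield

Analysis pipeline for paired floral-visitation experiments under weak
anthropogenic electric fields: do honeybees land less on flowers whose local
electric environment is perturbed by a mains-like AC or a ±DC stimulus?

The package is for behavioural ecologists and biostatisticians running (or
re-analysing) paired field experiments in which each treatment flower has a
simultaneously observed Paired Control — an identically rigged flower whose
electrode is electrically floating — and every landing is logged to the
nearest minute over a two-hour trial. It also covers the physics side of
such experiments: quantifying the stimulus field with a point-source model,
calibrating electrometers against a survey meter, and mapping transmission-
line fields from transect measurements.

## What it computes

**Paired permutation inference.** For n paired trials with landing counts
(cᵢ, tᵢ) the test statistic is the mean paired difference

    D = (1/n) Σᵢ (cᵢ − tᵢ),

a positive D meaning suppression at the treatment flower. The null
distribution is built by sign-flipping: each permutation swaps the
treatment/control labels within each pair independently with probability ½
and recomputes D (for n ≤ 20 all 2ⁿ assignments can be enumerated exactly; a
pooled full-relabel scheme is available as an option). The two-sided p-value
is the plain proportion of null statistics with |D*| ≥ |D|, ties counted as
exceedances. Results record the null mean, sample SD, empirical 2.5–97.5
percentile interval, and a Cohen's-d-style effect size D / SD(null) (the
classical paired d, mean(d)/sd(d), is available as an option).

**Time-resolved dynamics.** Pooled landings are placed in 10-minute bins
(half-open, final bin closed at 120 min) and summarised as per-bin
percent-of-control, 100·tᵦ/cᵦ, with zero-control bins flagged undefined and
excluded. Rates of change are successive per-bin differences divided by
elapsed minutes; the mean rate telescopes to (last − first)/elapsed.

**E-field quantification.** A small spherical stimulus electrode is treated
as a point source, E_RMS = V_RMS / r with V_RMS = Vpp/(2√2). Survey-meter
measurements (baseline-subtracted against unpowered controls) are regressed
on the model separately in near (60–300 mm) and far (360–600 mm) bands; the
fitted lines predict anchor fields at each electrometer position, and
dividing by the mean recorded potential yields each electrometer's
calibration factor (V/m per volt). Recorded waveforms are zero-phase
low-pass filtered (4th-order Butterworth, 30 Hz) to isolate a 20 Hz stimulus
from 50 Hz mains pickup before taking the RMS.

**Transect mapping.** Transmission-line transects (0–100 m × four heights)
with a 2000 V/m instrument ceiling are validated into a grid, bilinearly
interpolated into a 2-D map (overrange nodes render at the ceiling and
propagate an uncertainty mask), and thresholded to delimit the region within
the experimental field range (≤ 50 V/m).

**Synthetic studies.** A seeded generator produces paired visitation event
streams: control landings are homogeneous Poisson (default 0.1/min ≈ 12 per
trial); treatment landings are an inhomogeneous Poisson process at rate
λ·s(t), the suppression ratio s(t) recovering from s₀ to s∞ exponentially,
linearly, or not at all. Presets emulate the qualitative AC / +DC / −DC /
null dynamics so every downstream stage is testable without field data.

## Worked example

```python
import beefield as bf

design = bf.StudyDesign(n_trials=8, duration_min=120, seed=1)
pairs, events = bf.simulate_study_events(bf.PRESETS["AC"], design)
res = bf.paired_permutation_test(pairs, n_permutations=10_000, seed=2)
print(res.observed_difference, res.p_value, res.effect_size)

trace = bf.percent_trace(bf.bin_events(events), bin_range=(3, 12))
print(trace.mean_percent)
```

prints

```
4.25 0.0169 2.39690742178885
77.232683982684
```

i.e. the treatment flower received on average 4.25 fewer landings per trial
than its Paired Control, a difference attained by ~1.7% of sign-flipped
relabelings (two-sided p = 0.0169, effect 2.40 null-SD units), and from the
third 10-minute bin onward pooled treatment landings ran at ~77% of control.

The same pipeline runs from the shell:

```bash
beefield all --preset AC --n-perm 10000 --seed 7 --out runs/ac
beefield permtest --pairs runs/ac/pairs.csv --n-perm 10000 --scheme signflip --seed 1
```

## Layout

- `beefield.simulate` — presets, paired-study and transect generators, event-log CSV I/O
- `beefield.permutation` — paired permutation test, null summaries, effect sizes, diagnostics
- `beefield.temporal` — time binning, percent-of-control traces, rates of change
- `beefield.calibration` — point-source model, piecewise calibration, waveform RMS extraction
- `beefield.transect` — transect grids, bilinear maps, range masks
- `beefield.cli` — `beefield` command with `simulate`, `permtest`, `bins`, `calibrate`, `transect-map`, `all`

See `docs/methods.md` for the statistical model, conventions and known
limitations.
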