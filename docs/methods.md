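# Methods

This note records the models, conventions and numerical choices behind
`easyhrv`, and what the synthetic-data tests do and do not establish
about real recordings.

## Beat series and preprocessing

A recording is a strictly increasing sequence of beat times (s), with
RR intervals in ms and the non-interpolated instantaneous heart rate
niHR = 60000/RR defined at each beat after the first. In the default
`rr` file dialect each line is one interval in seconds; the first value
is treated as the interval preceding the first counted beat, so the
interval count equals the line count.

The artifact filter targets beat-detector errors: false detections
(spuriously short RR), missed detections (merged, long RR) and
ventricular beats. A beat is kept iff its rate lies in
[`min_bpm`, `max_bpm`] (25–200 by default) *and* it is within
`last_tolerance` = 13% of the previously accepted beat's rate, or of
the next beat's rate, or within `mean_tolerance` = 20% of the running
mean rate of the last `long_window` = 50 accepted beats. Two
deliberate choices:

* **Value filtering, not interval merging.** A rejected beat's RR
  value is dropped; survivors keep their original RR values and the
  output beat times are rebuilt from the surviving intervals.
  Re-deriving intervals across rejection gaps instead would cascade: a
  merged interval from one missed detection makes every subsequently
  re-derived interval longer and less plausible, destroying the tail
  of the recording. Value filtering keeps the filter idempotent; its
  cost is that the filtered recording is shorter in total time by the
  removed intervals, which slightly shifts the 300 s analysis windows.
* **Guarded next-beat comparison.** The next-beat similarity clause
  only applies when that next beat is itself in range and near the
  running mean. Without the guard, a false detection and the shortened
  interval that follows it validate each other and both survive. The
  guard makes the filter slightly conservative during sharp genuine
  rate transients.

The running mean is updated after a beat is accepted. Automatic
filtering can be disabled per run for externally edited files.

## Time-domain indices

Sample (n−1) standard deviations are used throughout; the
population/sample distinction is invisible at reporting precision but
must be fixed for reproducibility. SDANN and SDNNIDX partition the
recording into consecutive `window_s` = 300 s windows anchored at the
first beat; intervals belong to the window containing their ending
beat, and a trailing partial window is kept if it contains beats. If
only one window exists, or any window is empty, both indices are NA
with a warning and are excluded from statistics (NA never propagates
an exception). IRRR is the interquartile range of RR (not of the
successive differences — both readings circulate; this one is fixed
here). TINN and HRVi use an RR histogram with bins of 1/128 s
(7.8125 ms) aligned to multiples of the bin width; TINN is M−N from
the least-squares triangular fit through the modal bin, found by
exhaustive search of both base edges.

## Frequency-domain indices

Analysis runs on the niHR linearly interpolated at `interp_hz` = 4 Hz,
so powers are in (beats/min)². Band edges are half-open (lo, hi] to
avoid double counting: ULF (0, 0.03], VLF (0.03, 0.05], LF
(0.05, 0.15], HF (0.15, 0.4] — conventions for resting adult humans;
children, athletes and animal data need different edges, which are
configurable.

*Fourier route*: least-squares linear detrend; one-sided periodogram
normalised so the ordinates sum to the signal variance (checked as a
Parseval identity in the tests); smoothing by a composed modified
Daniell kernel with half-widths (5, 5) and reflective edge padding;
band power is the sum of smoothed ordinates in band.

*Wavelet route*: the detrended signal is decomposed with a Daubechies-4
wavelet-packet transform at the smallest depth whose uniform subband
width matches every configured band edge within `band_tolerance`
= 0.01 Hz (depth 7 at 4 Hz, i.e. 0.015625 Hz subbands). Dyadic
single-level decompositions cannot align with the standard band edges
at any tolerance this tight — e.g. the VLF upper edge 0.05 Hz sits
between the dyadic boundaries 0.03125 and 0.0625 — which is why a
packet (uniform-subband) decomposition is used. Band power is the
total squared coefficient mass of the assigned subbands divided by the
signal length: the time average of the instantaneous band power, by
Parseval's relation for orthogonal wavelets. If no depth up to 12
resolves the configured edges, the band is reported unresolvable.

Powers are reported absolute (not normalised, not logged).

## Non-linear indices

All phase-space distances use the maximum norm. A Theiler window
(default 100 beats, raised to the lag if larger) excludes temporal
neighbours from all pair counts.

1. **Poincaré**: SD1 = √(var(Δ)/2), SD2 = √(2 var(RR) − var(Δ)/2)
   (population variances, clamped at 0), the minor/major semi-axes of
   the fitted ellipse.
2. **Time lag**: first local minimum of the RR autocorrelation; else
   first decay below 1/e; else the same two criteria on the average
   mutual information (16-bin histograms); else a fallback of 30
   beats. The strategy that fired is reported.
3. **Embedding dimension**: Cao's method with threshold 0.95 on
   E1(d) = E(d+1)/E(d), requiring the criterion to hold for all larger
   tested d, capped at 15 (returned with a warning when never met — the
   signature of a stochastic series), floored at 2. Reference points
   are subsampled above 2500 (seeded) to bound the quadratic
   neighbour search.
4. **Correlation sums**: C(m, r) on a 100-point log-spaced radius grid
   for m ∈ {m₀, m₀+1, m₀+2}, counted by a chunked O(N²) scan that is
   tested for exact equality against a brute-force double loop. The
   grid spans the 1st percentile to the maximum of a seeded pairwise
   distance sample, floored at 10⁻⁴ of the attractor diameter so
   near-repeating series cannot push radii below numerical resolution.
5. **Scaling region**: local exponents d log C / d log r by central
   differences; a continuous 4-segment piecewise-linear fit (linear
   spline with free interior breakpoints; deterministic multi-start
   Nelder–Mead over a seeded set of initialisations, least-squares
   coefficients per start) whose flattest-slope segment is the scaling
   region. The per-m correlation-dimension estimate is the mean
   observed exponent inside the region; the final value averages the
   available per-m estimates.
6. **Sample entropy**: ln C(m, r) − ln C(m+1, r) averaged over the
   radii of the lower dimension's scaling region and over the
   consecutive pairs (m₀, m₀+1), (m₀+1, m₀+2).
7. **r_small**: the radius where the dimension-averaged correlation sum
   equals 10⁻³ (the probability of finding a phase-space neighbour),
   interpolated log-log between bracketing grid points; if the grid
   floor is above the target the grid is extended one decade downward
   once, and if the floor persists (clustered attractors) the smallest
   original radius is used with a log entry.
8. **Lyapunov**: Kantz divergence curve S(Δn) over horizons 0–40
   beats, averaging log mean neighbour distances over up to 1000
   seeded reference points; a 2-segment piecewise fit (growth then
   saturation) whose first slope is the exponent per beat. Exact
   recurrences are floored at 10⁻⁶ r_small so periodic trajectories
   give a flat curve rather than −∞.
9. **RQA** at radius r_small with lmin = vmin = 2. The diagonal
   histogram excludes the line of identity; Lmean re-adds it as one
   line of length N while LmeanWithoutMain does not. TREND is the
   least-squares slope of the diagonal-wise recurrence rate (%) against
   diagonal offset over offsets up to 90% of N. Divisions by zero
   (no recurrences, no lines above threshold) yield NA for the
   affected fields only.

Every stage failure is converted to NA plus a log entry; a recording
can never abort a cohort run. With a fixed seed the whole chain is
bit-reproducible, and results are independent of `n_jobs` because each
recording's seed derives from the run seed and the recording's
group/id.

## Statistics

Per index (NA excluded; indices leaving any group with < 3 values are
skipped with a warning): one-way ANOVA, Shapiro–Wilk on the pooled
within-group residuals (subsampled with a fixed seed above n = 5000,
the test's validity bound); if SW p < α the index is treated as
non-normal and tested with tie-corrected Kruskal–Wallis. Degenerate
inputs (constant residuals, fully tied ranks) fall back to
Kruskal–Wallis with p = 1. Omnibus p-values are corrected across the
whole family of computed indices (14 by default, up to 31 with the
non-linear block). Post-hocs run only for significant indices with
≥ 3 groups: unpaired two-sample t-tests after ANOVA (the groups are
independent subjects), or Dunn z-tests on mean ranks with tie
correction after Kruskal–Wallis; the pairwise family is corrected with
the same method. Confidence intervals are unadjusted (level 1 − α),
t-based for indices that passed the normality gate and otherwise a
percentile bootstrap of the mean (B = 2000) whose seed derives from
the run seed and the index/group name, making intervals independent of
evaluation order. The normality decision is made once per index (on
the omnibus residuals) and reused for the CI method.

## Synthetic data

The generator is the test bed standing in for public RR databases.
Heart-rate trajectories (mean 75 bpm, 5 bpm band-limited Gaussian
fluctuation, sinusoidal modulation at 0.1 Hz/2 bpm and 0.25 Hz/3 bpm
by default — resting adult values) are converted to beats by
integrate-and-fire (IPFM), so spectral ground truth is controlled.
`henon` dynamics map the Hénon attractor (a = 1.4, b = 0.3) into a
physiological RR range, giving known correlation dimension (≈1.22) and
Lyapunov exponent (≈0.42/iter). `periodic` dynamics use an asymmetric
two-harmonic waveform: a pure sine's reflection symmetry creates
mirror-phase recurrences in phase space that no real rhythm exhibits.
Corruption injects false detections by splitting an interval at a
U(0.2, 0.6) fraction and missed detections by merging neighbours,
with a full provenance map.

What passing tests show: the estimators recover constructed spectral
content, known attractor invariants and injected group effects, and the
statistics are calibrated under the null. What they do not show:
robustness to non-stationarity, ectopy patterns, circadian trends or
device-specific quantisation of real Holter data — the generator
produces stationary series with idealised artifact models.

## Problem sizes and determinism

Default verification sizes: 10⁴ beats for chaotic ground truth (the
correlation-sum scan is the dominant cost), 2×10³ for periodic RQA,
200 simulated families for null calibration, 500 repeats for CI
coverage. Cao and Kantz reference subsampling (2500 / 1000 points) are
accuracy/cost compromises whose effect on the Hénon benchmarks is well
inside the asserted tolerance bands. All stochastic components
(generator, subsampling, bootstrap, multi-start optimiser) derive from
explicit seeds; derived seeds are kept below 2³¹.

## Known limitations

* Only the `rr` and `ascii_beats` dialects ship; device formats (WFDB,
  Polar, Suunto, EDF+, Ambit) are extension points via
  `register_reader`.
* No detrended fluctuation analysis or 1/f slope; no Lomb–Scargle or
  windowed spectrograms; no surrogate-data testing.
* Non-linear indices on short recordings (< ~500 beats after
  filtering) are unreliable and frequently NA by design.
* The scaling-region detector assumes the canonical four-regime shape
  of correlation-sum exponent curves; exotic curves yield a flattest
  segment that may not be a true plateau (the fit residual is exposed
  for auditing).
* "Paired T-tests" in the post-hoc stage are unpaired two-sample
  tests: the compared groups are different subjects.
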