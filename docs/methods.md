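# Methods

## Signal model

A time-resolved SC-ICP-MS acquisition is modelled as a sequence of
independent per-dwell detector counts. Background counts are Poisson with
mean λ per dwell (matrix ions, plasma background, continuously dissolved
analyte). A cell that reaches the plasma contributes a short ion transient
— sub-millisecond against a 3-ms dwell — whose expected counts equal the
cell's element mass times a lumped detector sensitivity (counts per fg of
analyte reaching the plasma); the transient's counts are apportioned to
the one or two dwell windows it overlaps and the total per-dwell count is
Poisson around background-plus-signal. Cell arrivals are a homogeneous
Poisson process at rate C_cell · Q · TE, i.e. the aspiration rate thinned
by the transport efficiency.

## Event detection

Detection is the iterative mean-plus-k·σ outlier rejection used across
SP/SC-ICP-MS: estimate background statistics over the dwells not yet
classified as events, flag dwells above mean + k·σ (k = 3 by default),
remove them, repeat until an iteration removes nothing. Two conventions
needed fixing where common usage is loose:

- **σ convention.** The default takes σ = √mean, the Poisson counting
  value — the detector's shot-noise model — rather than the empirical
  sample SD. On genuinely Poisson backgrounds with thousands of dwells the
  two are nearly identical; on short or spike-heavy traces the Poisson
  form is far more robust, because a few massive spikes inflate the sample
  SD so much that the threshold never catches them (on the 10-dwell
  example trace with spikes of 500 and 490 counts over a background of
  ~10, the sample-SD threshold is 720 and rejects nothing). The empirical
  sample SD (n−1 denominator) remains available via `sd_mode="sample"`.
- **Strict inequality.** Dwells strictly *greater* than the threshold are
  removed. A non-strict rule would flag every dwell of a constant trace
  (σ = 0); strictness changes nothing whenever σ > 0 and counts are
  integer-scattered.

Convergence is guaranteed (the background set shrinks monotonically); an
iteration cap of 1000 guards degenerate input and reaching it is an error,
as is a background of fewer than two dwells.

Runs of consecutive above-threshold dwells form one event each;
`merge_gap` permits below-threshold dwells inside a run for long
transients (default 0 — at a 3-ms dwell against sub-ms transients,
multi-dwell events arise only from boundary straddling, which adjacency
merging already handles). Net counts subtract span × background mean and
clip at zero (mass cannot be negative); clipping is recorded on the event.

**False-positive floor.** A one-sided 3σ cut on Poisson counts passes
roughly 0.14–0.35% of pure-background dwells depending on λ and
discreteness. Over a 60-s acquisition at 3 ms (20 000 dwells) this is
~30 spurious single-dwell events, irreducible without changing k. Peak
counts, and therefore pulse-frequency TE estimates, carry this floor; at
the default study conditions (~150 true events) it biases TE upward by
roughly +20%, within the Poisson counting uncertainty of a single
estimate. Spurious events quantify to masses just above the single-cell
LOD and slightly deflate the apparent median mass.

## Transport efficiency

The pulse-frequency estimator divides detected peaks by aspirated cells
C_cell · Q · t_acq (viability-weighted when a Trypan-blue fraction is
given, since the reference concentration counts live cells). Uncertainty
is Poisson on N_peaks, with the hemocytometer replicate scatter (stated
precision < 10%) added in quadrature when replicates are supplied.
Estimates above 1 are clipped with a warning — they indicate inconsistent
inputs, not physics.

The particle-size method compares the dissolved calibration, reduced to
counts per fg *aspirated* per dwell via S / (Q[L/s] · t_dwell · 10⁶), with
the per-particle response in counts per fg *detected*; the ratio is the
transported fraction. The exact formulation follows the standard
Pace-style identity; the unit chain is recorded in the result object.

## Quantification

Calibration is ordinary least squares of counts per dwell against
concentration (ng/L). Internal-standard correction divides analyte counts
by (IS / mean IS over the run) before fitting — a pure drift correction
that is a no-op under a constant IS channel and preserves the slope's
units. The fitted intercept is retained (not forced through zero) so r²
reporting keeps its OLS meaning.

Mass per event is m = net · Q · t_dwell · TE / S, converted to fg with
1 ng = 10⁶ fg; all unit conversions live in one module (`units`) so the
dimensional chain is tested in a single place. Intuition: S/(Q·t·TE) is
the response per unit of mass reaching the plasma, and a detected cell
delivers its whole mass.

LODs use the 3σ convention — 3·SD(blank)/S for dissolved concentrations
(3σ rather than the 3.29σ variant; the field default), and the mass
equivalent of k·σ_background net counts for single-cell events. Cells
below the single-cell mass LOD are counted, never imputed, and excluded
from density estimates.

## Population analysis

Densities are Gaussian KDEs of above-LOD masses on a grid spanning
[0, 1.1 × max], Silverman bandwidth by default, renormalised on the grid
(trapezoid area 1, or peak 1 under `max_one`; area-one is canonical). A
zero-variance sample gets an analytic narrow Gaussian bump (1% of the
value) instead of a failing KDE. Heterogeneity is reported as CV, IQR and
quantiles rather than asserted by a named test; population comparisons
combine the two-sample Kolmogorov–Smirnov statistic with percentile
bootstrap 95% CIs on the median difference and CV ratio, fully
deterministic under a fixed seed.

QC rules: percentage peak-count reduction relative to a reference fixation
condition (negative = gain); cell recovery with a configurable 70%
pass threshold; count stability as |mean(later) − mean(baseline)| ≤
SD(baseline replicates).

## Synthetic data: what it emulates, and what it does not

Defaults are the optimised operating point for fixed THP-1-like cells:
5×10⁵ cells/mL, 0.3 mL/min, 3-ms dwell, 60 s, TE_true 0.1% — giving a
Poisson-mean 150 events per acquisition. Background λ = 2474 counts/dwell
is a measured ²⁴Mg matrix background of a PFA-fixed suspension; its
replicate scatter (± 58 ≈ √2474) is consistent with per-dwell Poisson
counting, which is why it is read as a per-dwell mean. Sensitivity is
200 counts/fg reaching the plasma — equivalent, through the matched
dissolved calibration, to ≈ 1 count/s per ng/L, a typical magnitude for an
abundant light analyte — and per-cell masses are lognormal (median 5 fg,
σ = 0.5), right-skewed as single-cell content distributions are; a
fixed-mass mode (σ = 0) supports exact round trips. Transients default to
0.5 ms so single-dwell events dominate. Leaching is a mass retention
factor per condition; debris adds exponential low-amplitude spikes that
raise the apparent background.

Not represented: plasma physics (ionisation/aerosol effects are one lumped
constant), element-specific interferences, detector dead time, flow or
plasma drift, correlated backgrounds, cell-size/mass correlation with
transport. Passing tests therefore demonstrate the correctness of the
reduction chain under the stated statistical model, not instrument
performance on real suspensions.

Experiment helpers mirror the optimisation designs: `rebin_trace` sums
blocks of dwells to emulate longer integration times (the dwell-time
series shows TE falling and maximum intensity rising with window width);
the concentration series shows event counts proportional to concentration
until coincidence sets in, after which counts fall short and median masses
inflate; the fixation series varies only the retention factor with paired
arrivals (common seed) so reductions are compared like-for-like.

## Numerical and design choices

- Detection is integer-exact and deterministic; event tables round-trip
  through CSV with the background model embedded in the header.
- Trace CSV stores the dwell time in the header at full precision; the
  time column is cosmetic and regenerated on write.
- The pipeline runner fans one top-level seed into every stochastic stage;
  stage reports are pure functions of (inputs, config, seed). The run
  manifest carries the wall-clock timestamp and input digests, kept out of
  the stage reports so those stay byte-reproducible.
- Problem sizes in the test suite and acceptance script: 20 seeds per
  Monte-Carlo claim, 60-s acquisitions (20 000 dwells), 1000 traces for
  the detector-oracle sweep, 200 acquisitions for the arrival-dispersion
  check — large enough that every asserted margin is several Monte-Carlo
  SDs wide, small enough to run in seconds.

## Known limitations

- The pulse-frequency TE inherits the 3σ false-positive floor described
  above; at very dilute suspensions (≲ 10⁵ cells/mL at 60 s) spurious
  peaks dominate true ones and the estimator degrades. Longer acquisitions
  or a blank-corrected peak count are the practical remedies.
- Coincidence is modelled (and flagged) but not corrected; no dead-time or
  split-event recovery is attempted.
- The particle-size method assumes ideal reference particles of exactly
  known mass and identical behaviour to cells.
- Below-LOD masses are excluded, so summary statistics describe the
  detectable subpopulation only; `frac_below_lod` quantifies the censoring.
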