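# Methods

## Model

A clonal telomerase-negative survivor culture is reduced to the dynamics of
one tracked telomere of length `L` (bp) and the culture growth it permits.

**Attrition.** Each population doubling (PD) removes a draw from
Normal(μ, σ) truncated at zero, with defaults μ = 2.7 bp/PD and σ = 0.5
bp/PD for the unperturbed (empty-vector) arm.  Truncation biases the
realized mean upward by < 0.5% even at μ = 1 bp/PD (μ/σ = 2), which is why
parameter-recovery tests at 2% tolerance pass without a truncation
correction.

**HDR re-elongation.** Recombination is permissive only below a critical
length `L_c` (default 120 bp).  While `L < L_c`, an HDR event fires at each
PD with probability `p` (default 0.25); fractional end-of-day PDs scale the
probability proportionally.  A firing event replaces that division's
attrition: type II (probability 0.7) adds a lognormal(5.3, 0.5) bp tract —
median ≈ 200 bp, heavy right tail, modelling heterogeneous TG-repeat
addition — and type I (probability 0.3) adds a fixed 150 bp, modelling a
stereotyped subtelomeric-element acquisition.  Long telomeres never
recombine in this model; event-free trajectories therefore provide clean
"pre-event segments" for rate estimation.

**Growth coupling.** Daily doublings `d(L)` interpolate linearly between
`d_max` = 6.5 PD/day at the senescence-onset length `L_s` = 220 bp and
`d_min` = 1.0 PD/day at `L_c`, clamped at `d_max` above `L_s`.  Below
`L_c`, `d(L)` continues to decline, halving for every further 25 bp of
loss, rather than plateauing at `d_min`.  This keeps the response strictly
increasing in length over the entire senescent range, so on noise-free runs
the day of minimum OD600 is *exactly* the day the telomere is shortest —
the identifiability assumption behind using the potential minimum as a
proxy for maximal telomere shortness.  A flat sub-critical floor would tie
every deeply senescent day at the same OD and make that day ill-defined.
At `L = L_c` the response equals `d_min` exactly.

**Culturing protocol.** Every 24 h the culture is diluted to OD600 0.01 and
regrown; `OD_end = 0.01 · 2^d(L)` times lognormal noise with CV 0.05.
Measured PDs accumulate as log2(OD_end/OD_start), matching how an
experimenter would count them; with zero noise this equals the generative
PD count.  The default propagation is 40 days (~250 PD for a healthy
clone), long enough for at least one full shortening → HDR cycle in the
default arms.

**TERRA.** Expected TERRA fold over the long-telomere baseline follows a
logistic in `L` centred midway between `L_c` and `L_s` (width 25 bp),
rescaled so the fold is exactly 1 at `L ≥ L_s` and exactly 6 at `L ≤ L_c`
(the clamped rescaling, rather than a raw logistic, lets the endpoint folds
be attained exactly, which the recovery tests rely on).  A fold `f` shifts
the target Ct by −log2 f against a reference amplicon at Ct ≈ 17.5 with a
baseline ΔCt of log2(100) ≈ 6.64 (TERRA ≈ 1% of actin mRNA at long
telomeres); both Cts carry independent Gaussian noise (SD 0.15 cycles).

**Gel lanes.** Band centers are a linear through-origin map of length onto
a [0, 1] migration coordinate — ratio-preserving, so relative lengths from
detected positions equal relative lengths from true lengths — jittered by
SD 0.005, rendered as Gaussians (width 0.012) on a small non-negative
background.

**ChIP.** IP and Input signals are generated per genotype × tag × locus
with multiplicative lognormal noise (CV 0.05, the same knob as OD noise);
tagged wild-type percent input is 2%, untagged background 0.2%, and the
survivor/wild-type enrichment ratio defaults to 0.5 at telomeric loci and
1.0 at the actin control.

## Analysis conventions

- **Replicative potential** divides every OD_end by the *day-0* OD_end of
  the reference clone (a single fixed denominator), so the reference's
  first reading maps to exactly 100%; a day-matched variant exists behind a
  flag but is not the default.  Series with missing days are rejected, not
  interpolated — the protocol is strictly daily.
- **SAS statistic.**  Smoothing is a single pass of consecutive-pair
  averaging (a repeat count is available).  "No other value in a
  neighbourhood of four is inferior" is read as four values on *each* side
  (window of 9, `k` exposed as a parameter); "inferior" is strict, so ties
  do not disqualify a candidate but later tied positions within the same
  window or flat run are suppressed, keeping a plateau's earliest
  qualifying position.  Minima in the first 3 days are excluded by default.
  The subjective cross-condition curve-similarity criterion is supported
  only as an explicit `forced` index, never automated.
- **Unmeasurable clones.**  A clone still in decline at the end of the
  observation window has no admissible minimum (the window rule needs `k`
  later values); `run_demo` records it with `pd_to_min = NaN` and excludes
  it from group comparisons rather than failing the cohort.  Under default
  conditions this affects ~2% of clones (those that have not recombined by
  day 40).
- **Rate estimators** operate on the pre-event segment of a trajectory
  (event annotations from the simulator, or a user-supplied cut for real
  data).  The difference-quotient estimator is the mean of per-interval
  ΔL/ΔPD; on equally spaced PDs it telescopes to (first − last)/span.  The
  regression estimator is unweighted OLS with the sign flipped so
  shortening is positive.  Both are invariant to adding a constant to all
  lengths and agree exactly on noise-free lines.
- **Blot-derived lengths stay relative** (normalized to the longest band);
  no bp calibration from migration distance is attempted, because restriction
  fragments include subtelomeric sequence of unknown length.  Absolute
  bp/PD rates are computed from telomere-PCR length tables only.
- **qPCR** assumes perfect doubling (efficiency fixed at 2.0 by default,
  parameterized); replicate averaging happens on the percent scale, after
  the 2^−ΔCt transform.  No-RT controls are validated (flagged when within
  5 cycles of the RT sample) but never subtracted.
- **ChIP** "corrected input" means dilution-factor correction by the input
  fraction (default 5%, i.e. 50 μl of a 1 ml extract; 1/60 for the
  dot-blot convention).  TAP experiments divide tagged by untagged percent
  input per genotype before the fold change to wild-type, making the chain
  invariant to any common calibration factor.  Same-day pairing uses an
  explicit `day` column, falling back to the wild-type mean per locus.

## What passing tests show — and what they do not

The generator reproduces the *statistical structure* the analysis assumes:
gradual per-PD shortening, abrupt re-elongation only below a critical
length, TERRA rising ~6-fold as telomeres shorten, potential fluctuations
of up to ~10-fold (OD ratio 2^6.5/2^1 ≈ 45 at the extremes, larger than
observed fluctuation ranges, which rarely visit both extremes in the same
window), and daily dilution culturing with multiplicative noise.  It does
not emulate: mixed-population masking (every simulated clone is perfectly
clonal), inter-telomere heterogeneity within a cell, type I/type II
competition, plasmid loss, or day-to-day drifts in media quality.  Passing
recovery tests therefore demonstrate correctness of the estimators and
pipeline plumbing under the stated model, not that the model captures every
feature of real survivor cultures.

## Numerical choices and degenerate inputs

- Telomere length is floored at 10 bp (a fully eroded end would be lost).
- Seeds: all stochastic operations accept either an integer or a numpy
  `SeedSequence`; orchestration spawns independent child sequences per
  clone/arm/assay, so outputs are bit-identical for a fixed (config, seed)
  and statistically independent across clones.
- Flat lane profiles, empty groups, zero denominators (reference OD,
  wild-type percent input, untagged signal, control rate), non-positive
  ODs/lengths, duplicate PDs and gappy day series all raise `ValueError`
  with a specific message rather than propagating NaNs.
- Problem sizes in the test-suite and acceptance script (200 recovery
  seeds per rate, 100 cohorts/pairs/clones, 1,000 oracle series) were
  chosen to keep Monte-Carlo error well inside the asserted tolerances
  while the whole suite runs in seconds.

## Known limitations

- The HDR hazard is a constant per-PD probability below a hard threshold;
  a deficit-dependent hazard would be more biological but is not
  identifiable from the data the pipeline consumes.
- The TERRA/length and growth/length response shapes (logistic, piecewise
  linear) are conventions anchored only at their endpoints; intermediate
  curvature is not constrained by any measurement in scope.
- `percent_reference` treats amplification efficiency as exactly 2 unless
  told otherwise; standard-curve fitting is out of scope.
- The SAS window statistic is sensitive to `k` near series boundaries: a
  minimum within `k` days of the end of propagation is undetectable by
  construction (see "Unmeasurable clones").
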