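# Methods

## Model and assumptions

The analysis rests on the spectral-compression model of myoelectric
fatigue: during sustained effort, muscle-fiber conduction velocity falls
and motor-unit synchronization rises, shifting the sEMG power spectrum
toward lower frequencies. The median frequency (MDF) of the spectrum is
the standard summary; its decline over time, quantified as the slope of a
linear regression of per-cycle MDF on time, is the fatigue index. A
negative slope indicates accumulating fatigue. The analysis assumes the
sEMG is approximately stationary *within* one stroke cycle (~2 s) and that
spectral change accumulates slowly *across* cycles — which is why the
signal is cut at kinematic cycle boundaries before spectral estimation.

Stroke cycles are delimited by minima of the knee flexion angle: the knee
is most flexed at the catch, so consecutive minima bracket exactly one
drive-plus-recovery cycle. The angle comes either directly or from the
hip–ankle marker distance via the law of cosines over the thigh (L1) and
shank (L2) segments; on the open interval (|L1−L2|, L1+L2) the angle is
strictly increasing in the distance, so distance minima and angle minima
coincide.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `band_low`, `band_high` | 20, 500 Hz | physiological sEMG band; Butterworth band-pass edges |
| `filter_order` | 4 | Butterworth order; applied forward–backward (zero net phase, doubled effective attenuation) |
| `wavelet_name` | `db4` | orthogonal Daubechies-4 mother wavelet |
| `decomposition_depth` | `auto` | smallest J with the approximation band ≤ `band_low`; J = 7 at 4 kHz (A7 covers 0–15.6 Hz, so 20–500 Hz spans details D3–D7). Explicit depths ≥ 4 are accepted; depth 4 reproduces the coarser D1–D4 layout |
| `stroke_rate_hint` | 30 strokes/min | expected pace; sets the smoothing window (0.1 × period) and minimum minima separation (0.5 × period) for boundary detection |
| `regression_time_base` | `seconds` | regress MDF on cycle mid-times (Hz/s) or on cycle index (Hz/cycle). At a steady 2 s stroke, slope/cycle = 2 × slope/s |
| `alpha` | 0.05 | significance level of all cohort tests |

## Numerical choices

- **DWT extension and length.** Periodization extension; each segment is
  truncated to a multiple of 2^J samples (< 32 ms of a ~2 s cycle at
  J = 7) so the periodized DWT is exactly orthogonal and coefficient
  energy equals sample energy to machine precision. Inverse
  reconstruction is provided and round-trips to < 1e−8 relative; it is a
  correctness check, not a pipeline stage — MDF is computed from
  coefficients.
- **Sub-band spectrum and MDF interpolation.** Band power of level j is
  the summed squared coefficients divided by segment length; bands carry
  their nominal dyadic ranges. The MDF interpolates linearly inside the
  band where cumulative power crosses half the total (uniform-power
  assumption). Dyadic bands are wide (125–250 Hz around a typical MDF), so
  an edge or center convention would quantize MDF and mask small
  per-cycle drifts; linear interpolation keeps the estimator responsive,
  at the cost of a smooth, spectrum-shape-dependent bias that is nearly
  constant over a trial and therefore largely cancels in the slope.
- **Boundary detection.** Minima are found on a zero-phase moving-average
  copy of the angle; indices refer to the unsmoothed trace. Two candidates
  closer than half a period resolve to the deeper one (ties: earlier).
  Endpoint samples count as minima when the smoothed trace rises away from
  them, so an integer number of cycles yields ⌊duration/period⌋ + 1
  boundaries and every retained segment is a complete cycle; partial
  cycles outside the first/last minimum are discarded.
- **Constant MDF series.** The regression's R² is 0/0 for a constant
  series; it is reported as 0 (no variance to explain), with slope 0.
- **Score rounding.** Proportional scores round to the nearest integer,
  half away from zero — the convention that reproduces the published
  score tables on both performance measures (one published torque cell is
  inconsistent with any nearest-integer rounding and is not used as a
  reference).
- **Degenerate inputs.** Zero-power cycles are dropped and logged; trials
  with < 3 cycles are excluded (OLS needs 3 points); non-finite samples
  reject the file rather than being imputed, since silent imputation would
  bias spectra; an exact dominant-leg tie is flagged indeterminate.

## The synthetic generator

`synthetic` emulates the paced-trial structure the analysis assumes, with
defaults matching the study conditions: 4 kHz sampling, 30 strokes/min,
300 s trials, six bilateral channels (L/R × GAS, RF, BF), knee angle
oscillating 60–170° with smooth 1° jitter, MDF starting at 120 Hz and
drifting at −0.05 Hz/s.

- **Per-cycle stationary synthesis.** Each cycle is an independent
  stationary Gaussian segment whose one-sided spectral median equals the
  programmed `mdf_start + mdf_drift · t_mid`. This matches the per-cycle
  MDF estimand exactly, making drift recovery a well-posed oracle, and is
  the reason the module exists.
- **Spectral shaping.** FFT-domain amplitude mask with a lognormal
  (Gaussian-in-log-f) power profile of log-width 0.3; the median of a
  lognormal is its log-center, so the target median is analytic, no
  iteration. The profile spans roughly 65–220 Hz around a 120 Hz center —
  a realistic sEMG bandwidth; essentially no mass falls outside 20–500 Hz,
  so band-passing does not move the median.
- **Activation envelope.** A raised-cosine envelope phase-locked to the
  stroke (trough at the catch, depth 0.5) modulates the amplitude;
  additive white noise at 2% relative amplitude emulates the recording
  floor. Both have negligible effect on the spectral median.
- **Angle jitter.** Gaussian-low-passed noise (kernel sd 0.1 × period)
  rescaled to the requested sd: smooth enough not to create spurious
  minima, broad enough to perturb minima timing. At 1° sd the detected
  cycle-duration spread stays well inside the ±0.082 s reported for real
  strokes.
- **Seeding.** One master seed; channel × cycle substreams are derived
  deterministically, so channels are independent but reproducible.
- **Cohorts.** `generate_cohort` draws 1000 m times and per-leg torque
  triples uniformly inside the envelopes of the published cohort tables.
  `generate_cohort_slopes` draws per-participant fatigue indices from one
  common normal distribution (−0.05 ± 0.02 Hz/s, 18 indices = 6 muscles ×
  3 trials) — the homogeneous null under which the cohort ANOVA's type-I
  rate is checked. Simulating the null at the fatigue-index level is the
  package's design choice: it isolates the statistical claim from the
  (separately validated) signal chain and makes hundreds of cohort
  replicates affordable; the full EMG→slope chain is validated once by the
  drift-recovery study.

**What the generator does not emulate:** motor-unit action-potential
trains (no physiological interference model), electrode crosstalk and
shift, movement artifacts, mains hum, inter-muscle correlation, or
nonlinear/stepwise fatigue dynamics. Passing tests therefore demonstrate
that the pipeline correctly extracts a linear spectral drift from cyclic
colored noise under realistic pacing — not that real recordings satisfy
the linear-drift model.

## Problem sizes

The validation studies use one 300 s single-channel trial per seed for
drift recovery (5 seeds per drift level −0.10/−0.05/−0.02 Hz/s, 20 seeds
at zero drift), 100 random segments for the transform and oracle checks,
and 200 simulated 8-participant cohorts for the ANOVA type-I study —
sizes at which every estimate's sampling error is comfortably below the
tolerance being asserted.

## Known limitations

- Dyadic sub-band MDF is a coarse spectral estimator; its absolute value
  carries a spectrum-shape-dependent bias of a few Hz relative to a
  periodogram median (always within one dyadic band). Slopes are much less
  affected but can be mildly attenuated for large drifts that cross band
  edges (~14% observed at −0.10 Hz/s, within the 20% validation band).
- The slope's units depend on the time base; Hz/s is the default, and
  published per-participant slope values of unstated units cannot be
  compared numerically without the raw recordings.
- One segmentation per trial is applied to all six channels; per-leg
  segmentation (if the legs desynchronize) is not modeled.
- Trials are pooled at whatever length they were recorded; no truncation
  to a common duration.
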