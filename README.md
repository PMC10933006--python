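# ergofatigue

Quantifies muscle fatigue from multichannel surface EMG (sEMG) recorded
during paced rowing-ergometer exercise. The package is aimed at biomedical
signal-processing researchers and sports scientists who want a tested,
scriptable version of the classic spectral-compression fatigue analysis:
as a muscle fatigues, the power spectrum of its sEMG shifts toward lower
frequencies, so the median frequency (MDF) of each stroke cycle declines
over the trial, and the slope of that decline is a per-muscle fatigue
index.

## The analysis

1. **Kinematic segmentation.** The knee flexion angle is computed from
   marker geometry by the law of cosines,
   `α = arccos((L1² + L2² − D²) / (2·L1·L2))`, with `L1` the hip–knee and
   `L2` the knee–ankle segment length and `D(t)` the hip–ankle marker
   distance. Local minima of `α(t)` (the catch position, once per stroke at
   30 strokes/min ⇒ ~2 s cycles) delimit complete stroke cycles.
2. **Band-limiting.** Each EMG channel is band-passed to the physiological
   20–500 Hz band with a zero-phase Butterworth filter.
3. **Wavelet MDF.** Each ~2 s cycle is decomposed with the Daubechies-4
   discrete wavelet transform; summed squared coefficients per level give a
   dyadic sub-band power spectrum, and the MDF is the frequency splitting
   that spectrum into equal-power halves (linear interpolation inside the
   straddling band).
4. **Fatigue index.** Ordinary least squares of MDF on cycle mid-time; the
   slope (Hz/s, negative under fatigue) is the fatigue index of one
   muscle × trial. Indices pool per participant as median ± IQR.
5. **Cohort statistics.** Proportional 0–100 scoring of 1000 m times and
   dominant-leg torques (best = 100, worst = 0), dominant-leg determination
   from isokinetic knee-extension torques at 30°/60°/90°, Shapiro-Wilk
   normality, Mann-Whitney dominant vs non-dominant comparison, and
   one-way ANOVA of fatigue across performance-score groups.

A synthetic-data module generates trials with exactly this structure —
cyclic knee kinematics plus EMG-band colored noise whose spectral median
drifts linearly — so every stage is testable without recordings, and the
pipeline's ability to recover a known drift can be measured.

## Worked example

```python
import ergofatigue as ef

spec = ef.SyntheticTrialSpec(duration=300.0, mdf_start=120.0,
                             mdf_drift=-0.05, seed=1)
angle = ef.generate_angle_trace(spec)     # knee angle, 30 strokes/min
emg = ef.generate_emg(spec)               # 6 channels, 4 kHz, drifting MDF
indices = ef.analyze_trial(emg, angle)    # filter -> segment -> DWT-MDF -> OLS
ix = indices[0]
print(f"{ix.channel}: slope {ix.slope:+.4f} Hz/s over {ix.n_cycles} cycles "
      f"(r^2 = {ix.r_squared:.2f})")
```

prints

```
L_GAS: slope -0.0453 Hz/s over 150 cycles (r^2 = 0.58)
```

The injected spectral drift was −0.05 Hz/s; the pipeline recovers
−0.0453 Hz/s from 150 detected stroke cycles. The negative sign is the
fatigue signature: over the 5-minute trial the gastrocnemius MDF fell by
roughly 0.05 Hz every second (~14 Hz in total).

The same analysis runs from the shell:

```sh
ergofatigue synth --out-dir trial --duration 300 --mdf-drift -0.05 --seed 1
ergofatigue run --emg trial/emg.csv --angle trial/angle.csv --out-dir results
ergofatigue report --results-dir results
```

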