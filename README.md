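# fnirsgait

An ambulatory fNIRS analysis pipeline for freezing-of-gait studies in
Parkinson's disease: from raw dual-wavelength intensities and head/body
kinematics to confound-corrected haemoglobin signals, gait/freeze event
tables, baseline-corrected region-of-interest (ROI) epochs and Bayesian
hierarchical model summaries.

Measuring cortical haemodynamics while people actually walk is what
makes fNIRS attractive for studying freezing of gait — and what makes it
treacherous. Walking changes heart rate, blood pressure and breathing
(systemic confounds that appear in the optical signal both intra- and
extracerebrally), head movements decouple optodes from the scalp (spikes
and baseline shifts), and changes in head position shift local blood
flow (slow, indirect artifacts). A freezing episode is itself a
cardiovascular event: a heart-rate surge time-locked to freezing can
masquerade as "prefrontal activation during freezing" if left
uncorrected. This package implements the full correction chain and ships
a synthetic-session generator with complete ground truth, so every stage
is validated against construction rather than convention.

## What the pipeline does

For each run (~6.5 min of corridor walking with doorway passages, 180°
turns, instructed 30 s stops and freezing episodes):

1. **I/O & alignment** — SNIRF-style HDF5 or TSV recordings (2
   wavelengths, 32 long/30 mm + 16 short/10 mm channels at 50 Hz), 60 Hz
   kinematics, BIDS-style events tables; offline stream alignment from
   known sync offsets.
2. **Preprocessing** — resample 50→60 Hz; prune channels whose signal
   quality index is < 2 for > 50 % of standing time; convert to optical
   density; correct direct motion artifacts by spline interpolation
   (stdv threshold 65, amplitude threshold 0.05, tMotion 0.5 s, tMask
   1 s) and wavelet coefficient clipping (IQR 0.8); convert to ΔHbO/ΔHbR
   via the modified Beer–Lambert law with an age- and
   wavelength-dependent differential pathlength factor.
3. **Confound regression** — 0.5 Hz low-pass (3rd-order Butterworth,
   zero-phase) on fNIRS and movement data; OLS per long channel on the
   first 8 principal components of the pooled short channels (> 90 % of
   their variance) plus nine z-transformed head regressors
   (acceleration, angular acceleration, head-relative-to-neck
   orientation). Residuals carry forward.
4. **Spectral normalisation** — 0.01 Hz high-pass (2nd order), 0.1 Hz
   low-pass (6th order), then z-transform per channel and run.
5. **Events** — two raters' freeze annotations merged by union within a
   2 s tolerance (non-matches surfaced as disputed); positive/negative
   agreement and prevalence index; kinematic detection of stops, starts,
   turns and doorway passages; 10 s refractory/clearance selection
   rules; % time frozen; walking-speed statistics.
6. **Epochs & models** — baseline-corrected window means (0–3 s after
   onset; 7–10 s for stops/starts; baseline −10…−5 s), ROI averaging,
   and three Gaussian hierarchical linear mixed models:

   * `group`: value ~ 1 + group(sum-coded) + (1 | participant)
   * `condition`: value ~ 1 + condition(freeze/stop/successful,
     sum-coded) + (1 + condition | participant)
   * `severity`: value ~ 1 + %-time-frozen + motor score (standardised)
     + (1 | participant)

   Posteriors are sampled by a blocked Gibbs sampler (joint Gaussian
   draws for all location parameters, slice steps for the half-normal sd
   priors), with 95 %/99 % credibility intervals, per-channel activity
   maps with star classification, R-hat and effective sample size.

Sum-contrast convention: the group coefficient is the deviation of the
PD group from the grand mean, so the PD−HC difference equals twice the
coefficient; summaries report both.

## Worked example

```bash
python analysis/03_confound_ablation.py 1
```

generates a session whose freezes carry a heart-rate-like scalp HbO
surge, runs the pipeline with and without confound regression, and
prints:

```
event-locked RMSE (µM): corrected 0.118, uncorrected 0.402 -> 71% reduction
freeze-epoch deflection: uncorrected +0.486, corrected -0.012 -> 98% suppressed
PFC freeze-stop contrast: uncorrected +0.784, corrected +0.155
```

Read: without short-channel/kinematic regression the freeze epochs show
a spurious global positive ΔHbO deflection (+0.49 µM — the systemic
surge, not cortex); the regression suppresses it by 98 % and roughly
triples the accuracy of event-locked response recovery. The numbered
scripts `analysis/01…05` walk through cohort simulation, preprocessing,
the ablation, event bookkeeping and the hierarchical models, each
writing its tables under `results/`.

The same stages are scriptable from the shell:

```bash
fnirsgait run-all --out results/pipeline --seed 1 --config configs/default.yaml
fnirsgait synth --out scratch/demo --seed 1 --n-runs 1
fnirsgait preprocess --session-dir scratch/demo --run-id run-01
fnirsgait denoise --session-dir scratch/demo --run-id run-01 --no-motion
```

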