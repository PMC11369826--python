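# Methods

This note documents the models and procedures implemented in
`fnirsgait`, the synthetic forward model used to validate them, the
numerical choices made where the design was genuinely open, and what
the validation does and does not establish.

## Signal model and correction chain

A continuous-wave fNIRS channel measures light attenuation at two
wavelengths (760/850 nm). Optical density is defined per measurement
row as OD(t) = −log10(I(t)/mean(I)). The modified Beer–Lambert law
relates OD changes to chromophore concentration changes,

    ΔOD(λ) = d · DPF(λ, age) · [ε_HbO(λ) ΔHbO + ε_HbR(λ) ΔHbR],

with source–detector distance d (3.0 cm long channels, 1.0 cm short
channels), extinction coefficients ε in 1/(mM·cm) from the standard
compiled haemoglobin spectra (shipped in
`src/fnirsgait/data/extinction_coefficients.csv` with provenance note),
and the differential pathlength factor from the published general
equation in age and wavelength,

    DPF = 223.3 + 0.05624·A^0.8493 − 5.723e−7·λ³ + 0.001245·λ² − 0.9025·λ.

The 2×2 system is solved per channel; the inversion is exact (the
round-trip test recovers µM inputs to < 1e−10).

The correction chain is ordered resample → prune → OD → spline →
wavelet → MBLL → low-pass → confound regression → band-pass → z-score.
Every stage is a pure function of its input recording.

**Channel pruning.** The decision rule is: prune a channel whose
signal quality index (SQI, 1–4 scale) is below 2 for more than half of
the standing-still time. The SQI itself is pluggable; the default
scorer maps the prominence of the cardiac spectral peak (maximum
periodogram power in 0.5–2.5 Hz over the median power in 0.25–5 Hz,
per 5 s window) through 1 + 3·clip((log10 ratio − 0.5)/1, 0, 1). A
coupled optode shows a sharp cardiac line and scores ≥ 3; a decoupled
optode measuring broadband noise scores ≈ 1. Pruning records a mask;
data are never deleted.

**Spline correction** targets direct artifacts (optode decoupling).
Samples are flagged when the local signal range within a 0.5 s window
exceeds either 65 × the channel's sample-to-sample standard deviation
or 0.05 OD; flags are extended by 1 s. Each flagged segment is replaced
by its residual about a closely-following cubic smoothing spline
(MATLAB-style p = 0.99, i.e. roughness weight λ = (1−p)/(6p) on the
unit sample grid) and re-levelled to the mean of the adjacent 2 s of
clean data. Unflagged samples are returned bit-identical — an
intentional contract that keeps the correction auditable.

**Wavelet correction** (db2, full decomposition) zeroes detail
coefficients outside [Q1 − 0.8·IQR, Q3 + 0.8·IQR] per level. Levels
with fewer than 32 coefficients — the slow-drift scales — are left
untouched: quartiles of a handful of coefficients are not robust, and
motion spikes carry no energy there. On Gaussian noise the rule retains
≈ 92 % of coefficients and removes ≈ 38 % of variance (the clipped-tail
second moment, 2(aφ(a)+Q(a)) at a ≈ 1.75); on spikes it removes ≥ 80 %
of the amplitude.

**Confound regression** is the pipeline's central step. Long-channel
concentrations and all regressors are low-passed at 0.5 Hz (3rd-order
Butterworth, zero-phase — single-pass magnitudes therefore apply
twice). The regressors are (i) the first k = 8 principal-component
scores of the pooled, z-transformed short-channel HbO and HbR rows and
(ii) nine z-transformed head series: acceleration (3), angular
acceleration (3) and head-relative-to-neck orientation (3), the last
included because participants look down around turns, stops, doorways
and freezes. OLS is fitted per run with an intercept; the dependent
variable is left in concentration units (only the regressors are
z-transformed); residuals are orthogonal to every regressor column by
construction. Both regressor families can be ablated independently to
reproduce the correction comparison. Time-lagged motion regressors and
direct cardiorespiratory reference signals are out of scope.

**Spectral normalisation.** 0.01 Hz high-pass (2nd order) and 0.1 Hz
low-pass (6th order), zero-phase; records shorter than two high-pass
periods are rejected rather than silently filtered. Fixed cut-offs are
used for reproducibility; per-participant spectrum-guided tuning is
deliberately not implemented. z-scores are computed per channel and
run; zero-variance channels are masked with a warning, never divided.

## Events

Freeze annotations from two raters are merged by interval union when
they lie within a 2 s tolerance ("include" correction); clusters seen
by only one rater are surfaced as disputed for manual resolution.
Agreement is computed on a sampled timeline (default 1 Hz): with
per-sample counts n11/n10/n01/n00, positive agreement =
2n11/(2n11+n10+n01), negative agreement = 2n00/(2n00+n10+n01),
prevalence index = (n11−n00)/N. The sampled definition is stated
explicitly so the metrics are well-defined; the sampling rate is
configurable. With no freezing marked by either rater, positive
agreement is undefined and reported as NaN with a note.

Kinematic definitions (the main text of gait protocols rarely pins
these down; the defaults here are explicit stand-ins): a stop starts
when velocity stays below 0.1 m/s for ≥ 2 s, with the onset refined
back to the half-cruise-speed crossing of the braking ramp; a start is
the symmetric rising crossing; a turn is a yaw angular speed above
30°/s inside a turning square (yaw rate is integrated from head angular
acceleration and detrended against integration drift); a doorway event
is the position trace crossing the door plane. Selection rules: a
freeze is analysed only when no earlier freeze ended within 10 s before
its onset; a successful gait event only when no freeze intersects
±10 s. Freezes inherit the trigger of the nearest detected event within
5 s (approaching stops → "destination"), else "walking". % time frozen
is the union length of freeze intervals over the task duration.

## Hierarchical models

All three models are Gaussian linear mixed models on baseline-corrected
window means: y = Xβ + Zu + ε, u ~ N(0, σ_j² I) per random term,
ε ~ N(0, σ²). Fixed effects carry flat (improper) priors; every
standard-deviation component carries a half-normal(1) prior — "flat"
alone is not samplable for variances, and half-normal(1) is weakly
informative on the z-scored response scale (the scale is a parameter;
the OLS-limit test uses half-normal(100)). Condition uses sum contrasts
over freeze/stop/successful with a participant random intercept and a
shared-variance random slope for the two contrast columns.

Sampling is by a blocked Gibbs sampler: all location parameters (β and
every u) are drawn jointly from their exact Gaussian conditional
(Cholesky of the (p+q)×(p+q) posterior precision), and each sd is
updated by univariate slice sampling on the log scale. The joint
location draw removes the intercept–random-effect random-walk that
plagues single-site updates; effective sample sizes are near the draw
count. Four chains (default 1000 draws after 500 warm-up; the pipeline
driver uses 600/300) are summarised by posterior means, 95 %/99 %
quantile credibility intervals, exclusion-of-zero flags, R-hat and ESS
via ArviZ; R-hat > 1.01 triggers a warning (an error in strict mode).
The contract is on the posterior, not the sampler: fixed-effect
estimates match an independent REML mixed-model fit, simulation
coverage of the 95 % CrI is nominal, and sparse participants shrink
harder toward the group mean than dense ones — all asserted in tests.
Contrasts are computed on draws, never refit. Channel maps fit one
model per channel and classify stars (none/95/99) by CrI exclusion;
under a null simulation ≈ 5 % of channels star at the 95 level.

## The synthetic forward model

The generator lays out the corridor protocol deterministically: runs of
390 s with 60 s initial quiet standing, ~20 s walking legs between a
doorway and two turning squares, an instructed 30 s stop every 2.5
corridor lengths (with a mid-stop turn-around at squares), turn
directions alternating between squares and switching after each stop.
Freezes attach to triggers with per-trigger Bernoulli rates (turn 0.33,
doorway 0.17, destination 0.30, start 0.08, plus a small
per-walking-second rate), chosen so a freezer produces a median of
~15 episodes over four runs with the trigger mix weighted toward turns;
durations are log-normal with median 3.8 s (σ_log = 0.6, capped at
20 s). Rater A jitters true boundaries by ~0.2 s; rater B is rater A
jittered within the merge tolerance and misses 5 % of episodes.

Kinematics replay the schedule's state machine: position advances only
during moving samples (so a freeze pauses progression yet landmark
arrivals stay on schedule), yaw rotates 180° per turn (deferred past
any overlapping freeze), the head pitches down ~10° around turns,
stops, doorways and freezes, and stride oscillations scale with speed.
PD participants walk slower than controls (0.95 vs 1.09 m/s group
means).

Each long channel's HbO is: HRF-convolved event responses (canonical
double gamma, peak 6 s, undershoot 16 s, ratio 1/6, each event's
regressor peak-normalised) scaled by a per-(condition, ROI) µM
amplitude table; plus a 0.6 share of the scalp systemic signal; plus a
pitch-coupled indirect artifact (~0.02 µM/deg). Short channels receive
the full systemic signal and half the pitch coupling but no neural
term — a construction invariant the tests assert. HbR is −1/3 × HbO.
The systemic signal is spatially rank-8: two smoothed random-walk
drifts and quadrature pairs at the Mayer (0.1 Hz), respiratory
(0.25 Hz) and cardiac (1.2 Hz) frequencies with wandering phase,
amplitude-profiled so drifts dominate (relative scales
1.0/0.7/0.5/0.3/0.25) — large slow blood-pressure drifts with a small
cardiac line is what walking scalp physiology looks like in OD terms,
and it keeps cardiac oscillations (~0.007 OD) well below the spline's
0.05 OD amplitude threshold. The overall scale (1.5 µM per channel sd
unit) is calibrated, as the design intends, so that an uncorrected
pipeline is visibly biased while the corrected one is not. The optional
freeze-locked surge — a gamma-shaped bump peaking ~3 s after each
freeze onset, riding on the (all-positive) cardiac spatial loading so
the total spatial rank stays 8 — reproduces the cardiovascular confound
that historically produced reports of prefrontal increases during
freezing; the correction-comparison experiments enable it at 2.5 µM.
Direct artifacts are OD-domain spikes (0.3–1 s, 0.05–0.15 OD) and
transient baseline shifts (0.02–0.05 OD, 10–30 s) on a random 20 % of
channels at turns/freezes. Forward MBLL (same coefficients as the
inverse) maps concentrations to OD; white OD noise (σ = 1.5e−3) and
per-row intensity scales complete I = I0 · 10^(−OD).

### What recovery means here

With the canonical HRF peaking at 6 s, the 0–3 s analysis window
captures only the initial rise, and the −10…−5 s baseline contains
tails of responses to events ~20 s earlier; the 0.01–0.1 Hz band then
reshapes the strongly periodic task structure. Epoch values therefore
measure the *processed* event-locked response, not the amplitude table
directly. Recovery experiments consequently compare pipeline estimates
against the generator's clean neural signal passed through the same
linear filters — an apples-to-apples reference that isolates confound
leakage from shared processing attenuation. The residual corrected
error is dominated by the wavelet step's interaction with mid-band
systemic rhythms, not by surge leakage.

### Problem sizes

Validation runs are sized to what the checks need, as this package's
own choice: parameter-recovery and ablation experiments use one session
of 1–3 runs; model calibration uses 50 replicates of 20 participants ×
30 events; the null channel-map rate uses 64 per-channel fits; the
end-to-end driver simulates a 3+3-participant cohort with the full
4-run protocol.

## Known limitations

* The generator is a signal-level emulation: no photon transport, no
  biomechanical gait model, no OFF-state medication dynamics, no
  trembling-vs-akinetic phenotypes. Passing tests certify the
  *pipeline's* behaviour on signals with the stated confound structure,
  not clinical conclusions about real cohorts.
* Indirect movement artifacts are modelled (and corrected) as
  instantaneous functions of head orientation; lagged haemodynamic
  coupling is neither generated nor regressed.
* The SQI is a stand-in scorer implementing the published decision
  rule's interface; a different index can be slotted in without
  touching the pruning logic.
* Agreement metrics use a sampled-timeline definition; per-interval
  matching tools can give slightly different numbers on the same
  annotations.
* Whether spline/wavelet run on OD or concentration is a convention;
  they run on OD here (before MBLL), which is where decoupling
  artifacts are generated.
* HbR is carried through every stage but never modelled statistically.
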