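# Methods

## The paradigm model

A cue-based run is generated by integrating the angular-velocity law
ω(t) = 90/T_ITI + A·sin(2π·a_base·t)·sin(2π·a_mod·t + φ) (deg/s) on a
1 ms grid with cumulative trapezoids, starting after a 1.5 s static
hold.  Cues fall where the cumulative angle crosses multiples of the
90° cross-symmetry angle; crossing times are linearly interpolated
between grid points.  Halving the grid step moves cue times by well
under 1 ms (convergence is tested).  Defaults T_ITI = 3.3 s,
A = 10.24 °/s, a_base = 0.032 Hz, a_mod = 0.016 Hz, φ = 28.1.

Two conventions were genuinely open:

- **φ units.** Interpreted as radians.  Radians place the minimum and
  maximum inter-trial interval at 2.51 / 4.75 s; degrees give
  2.44 / 4.97 s.  The radian reading is internally consistent with the
  rest of the schedule statistics and is used throughout.
- **Initial tilt.** The 10° starting offset of the rotating cross is
  taken in the direction that makes the first overlap occur after 80°
  of rotation (~3 s), giving the participant preparation time; the
  alternative reading would cue ~0.4 s after rotation start.  Run
  duration counts the static hold plus rotation up to the fade-out
  point 10° before the would-be 101st overlap (335.1 s for 100 trials).
  Inter-trial intervals are the 99 intervals between consecutive cues;
  the interval from rotation start to the first cue is not an ITI.

## The synthetic recording model

One simulated subject is described by `SubjectModel`: an MRCP waveform
per condition, per-channel spatial weights, an EOG-to-EEG coupling
matrix, noise and oscillation amplitudes, and movement-timing
parameters.  All randomness flows from one integer seed; identical
seeds give bit-identical recordings.

- **MRCP template**: monotone-cubic curve through (−2 s, 0),
  (0, −5 µV), (+0.6 s, +3 µV), (+2 s, 0) — a pre-onset negativity
  peaking at the kinematic onset followed by a positive rebound.
  Spatial weights peak at C1/Cz/C3 (contralateral to a right-hand
  movement) and fall off peripherally.  Amplitude, lag and both
  condition templates are configurable per subject.
- **Background**: 1/f-shaped Gaussian noise (amplitude ∝ f^−0.5 above
  0.1 Hz), default 10 µV RMS per channel, plus band-limited 8–12 Hz and
  18–22 Hz oscillations at 0.2 × the noise RMS each.  Around each
  movement the oscillation envelopes dip by `erd_depth` (from 1 s
  before onset until the movement end; raised-cosine ramps), and the
  beta envelope rebounds by 0.5 × `erd_depth` for 1 s after the
  movement — yielding the classical ERD/beta-rebound pattern, strongest
  over motor channels.
- **Ocular activity**: four EOG channels carry sensor noise, slow
  independent electrode drift (the component that makes the coupling
  matrix identifiable — gaze steps alone are nearly collinear across
  channels), spontaneous blinks (~8/min) and gaze steps; the
  eye-calibration run adds 10 s blocks of horizontal saccades, vertical
  saccades, blinks and rest.  EEG receives `coupling @ EOG`, strongest
  frontally.
- **Motion**: each movement is two raised-cosine speed pulses (flexion
  and return, width 0.25 s, peak 1 unit/s) separated by the 0.5 s hold,
  integrated to a 30 Hz position trace with 3·10⁻⁴ units of tracking
  noise.
- **Timing**: cued movements follow their cue by a Gaussian delay
  (mean 95 ms, SD 151 ms), truncated at ±3 SD to keep each movement in
  its trial.  The self-paced timeline alternates bursts (within-burst
  gaps ~N(3.6, 0.65²) s, ~24 movements per burst) with ~10 s pauses,
  giving a long-run mean ITI ≈ 3.9 s with SD ≈ 1.4 s.

What the generator deliberately does **not** model: volume conduction
from a head model (channels carry independent noise plus rank-limited
signal), non-stationary impedance drifts, muscle artifacts, realistic
saccade main-sequence dynamics, or any cue-locked visual potential.
Tests passing on this generator therefore certify the pipeline's
correctness and calibration on data satisfying its own assumptions, not
decoding performance on real EEG.

## Preprocessing

Band-pass 0.5–70 Hz, then EOG removal, then 3.5 Hz low-pass with
decimation to 10 Hz, then common-average reference — the last step only
for decoding features; waveform and time-frequency analyses use
unreferenced signals.  All filters are 4th-order Butterworth applied
forward-backward: the offline analyses are time-locked and causal
filtering would shift MRCP latencies.  The 3.5 Hz low-pass is itself the
anti-alias filter for the 50× decimation (Nyquist 5 Hz).  EOG removal is
a least-squares regression of each EEG channel on the four EOG channels,
fitted on the band-passed eye-calibration run and applied as a fixed
linear operator; no intercept is fitted because the signals are
band-passed (zero-mean), which also keeps the whole chain linear.

## Onset labeling

Finger speed is computed from central differences evaluated at
inter-sample midpoints (`(x[i+1] − x[i]) · rate` at time (i+½)/rate),
which keeps the estimate causal to within half a sample — a 3-point
stencil would leak movement energy one sample early and bias onsets
~25 ms early.  The threshold is adaptive: mean + 5 SD of the speed
inside the lowest-activity quartile of 1 s windows (a rest estimate).
An upward crossing must persist one extra sample (single-sample tracking
glitches otherwise pair with genuine crossings).  Crossings pair when
the second follows within 1.5 s; the first crossing of a pair is the
onset, isolated crossings emit nothing, and onsets within 1 s of the
previous one are suppressed.  The detector's residual deterministic
offset (interpolation across the onset corner plus threshold rise time,
net ≈ −5 ms at default settings) can be quantified at run time with
`crossing_latency`, which simulates the canonical pulse over sampling
phases and noise draws; the acceptance script subtracts it so the
reported delay statistics estimate movement timing rather than detector
latency.

## Decoding

Windows stack the last `n_window` 10 Hz feature samples of all 60
channels; exactly the window ending nearest `onset + d` is labeled
*movement*, every other window *no movement* (single-sample labels; no
exclusion zone around onsets).  The LDA uses the pooled within-class
covariance shrunk by closed-form Ledoit–Wolf linear shrinkage towards a
scaled identity (default) or the quadratic-inverse shrinkage (QIS)
nonlinear estimator — both CV-free.  Scores are posterior probabilities
under the shared-covariance Gaussian model.  `n_window` and `d` are
selected on a grid ({3..20} samples × {0, 0.1, …, 0.5} s by default;
the orchestrated experiment uses a condensed grid, n_window ∈
{5, 8, 10, 12, 15}, d ∈ {0–0.3}, to stay interactive) by run-wise
3-fold CV: train on one cue-based run, test on the pooled other two,
score the 0.5-thresholded posteriors sample-by-sample with MCC, average
over folds, break ties towards smaller `n_window` then smaller `d`, and
refit on all three runs.

## Evaluation

Event scoring follows the asymmetric [−0.5, +1] s hit window: the first
detection inside an onset's window is a hit, later detections in the
same window are ignored, detections outside every window are false
positives, FP/min divides by the full run duration.  When hit windows
overlap, a detection claims the nearest still-unclaimed eligible onset.
Detections are score threshold crossings with a 1 s refractory period.
The threshold is calibrated on the self-paced run itself — faithful to
the protocol being modeled, but optimistic, since the evaluation data
tunes one free parameter; calibrating on a held-out cue-based run is
possible by passing that run's scores instead.  By construction the
calibrated TPR is non-decreasing in the FP/min budget.

## Neural-correlate analyses

MRCP comparison: Mann–Whitney U per channel and time sample on ±1 s
epochs (exact null for small tie-free samples, midrank-corrected normal
approximation otherwise), Bonferroni-corrected over the full
channels × samples family — the conservative reading of "corrected for
multiple comparisons".  Waveform dissimilarity is RMSE normalized by
the peak-to-peak range of the self-paced reference average (scale-free;
the normalization itself was an open choice).  ERDS maps band-pass at
36 center frequencies (5–40 Hz, 2 Hz bandwidth, 4th-order zero-phase
Butterworth), square, average over trials, smooth with a 0.25 s boxcar,
and express power as percent change versus the [−2, −0.5] s reference;
0.5 s is trimmed from each epoch edge before averaging because band
filter transients otherwise dominate the borders (the usual reason maps
are epoched wider than they are displayed).  Significance is a
1000-resample percentile bootstrap over trials at α = 0.05; pixels whose
interval covers zero are masked.

## Numerical and scale choices

Problem sizes in the test suite and acceptance script are chosen for a
desk-scale single-CPU budget: 20–40-trial runs and condensed grids for
decoding experiments, 100-trial runs (the full schedule) wherever the
quantity under test depends on it, 300 trials for the behavioral delay
statistics, 50–200 bootstrap resamples in tests (1000 remains the
analysis default).  The "high-SNR subject" used for end-to-end detection
checks has 0.5 µV background noise against the 5 µV MRCP; at the nominal
10 µV the synthetic decoder operates near 30–40 % TPR at 1 FP/min,
which matches the regime reported for real recordings and is why
correctness checks use the high-SNR condition.  Degenerate inputs
(single-trial schedules, single-class label sets, zero-range NRMSE
references, rank-deficient EOG, unreachable cue counts) raise explicit
errors or flagged NaNs rather than propagating silently.

## Known limitations

Threshold calibration on the evaluation run leaks information (flagged
above).  The EOG removal is a plain regression, not a subspace method;
it assumes the calibration run's EEG is uncorrelated with true ocular
signals, which holds for the generator but only approximately for real
data.  The QIS estimator is exposed but the linear-shrinkage default is
what the cross-validation results in this package are based on.
BrainVision/EDF reading requires the optional MNE dependency and a TSV
event sidecar; EDF export is not provided.
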