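# Methods

This note documents the model, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Signal model and landmarks

A PPG stream `X` is a uniformly sampled amplitude series at rate `f_s`
(300 Hz throughout the defaults).  Landmark coordinates are 0-based sample
indices; timestamps are `t0 + i/f_s` seconds.  Preprocessing is a zero-phase
(forward–backward) Butterworth band-pass, default order 4, [0.5, 5] Hz.
Zero-phase application matters: a causal filter would delay every landmark
by the group delay, biasing interbeat intervals derived from them.  Filtering
is applied once to the full recording before batching.

## Boosted endpoint decision

Segmentation assigns each stream sample a likelihood of being a cycle
endpoint, the product of two scores in [0, 1]:

* **Heuristic score** `P(c_t|x_t)`: candidates are all strict local minima
  (plateaus collapse to their first sample).  Each candidate is scored by the
  maximum of the min–max scaled first derivative on the interval from the
  candidate to the next candidate, so each upstroke is attributed to exactly
  one candidate; a candidate with no following region scores 0.  The
  derivative is the forward difference with its last value repeated (keeps
  index alignment with the signal) and is scaled per batch; a zero-range
  batch scales to all ones with a warning.  True onsets are followed by the
  steep systolic rise; dicrotic notches and noise dips are not.
* **Morphology score** `exp(−γ·d)`: `d` is the DTW distance between the
  putative cycle (from the current onset to the candidate) and the template,
  accumulated by a streaming column update restarted at each accepted onset.
  Pointwise cost is the absolute difference; stream batch and template are
  min–max normalized before comparison.

The search window is anchored by the average cycle length `l_X = f_s / f*`,
with `f*` the argmax of the FFT magnitude of the mean-removed batch within a
configurable heart-rate band (default 0.5–3 Hz, i.e. 30–180 bpm, so
respiratory peaks cannot win).  Batches default to 60 s; a trailing batch
shorter than two cycles at the slowest plausible rate is merged into the
previous one.  From the current onset:

* a candidate closer than `α·l_X` resets the start only if its heuristic
  score *strictly* exceeds the current start's (`reset_policy=score_gated`,
  the default).  The alternative `literal` policy resets unconditionally; on
  morphologies with a dicrotic-notch minimum in every cycle it hands the
  start to each notch in turn and never settles, which is demonstrated in
  the test suite and is why gating is the default;
* among candidates in `[α·l_X, β·l_X]` the fused likelihood picks the
  endpoint; ties go to the earliest candidate;
* if the window holds no candidate the search abandons and restarts at the
  first candidate beyond `β·l_X`.

An accepted endpoint closes the cycle and becomes the next cycle's start, so
consecutive cycles share boundary onsets; the stream tail after the last
accepted endpoint of a batch is discarded as incomplete.

**Numerical note.** With the default `γ = 5000` the literal `exp(−γd)`
underflows double precision whenever `d > ~0.15`, which would collapse every
window score to 0.  Candidate ranking therefore works in log space,
`log p_c − γ·d`, which has the same argmax and no underflow.
`morphology_likelihood` still returns the literal exponential for use as a
probability.

## Fiducial mapping

The warping path of the accepted cycle against the template transfers the
template's annotations: for each template fiducial index, among all stream
samples the path aligns to it, the one with minimal pointwise cost is
chosen, earliest on ties; EP is forced to the cycle start.  For this closing
alignment the cycle slice is re-normalized on its own range: respiration
scales individual beats, and comparing shape-to-shape prevents the mapped
landmark from sliding along a slope to chase an amplitude offset (on gentle
upstrokes that slide can exceed the 30 ms match tolerance).  The streaming
search itself keeps batch-level normalization, which preserves the contrast
between strong and weak beats that the heuristic score relies on.

## Dynamic template ensemble

The ensemble holds at most `k` templates (default 3) and starts from the
expert-annotated prime.  Regions are `u = 30` s of stream.  Every template
segments the whole batch through the identical single-template code path;
a region's comparison uses the cycles whose endpoint falls inside it.  This
is deliberate: restricting each search to a region would break cycle
continuity at region boundaries, and it makes a one-template ensemble
reproduce the single-template run bit for bit — a property the test suite
asserts.  Per region:

1. the template with the lowest mean per-cycle average path distance `|w|`
   wins (ties favour the prime, then the lowest id) and its usage counter —
   regions won — increments;
2. below capacity, a new template is added: the DBA consensus of the
   winner's region cycles, annotated by aligning the prime to the consensus
   and mapping its fiducials through the path (a consensus whose mapped
   indices violate onset < MS < SYS is rejected with a warning);
3. at capacity, if the winner is not the prime, the least frequently used
   template (ties: oldest; never the current winner) is evicted before the
   new consensus is added;
4. when a template was added and `reanalysis` is enabled (default), the
   region is re-analyzed with it, and its cycles replace the reported ones
   if they align strictly better (usage credit moves accordingly).

DBA resamples cycles linearly to the median cycle length (fixed-length
averages make annotation transfer deterministic), initializes from the
medoid, and iterates the barycenter update to `1e-6` mean change or 30
iterations; the update never increases the sum of DTW distances to the
average.  Because consensus annotations are transferred *from the prime*,
the ensemble's mapping quality is anchored to the prime's: on the synthetic
suite the dynamic variant is neutral-to-positive relative to the single
template (the suite asserts the ordering, not a margin), with its value
concentrated where noise — not systematic shape bias — dominates the
alignment.

## SPRING baseline

The comparison baseline is the original streaming subsequence matcher:
per-cell start pointers, match reported when the running template-end
distance is a pending minimum below `τ` and no overlapping better alignment
is alive, plus an end-of-stream flush.  The method leaves `τ` open; the
default here is the 25th percentile of the template-end distance
distribution over the first batch, which adapts it to the signal scale and
is logged.  Matches are converted to cycles through the same fiducial
mapping as the boosted pipeline, so the two methods differ only in endpoint
choice.

## Synthetic generator

Each beat is a systolic plus a smaller, later diastolic Gaussian lobe,
rendered on the beat's own interval (lobe centers are fractions of the
interval, widths are seconds).  Five presets span the morphology variation
the detector must tolerate: `classic`, `prominent_notch`,
`fused_diastolic`, `steep_upstroke`, `broad_systole`; a schedule can switch
presets mid-recording.  Respiration (default 0.25 Hz) modulates per-beat
amplitude (`am_depth`), global baseline (`bw_depth`) and instantaneous rate
(`fm_depth`, applied to the onset-to-onset interval); white Gaussian noise
is added last.  The first onset sits half a beat into the record, with
partial lead-in/lead-out beats, so every in-range onset is an interior local
minimum.  All randomness flows from one seed.

Ground truth is located on the *noiseless* signal: EP as the boundary local
minimum, SYS as the beat maximum, MS as the first-difference maximum between
them.  When the detector runs on a preprocessed stream, `truth_for()`
relocates the truth on the identically filtered noiseless signal — the
[0.5, 5] Hz band-pass visibly reshapes onsets and slopes, and truth must
live in the representation the detector sees, just as annotated benchmark
recordings are labelled after preprocessing.  The prime template is likewise
cut from a filtered noiseless rendering (an interior cycle, away from filter
edge effects).

What the generator does **not** emulate: motion artifacts, sensor
saturation, skipped/ectopic beats, slow morphology drift within a preset,
and colored noise.  Passing the synthetic suite therefore demonstrates the
decision logic and its robustness to respiratory variation and broadband
noise, not artifact immunity on real recordings.

## Evaluation

Per class, predictions and truth are matched greedily nearest-in-time,
one-to-one, within a tolerance window (default 30 ms ≈ 9 samples at 300 Hz).
Precision, recall and F1 follow; empty denominators are reported as null
rather than 0, and F1 is null when precision + recall is 0.  Timestamp RMSE
uses matched pairs only.  IBIs are successive differences of one class's
landmark times, anchored at the later beat, filtered to the plausible
[300, 1500] ms range; agreement pairs each true interval with the predicted
interval whose anchor is closest within 1 s (one-to-one) and reports MAE and
Pearson r.  Suite-level numbers pool TP/FP/FN and interval pairs across
subjects, as multi-subject beat-detection benchmarks do.

## Problem sizes and defaults

The standard synthetic suite is 10 subjects × 120 s at 300 Hz (≈1550
annotated beats per class), SNR ≈ 20 dB, modulation depths drawn uniformly
in [0.1, 0.3], heart rates in [55, 95] bpm; the morphology-switch experiment
uses 3 recordings of 120 s switching preset at 60 s.  These sizes give
stable pooled metrics while keeping a full run (suite + baseline + dynamic
variant) under a minute on one CPU; the DTW inner loops are numba-compiled.

## Known limitations

* The FFT-argmax cycle length can lock onto a modulation sideband under
  strong rate modulation (`fm_depth` near 0.3 with fast respiration),
  overestimating `l_X` by ~10 % for such a subject; short beats then fall
  below the search window and per-subject recall dips (harmonic-sum and
  autocorrelation variants were evaluated and were less accurate on the
  remaining subjects, so the plain spectral argmax is kept).
* `γ = 5000` is calibrated for min–max normalized comparisons at 300 Hz;
  other normalizations or rates need re-calibration (it is a config field).
* Whether the two factors of the endpoint likelihood are calibrated
  probabilities is immaterial here: they are treated as scores and never
  renormalized, and only their ranking within a window matters.
* The plausibility filter bounds are the millisecond figures [300, 1500];
  IBI values outside them are discarded regardless of the nominal
  beats-per-minute labels sometimes attached to such bounds.
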