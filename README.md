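# ppgdtw

Streaming segmentation and fiducial-point detection for photoplethysmogram
(PPG) waveforms, built on subsequence dynamic time warping boosted with
minimal domain heuristics.

## The problem

Wearable PPG sensors record a quasi-periodic optical signal — one pulse per
heartbeat — from which clinically useful parameters (heart rate, interbeat
intervals, and downstream blood-pressure or respiration estimates) are
derived.  All of them depend on finding, beat by beat, three landmarks:

* **EP** — the cycle onset/endpoint, the local minimum immediately before the
  systolic upstroke (consecutive onsets delimit one cardiac cycle);
* **MS** — the maximum-slope point of the upstroke;
* **SYS** — the systolic peak.

Hand-crafted threshold detectors break when waveform morphology drifts
across subjects, with vascular state, or within a recording as respiration
modulates pulse amplitude, baseline and rate.  Pure template matching by
streaming DTW (the SPRING algorithm) breaks differently: a quasi-periodic
signal contains *meta-subsequences* — incomplete stretches that resemble a
full cycle — and a minimum-distance rule happily accepts them.

## The method

Every sample `x_t` of the stream gets an endpoint likelihood

```
P(e_t) = P(c_t | x_t) · P(d(x_t, y_m)),     P(d) = exp(−γ · d(x_t, y_m))
```

where `P(c_t|x_t)` is a domain score — candidate endpoints are all local
minima, scored by the peak of the min–max scaled first derivative on the
following upstroke — and `d(x_t, y_m)` is the running DTW distance between
the current putative cycle and an annotated single-cycle template `Y`.
The search for the next endpoint is confined to `[α·l_X, β·l_X]` after the
current onset, with `l_X = f_s / f*` the average cycle length from the
dominant frequency of each one-minute batch (defaults `α = 0.7`, `β = 1.3`,
`γ = 5000`).  The warping path of each accepted cycle transfers the
template's EP/MS/SYS annotations onto the stream.

A bounded **dynamic template ensemble** adapts to evolving morphology: after
each region of `u` seconds, the template with the lowest average
warping-path distance `|w|` wins the region; while the ensemble is below its
capacity `k`, a new template is generated as the DTW barycenter average
(DBA) of the region's cycles, annotated by the prime template, and when the
ensemble is full the least frequently used template is evicted.

The package also ships the original SPRING matcher as a baseline, a seeded
synthetic PPG generator with exact ground truth (two-Gaussian beats,
respiratory amplitude/baseline/rate modulation, morphology presets and
mid-recording switches), and evaluation code (per-class precision / recall /
F1 / timestamp RMSE, plus interbeat-interval MAE and Pearson agreement with
a 300–1500 ms plausibility filter).

## Worked example

```python
import ppgdtw as pp

cfg = pp.RunConfig()                      # α=0.7, β=1.3, γ=5000, band-pass [0.5, 5] Hz
spec = pp.make_cohort(seed=3, n_subjects=1, duration_s=120.0)[0]
subject = pp.prepare_subject(spec, cfg)   # simulate, band-pass, template + truth

cycles = pp.segment_stream(subject.stream, subject.template, cfg)
pred = pp.cycles_to_fiducials(cycles, subject.stream)
report = pp.evaluate_fiducials(pred, subject.truth, tolerance_ms=cfg.tolerance_ms)
```

Running `python examples/02_segment_beats.py` (the same computation) prints:

```
116 cardiac cycles detected (mean DTW distance to template 3.51)
 EP: precision 1.000  recall 1.000  F1 1.000  timestamp RMSE 7.7 ms  IBI MAE 8.6 ms over 117 intervals
 MS: precision 1.000  recall 0.983  F1 0.991  timestamp RMSE 3.3 ms  IBI MAE 3.0 ms over 114 intervals
SYS: precision 1.000  recall 0.983  F1 0.991  timestamp RMSE 2.2 ms  IBI MAE 2.0 ms over 114 intervals
```

F1 close to 1 means nearly every landmark was reported within 30 ms of its
true time on this noisy (≈20 dB SNR) two-minute recording; the IBI MAE is
the beat-to-beat heart-period error those landmarks imply.  The other
scripts in `examples/` demonstrate the simulator, the dynamic ensemble on a
morphology switch, and the premature-endpoint failure mode of plain
minimum-distance matching.

A thin CLI wraps the same pipeline:

```sh
ppgdtw simulate --duration 60 --hr 72 --noise-sd 0.02 --seed 7 --out-dir run/
ppgdtw segment  --signal run/signal.csv --template run/template.csv --mode dynamic --out-dir run/seg/
ppgdtw evaluate --pred run/seg/annotations.csv --truth run/truth.csv --out-dir run/report/
```

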