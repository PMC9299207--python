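"""Segment a noisy PPG stream into cardiac cycles with one annotated template.

Simulates two minutes of noisy PPG, band-pass filters it, segments it against
the subject's prime template, and scores the detected onsets, max-slope
points and systolic peaks against ground truth at a 30 ms tolerance.
"""
import ppgdtw as pp

cfg = pp.RunConfig()  # alpha=0.7, beta=1.3, gamma=5000, band-pass [0.5, 5] Hz
spec = pp.make_cohort(seed=3, n_subjects=1, duration_s=120.0)[0]
subject = pp.prepare_subject(spec, cfg)

cycles = pp.segment_stream(subject.stream, subject.template, cfg)
print(f"{len(cycles)} cardiac cycles detected "
      f"(mean DTW distance to template {sum(c.dtw_distance for c in cycles)/len(cycles):.2f})")

pred = pp.cycles_to_fiducials(cycles, subject.stream)
report = pp.evaluate_fiducials(pred, subject.truth, tolerance_ms=cfg.tolerance_ms)
for label in ("EP", "MS", "SYS"):
    row = report["classification"][label]
    ibi = report["ibi"][label]
    print(f"{label:>3}: precision {row['precision']:.3f}  recall {row['recall']:.3f}  "
          f"F1 {row['f1']:.3f}  timestamp RMSE {row['rmse_ms']:.1f} ms  "
          f"IBI MAE {ibi['mae_ms']:.1f} ms over {ibi['n_pairs']} intervals")
print("F1 near 1 means nearly every landmark was found within 30 ms of its true time;")
print("IBI MAE is the beat-to-beat heart-period error those landmarks imply.")
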