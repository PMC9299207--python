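"""Seeded synthetic PPG generator with exact ground-truth fiducials.

Each beat is the sum of two Gaussian lobes — a systolic lobe and a smaller,
later diastolic (reflected-wave) lobe — rendered on the beat's own interval
so the onset is a genuine local minimum between the previous beat's decay and
the systolic upstroke.  Respiration modulates the signal on three axes, as in
real PPG: per-beat amplitude (``am_depth``, reflected pulse strength),
baseline (``bw_depth``, perfusion-intensity wander) and instantaneous heart
rate (``fm_depth``).  White Gaussian noise is added last.

Ground-truth fiducials are located on the *noiseless* signal and carried to
the noisy one: EP is the local minimum at the beat boundary, SYS the beat's
amplitude maximum, MS the maximum of the first difference between them.  All
randomness flows from the single ``seed``.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import AnnotatedTemplate, FiducialPoint, SignalStream

__all__ = [
    "BeatModel",
    "SimulationSpec",
    "SimulationResult",
    "presets",
    "simulate",
    "make_prime_template",
    "noise_sd_for_snr",
]


@dataclass(frozen=True)
class BeatModel:
    """Two-lobe beat shape; centers are fractions of the beat interval, widths seconds."""

    sys_amp: float
    sys_width_s: float
    sys_center_frac: float
    dia_amp: float
    dia_width_s: float
    dia_center_frac: float
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        if not (0 < self.sys_center_frac < self.dia_center_frac < 1):
            raise ValueError("need 0 < sys_center_frac < dia_center_frac < 1")
        if min(self.sys_amp, self.dia_amp, self.sys_width_s, self.dia_width_s) <= 0:
            raise ValueError("amplitudes and widths must be positive")

    def render(self, tau: np.ndarray, period: float) -> np.ndarray:
        """Evaluate the beat at offsets ``tau`` (seconds from onset) for a given period."""
        sys_c = self.sys_center_frac * period
        dia_c = self.dia_center_frac * period
        return self.sys_amp * np.exp(-0.5 * ((tau - sys_c) / self.sys_width_s) ** 2) + self.dia_amp * np.exp(
            -0.5 * ((tau - dia_c) / self.dia_width_s) ** 2
        )


def presets() -> dict[str, BeatModel]:
    """Named beat morphologies spanning the variation seen across subjects.

    ``classic``        systolic peak with a moderate dicrotic wave;
    ``prominent_notch`` deep, well separated dicrotic notch (two minima per cycle);
    ``fused_diastolic`` broad diastolic lobe merged into the systolic decay;
    ``steep_upstroke``  narrow early systolic peak with fast rise;
    ``broad_systole``   wide, late systolic lobe with a weak reflection.
    """
    return {
        "classic": BeatModel(1.0, 0.10, 0.30, 0.35, 0.14, 0.68, "classic"),
        "prominent_notch": BeatModel(1.0, 0.085, 0.27, 0.55, 0.10, 0.60, "prominent_notch"),
        "fused_diastolic": BeatModel(1.0, 0.13, 0.33, 0.45, 0.20, 0.58, "fused_diastolic"),
        "steep_upstroke": BeatModel(1.0, 0.07, 0.22, 0.30, 0.13, 0.62, "steep_upstroke"),
        "broad_systole": BeatModel(0.9, 0.17, 0.42, 0.25, 0.11, 0.78, "broad_systole"),
    }


@dataclass
class SimulationSpec:
    duration_s: float
    fs: float = 300.0
    hr_bpm: float = 60.0
    resp_rate_hz: float = 0.25
    am_depth: float = 0.0  # amplitude modulation depth, [0, 1)
    bw_depth: float = 0.0  # baseline-wander depth, amplitude units
    fm_depth: float = 0.0  # heart-rate (frequency) modulation depth, [0, 1)
    noise_sd: float = 0.0  # additive white-noise standard deviation
    seed: int = 0
    morphology_schedule: list[tuple[float, BeatModel]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (30.0 <= self.hr_bpm <= 180.0):
            raise ValueError(f"hr_bpm {self.hr_bpm} outside the plausible [30, 180] range")
        if not self.fs >= 10.0:
            raise ValueError("fs must cover the band-pass high cutoff")
        for depth, name in ((self.am_depth, "am_depth"), (self.fm_depth, "fm_depth")):
            if not (0 <= depth < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if not self.morphology_schedule:
            self.morphology_schedule = [(0.0, presets()["classic"])]
        times = [t for t, _ in self.morphology_schedule]
        if times != sorted(times) or times[0] != 0.0:
            raise ValueError("morphology_schedule must be sorted and start at time 0")
        if any(t >= self.duration_s for t in times[1:]):
            raise ValueError("morphology_schedule times must lie inside the duration")


@dataclass
class SimulationResult:
    stream: SignalStream
    truth: dict[str, list[FiducialPoint]]  # per-label ground-truth fiducials
    beat_times: np.ndarray  # onset times (s) of in-range beats
    noiseless: np.ndarray  # noiseless samples (fiducial reference)
    beat_spans: list[tuple[float, float, int, int]] = field(default_factory=list)

    def truth_list(self) -> list[FiducialPoint]:
        return sorted((p for pts in self.truth.values() for p in pts), key=lambda p: (p.timestamp, p.label))

    def truth_for(self, reference: np.ndarray) -> dict[str, list[FiducialPoint]]:
        """Relocate the ground-truth fiducials on a transformed noiseless signal.

        When the detector runs on a preprocessed stream (e.g. band-pass
        filtered), landmarks move with the preprocessing: a zero-phase filter
        keeps beats in place but reshapes onsets and slopes.  Passing the
        identically transformed *noiseless* signal here yields ground truth
        in the same representation the detector sees — the synthetic
        counterpart of annotating recordings after preprocessing.
        """
        reference = np.asarray(reference, dtype=float)
        if reference.shape != self.noiseless.shape:
            raise ValueError("reference signal must match the simulated length")
        truth, _ = _locate_truth(reference, self.beat_spans, self.stream)
        return truth

    def truth_list_for(self, reference: np.ndarray) -> list[FiducialPoint]:
        t = self.truth_for(reference)
        return sorted((p for pts in t.values() for p in pts), key=lambda p: (p.timestamp, p.label))


def noise_sd_for_snr(noiseless: np.ndarray, snr_db: float) -> float:
    """White-noise SD giving the requested SNR against the mean-removed signal."""
    rms = float(np.sqrt(np.mean((noiseless - noiseless.mean()) ** 2)))
    return rms / (10.0 ** (snr_db / 20.0))


def _model_at(spec: SimulationSpec, t: float) -> BeatModel:
    model = spec.morphology_schedule[0][1]
    for start, m in spec.morphology_schedule:
        if t >= start:
            model = m
    return model


def simulate(spec: SimulationSpec) -> SimulationResult:
    """Render a synthetic PPG stream and its exact ground-truth fiducials.

    Beat onsets are spaced by ``60/hr_bpm`` modulated by
    ``fm_depth * sin(2*pi*resp_rate*t)``; the first in-range onset sits half a
    beat into the record so the initial onset is an interior local minimum.
    Deterministic given ``spec.seed``.
    """
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    base_T = 60.0 / spec.hr_bpm
    w = 2 * math.pi * spec.resp_rate_hz

    # lay out onsets, including lead-in/lead-out partial beats
    onsets: list[float] = []
    t = 0.5 * base_T - 2 * base_T
    while t < spec.duration_s + base_T:
        onsets.append(t)
        t = t + base_T * (1.0 + spec.fm_depth * math.sin(w * t))
    onsets_arr = np.asarray(onsets)

    times = np.arange(n) / fs
    clean = np.zeros(n)
    spans: list[tuple[float, float, int, int]] = []  # (onset, period, i0, i1) clipped to range
    for k in range(len(onsets_arr) - 1):
        t_on = onsets_arr[k]
        period = onsets_arr[k + 1] - t_on
        i0 = max(0, int(math.ceil(t_on * fs - 1e-9)))
        i1 = min(n, int(math.ceil((t_on + period) * fs - 1e-9)))
        if i1 <= i0:
            continue
        tau = times[i0:i1] - t_on
        model = _model_at(spec, max(t_on, 0.0))
        amp = 1.0 + spec.am_depth * math.sin(w * t_on)
        clean[i0:i1] += amp * model.render(tau, period)
        spans.append((t_on, period, i0, i1))

    clean = clean + spec.bw_depth * np.sin(w * times)
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else clean.copy()
    stream = SignalStream(noisy, fs, 0.0)

    truth, beat_times = _locate_truth(clean, spans, stream)
    return SimulationResult(stream, truth, beat_times, clean, spans)


def _locate_truth(
    clean: np.ndarray, spans: list[tuple[float, float, int, int]], stream: SignalStream
) -> tuple[dict[str, list[FiducialPoint]], np.ndarray]:
    """Locate one (EP, MS, SYS) triple per in-range beat on a noiseless signal."""
    n = clean.size
    fs = stream.fs
    truth: dict[str, list[FiducialPoint]] = {"EP": [], "MS": [], "SYS": []}
    beat_times: list[float] = []
    diff = np.diff(clean)
    for t_on, period, i0, i1 in spans:
        if t_on < 0 or i1 - i0 < 4:
            continue
        # EP: local minimum at the beat boundary (within a fifth of the period)
        half = max(2, int(round(0.2 * period * fs)))
        lo = max(0, i0 - half)
        hi = min(n, i0 + half)
        ep = lo + int(np.argmin(clean[lo:hi]))
        sys_i = i0 + int(np.argmax(clean[i0:i1]))
        if sys_i <= ep + 1:
            continue  # degenerate edge beat
        ms = ep + 1 + int(np.argmax(diff[ep + 1 : sys_i]))
        truth["EP"].append(stream.point(ep, "EP"))
        truth["MS"].append(stream.point(ms, "MS"))
        truth["SYS"].append(stream.point(sys_i, "SYS"))
        beat_times.append(t_on)
    return truth, np.asarray(beat_times)


def make_prime_template(
    spec: SimulationSpec, bandpass: tuple[float, float] | None = None, filter_order: int = 4
) -> AnnotatedTemplate:
    """One noiseless cycle of the first scheduled beat model, exactly annotated.

    With ``bandpass`` set, the template is cut from a band-pass filtered
    noiseless rendering instead of the raw beat shape, so it lives in the
    same representation as a preprocessed stream — the synthetic counterpart
    of annotating a template on the preprocessed recording.  The filter needs
    context around the cycle, so a short steady recording is rendered and an
    interior cycle is extracted.
    """
    fs = spec.fs
    model = spec.morphology_schedule[0][1]
    if bandpass is None:
        period = 60.0 / spec.hr_bpm
        m = int(round(period * fs))
        tau = np.arange(m) / fs
        samples = model.render(tau, period)
        sys_i = int(np.argmax(samples))
        d = np.diff(samples)
        ms = 1 + int(np.argmax(d[1:sys_i])) if sys_i > 2 else 1
        return AnnotatedTemplate(
            samples=samples, fs=fs, onset_idx=0, ms_idx=ms, sys_idx=sys_i,
            id=f"prime-{model.preset_name}",
        )

    from .io import bandpass_filter

    steady = SimulationSpec(
        duration_s=max(8.0, 6 * 60.0 / spec.hr_bpm),
        fs=fs, hr_bpm=spec.hr_bpm, seed=spec.seed,
        morphology_schedule=[(0.0, model)],
    )
    res = simulate(steady)
    filtered = bandpass_filter(SignalStream(res.noiseless, fs), bandpass[0], bandpass[1], filter_order).samples
    truth = res.truth_for(filtered)
    k = len(truth["EP"]) // 2  # interior beat, away from filter edge effects
    ep0 = truth["EP"][k].index
    ep1 = truth["EP"][k + 1].index
    return AnnotatedTemplate(
        samples=filtered[ep0 : ep1 + 1],
        fs=fs,
        onset_idx=0,
        ms_idx=truth["MS"][k].index - ep0,
        sys_idx=truth["SYS"][k].index - ep0,
        id=f"prime-{model.preset_name}",
    )


def write_simulation(result: SimulationResult, spec: SimulationSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write signal CSV, truth annotation CSV and the spec JSON (full provenance)."""
    from .io import write_annotations, write_signal

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "signal": out / "signal.csv",
        "truth": out / "truth.csv",
        "spec": out / "spec.json",
    }
    write_signal(result.stream, paths["signal"])
    write_annotations(result.truth_list(), paths["truth"])
    blob = asdict(spec)
    blob["morphology_schedule"] = [[t, asdict(m)] for t, m in spec.morphology_schedule]
    with open(paths["spec"], "w") as fh:
        json.dump(blob, fh, indent=2)
        fh.write("\n")
    return paths
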