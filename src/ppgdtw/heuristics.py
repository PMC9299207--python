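"""Domain heuristics: FFT cycle-length estimate and candidate-endpoint scoring.

Every cardiac cycle in a PPG stream begins at the onset — the local minimum
immediately preceding the systolic upstroke.  The candidate set for a batch is
therefore *all* local minima; each candidate is scored by the steepness of the
upstroke that follows it (the peak of the min–max scaled first derivative),
because true onsets are followed by the steep systolic rise while dicrotic
notches and noise dips are not.

The average cycle length l_X = fs / f* anchors the endpoint search window,
with f* the dominant frequency of the batch restricted to a plausible
heart-rate band.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DerivativeSeries, SignalStream

__all__ = [
    "CandidateEndpoint",
    "CycleLengthEstimate",
    "estimate_cycle_length",
    "detect_candidates",
    "score_candidates",
]


@dataclass
class CandidateEndpoint:
    """A local minimum with its max-slope value and heuristic likelihood."""

    index: int
    g: float | None  # peak of the scaled derivative after the candidate; None if no region
    p_c: float  # heuristic likelihood P(c_t | x_t), in [0, 1]


@dataclass
class CycleLengthEstimate:
    """Average samples per cardiac cycle for one batch."""

    l_x: float  # fs / f_star, in samples
    f_star: float  # dominant frequency in Hz
    batch_span: tuple[int, int]


def estimate_cycle_length(batch: SignalStream, band: tuple[float, float] = (0.5, 3.0)) -> CycleLengthEstimate:
    """Dominant-frequency cycle length: ``l_X = fs / f*``.

    ``f*`` is the argmax of the FFT magnitude of the mean-removed batch,
    restricted to ``band`` (Hz) so respiratory and harmonic peaks cannot win.
    The batch must span at least two cycles at the slowest plausible rate.
    """
    lo, hi = band
    if not (0 < lo < hi < batch.fs / 2):
        raise ValueError(f"band {band} must lie within (0, fs/2)")
    if batch.duration < 2.0 / lo:
        raise ValueError(
            f"batch too short: {batch.duration:.2f} s holds fewer than two cycles at {lo} Hz"
        )
    x = batch.samples - batch.samples.mean()
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, 1.0 / batch.fs)
    mask = (freqs >= lo) & (freqs <= hi)
    f_star = float(freqs[mask][np.argmax(mag[mask])])
    return CycleLengthEstimate(l_x=batch.fs / f_star, f_star=f_star, batch_span=(0, x.size))


def detect_candidates(batch: SignalStream | np.ndarray) -> np.ndarray:
    """Indices of all strict local minima, plateaus collapsed to their first sample.

    Output is strictly increasing; boundary samples are never candidates.
    """
    x = batch.samples if isinstance(batch, SignalStream) else np.asarray(batch, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to detect local minima")
    out: list[int] = []
    i = 1
    n = x.size
    while i < n - 1:
        if x[i] < x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] > x[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=np.int64)


def score_candidates(
    candidates: np.ndarray, derivative: DerivativeSeries, batch: SignalStream | np.ndarray | None = None
) -> list[CandidateEndpoint]:
    """Attach max-slope values and heuristic likelihoods to candidates.

    For candidate c_i the max-slope value g_i is the maximum of the scaled
    derivative on ``(c_i, c_{i+1}]`` (or to the end of the batch for the last
    candidate), so each upstroke is attributed to exactly one candidate.  On
    the already min–max scaled derivative the likelihood equals g_i.
    Candidates with no following region score 0.
    """
    d = derivative.values
    n = d.size
    cands = np.asarray(candidates, dtype=np.int64)
    scored: list[CandidateEndpoint] = []
    for k, c in enumerate(cands):
        hi = int(cands[k + 1]) if k + 1 < cands.size else n - 1
        region = d[c + 1 : hi + 1]
        if region.size == 0:
            scored.append(CandidateEndpoint(int(c), None, 0.0))
        else:
            g = float(region.max())
            scored.append(CandidateEndpoint(int(c), g, g))
    return scored
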