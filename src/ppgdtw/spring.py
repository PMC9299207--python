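"""DTW distances, warping paths, morphology likelihood and the SPRING baseline.

``dtw_full`` is the classical fixed-endpoint DTW between a detected cycle and
a template; ``StreamingDtw`` advances the same dynamic program one stream
sample at a time so the template-end distance ``d(x_t, y_m)`` is available at
every step of the stream.  Both use the absolute difference as pointwise cost
and the usual {diagonal, vertical, horizontal} step set.

``spring_matches``/``spring_baseline_segment`` implement the original SPRING
streaming subsequence matcher used as the comparison baseline: it reports a
match whenever the running template-end distance is a pending minimum below a
threshold and no overlapping, better alignment is still alive.  Pure distance
minima do not know how long a cardiac cycle should be, so this baseline can
accept an incomplete "meta-subsequence" as a full cycle — the failure mode
the boosted decision rule is designed to avoid.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._dp import _advance_column, _dtw_matrix, _last_row_series, _spring_dend, _spring_search
from .io import SignalStream, AnnotatedTemplate

__all__ = [
    "WarpingPath",
    "dtw_full",
    "StreamingDtw",
    "last_row_series",
    "morphology_likelihood",
    "log_morphology_likelihood",
    "spring_matches",
    "spring_baseline_segment",
    "normalize",
]

log = logging.getLogger(__name__)


@dataclass
class WarpingPath:
    """An alignment: ordered (stream_idx, template_idx) pairs and its cost."""

    pairs: np.ndarray  # (L, 2) int array, monotone steps
    distance: float  # accumulated cost along the path

    def __len__(self) -> int:
        return self.pairs.shape[0]

    @property
    def mean_cost(self) -> float:
        """Average pointwise distance along the path, |w| in the selection rule."""
        return self.distance / self.pairs.shape[0]


def normalize(x: np.ndarray, mode: str = "minmax") -> np.ndarray:
    """Amplitude normalization applied to stream batches and templates before DTW."""
    x = np.asarray(x, dtype=float)
    if mode == "none":
        return x
    if mode == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)
    if mode == "zscore":
        sd = x.std()
        if sd == 0:
            return np.zeros_like(x)
        return (x - x.mean()) / sd
    raise ValueError(f"unknown normalization {mode!r}")


def dtw_full(x: np.ndarray, y: np.ndarray, window: int | None = None) -> tuple[float, WarpingPath]:
    """Fixed-endpoint DTW distance and warping path.

    Ties during backtracking prefer the diagonal step, then the vertical
    (stream-advancing) step, which yields the shortest deterministic path.
    ``window`` optionally restricts the alignment to a Sakoe–Chiba band.
    """
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("dtw_full requires non-empty inputs")
    D = _dtw_matrix(x, y, -1 if window is None else int(window))
    dist = float(D[-1, -1])
    if not math.isfinite(dist):
        raise ValueError("no admissible warping path (band too narrow)")
    i, j = x.size - 1, y.size - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            best = min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
            if D[i - 1, j - 1] == best:
                i, j = i - 1, j - 1
            elif D[i - 1, j] == best:
                i -= 1
            else:
                j -= 1
        rev.append((i, j))
    pairs = np.asarray(rev[::-1], dtype=np.int64)
    return dist, WarpingPath(pairs, dist)


def last_row_series(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """``d_t = D(t, m-1)`` for every prefix of ``x``, anchored at the start of ``x``."""
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    return _last_row_series(x, y)


class StreamingDtw:
    """One-sample-at-a-time DTW against a fixed template.

    The accumulation is anchored at the stream sample where the object was
    created (or last ``reset``), so ``step`` returns the distance of the
    current putative cycle prefix to the full template.
    """

    def __init__(self, template: np.ndarray):
        self.y = np.ascontiguousarray(template, dtype=float)
        if self.y.size == 0:
            raise ValueError("empty template")
        self._col: np.ndarray | None = None
        self.n_fed = 0

    def reset(self) -> None:
        self._col = None
        self.n_fed = 0

    def step(self, x_t: float) -> float:
        """Feed one sample; return ``d(x_t, y_m)`` for the accumulated prefix."""
        first = self._col is None
        self._col = _advance_column(
            self._col if self._col is not None else np.empty(self.y.size), float(x_t), self.y, first
        )
        self.n_fed += 1
        return float(self._col[-1])

    def feed(self, x: np.ndarray) -> np.ndarray:
        return np.asarray([self.step(v) for v in np.asarray(x, dtype=float)])


def morphology_likelihood(d: float | np.ndarray, gamma: float) -> float | np.ndarray:
    """Morphology similarity score ``exp(-gamma * d)`` in (0, 1].

    A small DTW distance means the analyzed region resembles the template
    cycle; the exponential maps distance to a likelihood comparable with the
    heuristic candidate score.  For large ``gamma * d`` this underflows to
    0.0 in float64 — decision rules should rank with
    :func:`log_morphology_likelihood` instead.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("DTW distance must be nonnegative")
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    out = np.exp(-gamma * d)
    return float(out) if out.ndim == 0 else out


def log_morphology_likelihood(d: float | np.ndarray, gamma: float) -> float | np.ndarray:
    """``log`` of :func:`morphology_likelihood`, safe against underflow."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("DTW distance must be nonnegative")
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    out = -gamma * d
    return float(out) if out.ndim == 0 else out


def spring_end_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Template-end distance series under the SPRING (start-anywhere) recurrence."""
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    return _spring_dend(x, y)


def spring_matches(x: np.ndarray, y: np.ndarray, tau: float) -> list[tuple[int, int, float]]:
    """SPRING subsequence matches ``(start, end, distance)`` with distance <= tau."""
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    starts, ends, dists, count = _spring_search(x, y, float(tau))
    return [(int(starts[k]), int(ends[k]), float(dists[k])) for k in range(count)]


def default_spring_tau(x: np.ndarray, y: np.ndarray, q: float = 25.0) -> float:
    """Default SPRING threshold: a low percentile of observed end distances.

    The original algorithm leaves the threshold to the user; anchoring it to
    the 25th percentile of the template-end distance distribution over the
    first batch adapts it to the signal scale.
    """
    dend = spring_end_distances(x, y)
    tau = float(np.percentile(dend, q))
    log.info("SPRING tau defaulted to %.4f (%.0fth percentile of end distances)", tau, q)
    return tau


def spring_baseline_segment(stream: SignalStream, template: AnnotatedTemplate, config) -> list:
    """Segment a stream with the original SPRING minimum-distance rule.

    Matches become cycles; fiducials are mapped through the full-DTW warping
    path of each match exactly as in the boosted pipeline, so the two methods
    differ only in how endpoints are chosen.
    """
    from .segmentation import iter_batches, _cycle_from_bounds

    cycles = []
    tau = config.spring_tau
    yn = normalize(template.samples, config.normalization)
    for bs, be in iter_batches(stream, config):
        xn = normalize(stream.samples[bs:be], config.normalization)
        if tau is None:
            tau = default_spring_tau(xn, yn)
        for s, e, _dist in spring_matches(xn, yn, tau):
            if e - s < 2:
                continue
            cycles.append(_cycle_from_bounds(stream, bs + s, bs + e, xn[s : e + 1], yn, template, config))
    return cycles
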