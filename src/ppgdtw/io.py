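"""Core data types, file I/O and preprocessing for PPG streams.

A PPG recording is represented as a uniformly sampled amplitude series
(:class:`SignalStream`).  Waveform landmarks — the cardiac-cycle onset /
endpoint (EP), the maximum-slope point of the systolic upstroke (MS) and the
systolic peak (SYS) — are :class:`FiducialPoint` objects whose canonical
coordinate is the 0-based sample index; timestamps are seconds.

File formats are plain delimited text:

* signal files: CSV with columns ``time_s,amplitude`` or a single
  ``amplitude`` column (sampling rate supplied by the caller);
* annotation files: CSV with header ``timestamp_s,sample_index,label``;
* templates: an amplitude CSV plus a JSON sidecar holding the sampling rate,
  the three fiducial indices and an identifier.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as _sig

__all__ = [
    "LABELS",
    "ParseError",
    "SignalStream",
    "DerivativeSeries",
    "FiducialPoint",
    "AnnotatedTemplate",
    "read_signal",
    "write_signal",
    "bandpass_filter",
    "first_derivative",
    "read_annotations",
    "write_annotations",
    "read_template",
    "write_template",
]

log = logging.getLogger(__name__)

#: Fiducial labels: systolic peak, max-slope point, cycle endpoint, non-fiducial.
LABELS = ("SYS", "MS", "EP", "NF")


class ParseError(ValueError):
    """Raised when a delimited text file cannot be parsed."""


@dataclass(frozen=True, order=True)
class FiducialPoint:
    """A labelled waveform landmark.

    ``timestamp`` is ``t0 + index / fs`` of the stream the point belongs to;
    the sample index is the canonical coordinate.
    """

    timestamp: float
    index: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown fiducial label {self.label!r}; expected one of {LABELS}")


@dataclass
class SignalStream:
    """Uniformly sampled amplitude series.

    Parameters
    ----------
    samples : ndarray
        Amplitude values (arbitrary units).
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN/Inf; clean the input or load with on_nan='interpolate'")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds (number of samples / fs)."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def time_at(self, index: int) -> float:
        return self.t0 + index / self.fs

    def point(self, index: int, label: str) -> FiducialPoint:
        """Build a fiducial point at ``index`` in this stream's coordinates."""
        return FiducialPoint(self.time_at(int(index)), int(index), label)


@dataclass
class DerivativeSeries:
    """First-difference series min–max scaled to [0, 1] over a batch."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass(eq=False)
class AnnotatedTemplate:
    """Single-cycle template with fiducial sample indices and a usage counter."""

    samples: np.ndarray
    fs: float
    onset_idx: int
    ms_idx: int
    sys_idx: int
    id: str = "template"
    usage_count: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("template samples must be a non-empty 1-D array")
        if not (0 <= self.onset_idx < self.ms_idx < self.sys_idx < self.samples.size):
            raise ValueError(
                "template fiducials must satisfy onset < max-slope < systolic peak "
                f"within the template; got ({self.onset_idx}, {self.ms_idx}, {self.sys_idx}) "
                f"for length {self.samples.size}"
            )

    @property
    def fiducial_indices(self) -> dict[str, int]:
        return {"EP": self.onset_idx, "MS": self.ms_idx, "SYS": self.sys_idx}


# ---------------------------------------------------------------------------
# signal files


def _parse_delimited(path: str | Path) -> list[list[float]]:
    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.replace("\t", ",").split(",") if p.strip() != ""]
            if lineno == 1 and not _all_floatable(parts):
                continue  # header row
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: cannot parse {line!r}") from None
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise ParseError(f"{path}: line {lineno}: expected {ncols} columns, got {len(vals)}")
            rows.append(vals)
    return rows


def _all_floatable(parts: list[str]) -> bool:
    for p in parts:
        try:
            float(p)
        except ValueError:
            return False
    return True


def read_signal(path: str | Path, fs: float | None = None, on_nan: str = "error") -> SignalStream:
    """Read a delimited signal file.

    Two-column files are interpreted as ``time_s, amplitude`` and the sampling
    rate is inferred from the median time step; one-column files require
    ``fs`` and start at ``t0 = 0``.

    ``on_nan`` controls non-finite amplitudes: ``"error"`` rejects the file,
    ``"interpolate"`` fills them linearly from their finite neighbours.
    """
    rows = _parse_delimited(path)
    if not rows:
        raise ParseError(f"{path}: empty signal file")
    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] == 1:
        if fs is None:
            raise ValueError("one-column signal files require an explicit sampling rate fs")
        amplitude, t0, fs_eff = arr[:, 0], 0.0, float(fs)
    elif arr.shape[1] == 2:
        t, amplitude = arr[:, 0], arr[:, 1]
        dt = np.diff(t)
        if len(dt) == 0:
            if fs is None:
                raise ValueError("cannot infer fs from a single row; pass fs explicitly")
            fs_eff = float(fs)
        else:
            fs_eff = 1.0 / float(np.median(dt))
        t0 = float(t[0])
    else:
        raise ParseError(f"{path}: expected 1 or 2 columns, got {arr.shape[1]}")

    bad = ~np.isfinite(amplitude)
    if bad.any():
        if on_nan == "interpolate":
            idx = np.arange(amplitude.size)
            amplitude = amplitude.copy()
            amplitude[bad] = np.interp(idx[bad], idx[~bad], amplitude[~bad])
            log.warning("interpolated %d non-finite samples in %s", int(bad.sum()), path)
        else:
            raise ParseError(f"{path}: {int(bad.sum())} non-finite amplitude values")
    return SignalStream(amplitude, fs_eff, t0)


def write_signal(stream: SignalStream, path: str | Path) -> None:
    """Write ``time_s,amplitude`` CSV."""
    t = stream.times()
    with open(path, "w") as fh:
        fh.write("time_s,amplitude\n")
        for ti, xi in zip(t, stream.samples):
            fh.write(f"{ti:.6f},{xi:.9g}\n")


# ---------------------------------------------------------------------------
# preprocessing


def bandpass_filter(stream: SignalStream, low: float = 0.5, high: float = 5.0, order: int = 4) -> SignalStream:
    """Zero-phase Butterworth band-pass filter.

    Applied forward–backward (``sosfiltfilt``) so fiducial timestamps are not
    shifted by filter group delay; a causal pass would bias every landmark
    late.  Cutoffs must satisfy ``0 < low < high < fs/2``.
    """
    nyq = stream.fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"band [{low}, {high}] Hz invalid for fs={stream.fs} Hz (Nyquist {nyq})")
    sos = _sig.butter(order, [low, high], btype="bandpass", fs=stream.fs, output="sos")
    filtered = _sig.sosfiltfilt(sos, stream.samples)
    return replace(stream, samples=filtered)


def first_derivative(stream: SignalStream) -> DerivativeSeries:
    """Min–max scaled first difference, same length as the signal.

    The forward difference is padded by repeating its last value so indices in
    the derivative align with indices in the signal.  A constant-slope batch
    (zero range) scales to all ones and logs a warning rather than dividing
    by zero.
    """
    if len(stream) < 2:
        raise ValueError("need at least 2 samples for a derivative")
    raw = np.diff(stream.samples)
    raw = np.append(raw, raw[-1])
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        log.warning("constant-slope batch: derivative scaling is degenerate, returning all ones")
        return DerivativeSeries(np.ones_like(raw))
    return DerivativeSeries((raw - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# annotations


def write_annotations(points: list[FiducialPoint], path: str | Path) -> None:
    """Write fiducials as ``timestamp_s,sample_index,label`` CSV.

    Input must be sorted by timestamp (ties allowed).
    """
    ts = [p.timestamp for p in points]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError("fiducial points must be sorted by timestamp")
    with open(path, "w") as fh:
        fh.write("timestamp_s,sample_index,label\n")
        for p in points:
            fh.write(f"{p.timestamp:.6f},{p.index},{p.label}\n")


def read_annotations(path: str | Path) -> list[FiducialPoint]:
    points: list[FiducialPoint] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or (lineno == 1 and line.lower().startswith("timestamp")):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns")
            try:
                points.append(FiducialPoint(float(parts[0]), int(parts[1]), parts[2]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return points


# ---------------------------------------------------------------------------
# templates


def write_template(template: AnnotatedTemplate, csv_path: str | Path) -> None:
    """Write the amplitude CSV and its JSON sidecar (same stem, ``.json``)."""
    csv_path = Path(csv_path)
    with open(csv_path, "w") as fh:
        fh.write("amplitude\n")
        for v in template.samples:
            fh.write(f"{v:.9g}\n")
    meta = {
        "fs": template.fs,
        "onset_idx": int(template.onset_idx),
        "ms_idx": int(template.ms_idx),
        "sys_idx": int(template.sys_idx),
        "id": template.id,
    }
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def read_template(csv_path: str | Path) -> AnnotatedTemplate:
    csv_path = Path(csv_path)
    rows = _parse_delimited(csv_path)
    if not rows:
        raise ParseError(f"{csv_path}: empty template file")
    samples = np.asarray(rows, dtype=float).ravel()
    with open(csv_path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return AnnotatedTemplate(
        samples=samples,
        fs=float(meta["fs"]),
        onset_idx=int(meta["onset_idx"]),
        ms_idx=int(meta["ms_idx"]),
        sys_idx=int(meta["sys_idx"]),
        id=str(meta.get("id", csv_path.stem)),
    )
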