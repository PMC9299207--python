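"""Fiducial classification metrics and interbeat-interval (IBI) agreement.

Predictions and ground truth are matched per fiducial class by greedy
nearest-in-time one-to-one pairing within a tolerance window; matched pairs
are true positives, unmatched predictions false positives, unmatched truth
false negatives.  Precision, recall, F1 and the timestamp RMSE over matched
pairs summarize identification quality per class.

IBIs are successive differences of one class's fiducial times, anchored at
the later beat.  Implausible intervals outside [300, 1500] ms are discarded
before agreement is scored by mean absolute error and Pearson correlation
over truth/prediction pairs whose anchors lie within one second.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .io import FiducialPoint

__all__ = [
    "MatchResult",
    "IBISeries",
    "match_events",
    "classification_metrics",
    "timestamp_rmse",
    "ibi_from_fiducials",
    "plausibility_filter",
    "ibi_agreement",
    "evaluate_fiducials",
]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[float, float]] = field(default_factory=list)  # (pred_ts, truth_ts)


@dataclass
class IBISeries:
    values: np.ndarray  # milliseconds
    anchor_timestamps: np.ndarray  # seconds, time of the later beat
    source_label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.anchor_timestamps = np.asarray(self.anchor_timestamps, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("IBI values must be strictly positive")

    def __len__(self) -> int:
        return self.values.size


def _greedy_one_to_one(a: np.ndarray, b: np.ndarray, max_gap: float) -> list[tuple[int, int]]:
    """Greedy one-to-one pairing of two sorted time arrays, closest gaps first."""
    pairs: list[tuple[float, int, int]] = []
    for i, ta in enumerate(a):
        lo = int(np.searchsorted(b, ta - max_gap))
        hi = int(np.searchsorted(b, ta + max_gap, side="right"))
        for j in range(lo, hi):
            pairs.append((abs(ta - b[j]), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            out.append((i, j))
    return out


def match_events(
    pred: list[FiducialPoint], truth: list[FiducialPoint], tolerance_ms: float = 30.0
) -> MatchResult:
    """Greedy nearest-in-time one-to-one matching within a tolerance window."""
    pt = np.asarray([p.timestamp for p in pred])
    tt = np.asarray([p.timestamp for p in truth])
    if np.any(np.diff(pt) < 0) or np.any(np.diff(tt) < 0):
        raise ValueError("fiducial lists must be sorted by timestamp")
    matched = _greedy_one_to_one(pt, tt, tolerance_ms / 1000.0)
    pairs = sorted((float(pt[i]), float(tt[j])) for i, j in matched)
    return MatchResult(tp=len(pairs), fp=len(pred) - len(pairs), fn=len(truth) - len(pairs), matched_pairs=pairs)


def classification_metrics(m: MatchResult) -> tuple[float | None, float | None, float | None]:
    """Precision, recall and F1.  Empty denominators yield ``None``, not 0/0."""
    precision = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else None
    recall = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def timestamp_rmse(m: MatchResult) -> float:
    """RMSE (ms) of predicted vs true timestamps over matched pairs only."""
    if m.tp < 1:
        raise ValueError("no positive predictions: RMSE undefined")
    diffs = np.asarray([p - t for p, t in m.matched_pairs]) * 1000.0
    return float(np.sqrt(np.mean(diffs**2)))


def ibi_from_fiducials(points: list[FiducialPoint]) -> IBISeries:
    """Successive time differences (ms) of one class's fiducials."""
    if len(points) < 2:
        raise ValueError("need at least 2 fiducial points for an IBI series")
    labels = {p.label for p in points}
    if len(labels) != 1:
        raise ValueError(f"IBI series must come from a single fiducial class, got {sorted(labels)}")
    ts = np.asarray([p.timestamp for p in points])
    if np.any(np.diff(ts) <= 0):
        raise ValueError("fiducial points must be strictly increasing in time")
    return IBISeries(np.diff(ts) * 1000.0, ts[1:], points[0].label)


def plausibility_filter(ibis: IBISeries, lo: float = 300.0, hi: float = 1500.0) -> IBISeries:
    """Keep only physiologically plausible intervals, ``lo <= IBI <= hi`` (ms)."""
    keep = (ibis.values >= lo) & (ibis.values <= hi)
    return IBISeries(ibis.values[keep], ibis.anchor_timestamps[keep], ibis.source_label)


def ibi_agreement(
    pred: IBISeries, truth: IBISeries, max_gap_s: float = 1.0
) -> tuple[float | None, float | None, int]:
    """MAE (ms) and Pearson r between paired predicted and true IBIs.

    Each truth interval is paired with the closest-in-time predicted interval
    whose anchor lies within ``max_gap_s`` (one-to-one, closest gaps first).
    Returns ``(mae_ms, pearson_r, n_pairs)``; both metrics are ``None`` when
    no pairs exist, and r is ``None`` when it is undefined (fewer than two
    pairs or zero variance).
    """
    if len(pred) == 0 or len(truth) == 0:
        return None, None, 0
    matched = _greedy_one_to_one(truth.anchor_timestamps, pred.anchor_timestamps, max_gap_s)
    if not matched:
        return None, None, 0
    t_vals = np.asarray([truth.values[i] for i, _ in matched])
    p_vals = np.asarray([pred.values[j] for _, j in matched])
    mae = float(np.mean(np.abs(p_vals - t_vals)))
    if len(matched) >= 2 and np.std(t_vals) > 0 and np.std(p_vals) > 0:
        r = float(_stats.pearsonr(p_vals, t_vals).statistic)
    else:
        r = None
    return mae, r, len(matched)


def evaluate_fiducials(
    pred: list[FiducialPoint],
    truth: list[FiducialPoint],
    tolerance_ms: float = 30.0,
    ibi_lo_ms: float = 300.0,
    ibi_hi_ms: float = 1500.0,
    ibi_max_gap_s: float = 1.0,
) -> dict:
    """Full per-class report: P/R/F1/RMSE and IBI MAE/r/n per fiducial source."""
    report: dict[str, dict] = {"classification": {}, "ibi": {}}
    for label in ("SYS", "MS", "EP"):
        p = sorted((x for x in pred if x.label == label), key=lambda q: q.timestamp)
        t = sorted((x for x in truth if x.label == label), key=lambda q: q.timestamp)
        m = match_events(p, t, tolerance_ms)
        precision, recall, f1 = classification_metrics(m)
        rmse = timestamp_rmse(m) if m.tp >= 1 else None
        report["classification"][label] = {
            "tp": m.tp, "fp": m.fp, "fn": m.fn,
            "precision": precision, "recall": recall, "f1": f1, "rmse_ms": rmse,
        }
        if len(p) >= 2 and len(t) >= 2:
            try:
                pred_ibi = plausibility_filter(ibi_from_fiducials(p), ibi_lo_ms, ibi_hi_ms)
                truth_ibi = plausibility_filter(ibi_from_fiducials(t), ibi_lo_ms, ibi_hi_ms)
                mae, r, n = ibi_agreement(pred_ibi, truth_ibi, ibi_max_gap_s)
            except ValueError:
                mae, r, n = None, None, 0
        else:
            mae, r, n = None, None, 0
        report["ibi"][label] = {"mae_ms": mae, "pearson_r": r, "n_pairs": n}
    return report
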