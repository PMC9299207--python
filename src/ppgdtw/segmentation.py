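"""Boosted endpoint decision process and fiducial mapping.

For each batch the stream is reduced to a set of candidate endpoints (all
local minima) with heuristic scores, and an average cycle length l_X from the
dominant frequency.  Starting at the first candidate, the next endpoint is
searched in the window ``[start + alpha*l_X, start + beta*l_X]``:

* a candidate falling *before* the window (closer than one plausible cycle)
  triggers a start reset — under the default ``score_gated`` policy only when
  its heuristic score strictly beats the current start's, which keeps
  dicrotic-notch minima from stealing the start; the ``literal`` policy
  always resets;
* within the window the candidate maximizing the fused likelihood
  ``P(e) = P(c|x) * exp(-gamma * d)`` is accepted (ranked in log space so
  large gamma*d cannot underflow), where d is the streaming DTW distance of
  the putative cycle prefix to the template;
* an empty window abandons the search and restarts at the first candidate
  past the window.

Each accepted endpoint closes a cycle and becomes the next cycle's start, so
consecutive cycles share their boundary onsets.  Fiducials are transferred
from the template through the warping path of the accepted cycle.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .heuristics import detect_candidates, estimate_cycle_length, score_candidates
from .io import AnnotatedTemplate, FiducialPoint, SignalStream, first_derivative
from .spring import WarpingPath, dtw_full, last_row_series, normalize

__all__ = [
    "CardiacCycle",
    "endpoint_likelihood",
    "segment_stream",
    "map_fiducials",
    "map_fiducial_indices",
    "iter_batches",
    "cycles_to_fiducials",
]

log = logging.getLogger(__name__)


@dataclass
class CardiacCycle:
    """A detected segment [start_idx, end_idx] with mapped fiducials."""

    start_idx: int
    end_idx: int
    fiducials: dict[str, FiducialPoint]
    dtw_distance: float
    path: WarpingPath
    template_id: str

    @property
    def mean_cost(self) -> float:
        """Average warping-path distance |w| of this cycle against its template."""
        return self.path.mean_cost


def endpoint_likelihood(p_c: float, p_d: float) -> float:
    """Fused endpoint likelihood: the product of the two component scores."""
    if not (0.0 <= p_c <= 1.0 and 0.0 <= p_d <= 1.0):
        raise ValueError(f"likelihood components must be in [0, 1], got ({p_c}, {p_d})")
    return p_c * p_d


def map_fiducial_indices(
    cycle_samples: np.ndarray, template_indices: dict[str, int], path: WarpingPath, template_samples: np.ndarray
) -> dict[str, int]:
    """Map template fiducial indices to cycle-relative indices through a path.

    A template index j* may align to several stream samples; the one with the
    smallest pointwise cost wins, earliest index on ties.  The endpoint (EP)
    is forced to the cycle start — that is what "endpoint" means.
    """
    pairs = path.pairs
    if pairs[-1, 1] != len(template_samples) - 1 or pairs[0, 0] != 0 or pairs[0, 1] != 0:
        raise ValueError("malformed warping path: must align the full cycle to the full template")
    mapped: dict[str, int] = {"EP": 0}
    for label in ("MS", "SYS"):
        j_star = template_indices[label]
        rows = pairs[pairs[:, 1] == j_star, 0]
        if rows.size == 0:
            raise ValueError(f"warping path does not visit template index {j_star}")
        costs = np.abs(cycle_samples[rows] - template_samples[j_star])
        mapped[label] = int(rows[int(np.argmin(costs))])  # argmin: earliest on ties
    return mapped


def map_fiducials(
    cycle_samples: np.ndarray,
    template: AnnotatedTemplate,
    path: WarpingPath,
    template_samples: np.ndarray | None = None,
) -> dict[str, int]:
    """Cycle-relative fiducial indices for a cycle aligned to ``template``."""
    ts = template.samples if template_samples is None else template_samples
    return map_fiducial_indices(np.asarray(cycle_samples, dtype=float), template.fiducial_indices, path, ts)


def iter_batches(stream: SignalStream, config: RunConfig) -> list[tuple[int, int]]:
    """Batch spans (start, end) in samples.

    A trailing batch too short to hold two cycles at the slowest plausible
    rate is merged into the previous one.
    """
    n = len(stream)
    step = int(round(config.batch_seconds * stream.fs))
    min_len = int(math.ceil(2.0 / config.hr_band[0] * stream.fs))
    if n < min_len:
        raise ValueError(
            f"stream of {stream.duration:.2f} s is shorter than two cycles at {config.hr_band[0]} Hz"
        )
    spans = [(s, min(s + step, n)) for s in range(0, n, step)]
    if len(spans) > 1 and spans[-1][1] - spans[-1][0] < min_len:
        spans[-2] = (spans[-2][0], n)
        spans.pop()
    return spans


def _cycle_from_bounds(
    stream: SignalStream,
    start: int,
    end: int,
    xn_slice: np.ndarray,
    yn: np.ndarray,
    template: AnnotatedTemplate,
    config: RunConfig,
) -> CardiacCycle:
    """Build a CardiacCycle for absolute bounds; fiducials via the warping path.

    The closing alignment renormalizes the cycle slice on its own range:
    respiration scales individual beats, and aligning shape-to-shape keeps
    the template's fiducials from sliding along slopes to chase amplitude.
    """
    xc = normalize(xn_slice, config.normalization) if config.normalization != "none" else xn_slice
    yc = normalize(yn, config.normalization) if config.normalization != "none" else yn
    dist, path = dtw_full(xc, yc, window=config.window)
    rel = map_fiducial_indices(xc, template.fiducial_indices, path, yc)
    fids = {label: stream.point(start + idx, label) for label, idx in rel.items()}
    if not (start <= fids["MS"].index <= fids["SYS"].index <= end):
        log.warning(
            "fiducial ordering violated in cycle [%d, %d]: MS=%d SYS=%d",
            start, end, fids["MS"].index, fids["SYS"].index,
        )
    return CardiacCycle(
        start_idx=start,
        end_idx=end,
        fiducials=fids,
        dtw_distance=dist,
        path=path,
        template_id=template.id,
    )


def _segment_batch(
    stream: SignalStream,
    bs: int,
    be: int,
    template: AnnotatedTemplate,
    config: RunConfig,
    boost: bool = True,
) -> list[CardiacCycle]:
    """Run the endpoint search over one batch; returns cycles in absolute indices."""
    xb = stream.samples[bs:be]
    sub = SignalStream(xb, stream.fs, stream.t0 + bs / stream.fs)
    est = estimate_cycle_length(sub, config.hr_band)
    lx = est.l_x
    cands = detect_candidates(xb)
    if cands.size == 0:
        log.warning("batch [%d, %d): no candidate endpoints, skipping", bs, be)
        return []
    deriv = first_derivative(sub)
    scored = score_candidates(cands, deriv)
    p = np.asarray([c.p_c for c in scored])
    if not boost:
        p = np.ones_like(p)
    xn = normalize(xb, config.normalization)
    yn = normalize(template.samples, config.normalization)

    cycles: list[CardiacCycle] = []
    nc = cands.size
    i = 0
    while i < nc:
        start = int(cands[i])
        # --- reset phase: candidates closer than alpha*l_X to the start
        j = i + 1
        while j < nc and cands[j] < start + config.alpha * lx:
            if config.reset_policy == "literal" or p[j] > p[i]:
                i = j
                start = int(cands[i])
                j = i + 1
            else:
                j += 1
        la = start + config.alpha * lx
        lb = start + config.beta * lx
        # --- accept phase: candidates in [l_alpha, l_beta]
        kk = j
        win: list[int] = []
        while kk < nc and cands[kk] <= lb:
            if cands[kk] >= la:
                win.append(kk)
            kk += 1
        if not win:
            # abandon: restart at the first candidate strictly after l_beta
            nxt = None
            for k2 in range(j, nc):
                if cands[k2] > lb:
                    nxt = k2
                    break
            if nxt is None:
                break
            i = nxt
            continue
        last = int(cands[win[-1]])
        row = last_row_series(xn[start : last + 1], yn)
        d = row[cands[win] - start]
        with np.errstate(divide="ignore"):
            score = np.where(p[win] > 0, np.log(np.maximum(p[win], 1e-300)), -np.inf) - config.gamma * d
        best = win[int(np.argmax(score))]  # argmax returns the earliest maximizer
        end = int(cands[best])
        cycles.append(_cycle_from_bounds(stream, bs + start, bs + end, xn[start : end + 1], yn, template, config))
        i = best
    return cycles


def segment_stream(
    stream: SignalStream,
    template: AnnotatedTemplate,
    config: RunConfig | None = None,
    boost: bool = True,
) -> list[CardiacCycle]:
    """Segment a (filtered) stream into cardiac cycles with one template.

    ``boost=False`` disables the heuristic factor (all candidate scores forced
    to 1) so the contribution of the fused likelihood can be measured.
    The trailing stream portion after the last accepted endpoint of each
    batch is discarded as an incomplete cycle.
    """
    config = config or RunConfig()
    cycles: list[CardiacCycle] = []
    for bs, be in iter_batches(stream, config):
        cycles.extend(_segment_batch(stream, bs, be, template, config, boost=boost))
    return cycles


def bootstrap_template(stream: SignalStream, config: RunConfig | None = None) -> AnnotatedTemplate:
    """Derive a prime template from the first batch of a stream.

    Picks the pair of candidate onsets spaced within the plausible window
    around the estimated cycle length whose combined upstroke scores are
    highest, cuts that cycle, and annotates it heuristically (onset at the
    start, SYS at the maximum, MS at the steepest rise between them).  A
    bootstrap cannot match an expert-annotated template but lets the dynamic
    ensemble start without one.
    """
    config = config or RunConfig()
    bs, be = iter_batches(stream, config)[0]
    xb = stream.samples[bs:be]
    sub = SignalStream(xb, stream.fs, stream.t0 + bs / stream.fs)
    lx = estimate_cycle_length(sub, config.hr_band).l_x
    cands = detect_candidates(xb)
    if cands.size < 2:
        raise ValueError("cannot bootstrap a template: fewer than two candidate onsets")
    p = np.asarray([c.p_c for c in score_candidates(cands, first_derivative(sub))])
    best, best_score = None, -np.inf
    for i in range(cands.size):
        for j in range(i + 1, cands.size):
            gap = cands[j] - cands[i]
            if gap > config.beta * lx:
                break
            if gap >= config.alpha * lx and p[i] + p[j] > best_score:
                best, best_score = (int(cands[i]), int(cands[j])), p[i] + p[j]
    if best is None:
        raise ValueError("cannot bootstrap a template: no candidate pair spans a plausible cycle")
    s, e = best
    samples = xb[s : e + 1].copy()
    sys_i = int(np.argmax(samples))
    d = np.diff(samples)
    ms = 1 + int(np.argmax(d[1:sys_i])) if sys_i > 2 else 1
    if not (0 < ms < sys_i):
        raise ValueError("bootstrap cycle has no usable upstroke")
    return AnnotatedTemplate(samples, stream.fs, 0, ms, sys_i, id="bootstrap")


def cycles_to_fiducials(cycles: list[CardiacCycle], stream: SignalStream) -> list[FiducialPoint]:
    """Flatten cycles to a sorted, de-duplicated fiducial list.

    Shared boundary onsets are emitted once; the final endpoint of each
    contiguous run of cycles is emitted as an EP as well (it is an onset even
    though no following cycle was accepted).
    """
    out: set[FiducialPoint] = set()
    for k, c in enumerate(cycles):
        out.update(c.fiducials.values())
        is_chain_end = k + 1 >= len(cycles) or cycles[k + 1].start_idx != c.end_idx
        if is_chain_end:
            out.add(stream.point(c.end_idx, "EP"))
    return sorted(out, key=lambda p: (p.timestamp, p.label))
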