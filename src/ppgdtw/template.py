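"""Automated dynamic template ensemble.

A bounded set of annotated single-cycle templates adapts the segmenter to
evolving waveform morphology.  The ensemble starts from the expert-annotated
*prime* template.  After each region of ``u`` seconds of stream:

* every template's per-cycle average warping-path distance |w| over the
  region is compared, and the template with the lowest mean is the optimal
  template for the region (its usage counter is incremented);
* if the ensemble is not full, a new template is generated — the DTW
  barycenter average (DBA) of the cycles detected in the region, annotated by
  warping the prime template's fiducials onto the consensus;
* if the ensemble is full and the optimal template is not the prime, the
  least frequently used template is evicted to make room for the new
  consensus (ties evict the oldest; the just-selected optimum is never
  evicted).

Usage is counted as regions won.  Each template analyzes the whole batch
through the identical single-template code path and regions attribute cycles
by where their endpoint falls, so cycle continuity is preserved across region
boundaries and a one-template ensemble reproduces the single-template run
exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .io import AnnotatedTemplate, SignalStream
from .segmentation import CardiacCycle, _segment_batch, iter_batches, map_fiducial_indices
from .spring import dtw_full, normalize

__all__ = [
    "TemplateEnsemble",
    "dba_consensus",
    "annotate_consensus",
    "select_optimal",
    "update_ensemble",
    "segment_stream_dynamic",
]

log = logging.getLogger(__name__)


@dataclass
class TemplateEnsemble:
    """At most ``k`` annotated templates plus the always-kept prime reference."""

    prime: AnnotatedTemplate
    k: int = 3
    templates: list[AnnotatedTemplate] = field(default_factory=list)
    _counter: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.templates:
            self.templates = [self.prime]

    @property
    def prime_id(self) -> str:
        return self.prime.id

    def get(self, template_id: str) -> AnnotatedTemplate:
        for t in self.templates:
            if t.id == template_id:
                return t
        raise KeyError(template_id)

    def fresh_id(self) -> str:
        self._counter += 1
        return f"dba-{self._counter:03d}"


def dba_consensus(
    cycles: list[np.ndarray], max_iter: int = 30, tol: float = 1e-6
) -> np.ndarray:
    """DTW barycenter average of a set of cycles.

    Cycles are linearly resampled to the median cycle length so the average
    has a fixed, annotatable length.  The average is initialized from the
    medoid (the input minimizing total DTW distance to the others) and
    refined by the classical DBA update: align every cycle to the current
    average, replace each average sample by the mean of all cycle samples
    mapped onto it.  The update never increases the sum of DTW distances to
    the average; iteration stops at ``tol`` mean change or ``max_iter``.
    """
    if not cycles:
        raise ValueError("dba_consensus requires at least one cycle")
    arrs = [np.asarray(c, dtype=float) for c in cycles]
    if len(arrs) == 1:
        return arrs[0].copy()
    L = int(round(float(np.median([a.size for a in arrs]))))
    L = max(L, 2)
    res = [
        np.interp(np.linspace(0.0, 1.0, L), np.linspace(0.0, 1.0, a.size), a) if a.size != L else a.copy()
        for a in arrs
    ]
    # medoid initialization
    dmat = np.zeros((len(res), len(res)))
    for a in range(len(res)):
        for b in range(a + 1, len(res)):
            dist, _ = dtw_full(res[a], res[b])
            dmat[a, b] = dmat[b, a] = dist
    avg = res[int(np.argmin(dmat.sum(axis=1)))].copy()

    for _ in range(max_iter):
        sums = np.zeros(L)
        counts = np.zeros(L)
        for series in res:
            _, path = dtw_full(series, avg)
            for i, j in path.pairs:
                sums[j] += series[i]
                counts[j] += 1
        new_avg = sums / np.maximum(counts, 1)
        delta = float(np.mean(np.abs(new_avg - avg)))
        avg = new_avg
        if delta < tol:
            break
    return avg


def dba_objective(cycles: list[np.ndarray], avg: np.ndarray) -> float:
    """Sum of DTW distances from each (resampled) cycle to the average."""
    total = 0.0
    for c in cycles:
        a = np.asarray(c, dtype=float)
        if a.size != avg.size:
            a = np.interp(np.linspace(0.0, 1.0, avg.size), np.linspace(0.0, 1.0, a.size), a)
        dist, _ = dtw_full(a, avg)
        total += dist
    return total


def annotate_consensus(
    consensus: np.ndarray, prime: AnnotatedTemplate, fs: float | None = None, template_id: str = "consensus"
) -> AnnotatedTemplate:
    """Transfer the prime template's fiducials to a consensus cycle.

    The prime is aligned to the consensus with full DTW (both min–max
    normalized for the alignment only) and each fiducial index is mapped
    through the warping path: of all consensus samples aligned to the prime
    fiducial, the one with minimal pointwise cost wins, earliest on ties.
    A consensus whose mapped indices violate onset < MS < SYS is rejected.
    """
    consensus = np.asarray(consensus, dtype=float)
    pn = normalize(prime.samples, "minmax")
    cn = normalize(consensus, "minmax")
    _, path = dtw_full(pn, cn)
    # roles swapped relative to cycle mapping: stream side = prime, template side = consensus
    mapped: dict[str, int] = {}
    for label, i_star in prime.fiducial_indices.items():
        cols = path.pairs[path.pairs[:, 0] == i_star, 1]
        costs = np.abs(cn[cols] - pn[i_star])
        mapped[label] = int(cols[int(np.argmin(costs))])
    if not (mapped["EP"] < mapped["MS"] < mapped["SYS"]):
        raise ValueError(
            f"consensus annotation rejected: mapped indices {mapped} violate onset < MS < SYS"
        )
    return AnnotatedTemplate(
        samples=consensus,
        fs=prime.fs if fs is None else fs,
        onset_idx=mapped["EP"],
        ms_idx=mapped["MS"],
        sys_idx=mapped["SYS"],
        id=template_id,
        usage_count=0,
    )


def select_optimal(region_results: dict[str, list[float]], ensemble: TemplateEnsemble) -> str:
    """Template id with the lowest mean per-cycle |w| over a region.

    Ties favour the prime template, then the lexicographically lowest id.
    The winner's usage counter is incremented.
    """
    means = {tid: float(np.mean(costs)) for tid, costs in region_results.items() if len(costs) > 0}
    if not means:
        raise ValueError("select_optimal: no template produced any cycle in the region")
    best = min(means.values())
    tied = sorted(tid for tid, m in means.items() if m == best)
    winner = ensemble.prime_id if ensemble.prime_id in tied else tied[0]
    ensemble.get(winner).usage_count += 1
    return winner


def update_ensemble(
    ensemble: TemplateEnsemble,
    region_cycles: list[np.ndarray],
    region_results: dict[str, list[float]],
    y_opt: str,
    config: RunConfig | None = None,
) -> AnnotatedTemplate | None:
    """Apply the ensemble update protocol after a region completes.

    Returns the newly added template (the caller may trigger a reanalysis
    pass with it) or ``None`` when no update was triggered.
    """
    config = config or RunConfig()
    if not region_cycles:
        log.warning("region produced no cycles; ensemble unchanged")
        return None
    grow = len(ensemble.templates) < ensemble.k
    swap = not grow and y_opt != ensemble.prime_id
    if not grow and not swap:
        return None
    try:
        consensus = dba_consensus(region_cycles, config.dba_max_iter, config.dba_tol)
        new_t = annotate_consensus(consensus, ensemble.prime, template_id=ensemble.fresh_id())
    except ValueError as exc:
        log.warning("consensus template rejected: %s", exc)
        return None
    if swap:
        # least frequently used; ties evict the oldest; never the current optimum
        evictable = [t for t in ensemble.templates if t.id != y_opt]
        victim = min(evictable, key=lambda t: t.usage_count)  # min is stable -> oldest on ties
        ensemble.templates = [t for t in ensemble.templates if t is not victim]
        log.info("evicted template %s (usage %d)", victim.id, victim.usage_count)
    ensemble.templates.append(new_t)
    return new_t


def segment_stream_dynamic(
    stream: SignalStream,
    ensemble: TemplateEnsemble,
    config: RunConfig | None = None,
) -> list[CardiacCycle]:
    """Segment a stream with the dynamic template ensemble.

    Per batch, every template segments the batch independently; per region of
    ``config.region_seconds`` the optimal template's cycles are reported and
    the ensemble is updated.  When a template is added and
    ``config.reanalysis`` is set, the region is re-analyzed with it and the
    new cycles replace the reported ones if they align strictly better.
    """
    config = config or RunConfig()
    all_cycles: list[CardiacCycle] = []
    for bs, be in iter_batches(stream, config):
        cache: dict[str, list[CardiacCycle]] = {
            t.id: _segment_batch(stream, bs, be, t, config) for t in ensemble.templates
        }
        rstep = max(1, int(round(config.region_seconds * stream.fs)))
        edges = list(range(bs, be, rstep)) + [be]
        if len(edges) > 2 and edges[-1] - edges[-2] < rstep // 2:
            edges.pop(-2)  # merge a short trailing region
        for r0, r1 in zip(edges[:-1], edges[1:]):
            in_region = {
                tid: [c for c in cyc if r0 <= c.end_idx < r1 or (r1 == be and c.end_idx == be)]
                for tid, cyc in cache.items()
            }
            results = {tid: [c.mean_cost for c in cyc] for tid, cyc in in_region.items()}
            if not any(results.values()):
                log.warning("region [%d, %d): no cycles from any template", r0, r1)
                continue
            y_opt = select_optimal(results, ensemble)
            reported = in_region[y_opt]
            region_arrays = [stream.samples[c.start_idx : c.end_idx + 1] for c in reported]
            added = update_ensemble(ensemble, region_arrays, results, y_opt, config)
            if added is not None:
                cache[added.id] = _segment_batch(stream, bs, be, added, config)
                if config.reanalysis:
                    new_cycles = [c for c in cache[added.id] if r0 <= c.end_idx < r1]
                    if new_cycles and reported:
                        new_mean = float(np.mean([c.mean_cost for c in new_cycles]))
                        old_mean = float(np.mean([c.mean_cost for c in reported]))
                        if new_mean < old_mean:
                            ensemble.get(y_opt).usage_count -= 1
                            added.usage_count += 1
                            reported = new_cycles
            all_cycles.extend(reported)
    return all_cycles
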