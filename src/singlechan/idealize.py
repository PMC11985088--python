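"""Baseline estimation and two-level idealization of single-channel traces.

The jump detector is a higher-order Hinkley (cumulative-sum) detector: the
order-1 statistic is the classic cusum of deviations toward the alternative
level, clipped at zero; each higher order accumulates the one below it, which
boosts sensitivity to brief events at a given false-positive rate.  A jump
fires when the order-p statistic crosses the threshold, the jump time is
placed at the most recent zero of the order-1 statistic, and the detector
re-arms toward the other level.  Events shorter than the dead time (tied to
the recording filter's rise time) are merged into their neighbors: they are
not resolvable and would otherwise appear as spurious brief events.

The measured open-channel amplitude i_meas is deliberately the *filtered*
amplitude: flicker gating faster than the filter bandwidth is not
deconvolved, so i_meas < i_true at voltages where the channel flickers,
exactly as the recording instrumentation reports it.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .trace import Trace

__all__ = [
    "Trace",
    "BaselineEstimate",
    "DetectorConfig",
    "EventTable",
    "estimate_baseline",
    "hinkley_detect",
    "open_probability",
    "estimate_amplitude",
]


@dataclass(frozen=True)
class BaselineEstimate:
    """Closed-channel level and current noise of a trace, both in pA."""

    closed_level: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class DetectorConfig:
    """Hinkley detector settings.

    order
        Detector order p; higher orders detect briefer events (default 4).
    threshold_lambda
        Detection threshold on the order-p statistic of noise-standardized
        deviations (default 6, i.e. 6 noise-sd units).
    open_level_hint
        Open-channel level in pA; ``None`` estimates it from the trace and
        refines it from detected open segments (two-pass idealization).
    dead_time
        Minimum resolvable event in seconds; ``None`` derives
        ``0.4 / filter_cutoff`` from the trace metadata.  Sub-dead-time
        events are merged, not reported.
    edge_margin
        Samples excluded at each event boundary when averaging amplitudes;
        ``None`` derives ``ceil(2 fs / filter_cutoff)``.
    """

    order: int = 4
    threshold_lambda: float = 6.0
    open_level_hint: float | None = None
    dead_time: float | None = None
    edge_margin: int | None = None

    def __post_init__(self) -> None:
        if self.order < 1 or int(self.order) != self.order:
            raise ValueError("order must be an integer >= 1")
        if self.threshold_lambda <= 0:
            raise ValueError("threshold_lambda must be positive")
        if self.dead_time is not None and self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        if self.edge_margin is not None and self.edge_margin < 0:
            raise ValueError("edge_margin must be >= 0")

    def resolved_dead_time(self, trace: Trace) -> float:
        if self.dead_time is not None:
            return self.dead_time
        cutoff = trace.filter_cutoff
        if cutoff is None:
            cutoff = trace.fs / 5.0  # conservative guess: fs = 5 x cutoff
        return 0.4 / cutoff

    def resolved_edge_margin(self, trace: Trace) -> int:
        if self.edge_margin is not None:
            return int(self.edge_margin)
        cutoff = trace.filter_cutoff
        if cutoff is None:
            cutoff = trace.fs / 5.0
        return int(math.ceil(2.0 * trace.fs / cutoff))


@dataclass
class EventTable:
    """Contiguous, strictly alternating open/closed events of one trace.

    ``amplitudes`` holds each event's mean current level in pA (NaN when the
    event is too short for an edge-excluded mean).  ``flags`` carries
    detector warnings such as ``separation-below-detectability``.
    """

    states: np.ndarray  # bool, True = open
    starts: np.ndarray  # seconds
    durations: np.ndarray  # seconds
    t_total: float
    amplitudes: np.ndarray
    flags: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        self.starts = np.asarray(self.starts, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        n = self.states.size
        if not (self.starts.size == self.durations.size == self.amplitudes.size == n):
            raise ValueError("event columns must have equal length")
        if n:
            if np.any(self.states[1:] == self.states[:-1]):
                raise ValueError("event states must strictly alternate")
            if np.any(self.durations <= 0):
                raise ValueError("event durations must be positive")
            ends = self.starts + self.durations
            if np.any(np.abs(ends[:-1] - self.starts[1:]) > 1e-9):
                raise ValueError("events must be contiguous")

    @property
    def n_events(self) -> int:
        return self.states.size

    @property
    def t_open(self) -> float:
        """Summed open dwell time in seconds."""
        return float(self.durations[self.states].sum())


def estimate_baseline(trace: Trace) -> BaselineEstimate:
    """Robust closed level and noise sd of a trace.

    The closed level is the mode of the amplitude distribution (channels here
    spend most of the time closed, so the dominant mode is the baseline),
    located by a histogram peak and sharpened by iterating a one-sigma
    trimmed mean.  The noise sd comes from the median absolute deviation of
    first differences rescaled to a Gaussian sd, which open events barely
    perturb.
    """
    x = trace.samples
    if x.size < 100:
        raise ValueError(
            f"baseline estimation needs >= 100 samples, got {x.size}"
        )
    dx = np.diff(x)
    sigma = 1.4826 * float(np.median(np.abs(dx - np.median(dx)))) / math.sqrt(2.0)
    if sigma == 0.0:
        # noiseless trace: the closed level is the most common exact value
        values, counts = np.unique(x, return_counts=True)
        return BaselineEstimate(float(values[np.argmax(counts)]), 0.0)
    lo, hi = np.quantile(x, [0.001, 0.999])
    if hi <= lo:
        return BaselineEstimate(float(np.median(x)), sigma)
    nbins = max(10, min(2000, int(math.ceil((hi - lo) / (sigma / 2.0)))))
    hist, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    center = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    for _ in range(5):  # trimmed-mean iteration converges on the mode
        sel = np.abs(x - center) <= sigma
        if not np.any(sel):
            break
        center = float(np.mean(x[sel]))
    return BaselineEstimate(float(center), sigma)


@njit(cache=True)
def _hohd_scan(x, closed, open_, sigma, lam, order):  # pragma: no cover - numba
    """Sequential higher-order Hinkley scan.

    Returns sample indices at which the idealized state flips; the first
    flip is closed -> open (a flip at index 0 means the trace starts open).
    """
    n = x.size
    trans = np.empty(n, np.int64)
    m = 0
    g = np.zeros(order)
    state_open = False
    s = 1.0 if open_ > closed else -1.0
    mid = 0.5 * (closed + open_)
    last_zero = -1
    for i in range(n):
        d = s * (x[i] - mid) / sigma
        if state_open:
            d = -d
        g0 = g[0] + d
        if g0 <= 0.0:
            for k in range(order):
                g[k] = 0.0
            last_zero = i
        else:
            g[0] = g0
            for k in range(1, order):
                g[k] += g[k - 1]
            if g[order - 1] >= lam:
                trans[m] = last_zero + 1
                m += 1
                state_open = not state_open
                for k in range(order):
                    g[k] = 0.0
                last_zero = i
    return trans[:m]


def _merge_short_events(
    states: np.ndarray, durations: np.ndarray, dead_time: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge events shorter than the dead time into their neighbors.

    Shortest-first, via a doubly linked list plus a heap; interior short
    events fuse their two (same-state) neighbors into one event, edge events
    are absorbed by their single neighbor.  Total duration is conserved.
    """
    n = durations.size
    if n <= 1 or dead_time <= 0:
        return states, durations
    dur = durations.astype(float).copy()
    st = states.copy()
    prev = np.arange(-1, n - 1)
    nxt = np.arange(1, n + 1)
    alive = np.ones(n, dtype=bool)
    heap = [(dur[i], i) for i in range(n) if dur[i] < dead_time]
    heapq.heapify(heap)
    n_alive = n
    while heap and n_alive > 1:
        d, i = heapq.heappop(heap)
        if not alive[i] or dur[i] != d or dur[i] >= dead_time:
            continue
        p, q = prev[i], nxt[i]
        has_p = p >= 0 and alive[p]
        has_q = q < n and alive[q]
        if has_p and has_q:
            dur[p] += dur[i] + dur[q]
            alive[i] = alive[q] = False
            n_alive -= 2
            nq = nxt[q]
            nxt[p] = nq
            if nq < n:
                prev[nq] = p
            if dur[p] < dead_time:
                heapq.heappush(heap, (dur[p], p))
        elif has_q:  # first event
            dur[q] += dur[i]
            alive[i] = False
            n_alive -= 1
            prev[q] = -1
            if dur[q] < dead_time:
                heapq.heappush(heap, (dur[q], q))
        elif has_p:  # last event
            dur[p] += dur[i]
            alive[i] = False
            n_alive -= 1
            nxt[p] = n
            if dur[p] < dead_time:
                heapq.heappush(heap, (dur[p], p))
        else:
            break
    return st[alive], dur[alive]


def _event_amplitudes(
    x: np.ndarray, fs: float, starts: np.ndarray, durations: np.ndarray, margin: int
) -> np.ndarray:
    """Per-event mean level, excluding ``margin`` samples at each boundary.

    Falls back to the plain event mean when the event is too short for the
    margins but at least one sample long; NaN otherwise.
    """
    amps = np.full(starts.size, np.nan)
    for k in range(starts.size):
        i0 = int(round(starts[k] * fs))
        i1 = int(round((starts[k] + durations[k]) * fs))
        i1 = min(i1, x.size)
        if i1 - i0 > 2 * margin:
            amps[k] = float(np.mean(x[i0 + margin : i1 - margin]))
        elif i1 > i0:
            amps[k] = float(np.mean(x[i0:i1]))
    return amps


def _single_closed_table(trace: Trace, flags: list[str], meta: dict) -> EventTable:
    return EventTable(
        states=np.array([False]),
        starts=np.array([0.0]),
        durations=np.array([trace.duration]),
        t_total=trace.duration,
        amplitudes=np.array([float(np.mean(trace.samples))]),
        flags=flags,
        meta=meta,
    )


def _detect_pass(
    x: np.ndarray,
    fs: float,
    closed: float,
    open_level: float,
    sigma: float,
    config: DetectorConfig,
    dead_time: float,
    margin: int,
) -> tuple[np.ndarray, np.ndarray]:
    sep = abs(open_level - closed)
    sigma_eff = max(sigma, 1e-6 * sep)
    trans = _hohd_scan(
        np.ascontiguousarray(x, dtype=np.float64),
        float(closed),
        float(open_level),
        float(sigma_eff),
        float(config.threshold_lambda),
        int(config.order),
    )
    first_open = True
    if trans.size and trans[0] == 0:  # trace starts in the open state
        trans = trans[1:]
        first_open = False
    bounds = np.concatenate(([0], trans, [x.size]))
    durations = np.diff(bounds) / fs
    n_ev = durations.size
    states = np.zeros(n_ev, dtype=bool)
    states[0] = not first_open
    states[1::2] = first_open
    states[0::2] = not first_open
    keep = durations > 0
    states, durations = _merge_short_events(states[keep], durations[keep], dead_time)
    return states, durations


def hinkley_detect(
    trace: Trace,
    baseline: BaselineEstimate | None = None,
    config: DetectorConfig | None = None,
) -> EventTable:
    """Two-level idealization of a trace with the higher-order Hinkley detector.

    Without an ``open_level_hint`` the open level is first guessed from the
    extreme amplitude quantiles and then re-estimated from the detected open
    segments (two-pass idealization).  Returns an empty table with a warning
    flag when the level separation is below detectability.
    """
    config = config or DetectorConfig()
    baseline = baseline or estimate_baseline(trace)
    x = trace.samples
    fs = trace.fs
    dead_time = config.resolved_dead_time(trace)
    if trace.duration <= dead_time:
        raise ValueError(
            f"trace ({trace.duration} s) is not longer than the dead time "
            f"({dead_time} s)"
        )
    margin = config.resolved_edge_margin(trace)
    closed = baseline.closed_level
    sigma = baseline.noise_sd
    meta = {
        "genotype": trace.genotype,
        "voltage_mV": trace.voltage,
        "closed_level_pA": closed,
        "noise_sd_pA": sigma,
        "order": config.order,
        "threshold_lambda": config.threshold_lambda,
        "dead_time_s": dead_time,
        "edge_margin": margin,
    }

    if config.open_level_hint is not None:
        open_level = float(config.open_level_hint)
    else:
        dev_hi = float(np.quantile(x, 0.999)) - closed
        dev_lo = float(np.quantile(x, 0.001)) - closed
        dev = dev_hi if abs(dev_hi) >= abs(dev_lo) else dev_lo
        open_level = closed + dev
    sep = abs(open_level - closed)
    if sep == 0.0:
        # constant (or symmetric featureless) trace: a single closed event
        return _single_closed_table(trace, [], meta)
    if sigma > 0 and sep <= config.threshold_lambda * sigma:
        warnings.warn(
            "open/closed separation below detectability; returning empty table",
            stacklevel=2,
        )
        return EventTable(
            states=np.empty(0, dtype=bool),
            starts=np.empty(0),
            durations=np.empty(0),
            t_total=trace.duration,
            amplitudes=np.empty(0),
            flags=["separation-below-detectability"],
            meta=meta,
        )

    states, durations = _detect_pass(
        x, fs, closed, open_level, sigma, config, dead_time, margin
    )
    # second pass with the open level re-estimated from accepted open segments
    if config.open_level_hint is None and np.any(states):
        starts = np.concatenate(([0.0], np.cumsum(durations)[:-1]))
        amps = _event_amplitudes(x, fs, starts, durations, margin)
        w = durations[states]
        a = amps[states]
        ok = np.isfinite(a)
        if np.any(ok):
            refined = float(np.sum(a[ok] * w[ok]) / np.sum(w[ok]))
            if abs(refined - closed) > (config.threshold_lambda * sigma if sigma > 0 else 0):
                states, durations = _detect_pass(
                    x, fs, closed, refined, sigma, config, dead_time, margin
                )
                open_level = refined
    starts = np.concatenate(([0.0], np.cumsum(durations)[:-1]))
    amplitudes = _event_amplitudes(x, fs, starts, durations, margin)
    meta["open_level_pA"] = open_level
    return EventTable(
        states=states,
        starts=starts,
        durations=durations,
        t_total=trace.duration,
        amplitudes=amplitudes,
        flags=[],
        meta=meta,
    )


def open_probability(events: EventTable) -> float:
    """P_O = (sum of open dwell times) / (total recording time)."""
    if events.n_events == 0:
        raise ValueError("cannot compute open probability of an empty event table")
    if events.t_total <= 0:
        raise ValueError("t_total must be positive")
    po = events.t_open / events.t_total
    return float(min(max(po, 0.0), 1.0))


def estimate_amplitude(
    trace: Trace,
    events: EventTable,
    baseline: BaselineEstimate,
    config: DetectorConfig | None = None,
) -> float:
    """Measured open-channel amplitude i_meas in pA (sign preserved).

    Duration-weighted mean of open-event sample means, excluding
    ``edge_margin`` samples at each event boundary, minus the closed level.
    Returns NaN with a warning when no open event is long enough.
    """
    config = config or DetectorConfig()
    margin = config.resolved_edge_margin(trace)
    fs = trace.fs
    x = trace.samples
    total = 0.0
    weight = 0.0
    for k in range(events.n_events):
        if not events.states[k]:
            continue
        i0 = int(round(events.starts[k] * fs))
        i1 = min(int(round((events.starts[k] + events.durations[k]) * fs)), x.size)
        if i1 - i0 > 2 * margin:
            seg = x[i0 + margin : i1 - margin]
            total += float(np.sum(seg))
            weight += seg.size
    if weight == 0:
        warnings.warn(
            "no open event long enough for amplitude estimation; returning NaN",
            stacklevel=2,
        )
        return float("nan")
    return total / weight - baseline.closed_level
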