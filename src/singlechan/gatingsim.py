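"""Synthetic single-channel data: Markov gating, acquisition physics, growth.

The generator realizes a minimal kinetic scheme that reproduces the two
experimentally separable gating phenomena of small viral K+ channels such as
Kcv: a *slow* gate whose stationary open fraction sets the open probability
P_O(V), and a *fast* voltage-dependent flicker gate whose sub-millisecond
closures are averaged out by the recording filter and therefore reduce the
apparent (measured) open-channel amplitude below the true one,
i_meas = i_true * p_fast in the fast-gating limit.

Both gates are independent two-state Markov processes; the channel conducts
iff both are open.  Rates follow a Boltzmann voltage dependence
``k(V) = k0 * exp(z * V / V_T)`` with V_T = RT/F at 25 degC.  The conducting
level is Ohmic, ``i_true(V) = g_true * (V - e_rev)``.

Acquisition mimics a planar-bilayer setup: the level series is synthesized on
an oversampled grid, Gaussian noise is added there, a causal low-pass Bessel
filter is applied (the analog filter acts before digitization), and the
result is decimated to the recording rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trace import Trace

__all__ = [
    "VT_MV",
    "GatingModel",
    "AcquisitionConfig",
    "VoltageProtocol",
    "DwellSequence",
    "GrowthModel",
    "GrowthRecord",
    "Recording",
    "PanelEntry",
    "PanelResult",
    "bessel_lowpass",
    "sample_dwells",
    "render_trace",
    "simulate_recording",
    "simulate_growth",
    "make_panel",
    "gate_rates_for",
    "wildtype_model",
    "default_panel",
    "growth_records_to_table",
]

#: Thermal voltage RT/F at 25 degC, in mV.
VT_MV = 1e3 * 8.314462618 * 298.15 / 96485.33212

#: Rates above this are treated as an overflow (unphysical for a channel gate).
_RATE_CEILING = 1e9


def _rng_from(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, or a ready Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GatingModel:
    """Two-gate Markov model of one channel variant.

    ``slow_*`` parameters describe the gate that sets the open probability;
    ``fast_*`` the flicker gate.  ``*_rate0`` are rates at 0 mV in 1/s and
    ``*_z`` effective gating charges: ``k(V) = k0 * exp(z * V / V_T)``.
    A close rate of exactly 0 pins the corresponding gate open (used to
    disable flicker).
    """

    genotype_label: str
    g_true: float  # unitary conductance, pS
    e_rev: float = 0.0  # reversal potential, mV (symmetric 100 mM KCl)
    slow_open_rate0: float = 1.0
    slow_close_rate0: float = 50.0
    slow_z_open: float = 0.0
    slow_z_close: float = 0.0
    fast_open_rate0: float = 1.0
    fast_close_rate0: float = 0.0
    fast_z_open: float = 0.0
    fast_z_close: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.g_true) and self.g_true >= 0):
            raise ValueError(f"g_true must be >= 0, got {self.g_true}")
        for name in (
            "slow_open_rate0",
            "slow_close_rate0",
            "fast_open_rate0",
            "fast_close_rate0",
        ):
            value = getattr(self, name)
            if not (np.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        if self.slow_open_rate0 + self.slow_close_rate0 <= 0:
            raise ValueError("slow gate needs at least one positive rate")
        if self.fast_open_rate0 + self.fast_close_rate0 <= 0:
            raise ValueError("fast gate needs at least one positive rate")

    # -- voltage-dependent rates -------------------------------------------------

    def _rate(self, k0: float, z: float, voltage: float, name: str) -> float:
        k = k0 * math.exp(z * voltage / VT_MV)
        if not math.isfinite(k) or k > _RATE_CEILING:
            raise ValueError(
                f"rate {name} overflows at {voltage} mV (k0={k0}, z={z})"
            )
        return k

    def slow_rates(self, voltage: float) -> tuple[float, float]:
        """(k_open, k_close) of the slow gate at ``voltage`` mV."""
        return (
            self._rate(self.slow_open_rate0, self.slow_z_open, voltage, "slow_open"),
            self._rate(self.slow_close_rate0, self.slow_z_close, voltage, "slow_close"),
        )

    def fast_rates(self, voltage: float) -> tuple[float, float]:
        """(k_open, k_close) of the flicker gate at ``voltage`` mV."""
        return (
            self._rate(self.fast_open_rate0, self.fast_z_open, voltage, "fast_open"),
            self._rate(self.fast_close_rate0, self.fast_z_close, voltage, "fast_close"),
        )

    # -- stationary quantities ---------------------------------------------------

    def p_slow(self, voltage: float) -> float:
        ko, kc = self.slow_rates(voltage)
        return ko / (ko + kc)

    def p_fast(self, voltage: float) -> float:
        ko, kc = self.fast_rates(voltage)
        return ko / (ko + kc)

    def p_conducting(self, voltage: float) -> float:
        """Stationary conducting probability (both gates open)."""
        return self.p_slow(voltage) * self.p_fast(voltage)

    def i_true(self, voltage: float) -> float:
        """Fully open-channel (true) current in pA."""
        return self.g_true * (voltage - self.e_rev) * 1e-3

    def truth_activity(self, voltage: float = -140.0) -> float:
        """Model-truth time-averaged current i_true(V) * p_conducting(V), pA."""
        return self.i_true(voltage) * self.p_conducting(voltage)

    def without_flicker(self) -> "GatingModel":
        """Copy of the model with the fast gate pinned open."""
        return replace(
            self,
            fast_open_rate0=1.0,
            fast_close_rate0=0.0,
            fast_z_open=0.0,
            fast_z_close=0.0,
        )


@dataclass(frozen=True)
class AcquisitionConfig:
    """Recording physics: sampling, filtering, noise.

    Defaults match a typical bilayer setup: 5 kHz sampling after a 1-kHz
    4-pole Bessel filter.  ``noise_sd`` is the Gaussian current noise (pA)
    referred to the recording bandwidth; internally noise is injected at the
    oversampled rate with sd ``noise_sd * sqrt(oversample_factor)``.
    """

    fs: float = 5000.0
    filter_cutoff: float = 1000.0
    filter_order: int = 4
    noise_sd: float = 0.4
    oversample_factor: int = 10
    duration: float = 30.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 < self.filter_cutoff < self.fs / 2:
            raise ValueError(
                f"filter_cutoff must lie in (0, fs/2), got {self.filter_cutoff}"
            )
        if self.oversample_factor < 1 or int(self.oversample_factor) != self.oversample_factor:
            raise ValueError("oversample_factor must be an integer >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _default_voltages() -> tuple[float, ...]:
    return tuple(float(v) for v in range(160, -180, -20))


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered holding voltages (mV) and per-voltage record length (s)."""

    voltages: tuple[float, ...] = field(default_factory=_default_voltages)
    per_voltage_duration: float = 30.0

    def __post_init__(self) -> None:
        volts = tuple(float(v) for v in self.voltages)
        object.__setattr__(self, "voltages", volts)
        if len(volts) == 0:
            raise ValueError("protocol needs at least one voltage")
        if len(set(volts)) != len(volts):
            raise ValueError("protocol voltages must be distinct")
        if self.per_voltage_duration <= 0:
            raise ValueError("per_voltage_duration must be positive")


@dataclass
class DwellSequence:
    """Idealized ground-truth gating: alternating conducting/non-conducting
    intervals covering [0, total_duration]."""

    states: np.ndarray  # bool, True = conducting
    durations: np.ndarray  # seconds
    total_duration: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.states.shape != self.durations.shape:
            raise ValueError("states and durations must have equal length")
        if self.states.size == 0:
            raise ValueError("empty dwell sequence")
        if np.any(self.durations <= 0):
            raise ValueError("dwell durations must be positive")
        if np.any(self.states[1:] == self.states[:-1]):
            raise ValueError("dwell states must alternate")
        total = float(self.durations.sum())
        if not math.isclose(total, self.total_duration, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"durations sum to {total}, expected {self.total_duration}"
            )

    @property
    def conducting_fraction(self) -> float:
        """Empirical conducting time fraction (the generator truth)."""
        return float(self.durations[self.states].sum() / self.total_duration)

    def boundaries(self) -> np.ndarray:
        """Interval end times, last entry equals total_duration."""
        return np.cumsum(self.durations)


# ---------------------------------------------------------------------------
# dwell sampling
# ---------------------------------------------------------------------------


def _gate_flip_times(
    k_open: float, k_close: float, duration: float, rng: np.random.Generator
) -> tuple[bool, np.ndarray]:
    """Simulate one two-state gate; return (initial_open, flip times).

    The initial state is drawn from the stationary distribution, so a gate
    with a zero rate starts in (and never leaves) its absorbing state.
    """
    p_open = k_open / (k_open + k_close)
    open0 = bool(rng.random() < p_open)
    escape = k_close if open0 else k_open
    if escape == 0.0:
        return open0, np.empty(0)
    # expected number of flips plus headroom; draw in blocks until past the end
    mean_cycle = 1.0 / k_open + 1.0 / k_close if min(k_open, k_close) > 0 else np.inf
    expected = 0 if not np.isfinite(mean_cycle) else 2.0 * duration / mean_cycle
    block = int(expected + 4.0 * math.sqrt(expected + 1.0) + 16)
    times: list[np.ndarray] = []
    t = 0.0
    cur_open = open0
    while t < duration:
        rates = np.empty(block)
        first = k_close if cur_open else k_open
        second = k_open if cur_open else k_close
        rates[0::2] = first
        rates[1::2] = second
        if np.any(rates == 0.0):
            # gate falls into an absorbing state after the next flip
            stop = int(np.argmax(rates == 0.0))
            if stop == 0:
                break
            rates = rates[:stop]
        dwells = rng.exponential(1.0, size=rates.size) / rates
        flips = t + np.cumsum(dwells)
        times.append(flips)
        t = float(flips[-1])
        if rates.size < block:  # hit an absorbing state
            break
        cur_open = cur_open if rates.size % 2 == 0 else not cur_open
    if not times:
        return open0, np.empty(0)
    all_flips = np.concatenate(times)
    return open0, all_flips[all_flips < duration]


def sample_dwells(
    model: GatingModel, voltage: float, duration: float, seed=None
) -> DwellSequence:
    """Draw one realization of the two-gate process at a holding voltage.

    Both gates start from their stationary distribution; the channel conducts
    iff both gates are open.  Identical ``(model, voltage, duration, seed)``
    give identical output.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    ks_open, ks_close = model.slow_rates(voltage)
    kf_open, kf_close = model.fast_rates(voltage)
    rng = _rng_from(seed)
    s_open0, s_flips = _gate_flip_times(ks_open, ks_close, duration, rng)
    f_open0, f_flips = _gate_flip_times(kf_open, kf_close, duration, rng)

    starts = np.concatenate(([0.0], s_flips, f_flips))
    starts = np.unique(starts)  # sorted, deduplicated segment start times
    s_state = s_open0 ^ (np.searchsorted(s_flips, starts, side="right") % 2).astype(bool)
    f_state = f_open0 ^ (np.searchsorted(f_flips, starts, side="right") % 2).astype(bool)
    conducting = s_state & f_state

    keep = np.concatenate(([True], conducting[1:] != conducting[:-1]))
    seg_starts = starts[keep]
    states = conducting[keep]
    durations = np.diff(np.concatenate((seg_starts, [duration])))
    ok = durations > 0
    return DwellSequence(states[ok], durations[ok], duration)


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------


def bessel_lowpass(
    samples: np.ndarray, rate: float, cutoff: float, order: int = 4
) -> np.ndarray:
    """Causal low-pass Bessel filter with unity DC gain.

    ``cutoff`` is the -3 dB frequency (the convention used when specifying
    recording filters), realized with ``scipy.signal.bessel(..., norm="mag")``.
    """
    from scipy import signal

    if not 0 < cutoff < rate / 2:
        raise ValueError(f"cutoff must lie in (0, rate/2), got {cutoff}")
    if order < 1 or int(order) != order:
        raise ValueError(f"order must be a positive integer, got {order}")
    b, a = signal.bessel(int(order), cutoff, btype="low", norm="mag", fs=rate)
    return signal.lfilter(b, a, np.asarray(samples, dtype=float))


def render_trace(
    dwells: DwellSequence,
    model: GatingModel,
    voltage: float,
    acq: AcquisitionConfig,
    seed=None,
) -> Trace:
    """Turn a dwell sequence into a sampled, filtered, noisy current trace.

    The level series (0 or i_true) is synthesized at ``fs * oversample_factor``
    so that flicker faster than the sampling rate shapes the filtered
    amplitude, as the analog filter does in a real rig.
    """
    ov = int(acq.oversample_factor)
    rate_hi = acq.fs * ov
    if acq.filter_cutoff >= rate_hi / 2:
        raise ValueError(
            f"filter cutoff {acq.filter_cutoff} Hz >= Nyquist of the "
            f"oversampled rate ({rate_hi / 2} Hz)"
        )
    n = int(round(dwells.total_duration * acq.fs))
    if n < 1:
        raise ValueError("dwell sequence shorter than one sample period")
    n_hi = n * ov
    rng = _rng_from(seed)

    t_mid = (np.arange(n_hi) + 0.5) / rate_hi
    edges = dwells.boundaries()
    idx = np.searchsorted(edges, t_mid, side="right")
    np.minimum(idx, dwells.states.size - 1, out=idx)
    conducting = dwells.states[idx]
    del t_mid, idx
    x = np.where(conducting, model.i_true(voltage), 0.0)
    del conducting
    if acq.noise_sd > 0:
        x += rng.normal(0.0, acq.noise_sd * math.sqrt(ov), size=n_hi)
    y = bessel_lowpass(x, rate_hi, acq.filter_cutoff, acq.filter_order)
    del x
    samples = np.ascontiguousarray(y[::ov])
    return Trace(
        samples,
        fs=acq.fs,
        voltage=float(voltage),
        genotype=model.genotype_label,
        meta={"filter_hz": acq.filter_cutoff, "noise_sd_pA": acq.noise_sd},
    )


@dataclass
class Recording:
    """One voltage protocol run: traces plus ground-truth dwell sequences."""

    voltages: tuple[float, ...]
    traces: list[Trace]
    truth: list[DwellSequence]

    def trace_at(self, voltage: float) -> Trace:
        return self.traces[self.voltages.index(float(voltage))]

    def truth_at(self, voltage: float) -> DwellSequence:
        return self.truth[self.voltages.index(float(voltage))]


def simulate_recording(
    model: GatingModel,
    protocol: VoltageProtocol,
    acq: AcquisitionConfig,
    seed=None,
) -> Recording:
    """Simulate one trace per protocol voltage.

    Per-voltage sub-seeds are spawned deterministically from the master seed
    (``numpy.random.SeedSequence.spawn``), so runs are reproducible and the
    trace at a given voltage does not depend on the other voltages.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(protocol.voltages))
    traces: list[Trace] = []
    truth: list[DwellSequence] = []
    for voltage, child in zip(protocol.voltages, children):
        rng = np.random.default_rng(child)
        dwells = sample_dwells(model, voltage, protocol.per_voltage_duration, rng)
        traces.append(render_trace(dwells, model, voltage, acq, rng))
        truth.append(dwells)
    return Recording(protocol.voltages, traces, truth)


# ---------------------------------------------------------------------------
# growth model
# ---------------------------------------------------------------------------


def _default_sample_times() -> tuple[float, ...]:
    return (0.0, 6.0, 24.0, 48.0, 72.0)


@dataclass(frozen=True)
class GrowthModel:
    """Activity-driven logistic growth of K+-uptake-deficient yeast.

    The growth rate saturates with the magnitude of the channel's
    time-averaged inward current (Michaelis form), scaled by a hidden
    per-genotype ``expression_factor`` that stands for the unknown number of
    channels reaching the plasma membrane:

        A = expression_factor * |activity|
        r = baseline_rate + (max_rate - baseline_rate) * A / (A + half_sat_activity)
        OD(t) = K / (1 + (K/od0 - 1) * exp(-r t))

    Multiplicative log-normal noise of sd ``noise_sd`` is applied per sample.
    """

    od0: float = 0.1
    baseline_rate: float = 0.0  # 1/h, no-channel growth (empty vector ~ none)
    max_rate: float = 0.12  # 1/h at saturating activity
    half_sat_activity: float = 3.0  # pA
    carrying_capacity: float = 1.0  # OD600 ceiling
    expression_factor: float = 1.0
    noise_sd: float = 0.05
    sample_times: tuple[float, ...] = field(default_factory=_default_sample_times)

    def __post_init__(self) -> None:
        if self.od0 <= 0:
            raise ValueError("od0 must be positive")
        if self.carrying_capacity <= self.od0:
            raise ValueError("carrying_capacity must exceed od0")
        for name in ("baseline_rate", "max_rate", "half_sat_activity", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.expression_factor < 0:
            raise ValueError("expression_factor must be >= 0")

    def rate_for(self, activity: float) -> float:
        """Effective logistic rate (1/h) for a time-averaged current (pA)."""
        a = self.expression_factor * abs(activity)
        if a == 0.0:
            frac = 0.0
        else:
            frac = a / (a + self.half_sat_activity)
        return self.baseline_rate + (self.max_rate - self.baseline_rate) * frac

    def od_at(self, rate: float, time: float) -> float:
        """Noise-free logistic OD600 at ``time`` hours."""
        k, od0 = self.carrying_capacity, self.od0
        return k / (1.0 + (k / od0 - 1.0) * math.exp(-rate * time))


@dataclass(frozen=True)
class GrowthRecord:
    genotype_label: str
    replicate: int
    time: float  # hours
    od600: float

    def __post_init__(self) -> None:
        if self.od600 <= 0:
            raise ValueError("od600 must be positive")
        if self.time < 0:
            raise ValueError("time must be >= 0")


def simulate_growth(
    activity: float,
    model: GrowthModel,
    seed=None,
    genotype_label: str = "geno",
    n_replicates: int = 3,
) -> list[GrowthRecord]:
    """OD600 time courses for one genotype given its time-averaged current."""
    if not np.isfinite(activity):
        raise ValueError("activity must be finite")
    rng = _rng_from(seed)
    rate = model.rate_for(activity)
    records: list[GrowthRecord] = []
    for rep in range(1, n_replicates + 1):
        for t in model.sample_times:
            od = model.od_at(rate, t)
            if model.noise_sd > 0:
                od *= math.exp(rng.normal(0.0, model.noise_sd))
            records.append(GrowthRecord(genotype_label, rep, float(t), od))
    return records


def growth_records_to_table(records: list[GrowthRecord]):
    """Growth records as a tidy DataFrame (genotype, replicate, time_h, od600)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "genotype": [r.genotype_label for r in records],
            "replicate": [r.replicate for r in records],
            "time_h": [r.time for r in records],
            "od600": [r.od600 for r in records],
        }
    )


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelEntry:
    model: GatingModel
    expression_factor: float = 1.0
    is_wt: bool = False


@dataclass
class PanelResult:
    recordings: dict[str, Recording]
    growth: object  # pandas DataFrame, columns genotype/replicate/time_h/od600
    truth_activity: dict[str, float]
    wt_label: str


def make_panel(
    panel: list[PanelEntry],
    protocol: VoltageProtocol,
    acq: AcquisitionConfig,
    growth: GrowthModel,
    seed=None,
    activity_voltage: float = -140.0,
    n_replicates: int = 3,
) -> PanelResult:
    """Simulate recordings and growth for a genotype panel.

    Exactly one entry must be flagged as the WT reference.  Growth is driven
    by each genotype's model-truth time-averaged current at
    ``activity_voltage`` times its hidden expression factor.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    wt = [e.model.genotype_label for e in panel if e.is_wt]
    if len(wt) != 1:
        raise ValueError(
            f"exactly one panel entry must be flagged as WT, found {len(wt)}"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(panel))
    recordings: dict[str, Recording] = {}
    truth_activity: dict[str, float] = {}
    all_records: list[GrowthRecord] = []
    for i, entry in enumerate(panel):
        label = entry.model.genotype_label
        recordings[label] = simulate_recording(entry.model, protocol, acq, children[2 * i])
        activity = entry.model.truth_activity(activity_voltage)
        truth_activity[label] = activity
        gm = replace(growth, expression_factor=entry.expression_factor)
        all_records.extend(
            simulate_growth(
                activity,
                gm,
                np.random.default_rng(children[2 * i + 1]),
                genotype_label=label,
                n_replicates=n_replicates,
            )
        )
    return PanelResult(recordings, growth_records_to_table(all_records), truth_activity, wt[0])


# ---------------------------------------------------------------------------
# model factories
# ---------------------------------------------------------------------------


def gate_rates_for(
    p_neg: float,
    p_pos: float,
    k_close0: float,
    v_neg: float = -160.0,
    v_pos: float = 160.0,
) -> tuple[float, float, float, float]:
    """Boltzmann gate parameters hitting two stationary open fractions.

    Returns ``(k_open0, k_close0, z_open, z_close)`` such that the gate's
    stationary open fraction is ``p_neg`` at ``v_neg`` and ``p_pos`` at
    ``v_pos``; ``k_close0`` fixes the kinetic timescale (mean open dwell at
    0 mV is ``1 / k_close0``).  The gating charge is split symmetrically
    between opening and closing rates.
    """
    for p in (p_neg, p_pos):
        if not 0 < p < 1:
            raise ValueError(f"target open fractions must lie in (0, 1), got {p}")
    if k_close0 <= 0:
        raise ValueError("k_close0 must be positive")
    odds_neg = p_neg / (1.0 - p_neg)
    odds_pos = p_pos / (1.0 - p_pos)
    z_diff = VT_MV / (v_pos - v_neg) * math.log(odds_pos / odds_neg)
    log_r0 = math.log(odds_neg) - z_diff * v_neg / VT_MV
    k_open0 = k_close0 * math.exp(log_r0)
    return k_open0, k_close0, z_diff / 2.0, -z_diff / 2.0


def slow_gate_model(
    label: str,
    g_true: float,
    p_neg: float,
    p_pos: float,
    k_close0: float = 50.0,
    flicker: tuple[float, float, float, float] | None = None,
) -> GatingModel:
    """Build a model whose slow gate hits P_O targets at -160/+160 mV."""
    ko, kc, zo, zc = gate_rates_for(p_neg, p_pos, k_close0)
    kwargs = dict(
        genotype_label=label,
        g_true=g_true,
        slow_open_rate0=ko,
        slow_close_rate0=kc,
        slow_z_open=zo,
        slow_z_close=zc,
    )
    if flicker is not None:
        fo, fc, zfo, zfc = flicker
        kwargs.update(
            fast_open_rate0=fo,
            fast_close_rate0=fc,
            fast_z_open=zfo,
            fast_z_close=zfc,
        )
    return GatingModel(**kwargs)


#: Default flicker gate: essentially fully open at positive voltages,
#: dropping toward ~0.55 at -160 mV, with sub-millisecond dwell times --
#: the apparent-amplitude reduction seen at hyperpolarizing voltages.
_WT_FLICKER = gate_rates_for(0.55, 0.995, k_close0=2000.0)


def wildtype_model(flicker: bool = True) -> GatingModel:
    """WT-like channel: g = 174 pS; P_O 0.034 at -160 mV, 0.005 at +160 mV."""
    model = slow_gate_model(
        "WT",
        g_true=174.0,
        p_neg=0.034,
        p_pos=0.005,
        k_close0=50.0,
        flicker=_WT_FLICKER if flicker else None,
    )
    return model


#: Per-genotype (g_pS, P_O at -160 mV) defaults for the 20-variant demo panel.
#: Values span the ranges seen across cavity-entry point mutants: cationic
#: substitutions lower the conductance, anionic ones raise it slightly, and
#: open probability varies ~100-fold with two high-P_O outliers (C, P).
_PANEL_SPECS: dict[str, tuple[float, float]] = {
    "WT": (174.0, 0.034),
    "A": (165.0, 0.015),
    "C": (170.0, 0.42),
    "D": (190.0, 0.008),
    "E": (200.0, 0.020),
    "F": (160.0, 0.045),
    "G": (150.0, 0.020),
    "H": (90.0, 0.035),
    "I": (175.0, 0.030),
    "K": (60.0, 0.030),
    "M": (170.0, 0.006),
    "N": (155.0, 0.008),
    "P": (145.0, 0.45),
    "Q": (168.0, 0.060),
    "R": (40.5, 0.050),
    "S": (158.0, 0.010),
    "T": (172.0, 0.030),
    "V": (169.0, 0.025),
    "W": (152.0, 0.040),
    "Y": (163.0, 0.050),
}


def default_panel(expression_factors: dict[str, float] | None = None) -> list[PanelEntry]:
    """The built-in 20-genotype panel (WT reference plus 19 variants).

    Each variant keeps the WT voltage-dependence shape (P_O at +160 mV is
    the -160 mV value divided by 6.8) and the WT flicker gate; only
    conductance and slow-gate open fraction vary.
    """
    entries = []
    for label, (g, p_neg) in _PANEL_SPECS.items():
        model = slow_gate_model(
            label,
            g_true=g,
            p_neg=p_neg,
            p_pos=min(0.9, p_neg / 6.8),
            k_close0=50.0,
            flicker=_WT_FLICKER,
        )
        ef = 1.0 if expression_factors is None else expression_factors.get(label, 1.0)
        entries.append(PanelEntry(model, expression_factor=ef, is_wt=label == "WT"))
    return entries
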