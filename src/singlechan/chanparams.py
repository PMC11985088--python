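"""Per-genotype functional channel parameters from i/V and P_O/V relations.

The unitary conductance g is the slope of an ordinary least-squares line
through the mean open-channel currents at positive voltages (default
0..+100 mV, configurable because published fits also use 0..+160 mV).  The
intercept is left free: symmetric KCl implies a ~0 mV reversal potential,
but a free intercept absorbs residual baseline offsets, and only the slope
is reported as g.

The fully open ("true") current at negative voltages, where flicker gating
hides it, is estimated by extrapolating that fitted line; values at -140 mV
(the free-running yeast membrane potential) are exact protocol lookups,
never interpolations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IVRelation",
    "PoVRelation",
    "ChannelSummary",
    "build_relations",
    "fit_iv_line",
    "fit_conductance",
    "true_current_at",
    "activity",
    "mean_po",
    "po_at",
    "summarize_channel",
]

_V_ATOL = 1e-6  # mV tolerance for treating protocol voltages as equal


@dataclass
class _PerVoltage:
    voltages: np.ndarray
    mean: np.ndarray
    sd: np.ndarray  # NaN where n == 1 (sample sd undefined)
    n: np.ndarray

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if len({self.voltages.size, self.mean.size, self.sd.size, self.n.size}) != 1:
            raise ValueError("per-voltage columns must have equal length")
        if self.voltages.size and np.unique(self.voltages).size != self.voltages.size:
            raise ValueError("voltages must be distinct")

    def _index_of(self, voltage: float) -> int:
        hits = np.flatnonzero(np.abs(self.voltages - voltage) <= _V_ATOL)
        if hits.size != 1:
            raise KeyError(
                f"voltage {voltage} mV is not in the relation; refusing to "
                "interpolate"
            )
        return int(hits[0])


class IVRelation(_PerVoltage):
    """Per-voltage mean measured open-channel current (pA), sd, and n."""

    def i_at(self, voltage: float) -> float:
        return float(self.mean[self._index_of(voltage)])


class PoVRelation(_PerVoltage):
    """Per-voltage mean open probability, sd, and n."""

    def __post_init__(self) -> None:
        super().__post_init__()
        finite = np.isfinite(self.mean)
        if np.any((self.mean[finite] < 0) | (self.mean[finite] > 1)):
            raise ValueError("open probabilities must lie in [0, 1]")


def _aggregate(values_by_voltage: dict[float, list[float]]):
    volts = sorted(values_by_voltage, reverse=True)  # protocol order +V..-V
    means, sds, ns = [], [], []
    for v in volts:
        vals = np.asarray(values_by_voltage[v], dtype=float)
        means.append(float(np.mean(vals)) if vals.size else np.nan)
        sds.append(float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan)
        ns.append(vals.size)
    return np.asarray(volts), np.asarray(means), np.asarray(sds), np.asarray(ns)


def build_relations(
    results: list[tuple[float, float, float]],
) -> tuple[IVRelation, PoVRelation]:
    """Aggregate per-recording ``(voltage, i_meas, P_O)`` triples.

    Means use the sample sd (n - 1 denominator); the sd is NaN for single
    recordings.  Missing amplitudes (NaN i_meas, e.g. traces where no open
    event was resolvable) are excluded from the i/V relation but their open
    probabilities are kept.
    """
    if not results:
        raise ValueError("no recordings to aggregate")
    iv: dict[float, list[float]] = {}
    po: dict[float, list[float]] = {}
    for voltage, i_meas, p_open in results:
        v = float(voltage)
        po.setdefault(v, []).append(float(p_open))
        iv.setdefault(v, [])
        if np.isfinite(i_meas):
            iv[v].append(float(i_meas))
    return IVRelation(*_aggregate(iv)), PoVRelation(*_aggregate(po))


def fit_iv_line(
    iv: IVRelation, v_lo: float = 0.0, v_hi: float = 100.0
) -> tuple[float, float]:
    """OLS line (slope pA/mV, intercept pA) through mean currents in
    [v_lo, v_hi] inclusive."""
    sel = (
        (iv.voltages >= v_lo - _V_ATOL)
        & (iv.voltages <= v_hi + _V_ATOL)
        & np.isfinite(iv.mean)
    )
    if np.count_nonzero(sel) < 2:
        raise ValueError(
            f"need >= 2 voltages with amplitudes in [{v_lo}, {v_hi}] mV, "
            f"got {np.count_nonzero(sel)}"
        )
    fit = stats.linregress(iv.voltages[sel], iv.mean[sel])
    return float(fit.slope), float(fit.intercept)


def fit_conductance(iv: IVRelation, v_lo: float = 0.0, v_hi: float = 100.0) -> float:
    """Unitary conductance in pS from the positive-limb i/V fit."""
    slope, _ = fit_iv_line(iv, v_lo, v_hi)
    return slope * 1e3  # pA/mV -> pS


def true_current_at(
    iv: IVRelation, v: float = -140.0, v_lo: float = 0.0, v_hi: float = 100.0
) -> float:
    """i_true(v) in pA by extrapolating the positive-voltage i/V fit."""
    slope, intercept = fit_iv_line(iv, v_lo, v_hi)
    return slope * v + intercept


def activity(i: float, po: float) -> float:
    """Time-averaged current i * P_O in pA; sign follows the current."""
    if not 0.0 <= po <= 1.0:
        raise ValueError(f"open probability must lie in [0, 1], got {po}")
    return i * po


def mean_po(povr: PoVRelation) -> float:
    """Unweighted mean of per-voltage open probabilities over the window."""
    if povr.voltages.size == 0:
        raise ValueError("empty P_O/V relation")
    return float(np.nanmean(povr.mean))


def po_at(povr: PoVRelation, v: float) -> float:
    """Exact P_O lookup at a protocol voltage (no interpolation)."""
    return float(povr.mean[povr._index_of(v)])


@dataclass
class ChannelSummary:
    """Functional parameters of one genotype.

    ``activity_meas`` and ``activity_true`` are the time-averaged currents
    i_meas(-140) x P_O(-140) and i_true(-140) x P_O(-140); ``activity_pos``
    is the inverse-orientation product i_true(+140) x P_O(+140).
    """

    genotype_label: str
    g: float  # pS
    fit_range: tuple[float, float]
    mean_po: float
    po_minus140: float
    i_meas_minus140: float
    i_true_minus140: float
    activity_meas: float
    activity_true: float
    activity_pos: float
    n: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.g):
            raise ValueError("fitted conductance must be finite")


def summarize_channel(
    genotype_label: str,
    iv: IVRelation,
    povr: PoVRelation,
    v_lo: float = 0.0,
    v_hi: float = 100.0,
    activity_voltage: float = -140.0,
) -> ChannelSummary:
    """Assemble the per-genotype summary from its i/V and P_O/V relations."""
    slope, intercept = fit_iv_line(iv, v_lo, v_hi)
    g = slope * 1e3
    po_m = po_at(povr, activity_voltage)
    po_p = po_at(povr, -activity_voltage)
    try:
        i_meas_m = iv.i_at(activity_voltage)
    except KeyError:
        i_meas_m = float("nan")
    i_true_m = slope * activity_voltage + intercept
    i_true_p = slope * (-activity_voltage) + intercept
    return ChannelSummary(
        genotype_label=genotype_label,
        g=g,
        fit_range=(v_lo, v_hi),
        mean_po=mean_po(povr),
        po_minus140=po_m,
        i_meas_minus140=i_meas_m,
        i_true_minus140=i_true_m,
        activity_meas=i_meas_m * po_m,
        activity_true=i_true_m * po_m,
        activity_pos=i_true_p * po_p,
        n=int(np.max(povr.n)) if povr.n.size else 1,
    )
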