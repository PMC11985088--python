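"""Sampled single-channel current record with acquisition metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trace:
    """A single-channel current record at one holding voltage.

    Parameters
    ----------
    samples : ndarray
        Current samples in pA. The bilayer sign convention is kept
        throughout: negative currents are inward currents.
    fs : float
        Sampling rate in Hz.
    voltage : float, optional
        Holding voltage in mV.
    genotype : str, optional
        Channel variant label.
    meta : dict
        Free-form acquisition metadata; ``filter_hz`` (anti-alias low-pass
        cutoff) is used by the idealizer to derive its dead time.
    """

    samples: np.ndarray
    fs: float
    voltage: float | None = None
    genotype: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds (first sample at t = 0)."""
        return np.arange(self.samples.size) / self.fs

    @property
    def filter_cutoff(self) -> float | None:
        """Low-pass cutoff in Hz if recorded in the metadata."""
        value = self.meta.get("filter_hz")
        return None if value is None else float(value)
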