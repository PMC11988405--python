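"""Minimal current-trace utilities.

Threshold event detection, baseline-subtracted charge transfer and
half-width measurement.  These are transparent, testable stand-ins for
the commercial event-detection and baseline-fitting tools used in
typical patch-clamp workflows; their accuracy is asserted against the
analytic properties of the synthetic biexponential traces rather than
against any proprietary implementation.

Convention: traces hold membrane current in pA sampled at a fixed rate;
synaptic events are inward, i.e. negative deflections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = ["Trace", "detect_events", "charge_transfer", "half_width"]


@dataclass
class Trace:
    """A sampled current trace (pA) at a fixed sampling rate (Hz)."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "current_pA": self.samples})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 10_000.0
        return cls(samples=df["current_pA"].to_numpy(float), sampling_rate=float(rate))


def detect_events(trace: Trace, threshold: float, min_separation_ms: float = 5.0):
    """Detect inward events as local minima deeper than ``-threshold``.

    Returns an event table of peak amplitudes (positive magnitudes, pA)
    and peak times (s).  ``min_separation_ms`` suppresses secondary peaks
    closer than that interval.  Detection is threshold-monotone: raising
    the threshold can only remove events.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    distance = max(1, int(round(min_separation_ms * 1e-3 * trace.sampling_rate)))
    idx, props = find_peaks(-trace.samples, height=threshold, distance=distance)
    from .synthetic_data import EventTable  # local import to avoid a cycle

    return EventTable(
        amplitude=props["peak_heights"],
        time=idx / trace.sampling_rate,
        condition="detected",
        censored=np.zeros(len(idx), dtype=bool),
        duration=trace.duration,
    ) if len(idx) else EventTable(
        amplitude=np.empty(0),
        time=np.empty(0),
        condition="detected",
        censored=np.empty(0, dtype=bool),
        duration=trace.duration,
    )


def _baseline(trace: Trace, percentile: float, window_s: float = 1.0) -> np.ndarray:
    """Slowly varying baseline: per-window percentile, linearly interpolated.

    The trace is split into ``window_s`` blocks; the given percentile of
    each block is taken as a node at the block centre and nodes are
    joined by linear interpolation.  With sparse inward events a low
    percentile (default 20th) tracks the event-free baseline.
    """
    n = len(trace.samples)
    win = max(1, int(round(window_s * trace.sampling_rate)))
    n_blocks = max(1, n // win)
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    centers = (edges[:-1] + edges[1:]) / 2.0
    nodes = np.array(
        [np.percentile(trace.samples[a:b], percentile * 100.0) for a, b in zip(edges[:-1], edges[1:])]
    )
    return np.interp(np.arange(n), centers, nodes)


def charge_transfer(trace: Trace, baseline_percentile: float = 0.2) -> float:
    """Baseline-subtracted charge of inward current over the trace (pC).

    The baseline is a rolling low-percentile fit (see ``_baseline``);
    the charge is the integral of ``baseline - current`` over time, so
    inward (negative) deflections contribute positively.  pA x s = pC.
    Invariant to adding any constant offset to the trace.
    """
    if trace.duration < 1.0:
        raise ValueError("trace must be at least 1 s long")
    if not 0.0 < baseline_percentile < 1.0:
        raise ValueError("baseline_percentile must lie in (0, 1)")
    base = _baseline(trace, baseline_percentile)
    dt = 1.0 / trace.sampling_rate
    return float(np.sum(base - trace.samples) * dt)


def half_width(waveform: np.ndarray, sampling_rate: float) -> float:
    """Full width at half-maximal deflection of a unimodal event (ms).

    Accepts either sign; the waveform is rectified around its extremum.
    Crossing times are linearly interpolated between samples.
    """
    w = np.asarray(waveform, dtype=float)
    if len(w) < 3:
        raise ValueError("waveform too short")
    w = w - w[0]  # the waveform is assumed to start at baseline
    if abs(w.min()) >= abs(w.max()):
        w = -w  # make the deflection positive
    ipk = int(np.argmax(w))
    half = w[ipk] / 2.0
    if w[ipk] <= 0:
        raise ValueError("waveform has no deflection")

    def _cross(seg: np.ndarray, offset: int, rising: bool) -> float:
        # first crossing of `half` walking away from the peak
        idx = np.nonzero(seg < half)[0]
        if len(idx) == 0:
            raise ValueError("half-amplitude level never crossed")
        i = idx[-1] if rising else idx[0]
        if rising:
            x0, x1 = seg[i], seg[i + 1]
            return offset + i + (half - x0) / (x1 - x0)
        x0, x1 = seg[i - 1], seg[i]
        return offset + i - 1 + (half - x0) / (x1 - x0)

    left = _cross(w[: ipk + 1], 0, rising=True)
    right = _cross(w[ipk:], ipk, rising=False)
    return (right - left) / sampling_rate * 1e3
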