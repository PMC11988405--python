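"""Synthetic mEPSC data generator.

Emulates the statistical structure of miniature-EPSC recordings from
visual-cortex L2/3 pyramidal neurons so every downstream analysis stage
(mixture fitting, failure analysis, scaling decomposition, trace
utilities) is testable without any electrophysiological recording:

* amplitudes drawn from a weighted two-component gamma mixture
  ``kappa * Gamma(alpha1, beta1) + (1 - kappa) * Gamma(alpha2, beta2)``
  (amplitudes in pA, positive magnitudes);
* event times as a homogeneous Poisson train (spontaneous vesicle
  fusions carry no stated inter-event structure, so a Poisson process is
  the standard null);
* the benzothiazide (TCM/CTZ) intervention as an independent
  multiplicative amplitude scale (desensitization block, ~x1.4) plus a
  rate scale (unidling of transmission sites, larger at P30 than P16);
* detection-threshold censoring: events below threshold are *flagged*,
  never dropped, so threshold analyses can be checked against ground
  truth.

Sign convention: amplitudes are stored as positive magnitudes
throughout; synthesized current traces carry negative (inward)
deflections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace_analysis import Trace

__all__ = [
    "GeneratorParams",
    "TCMEffect",
    "EventTable",
    "sample_amplitudes",
    "generate_recording",
    "synthesize_trace",
    "biexp_kernel",
    "biexp_peak_time",
    "biexp_area",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the two-gamma mEPSC amplitude model and event train.

    ``kappa`` is the mixture weight of component 1; ``alpha*``/``beta*``
    are gamma shape/scale pairs (component mean = alpha * beta, in pA).
    ``event_rate`` is the true, pre-censoring event frequency in Hz over
    ``duration`` seconds.  ``detection_threshold`` (pA) marks events as
    censored; ``noise_sd`` (pA) is baseline noise for trace synthesis.
    """

    kappa: float = 0.45
    alpha1: float = 16.0
    beta1: float = 1.05
    alpha2: float = 20.0
    beta2: float = 0.5
    event_rate: float = 3.5
    duration: float = 300.0
    noise_sd: float = 2.0
    detection_threshold: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must lie in [0, 1], got {self.kappa}")
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def mixture_mean(self) -> float:
        """Population mean amplitude kappa*a1*b1 + (1-kappa)*a2*b2 (pA)."""
        return self.kappa * self.alpha1 * self.beta1 + (1.0 - self.kappa) * self.alpha2 * self.beta2


@dataclass(frozen=True)
class TCMEffect:
    """Multiplicative effect of a desensitization blocker (TCM/CTZ).

    ``amplitude_scale`` models the ~40% quantal-size increase from
    desensitization block; ``unidle_rate_factor`` models the frequency
    increase from unidling of idle-able transmission sites (the effect
    roughly doubles between P16 and P30).  Both are 1 for vehicle.
    """

    amplitude_scale: float = 1.0
    unidle_rate_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude_scale < 1.0 or self.unidle_rate_factor < 1.0:
            raise ValueError("TCM factors must be >= 1 (use 1.0 for vehicle)")


#: TCM effect at P16: x1.4 amplitudes, doubled event rate.
TCM_P16 = TCMEffect(amplitude_scale=1.4, unidle_rate_factor=2.0)
#: TCM effect at P30: same amplitude scaling, twice the frequency effect.
TCM_P30 = TCMEffect(amplitude_scale=1.4, unidle_rate_factor=3.0)
VEHICLE = TCMEffect()


@dataclass
class EventTable:
    """Per-event mEPSC table: amplitudes (pA), times (s), condition label.

    ``censored`` flags events below the detection threshold that a real
    event detector would miss; they are retained so that censoring
    analyses can be validated against ground truth.
    """

    amplitude: np.ndarray
    time: np.ndarray
    condition: str
    censored: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if not (len(self.amplitude) == len(self.time) == len(self.censored)):
            raise ValueError("amplitude, time and censored must have equal length")
        if np.any(self.amplitude <= 0):
            raise ValueError("amplitudes must be positive magnitudes (pA)")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("event times must be strictly increasing")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    def __len__(self) -> int:
        return len(self.amplitude)

    @property
    def detected(self) -> np.ndarray:
        """Amplitudes of non-censored events (pA)."""
        return self.amplitude[~self.censored]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "amplitude_pA": self.amplitude,
                "time_s": self.time,
                "condition": self.condition,
                "censored": self.censored,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, duration: float | None = None) -> "EventTable":
        df = pd.read_csv(path)
        cond = str(df["condition"].iloc[0]) if len(df) else "unknown"
        if duration is None:
            duration = float(df["time_s"].max()) if len(df) else 1.0
        return cls(
            amplitude=df["amplitude_pA"].to_numpy(float),
            time=df["time_s"].to_numpy(float),
            condition=cond,
            censored=df["censored"].to_numpy(bool),
            duration=duration,
        )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_amplitudes(params: GeneratorParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` amplitudes (pA) from the two-gamma mixture.

    Each draw comes from component 1 with probability ``kappa``,
    otherwise from component 2.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    from_first = rng.random(n) < params.kappa
    amps = np.empty(n)
    n1 = int(from_first.sum())
    amps[from_first] = rng.gamma(params.alpha1, params.beta1, size=n1)
    amps[~from_first] = rng.gamma(params.alpha2, params.beta2, size=n - n1)
    return amps


def generate_recording(
    params: GeneratorParams,
    tcm: TCMEffect = VEHICLE,
    seed=0,
    condition: str | None = None,
) -> EventTable:
    """Simulate one mEPSC recording under ``params`` and a drug effect.

    Event times follow a homogeneous Poisson process at
    ``event_rate * unidle_rate_factor`` over ``duration``; amplitudes are
    mixture draws multiplied by ``amplitude_scale``.  Events below
    ``detection_threshold`` are flagged censored, not deleted.
    """
    rng = _rng(seed)
    rate = params.event_rate * tcm.unidle_rate_factor
    n = rng.poisson(rate * params.duration)
    if condition is None:
        condition = "vehicle" if tcm == VEHICLE else "TCM"
    if n == 0:
        return EventTable(
            amplitude=np.empty(0),
            time=np.empty(0),
            condition=condition,
            censored=np.empty(0, dtype=bool),
            duration=params.duration,
        )
    times = np.sort(rng.uniform(0.0, params.duration, size=n))
    # strictly increasing times (ties have probability 0 but guard anyway)
    times = np.maximum.accumulate(times + np.arange(n) * 1e-12)
    amps = sample_amplitudes(params, n, rng) * tcm.amplitude_scale
    return EventTable(
        amplitude=amps,
        time=times,
        condition=condition,
        censored=amps < params.detection_threshold,
        duration=params.duration,
    )


# --- biexponential kernel -------------------------------------------------

def biexp_peak_time(rise_ms: float, decay_ms: float) -> float:
    """Time to peak (ms) of exp(-t/decay) - exp(-t/rise)."""
    return rise_ms * decay_ms / (decay_ms - rise_ms) * np.log(decay_ms / rise_ms)


def _biexp_norm(rise_ms: float, decay_ms: float) -> float:
    tp = biexp_peak_time(rise_ms, decay_ms)
    return np.exp(-tp / decay_ms) - np.exp(-tp / rise_ms)


def biexp_kernel(t_ms: np.ndarray, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Unit-peak biexponential waveform evaluated at ``t_ms`` (ms >= 0)."""
    if rise_ms >= decay_ms:
        raise ValueError("kernel rise must be shorter than decay")
    t = np.asarray(t_ms, dtype=float)
    out = np.where(
        t >= 0.0,
        np.exp(-np.clip(t, 0, None) / decay_ms) - np.exp(-np.clip(t, 0, None) / rise_ms),
        0.0,
    )
    return out / _biexp_norm(rise_ms, decay_ms)


def biexp_area(amplitude_pA: float, rise_ms: float, decay_ms: float) -> float:
    """Analytic area (pA*s = pC) of a unit-peak kernel scaled to a peak.

    The unnormalized kernel integrates to (decay - rise) ms; dividing by
    the peak value gives the area of the unit-peak waveform.
    """
    return amplitude_pA * (decay_ms - rise_ms) / _biexp_norm(rise_ms, decay_ms) * 1e-3


def synthesize_trace(
    events: EventTable,
    kernel_rise_ms: float = 0.5,
    kernel_decay_ms: float = 4.0,
    noise_sd: float = 0.0,
    sampling_rate: float = 10_000.0,
    seed=0,
) -> Trace:
    """Render an event table as a sampled current trace (pA).

    Each event contributes an inward (negative) biexponential deflection
    whose peak magnitude equals the event amplitude; Gaussian baseline
    noise of ``noise_sd`` pA is added.  An empty table yields flat noise.
    """
    if kernel_rise_ms >= kernel_decay_ms:
        raise ValueError("kernel rise must be shorter than decay")
    if sampling_rate < 1000.0:
        raise ValueError("sampling_rate must be >= 1 kHz")
    rng = _rng(seed)
    n_samp = int(round(events.duration * sampling_rate))
    samples = np.zeros(n_samp)
    # kernel support: ~12 decay constants keeps the truncated tail < 1e-5
    kernel_len = int(round(12.0 * kernel_decay_ms * 1e-3 * sampling_rate))
    t_ms = np.arange(kernel_len) / sampling_rate * 1e3
    kernel = biexp_kernel(t_ms, kernel_rise_ms, kernel_decay_ms)
    for amp, t in zip(events.amplitude, events.time):
        i0 = int(round(t * sampling_rate))
        i1 = min(i0 + kernel_len, n_samp)
        if i0 < n_samp:
            samples[i0:i1] -= amp * kernel[: i1 - i0]
    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, size=n_samp)
    return Trace(samples=samples, sampling_rate=sampling_rate)
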