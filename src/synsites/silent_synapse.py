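"""Silent-synapse fraction estimation and minimal-stimulation simulation.

A silent synapse carries NMDARs but no functional AMPARs: at a holding
potential of -60 mV it produces transmission failures (NMDARs are
Mg2+-blocked), while at +40 mV both receptor types respond.  With
minimal stimulation of a unitary connection the failure rates at the two
potentials therefore estimate the silent fraction ``s`` via

    s_hat = 1 - ln(F_-60) / ln(F_+40)

Under the binomial release model a connection of ``n`` synapses, each
releasing independently with probability ``p`` and ``m`` of them
non-silent, has F_+40 = (1-p)^n and F_-60 = (1-p)^m, so the estimator
returns ``m/n`` exactly in expectation of the rates.  The estimate is
undefined whenever a failure count is 0 or equals the sweep count (the
log of 0, or a degenerate ratio) — in real experiments this happens for
high release probabilities, and such cells are excluded, not clipped.

``simulate_sweeps`` models single sweeps with a discrete number of
silent synapses (``round(n * s)``); ``mode="scaled-p"`` instead scales
the per-synapse release probability by ``1 - s`` at -60 mV, the
continuous approximation sometimes used for this calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FailureCounts",
    "UnitaryConnection",
    "AgePopulationConfig",
    "PopulationResult",
    "silent_fraction_estimate",
    "silent_fraction_from_rates",
    "simulate_sweeps",
    "simulate_population",
]


@dataclass(frozen=True)
class FailureCounts:
    """Sweep and failure counts at the two holding potentials."""

    n_sweeps_neg: int
    n_fail_neg: int
    n_sweeps_pos: int
    n_fail_pos: int

    def __post_init__(self) -> None:
        if self.n_sweeps_neg < 1 or self.n_sweeps_pos < 1:
            raise ValueError("sweep counts must be >= 1")
        if not (0 <= self.n_fail_neg <= self.n_sweeps_neg):
            raise ValueError("failures at -60 mV out of range")
        if not (0 <= self.n_fail_pos <= self.n_sweeps_pos):
            raise ValueError("failures at +40 mV out of range")

    @property
    def f_neg(self) -> float:
        """Failure rate at Vh = -60 mV."""
        return self.n_fail_neg / self.n_sweeps_neg

    @property
    def f_pos(self) -> float:
        """Failure rate at Vh = +40 mV."""
        return self.n_fail_pos / self.n_sweeps_pos


@dataclass(frozen=True)
class UnitaryConnection:
    """A unitary L4-to-L2/3 connection under the binomial release model.

    ``n_synapses`` is typically 3-5; ``silent_fraction`` of them are
    AMPAR-silent (non-responding at -60 mV, responding at +40 mV).
    """

    n_synapses: int
    p_release: float
    silent_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_synapses < 1:
            raise ValueError("n_synapses must be >= 1")
        if not 0.0 <= self.p_release <= 1.0:
            raise ValueError("p_release must lie in [0, 1]")
        if not 0.0 <= self.silent_fraction <= 1.0:
            raise ValueError("silent_fraction must lie in [0, 1]")

    @property
    def n_silent(self) -> int:
        """Integer number of silent synapses, round(n * s)."""
        return int(round(self.n_synapses * self.silent_fraction))


@dataclass(frozen=True)
class AgePopulationConfig:
    """Population of simulated neurons at one age.

    Per neuron the silent fraction is drawn from a truncated normal
    (clip-resample to [0, 1]), the release probability uniformly from
    ``p_release_range`` and the synapse count uniformly from the integer
    ``n_synapses_range``.
    """

    mean_silent: float
    sd_silent: float
    p_release_range: tuple[float, float] = (0.3, 0.5)
    n_synapses_range: tuple[int, int] = (3, 5)
    n_neurons: int = 20
    n_sweeps: int = 50

    def __post_init__(self) -> None:
        if self.sd_silent < 0:
            raise ValueError("sd_silent must be >= 0")
        if self.n_neurons < 1 or self.n_sweeps < 1:
            raise ValueError("n_neurons and n_sweeps must be >= 1")


#: Start of the critical period: ~50 +/- 15 % silent synapses.
P16_POPULATION = AgePopulationConfig(mean_silent=0.5, sd_silent=0.15)
#: End of the critical period: ~20 +/- 15 % silent synapses.
P30_POPULATION = AgePopulationConfig(mean_silent=0.2, sd_silent=0.15)


def silent_fraction_from_rates(f_neg: float, f_pos: float) -> float:
    """``1 - ln(F_-60)/ln(F_+40)`` from failure *rates* directly.

    NaN (the explicit undefined marker) when either rate is 0 or 1.
    """
    if not (0.0 <= f_neg <= 1.0 and 0.0 <= f_pos <= 1.0):
        raise ValueError("failure rates must lie in [0, 1]")
    if f_neg in (0.0, 1.0) or f_pos in (0.0, 1.0):
        return math.nan
    return 1.0 - math.log(f_neg) / math.log(f_pos)


def silent_fraction_estimate(counts: FailureCounts) -> float:
    """Estimate the silent-synapse fraction from failure counts.

    Returns ``1 - ln(F_-60)/ln(F_+40)``; the result lies in (-inf, 1]
    and may be negative by sampling noise (it is deliberately not
    clipped).  Returns NaN as an explicit undefined marker when either
    failure count is 0 or equals the sweep count (the log of 0, or a
    degenerate ratio), mirroring the experimental exclusion of cells
    without failures.
    """
    return silent_fraction_from_rates(counts.f_neg, counts.f_pos)


def simulate_sweeps(
    conn: UnitaryConnection,
    n_sweeps: int,
    seed,
    mode: str = "discrete",
) -> FailureCounts:
    """Simulate minimal-stimulation sweeps at both holding potentials.

    Each sweep, every synapse releases independently with ``p_release``.
    A +40 mV sweep fails iff zero synapses release.  At -60 mV, in
    ``"discrete"`` mode a sweep fails iff zero of the non-silent
    synapses release; in ``"scaled-p"`` mode all synapses respond but
    with release probability scaled by ``1 - silent_fraction``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, p = conn.n_synapses, conn.p_release
    fails_pos = int((rng.binomial(n, p, size=n_sweeps) == 0).sum())
    if mode == "discrete":
        m = n - conn.n_silent
        releases_neg = rng.binomial(m, p, size=n_sweeps) if m > 0 else np.zeros(n_sweeps, dtype=int)
    elif mode == "scaled-p":
        releases_neg = rng.binomial(n, p * (1.0 - conn.silent_fraction), size=n_sweeps)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    fails_neg = int((releases_neg == 0).sum())
    return FailureCounts(
        n_sweeps_neg=n_sweeps,
        n_fail_neg=fails_neg,
        n_sweeps_pos=n_sweeps,
        n_fail_pos=fails_pos,
    )


@dataclass
class PopulationResult:
    """Per-neuron silent-fraction estimates for one simulated age group."""

    estimates: np.ndarray  # NaN where undefined
    true_fractions: np.ndarray
    p_release: np.ndarray
    n_synapses: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.estimates[~np.isnan(self.estimates)]

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.estimates).sum())

    @property
    def mean_estimate(self) -> float:
        """Mean over defined estimates (undefined neurons are excluded)."""
        d = self.defined
        return float(d.mean()) if len(d) else math.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": np.arange(len(self.estimates)),
                "estimate": self.estimates,
                "undefined_flag": np.isnan(self.estimates),
                "true_silent_fraction": self.true_fractions,
                "p_release": self.p_release,
                "n_synapses": self.n_synapses,
            }
        )


def _truncated_normal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Clip-resample normal draws to [0, 1]."""
    if sd == 0:
        return np.full(size, np.clip(mean, 0.0, 1.0))
    out = rng.normal(mean, sd, size=size)
    bad = (out < 0.0) | (out > 1.0)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < 0.0) | (out > 1.0)
    return out


def simulate_population(
    cfg: AgePopulationConfig,
    seed,
    mode: str = "discrete",
) -> PopulationResult:
    """Simulate a population of neurons and estimate silent fractions.

    Undefined estimates (no failures, or all failures, at either
    potential) are reported as NaN and counted separately, never
    imputed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = _truncated_normal(rng, cfg.mean_silent, cfg.sd_silent, cfg.n_neurons)
    p = rng.uniform(*cfg.p_release_range, size=cfg.n_neurons)
    lo, hi = cfg.n_synapses_range
    n_syn = rng.integers(lo, hi + 1, size=cfg.n_neurons)
    estimates = np.empty(cfg.n_neurons)
    for i in range(cfg.n_neurons):
        conn = UnitaryConnection(int(n_syn[i]), float(p[i]), float(s[i]))
        counts = simulate_sweeps(conn, cfg.n_sweeps, rng, mode=mode)
        estimates[i] = silent_fraction_estimate(counts)
    return PopulationResult(estimates=estimates, true_fractions=s, p_release=p, n_synapses=n_syn)


def sweep_table(counts_neg: np.ndarray, counts_pos: np.ndarray) -> pd.DataFrame:
    """Render success/failure sweeps as a tidy table.

    Columns: sweep_index, vh_mV, success_flag.
    """
    rows = []
    for vh, arr in ((-60, counts_neg), (40, counts_pos)):
        for i, success in enumerate(arr):
            rows.append({"sweep_index": i, "vh_mV": vh, "success_flag": bool(success)})
    return pd.DataFrame(rows)
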