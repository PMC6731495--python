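"""Firing-rate estimation and response metrics.

Rates are estimated by convolving the spike train with a Gaussian kernel
(standard deviation 0.03 s by default): the rate trace is the sum of
unit-mass Gaussian densities centred at the spike times, evaluated on a
uniform grid (1 ms resolution by default, decoupled from the simulation
step).  No edge renormalization is applied — plain convolution — so a rate
integrates back to the spike count only when the grid extends a few SDs
beyond the spikes.

Also provided: across-cell averaging with quartile bands, response
characteristics (peak rate and first-spike latency after stimulus onset),
the coefficient of determination R² between a measured and a modelled rate,
and extraction of pulse-response segments from intermittent valve
recordings (puffs of at least 0.5 s preceded by at least 0.1 s of blank).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .neuron import SpikeTrain
from .stimulus import StimulusTrace

__all__ = [
    "RateTrace",
    "ResponseSegment",
    "kernel_rate",
    "average_rate",
    "response_characteristics",
    "r_squared",
    "extract_response_segments",
    "DEFAULT_KERNEL_SD",
    "DEFAULT_RATE_DT",
]

DEFAULT_KERNEL_SD = 0.03  # s, Gaussian kernel SD for rate estimation
DEFAULT_RATE_DT = 0.001  # s, rate-grid resolution

_TRUNC_SD = 8.0  # kernel support truncated at +/- 8 SD (mass error < 1e-15)


@dataclass
class RateTrace:
    """Kernel-smoothed firing rate (Hz) on a uniform time grid (s)."""

    time: np.ndarray
    rate: np.ndarray
    kernel_sd: float = DEFAULT_KERNEL_SD

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.time.shape != self.rate.shape:
            raise ValueError("time and rate must have the same shape")
        if np.any(self.rate < -1e-12):
            raise ValueError("rates must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def integral(self) -> float:
        """Trapezoidal integral of the rate (expected spike count)."""
        return float(np.trapezoid(self.rate, self.time))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.time, "rate_hz": self.rate}).to_csv(
            path, sep="\t", index=False
        )


def rate_grid(t0: float, t1: float, dt: float = DEFAULT_RATE_DT) -> np.ndarray:
    """Uniform grid [t0, t1] with step dt (t1 adjusted to the grid)."""
    n = int(round((t1 - t0) / dt))
    return t0 + np.arange(n + 1) * dt


def kernel_rate(
    spikes: SpikeTrain | np.ndarray,
    grid: np.ndarray,
    sd: float = DEFAULT_KERNEL_SD,
) -> RateTrace:
    """Gaussian-kernel rate estimate on a uniform grid.

    Each spike contributes a unit-mass normal density N(t_spike, sd²); the
    rate is their sum in Hz.  The kernel is truncated at ±8 SD (negligible
    mass).
    """
    if sd <= 0:
        raise ValueError("kernel sd must be positive")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty rate grid")
    times = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    rate = np.zeros(grid.size)
    if times.size:
        dt = grid[1] - grid[0] if grid.size > 1 else sd
        half = _TRUNC_SD * sd
        norm = 1.0 / (np.sqrt(2.0 * np.pi) * sd)
        for t_sp in times:
            lo = np.searchsorted(grid, t_sp - half, side="left")
            hi = np.searchsorted(grid, t_sp + half, side="right")
            if lo < hi:
                z = (grid[lo:hi] - t_sp) / sd
                rate[lo:hi] += norm * np.exp(-0.5 * z * z)
    return RateTrace(grid, rate, kernel_sd=sd)


def average_rate(traces: list[RateTrace]) -> tuple[RateTrace, RateTrace, RateTrace]:
    """Pointwise mean and lower/upper quartile traces across cells.

    All traces must share the same grid (rates aligned to stimulus onset).
    Returns (mean, lower quartile, upper quartile).
    """
    if not traces:
        raise ValueError("need at least one trace")
    grid = traces[0].time
    for tr in traces[1:]:
        if tr.time.shape != grid.shape or not np.allclose(tr.time, grid):
            raise ValueError("traces are not on a common grid")
    stack = np.vstack([tr.rate for tr in traces])
    sd = traces[0].kernel_sd
    mean = RateTrace(grid, stack.mean(axis=0), kernel_sd=sd)
    lq = RateTrace(grid, np.percentile(stack, 25, axis=0), kernel_sd=sd)
    uq = RateTrace(grid, np.percentile(stack, 75, axis=0), kernel_sd=sd)
    return mean, lq, uq


def response_characteristics(
    trace: RateTrace, spikes: SpikeTrain, onset: float
) -> tuple[float, float, float]:
    """Peak smoothed rate after stimulus onset and first-spike latency.

    Returns (peak_rate_hz, peak_time_s, first_spike_latency_s); the peak
    time is relative to the recording origin, the latency to ``onset``.
    The latency is NaN if no spike follows the onset.
    """
    if not trace.time[0] <= onset <= trace.time[-1]:
        raise ValueError("onset lies outside the rate grid")
    after = trace.time >= onset
    idx = np.argmax(trace.rate[after])
    peak_rate = float(trace.rate[after][idx])
    peak_time = float(trace.time[after][idx])
    later = spikes.spike_times[spikes.spike_times >= onset]
    latency = float(later[0] - onset) if later.size else float("nan")
    return peak_rate, peak_time, latency


def r_squared(f_d: RateTrace, f_m: RateTrace) -> float:
    """Coefficient of determination between a data rate and a model rate,

        R² = 1 − ∫(f_d − f_m)² dt / ∫(f_d − ⟨f_d⟩)² dt,

    with ⟨f_d⟩ the data mean over the same window and both integrals
    trapezoidal on the common grid.  Can be negative (prediction worse than
    the data mean); not clipped.
    """
    if f_d.time.shape != f_m.time.shape or not np.allclose(f_d.time, f_m.time):
        raise ValueError("rate traces are not on a common grid")
    t = f_d.time
    span = t[-1] - t[0]
    mean_d = np.trapezoid(f_d.rate, t) / span
    denom = np.trapezoid((f_d.rate - mean_d) ** 2, t)
    if denom <= 1e-12 * span * (mean_d**2 + 1.0):
        raise ZeroDivisionError(
            "R^2 undefined: the data rate is constant over the window"
        )
    num = np.trapezoid((f_d.rate - f_m.rate) ** 2, t)
    return float(1.0 - num / denom)


@dataclass
class ResponseSegment:
    """A pulse response extracted from an intermittent recording.

    ``spikes`` starts ``pre_window`` s before the puff onset, so onset sits
    at t = pre_window within the segment; ``spike_times_rel_onset`` gives
    the same spikes referenced to the onset itself.
    """

    onset: float  # puff onset in recording time (s)
    puff_s: float  # puff duration (s)
    pre_blank_s: float  # blank duration preceding the puff (s)
    spikes: SpikeTrain  # segment-local times, origin at onset - pre_window
    pre_window: float = 0.1
    metadata: dict = field(default_factory=dict)

    @property
    def spike_times_rel_onset(self) -> np.ndarray:
        return self.spikes.spike_times - self.pre_window


def extract_response_segments(
    stimulus: StimulusTrace,
    spikes: SpikeTrain,
    min_puff: float = 0.5,
    min_pre_blank: float = 0.1,
    pre_window: float = 0.1,
) -> list[ResponseSegment]:
    """Find qualifying pulse responses in an intermittent valve recording.

    A segment qualifies when a puff of at least ``min_puff`` s follows a
    blank of at least ``min_pre_blank`` s.  Each segment's spike train is
    re-referenced to the puff onset and spans [-pre_window, puff duration].
    The recording must carry the binary valve state.
    """
    if stimulus.valve is None:
        raise ValueError("stimulus has no valve-state channel")
    v = np.asarray(stimulus.valve) > 0.5
    dt = stimulus.dt
    # run-length encode the valve state
    change = np.flatnonzero(np.diff(v.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [v.size]])
    # sample i covers [t_i, t_i + dt); the closing grid point adds no time
    lengths = (ends - starts) * dt
    lengths[-1] -= dt
    segments: list[ResponseSegment] = []
    tol = dt / 2
    for j in range(len(starts)):
        if not v[starts[j]]:
            continue
        puff_len = lengths[j]
        if puff_len < min_puff - tol:
            continue
        if j == 0:
            continue  # no preceding blank on record
        blank_len = lengths[j - 1]
        if blank_len < min_pre_blank - tol:
            continue
        onset = stimulus.time[starts[j]]
        seg_spikes = spikes.spike_times - (onset - pre_window)
        keep = (seg_spikes >= 0) & (seg_spikes <= pre_window + puff_len)
        seg = SpikeTrain(
            seg_spikes[keep], pre_window + puff_len,
            metadata=dict(spikes.metadata),
        )
        segments.append(
            ResponseSegment(
                onset=float(onset),
                puff_s=float(puff_len),
                pre_blank_s=float(blank_len),
                spikes=seg,
                pre_window=pre_window,
            )
        )
    return segments
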