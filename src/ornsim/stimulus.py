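"""Stimulation protocols: constant pulses and randomized puff/blank valve
sequences, plus the mapping from pheromone dose to airborne concentration.

The experiments deliver pheromone through an electrovalve.  Two protocols are
modelled: a single constant pulse (``pulse_stimulus``) and an intermittent
sequence in which time is divided into bins of fixed duration (50 or 100 ms)
and the valve is open in each bin independently with probability 0.5
(``random_puff_stimulus``).  Consecutive open bins merge into longer puffs, so
puff and pause durations are geometrically distributed.  Valve transitions are
idealized as instantaneous steps (the physical valve switches in < 5 ms,
below the bin scale); an optional first-order rise/decay time constant is
available but defaults off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StimulusTrace",
    "dose_to_concentration",
    "pulse_stimulus",
    "random_puff_stimulus",
]

#: Dose (pg) per μM of airborne concentration.  The calibration is linear:
#: 1, 10, 100, 1000 pg map to 0.1, 1, 10, 100 pM (1 pM = 1e-6 μM).
_PG_PER_UM = 1e7

_CALIBRATED_DOSES_PG = (1.0, 10.0, 100.0, 1000.0)


@dataclass
class StimulusTrace:
    """Time-resolved airborne odorant concentration on a uniform grid.

    Attributes
    ----------
    time : np.ndarray
        Uniform time grid (s), starting at 0.
    L_air : np.ndarray
        Airborne odorant concentration (μM) at each grid point.
    valve : np.ndarray or None
        Optional binary valve state per grid point (1 = open).
    metadata : dict
        Protocol metadata (dose_pg, bin_s, p_open, seed, ...).
    """

    time: np.ndarray
    L_air: np.ndarray
    valve: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.L_air = np.asarray(self.L_air, dtype=float)
        if self.time.shape != self.L_air.shape:
            raise ValueError("time and L_air must have the same shape")
        if self.time.size < 2:
            raise ValueError("stimulus needs at least two grid points")
        if np.any(self.L_air < 0):
            raise ValueError("L_air must be non-negative everywhere")
        steps = np.diff(self.time)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1])

    def to_tsv(self, path: str | Path) -> None:
        cols = {"time_s": self.time, "L_air_uM": self.L_air}
        if self.valve is not None:
            cols["valve"] = self.valve.astype(int)
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StimulusTrace":
        df = pd.read_csv(path, sep="\t")
        valve = df["valve"].to_numpy() if "valve" in df.columns else None
        return cls(df["time_s"].to_numpy(), df["L_air_uM"].to_numpy(), valve=valve)


def dose_to_concentration(dose_pg: float) -> float:
    """Convert a pheromone dose on the stimulus cartridge to airborne
    concentration ``L_air`` in μM.

    The calibrated points are 1, 10, 100, 1000 pg → 0.1, 1, 10, 100 pM;
    other positive doses are mapped by the same linear rule (extrapolation).

    Parameters
    ----------
    dose_pg : float
        Pheromone dose in picograms; must be positive.
    """
    if not dose_pg > 0:
        raise ValueError(f"dose must be positive, got {dose_pg} pg")
    return float(dose_pg) / _PG_PER_UM


def _time_grid(total_s: float, dt: float) -> np.ndarray:
    n = int(round(total_s / dt))
    return np.arange(n + 1) * dt


def pulse_stimulus(
    pre_s: float,
    pulse_s: float,
    post_s: float,
    L_air: float,
    dt: float,
    rise_tau_s: float = 0.0,
) -> StimulusTrace:
    """Single constant pulse: zero concentration for ``pre_s``, ``L_air``
    for ``pulse_s``, zero again for ``post_s``.

    With ``rise_tau_s`` > 0 the square valve transitions are low-pass
    filtered with a first-order time constant; the default is an ideal step.
    """
    if min(pre_s, pulse_s, post_s) < 0:
        raise ValueError("durations must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if L_air < 0:
        raise ValueError("L_air must be non-negative")
    t = _time_grid(pre_s + pulse_s + post_s, dt)
    valve = ((t >= pre_s - dt / 2) & (t < pre_s + pulse_s - dt / 2)).astype(float)
    conc = L_air * valve
    if rise_tau_s > 0:
        conc = _first_order_filter(conc, dt, rise_tau_s)
    return StimulusTrace(
        t,
        conc,
        valve=valve,
        metadata={"protocol": "pulse", "pre_s": pre_s, "pulse_s": pulse_s,
                  "post_s": post_s, "L_air_uM": L_air, "dt": dt},
    )


def random_puff_stimulus(
    total_s: float,
    bin_s: float,
    L_air: float,
    dt: float,
    seed: int,
    p_open: float = 0.5,
    rise_tau_s: float = 0.0,
) -> StimulusTrace:
    """Randomized puff/blank valve sequence.

    Time is divided into bins of ``bin_s`` (50 or 100 ms in the experiments);
    in each bin the valve is open independently with probability ``p_open``.
    Runs of open bins form puffs, runs of closed bins form pauses, so both
    durations are geometric with mean ``bin_s / (1 - p_open)`` and
    ``bin_s / p_open`` respectively.  The sequence is deterministic under
    ``seed``; distinct seeds give each simulated neuron its own sequence.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_bins = round(total_s / bin_s)
    if abs(n_bins * bin_s - total_s) > 1e-9:
        raise ValueError(f"total_s={total_s} is not a multiple of bin_s={bin_s}")
    per_bin = round(bin_s / dt)
    if abs(per_bin * dt - bin_s) > 1e-12:
        raise ValueError(f"dt={dt} does not divide bin_s={bin_s}")
    if not 0 <= p_open <= 1:
        raise ValueError("p_open must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bins = (rng.random(n_bins) < p_open).astype(float)
    valve = np.repeat(bins, per_bin)
    valve = np.concatenate([valve, valve[-1:]])  # closing grid point
    t = np.arange(valve.size) * dt
    conc = L_air * valve
    if rise_tau_s > 0:
        conc = _first_order_filter(conc, dt, rise_tau_s)
    return StimulusTrace(
        t,
        conc,
        valve=valve,
        metadata={"protocol": "random_puff", "total_s": total_s, "bin_s": bin_s,
                  "p_open": p_open, "L_air_uM": L_air, "dt": dt, "seed": seed},
    )


def _first_order_filter(x: np.ndarray, dt: float, tau: float) -> np.ndarray:
    out = np.empty_like(x)
    out[0] = x[0]
    a = dt / tau
    for i in range(1, x.size):
        out[i] = out[i - 1] + a * (x[i] - out[i - 1])
    return out
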