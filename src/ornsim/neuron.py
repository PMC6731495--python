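"""Spike generation: a leaky integrate-and-fire neuron driven by the
receptor conductance, with either a constant or an adaptive spike threshold.

The membrane obeys

    C_m dV/dt = −g_L (V − E_L) − γ R*(t) (V − E_R),

where the activated-receptor concentration R*(t) from the transduction
cascade opens a conductance γ·R* with reversal E_R.  A spike is emitted when
V reaches the threshold θ(t) (test V ≥ θ) and V resets instantly to
V_reset.

Two threshold descriptions:

* constant — θ(t) = θ₀, with an absolute refractory period ``t_ref``
  (3 ms by default) during which V is clamped at V_reset; this is the
  standard LIF model and produces rates that track the stimulus
  monotonically;
* adaptive — between spikes θ relaxes exponentially to θ₀ with time
  constant τ (τ dθ/dt = −(θ − θ₀)) and each spike increments it by Δ/τ
  applied to the pre-spike value.  The jump-and-decay threshold produces
  spike-frequency adaptation and the phasic–tonic response profile
  characteristic of pheromone-sensitive neurons.

Integration is forward Euler on the same grid as the kinetics (reference
step 0.01 ms); V(0) = E_L, θ(0) = θ₀.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._engine import euler_neuron
from .kinetics import KineticParams, KineticState, KineticTrajectory, simulate_kinetics
from .stimulus import StimulusTrace

__all__ = [
    "MembraneParams",
    "ThresholdParams",
    "SpikeTrain",
    "NeuronTraces",
    "threshold_trace",
    "simulate_neuron",
    "simulate_orn",
]


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane and receptor-current parameters.

    Units: C_m nF, conductances nS, voltages mV, γ nS·μM⁻¹.  With these
    units C_m/g_L = 1 ms, the membrane time constant of the moth neuron.
    """

    C_m: float = 0.00144
    g_L: float = 1.44
    gamma: float = 99.27
    E_L: float = -62.0
    E_R: float = 0.0
    V_reset: float = -62.0

    def __post_init__(self) -> None:
        if not self.C_m > 0:
            raise ValueError("C_m must be positive")
        if not self.g_L > 0:
            raise ValueError("g_L must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not self.V_reset < self.E_R:
            raise ValueError("V_reset must lie below E_R")

    def replace(self, **kwargs) -> "MembraneParams":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True)
class ThresholdParams:
    """Spike-threshold dynamics.

    ``mode`` selects constant (LIF + refractory period ``t_ref``) or
    adaptive (exponential relaxation to θ₀ with time constant τ, jump Δ/τ
    per spike).  Defaults: θ₀ = −55 mV, Δ = 0.77 mV·s, τ = 0.58 s,
    t_ref = 3 ms (constant mode only).
    """

    mode: str = "adaptive"
    theta0: float = -55.0
    delta: float = 0.77
    tau: float = 0.58
    t_ref: float = 0.003

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "adaptive"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")

    def replace(self, **kwargs) -> "ThresholdParams":
        from dataclasses import replace

        return replace(self, **kwargs)

    def validate_against(self, mem: MembraneParams) -> None:
        if not self.theta0 > mem.V_reset:
            raise ValueError("theta0 must lie above V_reset")


@dataclass
class SpikeTrain:
    """Sorted spike times (s) within a recording of known duration."""

    spike_times: np.ndarray
    duration: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.spike_times[0] < 0 or self.spike_times[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    def __len__(self) -> int:
        return int(self.spike_times.size)

    def shifted(self, offset: float, duration: float | None = None) -> "SpikeTrain":
        """Re-reference spike times to a new origin, keeping those in range."""
        dur = self.duration - offset if duration is None else duration
        t = self.spike_times - offset
        t = t[(t >= 0) & (t <= dur)]
        return SpikeTrain(t, dur, metadata=dict(self.metadata))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "cell_id": self.metadata.get("cell_id", 0),
                "trial_id": self.metadata.get("trial_id", 0),
                "spike_time_s": self.spike_times,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, duration: float) -> "SpikeTrain":
        df = pd.read_csv(path, sep="\t")
        meta = {}
        if len(df):
            meta = {"cell_id": df["cell_id"].iloc[0], "trial_id": df["trial_id"].iloc[0]}
        return cls(df["spike_time_s"].to_numpy(), duration, metadata=meta)


@dataclass
class NeuronTraces:
    """Voltage and threshold traces accompanying a simulated spike train."""

    time: np.ndarray
    V: np.ndarray
    theta: np.ndarray
    Rstar: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.time, "V_mV": self.V, "theta_mV": self.theta,
             "Rstar_uM": self.Rstar}
        ).to_csv(path, sep="\t", index=False)


def threshold_trace(
    spikes: SpikeTrain, thr: ThresholdParams, grid: np.ndarray
) -> np.ndarray:
    """Closed-form adaptive threshold θ(t) on an arbitrary time grid.

    Between spikes θ decays exponentially toward θ₀; at each spike the
    pre-spike (left-limit) value is incremented by Δ/τ.  θ(0) = θ₀.
    """
    if thr.mode != "adaptive":
        raise ValueError("threshold_trace requires adaptive mode")
    grid = np.asarray(grid, dtype=float)
    out = np.full(grid.shape, thr.theta0)
    excess = 0.0  # theta(t_f+) - theta0 after the most recent spike
    t_last = 0.0
    edges = np.concatenate([spikes.spike_times, [np.inf]])
    for k, t_sp in enumerate(edges):
        sel = slice(
            np.searchsorted(grid, t_last if k else -np.inf, side="left"),
            np.searchsorted(grid, t_sp, side="right"),
        )
        out[sel] = thr.theta0 + excess * np.exp(-(grid[sel] - t_last) / thr.tau)
        if np.isinf(t_sp):
            break
        # decay the excess to the spike time, then jump by delta/tau
        excess = excess * np.exp(-(t_sp - t_last) / thr.tau) + thr.delta / thr.tau
        t_last = t_sp
    return out


def simulate_neuron(
    Rstar: np.ndarray,
    mem: MembraneParams,
    thr: ThresholdParams,
    dt: float,
    time: np.ndarray | None = None,
    record_traces: bool = True,
) -> tuple[SpikeTrain, NeuronTraces | None]:
    """Integrate the membrane equation for a given R*(t) and emit spikes.

    ``Rstar`` must be sampled on a uniform grid with step ``dt`` (supply
    ``time`` to carry the grid through to the traces).  Per Euler step:
    voltage update using the current step's R*, threshold decay (adaptive),
    crossing test V ≥ θ, then reset — plus threshold jump Δ/τ (adaptive) or
    a refractory clamp of V at V_reset for ``t_ref`` (constant mode).
    Spike times are the grid times of the crossing steps.
    """
    Rstar = np.ascontiguousarray(Rstar, dtype=np.float64)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if time is not None:
        time = np.asarray(time, dtype=float)
        if time.shape != Rstar.shape:
            raise ValueError("time grid and Rstar trace have mismatched lengths")
        if abs((time[1] - time[0]) - dt) > 1e-12:
            raise ValueError("time grid step does not match dt")
    thr.validate_against(mem)
    V, theta, spike_idx, nspk = euler_neuron(
        Rstar,
        dt,
        mem.C_m,
        mem.g_L,
        mem.gamma,
        mem.E_L,
        mem.E_R,
        mem.V_reset,
        thr.theta0,
        thr.delta,
        thr.tau,
        thr.t_ref,
        thr.mode == "adaptive",
        record_traces,
    )
    t = time if time is not None else np.arange(Rstar.size) * dt
    duration = float(t[-1])
    spikes = SpikeTrain(t[spike_idx[:nspk]], duration)
    traces = NeuronTraces(t, V, theta, Rstar) if record_traces else None
    return spikes, traces


def simulate_orn(
    stimulus: StimulusTrace,
    kin: KineticParams | None = None,
    mem: MembraneParams | None = None,
    thr: ThresholdParams | None = None,
    dt: float | None = None,
    initial: KineticState | None = None,
    record_traces: bool = False,
) -> tuple[SpikeTrain, NeuronTraces | None, KineticTrajectory]:
    """Full sensory pathway: transduction cascade then spike generation.

    Runs :func:`~ornsim.kinetics.simulate_kinetics` on the stimulus grid and
    feeds R*(t) into :func:`simulate_neuron`.  Deterministic given inputs.
    Returns (spike train, optional V/θ traces, kinetic trajectory).
    """
    kin = kin or KineticParams()
    mem = mem or MembraneParams()
    thr = thr or ThresholdParams()
    traj = simulate_kinetics(stimulus, kin, dt=dt, initial=initial)
    spikes, traces = simulate_neuron(
        traj.Rstar, mem, thr, traj.dt, time=traj.time, record_traces=record_traces
    )
    spikes.metadata.update(stimulus.metadata)
    return spikes, traces, traj
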