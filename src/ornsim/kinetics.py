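"""Receptor-activation kinetics of the pheromone transduction cascade.

The cascade is a mass-action scheme in the sensillum lymph: airborne odorant
L_air is adsorbed at rate ``k_i`` into the lymph concentration L; L binds the
free receptor R cooperatively (exponent ``n``) to form the receptor–ligand
complex R_L, which activates reversibly to R*; in parallel a deactivating
enzyme N binds L and degrades it into an inactive product (an untracked
sink).  Conservation of receptor and enzyme (R + R_L + R* = R_tot,
N + N_L = N_tot) reduces the scheme to four ODEs in (L, R, R*, N); the
complexed states R_L and N_L are derived quantities.

The reduced system is integrated with forward Euler (reference step
0.01 ms), which is how the reference output of the model is defined.  The
activated-receptor concentration R*(t) is the output that drives the
spike generator (:mod:`ornsim.neuron`).

Units: time s, concentration μM, rates s⁻¹ (binding rates s⁻¹·μM⁻ⁿ and
s⁻¹·μM⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._engine import euler_kinetics
from .stimulus import StimulusTrace

__all__ = [
    "KineticParams",
    "KineticState",
    "KineticTrajectory",
    "KineticsInstabilityError",
    "kinetic_derivatives",
    "simulate_kinetics",
    "steady_state_kinetics",
]


class KineticsInstabilityError(RuntimeError):
    """Raised when Euler integration undershoots zero beyond tolerance."""


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and total concentrations of the transduction cascade.

    Defaults are the fitted/fixed values for the moth pheromone receptor:
    ``n`` (cooperativity) was fitted to data, the rest come from earlier
    biophysical measurements, with ``k3``/``k4`` chosen for rapid odorant
    clearance.

    Attributes
    ----------
    R_tot, N_tot : float
        Total receptor / deactivating-enzyme concentration (μM).
    k_i : float
        Adsorption rate of airborne odorant into the lymph (s⁻¹).
    k1, k_m1 : float
        Receptor binding (s⁻¹·μM⁻ⁿ) / unbinding (s⁻¹) rates.
    k2, k_m2 : float
        Receptor activation / deactivation rates (s⁻¹).
    k3, k_m3 : float
        Enzyme binding (s⁻¹·μM⁻¹) / unbinding (s⁻¹) rates.
    k4 : float
        Degradation rate of enzyme-bound odorant (s⁻¹).
    n : float
        Binding cooperativity exponent (dimensionless).
    """

    R_tot: float = 1.64
    N_tot: float = 1.0
    k_i: float = 1e6
    k1: float = 0.209
    k_m1: float = 7.9
    k2: float = 16.8
    k_m2: float = 98.0
    k3: float = 100.0
    k_m3: float = 98.9
    k4: float = 40000.0
    n: float = 0.056

    def __post_init__(self) -> None:
        for name in ("R_tot", "N_tot", "k_i", "k1", "k_m1", "k2", "k_m2",
                     "k3", "k_m3", "k4", "n"):
            if not getattr(self, name) > 0:
                raise ValueError(f"KineticParams.{name} must be positive")

    def replace(self, **kwargs) -> "KineticParams":
        from dataclasses import replace

        return replace(self, **kwargs)

    def as_tuple(self) -> tuple:
        return (self.R_tot, self.N_tot, self.k_i, self.k1, self.k_m1,
                self.k2, self.k_m2, self.k3, self.k_m3, self.k4, self.n)


@dataclass(frozen=True)
class KineticState:
    """Concentrations (μM) of the four dynamic species.

    ``L`` free odorant in the lymph, ``R`` free receptor, ``Rstar``
    activated receptor, ``N`` free enzyme.  The complexed species follow by
    conservation (see :meth:`R_L` and :meth:`N_L`).
    """

    L: float = 0.0
    R: float = 1.64
    Rstar: float = 0.0
    N: float = 1.0

    def validate(self, params: KineticParams) -> None:
        if min(self.L, self.R, self.Rstar, self.N) < 0:
            raise ValueError("kinetic state fields must be non-negative")
        if self.R_L(params) < -1e-12:
            raise ValueError("derived R_L = R_tot - R - Rstar is negative")
        if self.N_L(params) < -1e-12:
            raise ValueError("derived N_L = N_tot - N is negative")

    def R_L(self, params: KineticParams) -> float:
        """Receptor–ligand complex concentration from conservation."""
        return params.R_tot - self.R - self.Rstar

    def N_L(self, params: KineticParams) -> float:
        """Enzyme–ligand complex concentration from conservation."""
        return params.N_tot - self.N

    @classmethod
    def resting(cls, params: KineticParams) -> "KineticState":
        """All receptors and enzymes free, no odorant."""
        return cls(L=0.0, R=params.R_tot, Rstar=0.0, N=params.N_tot)


@dataclass
class KineticTrajectory:
    """Euler trajectory of the cascade on a uniform time grid."""

    time: np.ndarray
    L: np.ndarray
    R: np.ndarray
    Rstar: np.ndarray
    N: np.ndarray
    params: KineticParams = field(default_factory=KineticParams)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def state_at(self, i: int) -> KineticState:
        return KineticState(self.L[i], self.R[i], self.Rstar[i], self.N[i])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.time, "L_uM": self.L, "R_uM": self.R,
             "Rstar_uM": self.Rstar, "N_uM": self.N}
        ).to_csv(path, sep="\t", index=False)


def _pow0(L: float, n: float) -> float:
    # 0**n := 0 also for fractional n; L clamped at 0 first
    L = max(L, 0.0)
    return L**n if L > 0 else 0.0


def kinetic_derivatives(
    state: KineticState, L_air: float, params: KineticParams
) -> KineticState:
    """Time-derivatives (μM·s⁻¹) of the reduced 4-state system.

    dL/dt  = k_i·L_air − n(k1·Lⁿ + k₋₁)R − n·k₋₁·R* − (k3·L + k₋₃)N
             + n·k₋₁·R_tot + k₋₃·N_tot
    dR/dt  = −(k1·Lⁿ + k₋₁)R − k₋₁·R* + k₋₁·R_tot
    dR*/dt = −k2·R − (k2 + k₋₂)R* + k2·R_tot
    dN/dt  = −(k3·L + k₋₃ + k4)N + (k₋₃ + k4)N_tot

    ``L`` is clamped at zero before exponentiation (0ⁿ := 0).  The result is
    packaged as a :class:`KineticState` whose fields hold the derivatives.
    """
    if L_air < 0:
        raise ValueError("L_air must be non-negative")
    state.validate(params)
    p = params
    L = max(state.L, 0.0)
    Ln = _pow0(L, p.n)
    a1 = p.k1 * Ln + p.k_m1
    dL = (
        p.k_i * L_air
        - p.n * a1 * state.R
        - p.n * p.k_m1 * state.Rstar
        - (p.k3 * L + p.k_m3) * state.N
        + p.n * p.k_m1 * p.R_tot
        + p.k_m3 * p.N_tot
    )
    dR = -a1 * state.R - p.k_m1 * state.Rstar + p.k_m1 * p.R_tot
    dRstar = -p.k2 * state.R - (p.k2 + p.k_m2) * state.Rstar + p.k2 * p.R_tot
    dN = -(p.k3 * L + p.k_m3 + p.k4) * state.N + (p.k_m3 + p.k4) * p.N_tot
    return KineticState(L=dL, R=dR, Rstar=dRstar, N=dN)


def simulate_kinetics(
    stimulus: StimulusTrace,
    params: KineticParams | None = None,
    dt: float | None = None,
    initial: KineticState | None = None,
    undershoot_tol: float = 1e-3,
) -> KineticTrajectory:
    """Forward-Euler trajectory of the cascade driven by a stimulus.

    The trajectory lives on the stimulus grid (``dt``, if given, must match
    the stimulus step).  The default initial condition is the resting state
    (L = 0, R = R_tot, R* = 0, N = N_tot).  States are clamped at zero after
    each step; an undershoot beyond ``undershoot_tol`` μM raises
    :class:`KineticsInstabilityError` advising a smaller step.
    """
    params = params or KineticParams()
    if dt is not None and abs(dt - stimulus.dt) > 1e-12 * max(dt, stimulus.dt):
        raise ValueError(
            f"dt={dt} does not match the stimulus grid step {stimulus.dt}; "
            "resample the stimulus instead"
        )
    step = stimulus.dt
    init = initial or KineticState.resting(params)
    init.validate(params)
    L, R, Rstar, N, undershoot = euler_kinetics(
        np.ascontiguousarray(stimulus.L_air, dtype=np.float64),
        step,
        *params.as_tuple(),
        init.L,
        init.R,
        init.Rstar,
        init.N,
    )
    if undershoot > undershoot_tol:
        raise KineticsInstabilityError(
            f"Euler step dt={step:g} s undershot zero by {undershoot:.3g} μM "
            f"(tolerance {undershoot_tol:g}); use a smaller dt "
            "(reference: 1e-5 s)"
        )
    return KineticTrajectory(stimulus.time, L, R, Rstar, N, params)


def steady_state_kinetics(L_air: float, params: KineticParams | None = None) -> KineticState:
    """Fixed point of the cascade at constant airborne concentration.

    Solved independently of the Euler integrator: at steady state the
    receptor and enzyme balances are linear given the lymph concentration L,
    and the odorant balance reduces to adsorption = enzymatic degradation,

        k_i·L_air = k3·k4·N_tot·L / (k3·L + k₋₃ + k4),

    which is solved for L in closed form; the remaining species follow.
    A steady state exists only while adsorption stays below the maximum
    degradation capacity k4·N_tot (otherwise L grows without bound).
    """
    params = params or KineticParams()
    if L_air < 0:
        raise ValueError("L_air must be non-negative")
    p = params
    if L_air == 0:
        return KineticState.resting(p)
    influx = p.k_i * L_air
    capacity = p.k4 * p.N_tot
    if influx >= capacity:
        raise RuntimeError(
            f"no steady state: adsorption k_i*L_air = {influx:g} μM/s meets or "
            f"exceeds the degradation capacity k4*N_tot = {capacity:g} μM/s"
        )
    c = p.k_m3 + p.k4
    L = influx * c / (p.k3 * (capacity - influx))
    # receptor branch: dR*/dt = 0 gives R_L = (k_m2/k2) R*;
    # dR/dt = 0 gives k1 L^n R = k_m1 R_L; conservation closes the system.
    a = p.k_m2 / p.k2
    Ln = _pow0(L, p.n)
    Rstar = p.R_tot / (1.0 + a + a * p.k_m1 / (p.k1 * Ln))
    R = a * p.k_m1 / (p.k1 * Ln) * Rstar
    N = c * p.N_tot / (p.k3 * L + c)
    state = KineticState(L=L, R=R, Rstar=Rstar, N=N)
    d = kinetic_derivatives(state, L_air, p)
    scale = max(influx, 1.0)
    if max(abs(d.L), abs(d.R), abs(d.Rstar), abs(d.N)) > 1e-6 * scale:
        raise RuntimeError(
            "steady-state solve did not converge: residual derivatives "
            f"({d.L:.3g}, {d.R:.3g}, {d.Rstar:.3g}, {d.N:.3g}) μM/s"
        )
    return state
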