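"""Two-stage parameter fitting of the sensory-neuron model.

Stage one fits the four free parameters (n, γ, τ, Δ) to dose-resolved
average pulse responses by minimizing the integrated squared error summed
over doses,

    ε²_ave = Σ_L_air ∫ (f_d(t|L_air) − f_m(t|L_air))² dt,

where f_d is the kernel-smoothed average firing rate of the data and f_m
that of the model under a 0.5 s constant pulse at each dose.

Stage two adapts a per-cell subset of parameters — γ alone, (Δ, τ), or
(γ, Δ, τ) — to each individual recording by minimizing the same integral
over a 10 s training window,

    ε²_ind = ∫ (f_d(t) − f_m(t))² dt,

with all remaining parameters fixed at their stage-one values, and scores
the fitted cell by the coefficient of determination R² on the subsequent
10 s prediction window.  Model simulations for scored windows start 1 s
early (burn-in) from the resting state to wash out initial conditions.

Minimization uses Nelder–Mead on log-transformed parameters (which keeps
them positive).  The stage-one objective is rugged — spike counts are
integers, so ε²_ave is piecewise smooth with many shallow local minima and
a basin of attraction only ~±10% wide around the optimum — and a single
Nelder–Mead run from a far start reliably stalls.  The stage-one driver
therefore wraps Nelder–Mead in a multiscale continuation: the objective is
first minimized with the rate traces additionally smoothed by a broad
Gaussian (which widens the basin), starting from a small Sobol multistart
around the user's initial point, and the smoothing is then annealed away
in stages, warm-starting each stage from the previous optimum.  Per-cell
fits (one or two free parameters, stage two) use plain Nelder–Mead with a
restart from the incumbent.  The model is deterministic, so a single
simulation per objective evaluation suffices; within a per-cell fit the
transduction cascade does not depend on any free parameter, so R*(t) is
simulated once per cell and only the spike generator is re-run per
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize
from scipy.stats import qmc

from .kinetics import KineticParams, simulate_kinetics
from .neuron import MembraneParams, SpikeTrain, ThresholdParams, simulate_neuron
from .rates import (
    DEFAULT_KERNEL_SD,
    DEFAULT_RATE_DT,
    RateTrace,
    kernel_rate,
    r_squared,
    rate_grid,
)
from .stimulus import StimulusTrace, pulse_stimulus

__all__ = [
    "AveragePulseProtocol",
    "FitResult",
    "PopulationSummary",
    "SCHEME_FREE_PARAMS",
    "ise_average",
    "ise_individual",
    "fit_average",
    "fit_cell",
    "evaluate_prediction",
    "population_summary",
    "simulate_average_responses",
]

#: Free parameters per heterogeneity scheme.
SCHEME_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "homogeneous": (),
    "gamma": ("gamma",),
    "delta_tau": ("delta", "tau"),
    "gamma_delta_tau": ("gamma", "delta", "tau"),
}

_AVERAGE_FREE = ("n", "gamma", "tau", "delta")


@dataclass(frozen=True)
class AveragePulseProtocol:
    """Pulse protocol and scoring grid for the stage-one (average) fit.

    The scored window covers the whole simulated trace: ``pre_s`` of blank,
    the 0.5 s pulse, and ``post_s`` of decay, so both the phasic onset and
    the adaptation-driven decay inform the objective.
    """

    L_airs: tuple[float, ...] = (1e-7, 1e-6, 1e-5, 1e-4)
    pre_s: float = 0.1
    pulse_s: float = 0.5
    post_s: float = 0.4
    dt: float = 1e-5
    rate_dt: float = DEFAULT_RATE_DT
    kernel_sd: float = DEFAULT_KERNEL_SD

    @property
    def total_s(self) -> float:
        return self.pre_s + self.pulse_s + self.post_s

    def grid(self) -> np.ndarray:
        return rate_grid(0.0, self.total_s, self.rate_dt)


@dataclass
class FitResult:
    """Outcome of one Nelder–Mead fit."""

    scheme: str  # average | homogeneous | gamma | delta_tau | gamma_delta_tau
    params: dict  # fitted name -> value
    fixed: dict  # snapshot of the non-fitted parameters
    objective: float  # final epsilon^2 (Hz^2 * s)
    n_iter: int = 0
    n_fev: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be non-negative")
        for k, v in self.params.items():
            if k in ("n", "gamma", "tau", "delta") and not v > 0:
                raise ValueError(f"fitted {k} must be positive, got {v}")


@dataclass
class PopulationSummary:
    """Population statistics of per-cell fits."""

    n_cells: int
    mean: dict  # parameter -> population mean
    sd: dict  # parameter -> population SD (ddof=1)
    corr_delta_tau: float  # Pearson correlation of (delta, tau); NaN if undefined
    r2: np.ndarray  # per-cell prediction R^2
    r2_median: float
    r2_iqr: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "mean": self.mean,
            "sd": self.sd,
            "corr_delta_tau": self.corr_delta_tau,
            "r2_median": self.r2_median,
            "r2_iqr": list(self.r2_iqr),
        }


def _apply_free(
    free: dict,
    kin: KineticParams,
    mem: MembraneParams,
    thr: ThresholdParams,
) -> tuple[KineticParams, MembraneParams, ThresholdParams]:
    kin_kw = {k: v for k, v in free.items() if k in ("n",)}
    mem_kw = {k: v for k, v in free.items() if k in ("gamma",)}
    thr_kw = {k: v for k, v in free.items() if k in ("tau", "delta")}
    unknown = set(free) - {"n", "gamma", "tau", "delta"}
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    return (
        kin.replace(**kin_kw) if kin_kw else kin,
        mem.replace(**mem_kw) if mem_kw else mem,
        thr.replace(**thr_kw) if thr_kw else thr,
    )


def simulate_average_responses(
    kin: KineticParams | None = None,
    mem: MembraneParams | None = None,
    thr: ThresholdParams | None = None,
    protocol: AveragePulseProtocol | None = None,
) -> dict[float, RateTrace]:
    """Model pulse responses per dose, kernel-smoothed on the scoring grid.

    Returns a mapping L_air (μM) -> RateTrace, the model-side f_m(t|L_air)
    of the stage-one objective (also usable as synthetic targets).
    """
    kin = kin or KineticParams()
    mem = mem or MembraneParams()
    thr = thr or ThresholdParams()
    proto = protocol or AveragePulseProtocol()
    grid = proto.grid()
    out: dict[float, RateTrace] = {}
    for L_air in proto.L_airs:
        stim = pulse_stimulus(proto.pre_s, proto.pulse_s, proto.post_s, L_air, proto.dt)
        traj = simulate_kinetics(stim, kin)
        spikes, _ = simulate_neuron(
            traj.Rstar, mem, thr, traj.dt, time=traj.time, record_traces=False
        )
        out[L_air] = kernel_rate(spikes, grid, sd=proto.kernel_sd)
    return out


def average_targets_from_recordings(
    recordings: list,
    protocol: AveragePulseProtocol | None = None,
) -> dict[float, RateTrace]:
    """Build stage-one targets from intermittent recordings.

    Extracts qualifying pulse segments (puff ≥ 0.5 s after ≥ 0.1 s blank)
    from each recording, smooths each segment's spikes, aligns them at the
    puff onset and averages across cells sharing a dose.  ``recordings``
    are objects with ``stimulus``, ``spikes`` and a ``metadata['dose_pg']``
    entry (e.g. :class:`~ornsim.synthpop.CellRecording`).  Segment rates
    are evaluated on the protocol grid, with the onset at ``pre_s``.
    """
    from .rates import extract_response_segments
    from .stimulus import dose_to_concentration

    proto = protocol or AveragePulseProtocol(post_s=0.0)
    grid = proto.grid()
    by_dose: dict[float, list[np.ndarray]] = {}
    for rec in recordings:
        dose = rec.metadata["dose_pg"]
        segs = extract_response_segments(
            rec.stimulus, rec.spikes, pre_window=proto.pre_s
        )
        for seg in segs:
            # segment-local time 0 is onset - pre_s, matching the protocol
            tr = kernel_rate(seg.spikes, grid, sd=proto.kernel_sd)
            by_dose.setdefault(dose, []).append(tr.rate)
    targets: dict[float, RateTrace] = {}
    for dose, stack in sorted(by_dose.items()):
        targets[dose_to_concentration(dose)] = RateTrace(
            grid, np.mean(stack, axis=0), kernel_sd=proto.kernel_sd
        )
    return targets


def _extra_smooth(rate: np.ndarray, extra_sd: float, rate_dt: float) -> np.ndarray:
    """Convolve a rate trace with an additional Gaussian of SD ``extra_sd``.

    Used by the continuation stages of the stage-one fit: applying the same
    extra kernel to both data and model leaves the optimum in place (a
    self-match still scores zero) but widens the basin of attraction.
    """
    if extra_sd <= 0:
        return rate
    return gaussian_filter1d(rate, extra_sd / rate_dt, mode="nearest")


def ise_average(
    free_params: tuple[float, float, float, float] | dict,
    target_rates: dict[float, RateTrace],
    kin: KineticParams | None = None,
    mem: MembraneParams | None = None,
    thr: ThresholdParams | None = None,
    protocol: AveragePulseProtocol | None = None,
    extra_sd: float = 0.0,
) -> float:
    """Stage-one objective ε²_ave for free parameters (n, γ, τ, Δ).

    Simulates the pulse protocol at every dose present in ``target_rates``,
    smooths the model spike trains with the same kernel, and sums the
    trapezoidal integrated squared error across doses (Hz²·s).
    ``extra_sd`` > 0 smooths both sides further (continuation stages only;
    the reported objective always uses extra_sd = 0).
    """
    if not isinstance(free_params, dict):
        free_params = dict(zip(_AVERAGE_FREE, free_params))
    kin = kin or KineticParams()
    mem = mem or MembraneParams()
    thr = thr or ThresholdParams()
    proto = protocol or AveragePulseProtocol(L_airs=tuple(sorted(target_rates)))
    kin, mem, thr = _apply_free(free_params, kin, mem, thr)
    total = 0.0
    for L_air, target in target_rates.items():
        stim = pulse_stimulus(proto.pre_s, proto.pulse_s, proto.post_s, L_air, proto.dt)
        traj = simulate_kinetics(stim, kin)
        spikes, _ = simulate_neuron(
            traj.Rstar, mem, thr, traj.dt, time=traj.time, record_traces=False
        )
        model = _extra_smooth(
            kernel_rate(spikes, target.time, sd=proto.kernel_sd).rate,
            extra_sd, proto.rate_dt,
        )
        data = _extra_smooth(target.rate, extra_sd, proto.rate_dt)
        total += float(np.trapezoid((data - model) ** 2, target.time))
    return total


def _model_rate_for_window(
    stimulus: StimulusTrace,
    kin: KineticParams,
    mem: MembraneParams,
    thr: ThresholdParams,
    window: tuple[float, float],
    burn_in: float,
    rate_dt: float,
    kernel_sd: float,
    cached_rstar: tuple[np.ndarray, np.ndarray] | None = None,
) -> RateTrace:
    """Simulate the model over window (with burn-in) and smooth its spikes.

    ``cached_rstar`` is an optional (time, Rstar) pair for the sliced
    stimulus, letting per-cell fits skip the kinetics re-run.
    """
    t0, t1 = window
    if cached_rstar is None:
        time, rstar = _sliced_rstar(
            stimulus, kin, t0 - burn_in, t1 + _kernel_pad(kernel_sd)
        )
    else:
        time, rstar = cached_rstar
    dt = float(time[1] - time[0])
    spikes, _ = simulate_neuron(rstar, mem, thr, dt, time=time, record_traces=False)
    grid = rate_grid(t0, t1, rate_dt)
    return kernel_rate(spikes, grid, sd=kernel_sd)


def _kernel_pad(kernel_sd: float) -> float:
    """Simulation overhang past a scored window so model spikes just outside
    it contribute the same kernel mass as the data's do (kernel support)."""
    from .rates import _TRUNC_SD

    return _TRUNC_SD * kernel_sd


def _sliced_rstar(
    stimulus: StimulusTrace, kin: KineticParams, t_start: float, t_end: float
) -> tuple[np.ndarray, np.ndarray]:
    """Run the cascade on the stimulus restricted to [t_start, t_end].

    The simulation starts from the resting state at max(t_start, 0); the
    returned grid keeps recording-absolute times.
    """
    t_start = max(t_start, 0.0)
    dt = stimulus.dt
    i0 = int(round(t_start / dt))
    i1 = min(int(round(t_end / dt)), stimulus.time.size - 1)
    if i1 <= i0:
        raise ValueError("window does not overlap the stimulus")
    sub = StimulusTrace(
        stimulus.time[i0 : i1 + 1] - stimulus.time[i0],
        stimulus.L_air[i0 : i1 + 1],
    )
    traj = simulate_kinetics(sub, kin)
    return traj.time + stimulus.time[i0], traj.Rstar


def ise_individual(
    free_params: dict,
    stimulus: StimulusTrace,
    data_rate: RateTrace,
    window: tuple[float, float],
    kin: KineticParams | None = None,
    mem: MembraneParams | None = None,
    thr: ThresholdParams | None = None,
    burn_in: float = 1.0,
    kernel_sd: float = DEFAULT_KERNEL_SD,
    cached_rstar: tuple[np.ndarray, np.ndarray] | None = None,
    extra_sd: float = 0.0,
) -> float:
    """Stage-two objective ε²_ind over a training window (Hz²·s).

    ``data_rate`` must live on the window's rate grid.  The model is
    simulated from ``window[0] − burn_in`` (resting start) but scored on the
    window only.  ``extra_sd`` > 0 smooths both sides further (continuation
    stages only; the reported objective always uses extra_sd = 0).
    """
    kin = kin or KineticParams()
    mem = mem or MembraneParams()
    thr = thr or ThresholdParams()
    kin, mem, thr = _apply_free(free_params, kin, mem, thr)
    t0, t1 = window
    if t1 < t0:
        raise ValueError("window must have t1 >= t0")
    if t1 == t0:
        return 0.0
    model = _model_rate_for_window(
        stimulus, kin, mem, thr, window, burn_in, data_rate.dt, kernel_sd,
        cached_rstar=cached_rstar,
    )
    m = _extra_smooth(model.rate, extra_sd, data_rate.dt)
    d = _extra_smooth(data_rate.rate, extra_sd, data_rate.dt)
    return float(np.trapezoid((d - m) ** 2, data_rate.time))


def _nelder_mead_log(
    objective,
    names: tuple[str, ...],
    init: dict,
    maxiter: int = 500,
    xtol: float = 1e-4,
    restarts: int = 1,
) -> tuple[dict, float, int, int, bool]:
    """Nelder–Mead on log-parameters with restart(s) from the incumbent."""
    x0 = np.log([init[k] for k in names])

    def f(x):
        return objective(dict(zip(names, np.exp(x))))

    best_x, best_f = x0, f(x0)
    n_iter = n_fev = 0
    converged = False
    for _ in range(restarts + 1):
        res = minimize(
            f,
            best_x,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "xatol": xtol,
                "fatol": xtol * max(abs(best_f), 1e-12),
                "adaptive": True,
            },
        )
        n_iter += res.nit
        n_fev += res.nfev
        if res.fun <= best_f:
            best_x, best_f = res.x, res.fun
        converged = bool(res.success)
    return dict(zip(names, np.exp(best_x))), float(best_f), n_iter, n_fev, converged


def fit_average(
    target_rates: dict[float, RateTrace],
    init: dict | None = None,
    kin: KineticParams | None = None,
    mem: MembraneParams | None = None,
    thr: ThresholdParams | None = None,
    protocol: AveragePulseProtocol | None = None,
    maxiter: int = 400,
    continuation_sds: tuple[float, ...] = (0.12, 0.06, 0.03, 0.0),
    n_multistart: int = 8,
    multistart_seed: int = 0,
) -> FitResult:
    """Stage-one fit of (n, γ, τ, Δ) to dose-resolved average responses.

    Nelder–Mead with multiscale continuation: the objective is first
    minimized under heavy extra smoothing (``continuation_sds[0]``, in s)
    from ``n_multistart`` Sobol-scrambled starts within ±2× of ``init``
    (plus ``init`` itself), and the best coarse optimum is refined through
    the remaining smoothing stages down to the plain objective.  ``init``
    maps the four free-parameter names to positive starting values and
    defaults to the current parameter defaults.  Deterministic under
    ``multistart_seed``.
    """
    kin = kin or KineticParams()
    mem = mem or MembraneParams()
    thr = thr or ThresholdParams()
    proto = protocol or AveragePulseProtocol(L_airs=tuple(sorted(target_rates)))
    init = dict(init or {"n": kin.n, "gamma": mem.gamma, "tau": thr.tau,
                         "delta": thr.delta})
    for k in _AVERAGE_FREE:
        if not init.get(k, 0) > 0:
            raise ValueError(f"initial {k} must be positive")

    def objective_at(extra_sd: float):
        def f(x: np.ndarray) -> float:
            free = dict(zip(_AVERAGE_FREE, np.exp(x)))
            return ise_average(free, target_rates, kin, mem, thr, proto,
                               extra_sd=extra_sd)
        return f

    x0 = np.log([init[k] for k in _AVERAGE_FREE])
    n_iter = n_fev = 0

    # coarse stage: short Nelder-Mead runs from a Sobol cloud around init
    starts = [x0]
    if n_multistart > 0:
        sob = qmc.Sobol(len(_AVERAGE_FREE), scramble=True, seed=multistart_seed)
        offsets = (sob.random(n_multistart) * 2.0 - 1.0) * np.log(2.0)
        starts += [x0 + off for off in offsets]
    f_coarse = objective_at(continuation_sds[0])
    best_x, best_f = None, np.inf
    for s in starts:
        res = minimize(
            f_coarse, s, method="Nelder-Mead",
            options={"maxiter": max(maxiter // 3, 50), "xatol": 1e-3,
                     "fatol": 1e-6, "adaptive": True},
        )
        n_iter += res.nit
        n_fev += res.nfev
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun

    # continuation: anneal the extra smoothing away
    x = best_x
    converged = False
    for extra_sd in continuation_sds:
        res = minimize(
            objective_at(extra_sd), x, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-8,
                     "adaptive": True},
        )
        n_iter += res.nit
        n_fev += res.nfev
        x = res.x
        converged = bool(res.success)

    params = dict(zip(_AVERAGE_FREE, np.exp(x)))
    obj = ise_average(params, target_rates, kin, mem, thr, proto)
    fixed = {"kin": kin, "mem": mem, "thr": thr}
    return FitResult("average", params, fixed, obj, n_iter, n_fev, converged)


def fit_cell(
    stimulus: StimulusTrace,
    spikes: SpikeTrain,
    scheme: str,
    training_window: tuple[float, float] = (1.0, 11.0),
    kin: KineticParams | None = None,
    mem: MembraneParams | None = None,
    thr: ThresholdParams | None = None,
    burn_in: float = 1.0,
    rate_dt: float = DEFAULT_RATE_DT,
    kernel_sd: float = DEFAULT_KERNEL_SD,
    maxiter: int = 500,
    restarts: int = 1,
    continuation_sds: tuple[float, ...] = (0.12, 0.06, 0.0),
) -> FitResult:
    """Stage-two fit of a heterogeneity scheme to one cell's recording.

    ``scheme`` selects the free subset: ``homogeneous`` (none — the
    objective is just evaluated at the fixed values), ``gamma``,
    ``delta_tau`` or ``gamma_delta_tau``.  Starting values are the fixed
    (stage-one) parameter values.  Like the stage-one fit, Nelder–Mead runs
    through a short smoothing continuation (``continuation_sds``) so it
    cannot stall on the plateau around the starting point; the reported
    objective is always the plain (unsmoothed) ε²_ind.  The cascade output
    R*(t) is independent of every free parameter here, so it is computed
    once and reused across objective evaluations.
    """
    if scheme not in SCHEME_FREE_PARAMS:
        raise ValueError(
            f"unknown scheme {scheme!r}; expected one of {sorted(SCHEME_FREE_PARAMS)}"
        )
    kin = kin or KineticParams()
    mem = mem or MembraneParams()
    thr = thr or ThresholdParams()
    t0, t1 = training_window
    grid = rate_grid(t0, t1, rate_dt)
    data_rate = kernel_rate(spikes, grid, sd=kernel_sd)
    cached = _sliced_rstar(stimulus, kin, t0 - burn_in, t1 + _kernel_pad(kernel_sd))

    names = SCHEME_FREE_PARAMS[scheme]
    defaults = {"gamma": mem.gamma, "tau": thr.tau, "delta": thr.delta}
    fixed = {"kin": kin, "mem": mem, "thr": thr}

    def objective_at(extra_sd: float):
        def f(free: dict) -> float:
            return ise_individual(
                free, stimulus, data_rate, training_window, kin, mem, thr,
                burn_in=burn_in, kernel_sd=kernel_sd, cached_rstar=cached,
                extra_sd=extra_sd,
            )
        return f

    objective = objective_at(0.0)
    if not names:  # homogeneous: nothing to optimize
        obj = objective({})
        return FitResult(scheme, {}, fixed, obj, 0, 1, True)

    def continued_fit(run_names, start):
        total_iter = total_fev = 0
        cur = dict(start)
        ok = False
        for k, extra_sd in enumerate(continuation_sds):
            last = k == len(continuation_sds) - 1
            cur, _, it, fev, ok = _nelder_mead_log(
                objective_at(extra_sd), run_names, cur,
                maxiter=maxiter, restarts=restarts if last else 0,
            )
            total_iter += it
            total_fev += fev
        return cur, total_iter, total_fev, ok

    init = {k: defaults[k] for k in names}
    n_iter = n_fev = 0
    if scheme == "gamma_delta_tau":
        # warm start from the nested two-parameter optimum, which also
        # guarantees the scheme can only improve on (delta, tau) alone
        pre, it0, fev0, _ = continued_fit(("delta", "tau"), init)
        init.update(pre)
        n_iter, n_fev = it0, fev0
    params, it1, fev1, ok = continued_fit(names, init)
    obj = objective(params)
    return FitResult(scheme, params, fixed, obj, n_iter + it1, n_fev + fev1, ok)


def evaluate_prediction(
    stimulus: StimulusTrace,
    spikes: SpikeTrain,
    fit: FitResult,
    prediction_window: tuple[float, float] = (11.0, 21.0),
    burn_in: float = 1.0,
    rate_dt: float = DEFAULT_RATE_DT,
    kernel_sd: float = DEFAULT_KERNEL_SD,
) -> float:
    """Coefficient of determination of a fitted cell on held-out data.

    Simulates the model with the fitted parameters over the prediction
    window (starting 1 s early from rest), smooths both spike trains on the
    window's rate grid, and applies R² = 1 − ISE / variance-integral.
    """
    kin, mem, thr = _apply_free(
        fit.params, fit.fixed["kin"], fit.fixed["mem"], fit.fixed["thr"]
    )
    t0, t1 = prediction_window
    grid = rate_grid(t0, t1, rate_dt)
    data_rate = kernel_rate(spikes, grid, sd=kernel_sd)
    model_rate = _model_rate_for_window(
        stimulus, kin, mem, thr, prediction_window, burn_in, rate_dt, kernel_sd
    )
    return r_squared(data_rate, model_rate)


def population_summary(
    fits: list[FitResult], r2: list[float] | np.ndarray
) -> PopulationSummary:
    """Summarize per-cell fits: moments, (Δ, τ) correlation, R² spread.

    The Pearson correlation of (Δ, τ) is NaN (undefined) when either
    parameter has zero variance across cells, e.g. for identical cells.
    """
    if len(fits) < 2:
        raise ValueError("population summary needs at least 2 cells")
    if len(r2) != len(fits):
        raise ValueError("r2 list length must match fits")
    names = sorted({k for f in fits for k in f.params})
    mean: dict = {}
    sd: dict = {}
    for k in names:
        vals = np.array([f.params[k] for f in fits])
        mean[k] = float(vals.mean())
        sd[k] = float(vals.std(ddof=1))
    corr = float("nan")
    if "delta" in names and "tau" in names:
        d = np.array([f.params["delta"] for f in fits])
        t = np.array([f.params["tau"] for f in fits])
        if d.std() > 0 and t.std() > 0:
            corr = float(np.corrcoef(d, t)[0, 1])
    r2 = np.asarray(r2, dtype=float)
    lo, hi = np.percentile(r2, [25, 75])
    return PopulationSummary(
        n_cells=len(fits),
        mean=mean,
        sd=sd,
        corr_delta_tau=corr,
        r2=r2,
        r2_median=float(np.median(r2)),
        r2_iqr=(float(lo), float(hi)),
    )
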