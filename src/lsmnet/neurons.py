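"""Neuron models: linear summation (LSM), Izhikevich (IZ) and a simplified
conductance-based model.

The LSM is a non-spiking neuron whose instantaneous drive is a normalized
signed sum of weighted synaptic inputs,

    A_nodyn = sum(w_i * a_i) / (k_static * i + sum(|w_i * a_i|)),

thresholded at zero.  The "static leak" term ``k_static * i`` (leak constant
times synapse count) normalizes activity; the activity-dependent absolute sum
in the denominator models shunting by open synaptic channels and bounds the
output strictly below 1.  The optional "dynamic leak" low-pass filters the
drive with a first-order relaxation

    tau_dyn * dA_dyn/dt = -A_dyn + A_nodyn,

modeling the RC circuit of the membrane (default tau_dyn = 10 ms).

The Izhikevich model serves as the spiking reference, and the simplified
conductance-based model (implicit-Euler integrated, analytically solvable)
shows that the LSM drive equals the conductance model's steady-state membrane
potential when the leak conductance is identified with ``k_static * i`` and
synaptic conductances with ``|w_i * a_i|``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "LSMParams",
    "LSMState",
    "lsm_drive",
    "lsm_step",
    "lsm_filter",
    "IZParams",
    "IZState",
    "iz_step",
    "iz_run",
    "iz_parameter_grid",
    "HHParams",
    "hh_step_implicit",
    "hh_analytic",
]


# ---------------------------------------------------------------------------
# Linear summation model

@dataclass(frozen=True)
class LSMParams:
    """Parameters of the linear summation neuron.

    ``tau_dyn`` is the dynamic-leak time constant in ms (1/100 s = 10 ms
    default); ``n_synapses`` is the afferent synapse count ``i`` entering the
    static-leak term.
    """

    k_static: float = 1.0
    tau_dyn: float = 10.0
    n_synapses: int = 1
    use_dynamic_leak: bool = True

    def __post_init__(self) -> None:
        if self.k_static <= 0:
            raise ValueError("k_static must be positive")
        if self.tau_dyn <= 0:
            raise ValueError("tau_dyn must be positive")
        if self.n_synapses < 1:
            raise ValueError("n_synapses must be >= 1")


@dataclass
class LSMState:
    a_nodyn: float = 0.0
    a_dyn: float = 0.0


def lsm_drive(weighted_inputs: np.ndarray, params: LSMParams) -> float:
    """Instantaneous normalized drive from signed weighted inputs ``w_i * a_i``.

    The numerator is the signed sum, the denominator the static leak plus the
    sum of absolute values; the result is thresholded at zero and is strictly
    less than 1 for any finite input.
    """
    wa = np.asarray(weighted_inputs, dtype=float)
    if wa.size != params.n_synapses:
        raise ValueError(f"expected {params.n_synapses} inputs, got {wa.size}")
    if not np.all(np.isfinite(wa)):
        raise ValueError("inputs must be finite")
    num = wa.sum()
    den = params.k_static * params.n_synapses + np.abs(wa).sum()
    return max(0.0, num / den)


def lsm_step(state: LSMState, drive: float, dt: float, params: LSMParams) -> LSMState:
    """Advance the dynamic-leak activity one time step.

    Uses the exact exponential update for the first-order relaxation,
    ``A_dyn <- drive + (A_dyn - drive) * exp(-dt/tau)`` — unconditionally
    stable and exact for piecewise-constant drive.  Without dynamic leak the
    activity equals the drive.  Both quantities are thresholded at zero.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a_nodyn = max(0.0, drive)
    if not params.use_dynamic_leak:
        return LSMState(a_nodyn=a_nodyn, a_dyn=a_nodyn)
    alpha = np.exp(-dt / params.tau_dyn)
    a_dyn = a_nodyn + (state.a_dyn - a_nodyn) * alpha
    return LSMState(a_nodyn=a_nodyn, a_dyn=max(0.0, a_dyn))


def lsm_filter(
    drive: np.ndarray, dt: float, params: LSMParams, method: str = "exact"
) -> np.ndarray:
    """Apply the dynamic leak to a whole drive trace (vectorized ``lsm_step``).

    ``method='exact'`` uses the exponential update; ``'euler'`` the forward
    Euler discretization for strict-fidelity comparisons.  Initial activity 0.
    """
    d = np.clip(np.asarray(drive, dtype=float), 0.0, None)
    if not params.use_dynamic_leak:
        return d
    if method == "exact":
        alpha = np.exp(-dt / params.tau_dyn)
    elif method == "euler":
        alpha = 1.0 - dt / params.tau_dyn
        if alpha < 0:
            raise ValueError("forward Euler unstable: dt > tau_dyn")
    else:
        raise ValueError(f"unknown method {method!r}")
    # y[n] = alpha*y[n-1] + (1-alpha)*d[n]
    y = lfilter([1.0 - alpha], [1.0, -alpha], d)
    return np.clip(y, 0.0, None)


# ---------------------------------------------------------------------------
# Izhikevich model

@dataclass(frozen=True)
class IZParams:
    """Izhikevich neuron parameters (regular-spiking defaults).

    ``A, B, C`` are the fixed quadratic coefficients of the membrane equation;
    ``a, b, c, d`` govern the recovery variable and post-spike reset; ``k``
    is the input gain and ``v_threshold`` the spike cutoff in mV.
    """

    A: float = 0.04
    B: float = 5.0
    C: float = 140.0
    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    k: float = 300.0
    v_threshold: float = 30.0


@dataclass
class IZState:
    v: float = -70.0
    u: float = -14.0
    spikes: list = field(default_factory=list)


def iz_step(
    state: IZState, input_activity: float, dt: float, params: IZParams, t: float = 0.0
) -> IZState:
    """One forward-Euler step of the membrane and recovery equations.

    If the membrane potential reaches ``v_threshold`` a spike time is recorded
    and the reset (v <- c, u <- u + d) applied within the same step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v, u = state.v, state.u
    dv = params.A * v * v + params.B * v + params.C - u + input_activity * params.k
    du = params.a * (params.b * v - u)
    v = v + dt * dv
    u = u + dt * du
    if abs(v) > 1e6:
        raise FloatingPointError("Izhikevich integration diverged; reduce dt or input gain")
    spikes = state.spikes
    if v >= params.v_threshold:
        spikes = spikes + [t]
        v = params.c
        u = u + params.d
    return IZState(v=v, u=u, spikes=spikes)


def iz_run(
    input_trace: np.ndarray,
    dt: float,
    params: IZParams,
    v0: float = -70.0,
    u0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the neuron over a full input trace.

    Returns (spike times in ms, membrane-potential trace).  The default
    initial condition is the resting fixed point of the regular-spiking
    parameter set (v = -70, u = b*v).
    """
    x = np.asarray(input_trace, dtype=float)
    v = v0
    u = params.b * v0 if u0 is None else u0
    vtrace = np.empty(x.size)
    spikes: list[float] = []
    A, B, C, a, b, k, thr = (
        params.A, params.B, params.C, params.a, params.b, params.k, params.v_threshold,
    )
    for n in range(x.size):
        v = v + dt * (A * v * v + B * v + C - u + x[n] * k)
        u = u + dt * a * (b * v - u)
        if abs(v) > 1e6:
            raise FloatingPointError("Izhikevich integration diverged; reduce dt or input gain")
        if v >= thr:
            spikes.append(n * dt)
            v = params.c
            u = u + params.d
        vtrace[n] = v
    return np.asarray(spikes), vtrace


def iz_parameter_grid() -> list[IZParams]:
    """Cartesian product of the explored (a, b, c, d, k) values: 405 settings.

    A, B, C stay at their standard values.
    """
    grid = itertools.product(
        (0.02, 0.07, 0.1),
        (0.2, 0.225, 0.25),
        (-65.0, -55.0, -50.0),
        (2.0, 4.0, 8.0),
        (100.0, 200.0, 300.0, 400.0, 500.0),
    )
    return [IZParams(a=a, b=b, c=c, d=d, k=k) for a, b, c, d, k in grid]


# ---------------------------------------------------------------------------
# Simplified conductance-based model

@dataclass(frozen=True)
class HHParams:
    """Simplified conductance-based neuron with normalized reversal potentials.

    Membrane equation (unit capacitance):
    dV/dt = -g_leak*V + g_exc*(e_exc - V) + g_inh*(e_inh - V),
    with excitatory/inhibitory reversal potentials fixed at +1 / -1.
    """

    g_leak: float = 1.0
    e_exc: float = 1.0
    e_inh: float = -1.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.g_leak <= 0:
            raise ValueError("g_leak must be positive")
        if self.e_exc != 1.0 or self.e_inh != -1.0:
            raise ValueError("reversal potentials are normalized to +1 and -1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def hh_step_implicit(v: float, g_exc: float, g_inh: float, params: HHParams) -> float:
    """One implicit-Euler step; unconditionally stable for any dt > 0.

    V' = (V + dt*(g_exc*e_exc + g_inh*e_inh)) / (1 + dt*(g_leak + g_exc + g_inh)).
    """
    if g_exc < 0 or g_inh < 0:
        raise ValueError("conductances must be non-negative")
    dt = params.dt
    num = v + dt * (g_exc * params.e_exc + g_inh * params.e_inh)
    den = 1.0 + dt * (params.g_leak + g_exc + g_inh)
    return num / den


def hh_analytic(v0: float, g_exc: float, g_inh: float, t: float, params: HHParams) -> float:
    """Closed-form relaxation under constant conductances.

    V(t) = V_ss + (v0 - V_ss) * exp(-g_tot * t), with
    g_tot = g_leak + g_exc + g_inh and
    V_ss = (g_exc*e_exc + g_inh*e_inh) / g_tot — the same value as the LSM
    drive with g_leak = k_static * i.
    """
    if g_exc < 0 or g_inh < 0:
        raise ValueError("conductances must be non-negative")
    g_tot = params.g_leak + g_exc + g_inh
    v_ss = (g_exc * params.e_exc + g_inh * params.e_inh) / g_tot
    return v_ss + (v0 - v_ss) * np.exp(-g_tot * t)
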