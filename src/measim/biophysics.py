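"""Single-neuron membrane dynamics.

Hodgkin-Huxley sodium and delayed-rectifier potassium currents with rate
constants adapted to cortical pyramidal neurons, a leak current, a
spike-triggered slow afterhyperpolarization (sAHP) conductance, additive
membrane noise (Ornstein-Uhlenbeck scaling) and heterogeneous constant bias
currents.

All rate constants are in kHz (1/ms) for voltages in mV.  The parameter ``VT``
shifts every voltage dependence and thereby sets the spike threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import IDENTITY_MODIFIER, NeuronParams, RateModifier

# Currents in this module are absolute (pA); `_pA_to_uA_per_cm2` moves them
# into the per-area membrane equation.
_SINGULARITY_TOL = 1e-9  # mV; below this the analytic limit is used


@dataclass
class GateState:
    """HH activation/inactivation variables, each constrained to [0, 1]."""

    m: np.ndarray | float
    h: np.ndarray | float
    n: np.ndarray | float


@dataclass
class NeuronState:
    """Dynamical state of one neuron (or an array of neurons)."""

    Vm: np.ndarray | float         # membrane potential, mV
    gates: GateState
    gAHP: np.ndarray | float = 0.0  # sAHP conductance, nS
    I_bias: np.ndarray | float = 0.0  # constant applied current, pA


def _x_over_expm1(x: np.ndarray) -> np.ndarray:
    """x / (exp(x) - 1) with the removable singularity at x = 0 filled in."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SINGULARITY_TOL
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0, safe / np.expm1(safe))
    return out


def rate_constants(
    Vm: np.ndarray | float,
    VT: float,
    mod: RateModifier = IDENTITY_MODIFIER,
) -> tuple[np.ndarray, ...]:
    """Evaluate the six HH rate constants (αm, βm, αh, βh, αn, βn) in kHz.

    The sodium-gate modifications in ``mod`` (rate scales, activation /
    inactivation voltage shifts) apply to αm, βm, αh, βh only; the potassium
    gate is untouched.  Removable singularities of αm, βm and αn are evaluated
    as their analytic limits.
    """
    Vm = np.asarray(Vm, dtype=float)
    if not np.all(np.isfinite(Vm)) or not np.isfinite(VT):
        raise ValueError("Vm and VT must be finite")

    v_act = Vm + mod.shift_activation
    v_inact = Vm + mod.shift_inactivation

    # alpha_m = -0.32 (V - VT - 13) / (exp(-(V - VT - 13)/4) - 1)
    x = v_act - VT - 13.0
    alpha_m = mod.scale_alpha_m * 0.32 * 4.0 * _x_over_expm1(-x / 4.0)
    # beta_m = 0.28 (V - VT - 40) / (exp((V - VT - 40)/5) - 1)
    y = v_act - VT - 40.0
    beta_m = mod.scale_beta_m * 0.28 * 5.0 * _x_over_expm1(y / 5.0)
    # alpha_h = 0.128 exp(-(V - VT - 17)/18)
    alpha_h = mod.scale_alpha_h * 0.128 * np.exp(-(v_inact - VT - 17.0) / 18.0)
    # beta_h = 4 / (1 + exp(-(V - VT - 40)/5))
    beta_h = mod.scale_beta_h * 4.0 / (1.0 + np.exp(-(v_inact - VT - 40.0) / 5.0))
    # alpha_n = -0.032 (V - VT - 15) / (exp(-(V - VT - 15)/5) - 1)
    z = Vm - VT - 15.0
    alpha_n = 0.032 * 5.0 * _x_over_expm1(-z / 5.0)
    # beta_n = 0.5 exp(-(V - VT - 10)/40)
    beta_n = 0.5 * np.exp(-(Vm - VT - 10.0) / 40.0)

    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def steady_state_gates(
    Vm: np.ndarray | float,
    VT: float,
    mod: RateModifier = IDENTITY_MODIFIER,
) -> GateState:
    """Gate values with d(gate)/dt = 0 at fixed voltage: x∞ = α/(α+β)."""
    am, bm, ah, bh, an, bn = rate_constants(Vm, VT, mod)
    return GateState(m=am / (am + bm), h=ah / (ah + bh), n=an / (an + bn))


def _pA_to_uA_per_cm2(I_pA, area_cm2: float):
    return np.asarray(I_pA, dtype=float) * 1e-6 / area_cm2


def membrane_derivative(
    state: NeuronState,
    params: NeuronParams,
    I_syn: np.ndarray | float = 0.0,
) -> np.ndarray | float:
    """Deterministic drift dVm/dt in mV·ms⁻¹ (noise is added by the engine).

    ``I_syn`` is the absolute synaptic current in pA with the depolarizing
    direction positive (like the bias current).  The sAHP current
    ``gAHP·(Vm−EK)`` hyperpolarizes whenever Vm > EK; gAHP (nS), bias and
    synaptic currents (pA) are converted to per-area units via ``params.area``.
    """
    V = np.asarray(state.Vm, dtype=float)
    g = state.gates
    m, h, n = (np.asarray(v, dtype=float) for v in (g.m, g.h, g.n))
    if np.any((m < 0) | (m > 1) | (h < 0) | (h > 1) | (n < 0) | (n > 1)):
        raise ValueError("gating variables must lie in [0, 1]")

    I_ion = (
        -params.gK_max * n**4 * (V - params.EK)
        - params.gNa_max * m**3 * h * (V - params.ENa)
        - params.gl * (V - params.El)
    )  # µA/cm²
    I_sahp_pA = -np.asarray(state.gAHP, dtype=float) * (V - params.EK)  # nS·mV = pA
    I_abs = (
        np.asarray(state.I_bias, dtype=float)
        + params.I_app
        + I_sahp_pA
        + np.asarray(I_syn, dtype=float)
    )
    dV = (I_ion + _pA_to_uA_per_cm2(I_abs, params.area)) / params.Cm
    return dV if dV.shape else float(dV)


def sahp_step(
    gAHP: np.ndarray | float,
    spiked: np.ndarray | bool,
    dt: float,
    params: NeuronParams,
) -> np.ndarray | float:
    """One timestep of the sAHP conductance (nS).

    Exponential decay with time constant ``tauAHP`` (seconds), then an
    increment of ``alphaCa`` for every neuron that spiked during the step.
    """
    g = np.asarray(gAHP, dtype=float)
    if np.any(g < 0):
        raise ValueError("gAHP must be non-negative")
    tau_ms = params.tauAHP * 1000.0
    out = g * np.exp(-dt / tau_ms) + params.alphaCa * np.asarray(spiked, dtype=float)
    return out if out.shape else float(out)


def noise_coefficient(params: NeuronParams, dt: float) -> float:
    """Per-step noise amplitude σ·√(2·(gl/Cm)·dt) of the Euler-Maruyama scheme.

    On a passive leak-only membrane this makes the stationary standard
    deviation of Vm equal ``params.sigma`` regardless of dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return params.sigma * np.sqrt(2.0 * (params.gl / params.Cm) * dt)


def noise_increment(
    params: NeuronParams,
    dt: float,
    rng: np.random.Generator,
    size: int | tuple | None = None,
) -> np.ndarray | float:
    """Stochastic voltage increment ΔV (mV) for one timestep."""
    return noise_coefficient(params, dt) * rng.standard_normal(size)


def draw_bias_currents(
    N: int,
    rng: np.random.Generator,
    params: NeuronParams | None = None,
) -> np.ndarray:
    """Heterogeneous constant currents, i.i.d. uniform on ±bias_range pA."""
    if N < 1:
        raise ValueError("N must be >= 1")
    r = (params or NeuronParams()).bias_range
    return rng.uniform(-r, r, size=N)


def resting_state(
    params: NeuronParams,
    I_bias: float = 0.0,
    mod: RateModifier = IDENTITY_MODIFIER,
) -> NeuronState:
    """Self-consistent resting fixed point with gates at steady state.

    Root-finds the full current balance on [EK, VT + 15 mV] and returns the
    most hyperpolarized zero (the stable rest for the control model).  Used
    for initial conditions; the discarded transient absorbs any residual.
    """
    gNa_eff = params.gNa_max * mod.scale_gNa

    def drift(V: float) -> float:
        g = steady_state_gates(V, params.VT, mod)
        st = NeuronState(Vm=V, gates=g, gAHP=0.0, I_bias=I_bias)
        p = params if mod.scale_gNa == 1.0 else None
        if p is None:
            from dataclasses import replace

            p = replace(params, gNa_max=gNa_eff)
        return membrane_derivative(st, p)

    lo, hi = params.EK + 0.5, params.VT + 15.0
    grid = np.linspace(lo, hi, 400)
    vals = np.array([drift(v) for v in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise RuntimeError("no resting fixed point found in the search window")
    i = sign_change[0]
    V_rest = brentq(drift, grid[i], grid[i + 1], xtol=1e-10)
    return NeuronState(
        Vm=float(V_rest),
        gates=steady_state_gates(V_rest, params.VT, mod),
        gAHP=0.0,
        I_bias=I_bias,
    )
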