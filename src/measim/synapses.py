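"""Conductance-based AMPA and NMDA synapses with magnesium block and STD.

The open fraction of AMPA channels from presynaptic neuron *j* decays with
``tauAMPA`` and jumps by 1 on every (delayed) spike arrival; the AMPA rise
time is neglected.  NMDA channels use a two-variable scheme: an auxiliary
gating variable ``x`` (jump +1 per arrival, decay ``tauNMDA_rise``) drives a
saturating open fraction ``s`` via ds/dt = −s/τ_decay + αNMDA·x·(1−s).  The
NMDA conductance is additionally gated by the voltage-dependent magnesium
unblock fraction of the postsynaptic membrane.

Short-term depression (STD) follows the synaptic-resource picture: a fraction
``x_std`` of resources is available, recovers as (1−x)/τD and is reduced by
``U·x`` at every presynaptic spike; the weight transmitted by a spike is
``w·x_std`` evaluated immediately before the decrement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SynapseParams


@dataclass
class SynapticState:
    """Per-presynaptic-neuron synaptic gating state."""

    s_ampa: np.ndarray   # AMPA open fraction (≥ 0)
    s_nmda: np.ndarray   # NMDA open fraction, in [0, 1)
    x_nmda: np.ndarray   # NMDA auxiliary gating variable (≥ 0)
    x_std: np.ndarray    # STD available-resource fraction, in (0, 1]

    @classmethod
    def zeros(cls, n_sources: int) -> "SynapticState":
        return cls(
            s_ampa=np.zeros(n_sources),
            s_nmda=np.zeros(n_sources),
            x_nmda=np.zeros(n_sources),
            x_std=np.ones(n_sources),
        )


def mg_unblock(Vm: np.ndarray | float, params: SynapseParams) -> np.ndarray | float:
    """Fraction of NMDA channels free of magnesium block at voltage Vm.

    u(Vm) = 1 / (1 + exp(−a·Vm)·[Mg²⁺]/b); strictly increasing in Vm, equal
    to 1 at any voltage when [Mg²⁺] = 0.
    """
    V = np.asarray(Vm, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("Vm must be finite")
    u = 1.0 / (1.0 + np.exp(-params.a_mg * V) * params.mg_conc / params.b_mg)
    return u if u.shape else float(u)


def gating_step(
    state: SynapticState,
    arrivals: np.ndarray,
    dt: float,
    params: SynapseParams,
) -> SynapticState:
    """Advance channel gating by one timestep.

    ``arrivals`` counts delayed presynaptic spike arrivals per source during
    the step (simultaneous arrivals sum).  Linear decays use the exact
    exponential update; the saturating NMDA open fraction is integrated with
    forward Euler.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.asarray(arrivals, dtype=float)
    s_ampa = state.s_ampa * np.exp(-dt / params.tauAMPA) + a
    x_nmda = state.x_nmda * np.exp(-dt / params.tauNMDA_rise) + a
    ds = (
        -state.s_nmda / params.tauNMDA_decay
        + params.alphaNMDA * state.x_nmda * (1.0 - state.s_nmda)
    )
    s_nmda = state.s_nmda + dt * ds
    return SynapticState(s_ampa=s_ampa, s_nmda=s_nmda, x_nmda=x_nmda, x_std=state.x_std)


def std_step(
    x_std: np.ndarray | float,
    spiked: np.ndarray | bool,
    dt: float,
    params: SynapseParams,
) -> np.ndarray | float:
    """One timestep of the STD resource variable.

    Recovery toward 1 with time constant ``tauD`` (exact exponential update),
    then a fractional decrement ``U·x`` for sources that spiked.
    """
    x = np.asarray(x_std, dtype=float)
    if np.any(x <= 0) or np.any(x > 1):
        raise ValueError("x_std must lie in (0, 1]")
    x = 1.0 - (1.0 - x) * np.exp(-dt / params.tauD)
    x = np.where(np.asarray(spiked, dtype=bool), x * (1.0 - params.U), x)
    return x if x.shape else float(x)


def transmitted_weight(
    w: np.ndarray | float,
    x_std: np.ndarray | float,
    params: SynapseParams,
) -> np.ndarray | float:
    """Effective weight carried by a spike: S·w·x_std before the decrement."""
    return params.S * np.asarray(w, dtype=float) * np.asarray(x_std, dtype=float)


def draw_weights(
    edges: np.ndarray,
    rng: np.random.Generator,
    params: SynapseParams | None = None,
) -> np.ndarray:
    """Per-edge synaptic weights: i.i.d. normal(1, 0.7) clipped to [0, 2].

    ``edges`` is an (E, 2) array of (source, target) pairs; the return value
    aligns with its rows.  The clipping silences the left normal tail
    (Φ(−1/0.7) ≈ 7.7% of draws become exact zeros — "perished" synapses).
    """
    edges = np.asarray(edges)
    if edges.size == 0:
        raise ValueError("edge set must be non-empty")
    p = params or SynapseParams()
    raw = rng.normal(p.weight_mean, p.weight_std, size=len(edges))
    return np.clip(raw, *p.weight_clip)


def synaptic_current(
    Vm_post: float,
    state: SynapticState,
    weights: np.ndarray,
    params: SynapseParams,
) -> float:
    """Total synaptic current (pA) onto one postsynaptic neuron.

    I = gAMPA·(E−Vm)·Σ w_j·s_j^AMPA + gNMDA·u(Vm)·(E−Vm)·Σ w_j·s_j^NMDA,
    with the depolarizing direction positive (both reversals are 0 mV, so the
    current is positive for Vm < 0).  ``weights`` are the per-source effective
    weights (synaptic scaling and STD applied at transmission time).
    """
    w = np.asarray(weights, dtype=float)
    i_ampa = params.gAMPA_max * (params.EAMPA - Vm_post) * float(np.dot(w, state.s_ampa))
    u = mg_unblock(Vm_post, params)
    i_nmda = (
        params.gNMDA_max * u * (params.ENMDA - Vm_post) * float(np.dot(w, state.s_nmda))
    )
    return i_ampa + i_nmda
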