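"""Simulation engine: configuration, condition protocol, integration, I/O.

A :class:`SimulationConfig` bundles neuron, synapse and layout parameters with
the run protocol (650 s per network, 0.1 ms timestep, first 50 s discarded as
transient, 10 kHz virtual-electrode sampling, 12 networks per condition by
default).  Conditions mimic the pharmacology and disease protocols: halved
sAHP conductance (linopirdine), sodium-channel block (TTX), NMDA-receptor
block (MK-801), AMPA-receptor block (NBQX/NASPM), the Dravet-syndrome (DS)
parameter set, and arbitrary sodium-channel modifications for the
channelopathy scan.

Paired comparisons re-simulate the *same* network (connectivity, weights,
bias currents and noise stream all derived from the same seeds) under a
different condition, so condition effects are not confounded by network
realization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from . import biophysics
from ._kernel import FLAG_BLOWUP, _integrate_chunk
from .network import NetworkLayout, build_layout
from .params import (
    DS_DEFAULTS,
    IDENTITY_MODIFIER,
    LayoutParams,
    NeuronParams,
    RateModifier,
    SynapseParams,
)
from .synapses import draw_weights

CONDITION_NAMES = (
    "control",
    "sAHP_half",
    "Na_block",
    "NMDA_block",
    "AMPA_block",
    "DS",
    "sodium_mod",
)

# Pure sodium-channel modifications spanning the channelopathy scan:
# faster/slower activation and inactivation kinetics and changed maximal
# conductance, each a plausible consequence of an SCN1A mutation.
DEFAULT_SODIUM_GRID: dict[str, RateModifier] = {
    "act_rate_x0.7": RateModifier(scale_alpha_m=0.7, scale_beta_m=0.7),
    "act_rate_x1.3": RateModifier(scale_alpha_m=1.3, scale_beta_m=1.3),
    "inact_rate_x0.7": RateModifier(scale_alpha_h=0.7, scale_beta_h=0.7),
    "inact_rate_x1.3": RateModifier(scale_alpha_h=1.3, scale_beta_h=1.3),
    "gNa_x0.7": RateModifier(scale_gNa=0.7),
    "gNa_x1.3": RateModifier(scale_gNa=1.3),
}

# Allocation of condition networks in the full validation battery: 30 baseline
# networks, of which 8 are re-run with halved sAHP, 8 with sodium channels
# blocked, 10 with NMDA receptors blocked and 4 with AMPA receptors blocked.
FULL_BATTERY_ALLOCATION = {
    "control": 30,
    "sAHP_half": 8,
    "Na_block": 8,
    "NMDA_block": 10,
    "AMPA_block": 4,
}


@dataclass(frozen=True)
class ConditionSpec:
    """A named experimental condition as multiplicative parameter overrides."""

    name: str = "control"
    alphaCa_factor: float = 1.0
    gNa_factor: float = 1.0
    gNMDA_factor: float = 1.0
    gAMPA_factor: float = 1.0
    S_factor: float = 1.0
    U_factor: float = 1.0
    modifier: RateModifier = IDENTITY_MODIFIER

    @staticmethod
    def from_name(name: str, modifier: RateModifier | None = None,
                  ds_overrides: dict | None = None) -> "ConditionSpec":
        if name == "control":
            return ConditionSpec()
        if name == "sAHP_half":
            return ConditionSpec(name=name, alphaCa_factor=0.5)
        if name == "Na_block":
            return ConditionSpec(name=name, gNa_factor=0.0)
        if name == "NMDA_block":
            return ConditionSpec(name=name, gNMDA_factor=0.0)
        if name == "AMPA_block":
            return ConditionSpec(name=name, gAMPA_factor=0.0)
        if name == "DS":
            ov = dict(DS_DEFAULTS)
            ov.update(ds_overrides or {})
            f = ov["na_activation_factor"]
            return ConditionSpec(
                name=name,
                alphaCa_factor=ov["alphaCa_factor"],
                S_factor=ov["S_factor"],
                U_factor=ov["U_factor"],
                modifier=RateModifier(scale_alpha_m=f, scale_beta_m=f),
            )
        if name == "sodium_mod":
            return ConditionSpec(name=name, modifier=modifier or IDENTITY_MODIFIER)
        raise ValueError(
            f"unknown condition {name!r}; expected one of {CONDITION_NAMES}"
        )


def apply_condition(
    neuron: NeuronParams,
    synapse: SynapseParams,
    condition: ConditionSpec,
) -> tuple[NeuronParams, SynapseParams, RateModifier]:
    """Return the condition-modified parameter set and sodium-rate modifier."""
    if condition.name not in CONDITION_NAMES:
        raise ValueError(f"unknown condition {condition.name!r}")
    n = replace(
        neuron,
        alphaCa=neuron.alphaCa * condition.alphaCa_factor,
        gNa_max=neuron.gNa_max * condition.gNa_factor,
    )
    s = replace(
        synapse,
        gNMDA_max=synapse.gNMDA_max * condition.gNMDA_factor,
        gAMPA_max=synapse.gAMPA_max * condition.gAMPA_factor,
        S=synapse.S * condition.S_factor,
        U=synapse.U * condition.U_factor,
    )
    return n, s, condition.modifier


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one simulated MEA experiment."""

    duration: float = 650.0        # s
    transient_discard: float = 50.0  # s, dropped from all outputs
    dt: float = 0.1                # ms
    record_rate: float = 10.0      # kHz
    n_networks: int = 12
    seed: int = 0
    condition: ConditionSpec = field(default_factory=ConditionSpec)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    layout: LayoutParams = field(default_factory=LayoutParams)

    def __post_init__(self) -> None:
        if self.duration <= self.transient_discard:
            raise ValueError("duration must exceed transient_discard")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        stride = 1.0 / (self.record_rate * self.dt)
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError("dt must divide the recording interval")

    @property
    def record_stride(self) -> int:
        return round(1.0 / (self.record_rate * self.dt))

    @property
    def n_steps(self) -> int:
        return round(self.duration * 1000.0 / self.dt)

    @property
    def record_start_step(self) -> int:
        return round(self.transient_discard * 1000.0 / self.dt)

    @property
    def n_recorded_samples(self) -> int:
        return round((self.duration - self.transient_discard) * self.record_rate * 1e3)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["condition"]["modifier"] = asdict(self.condition.modifier)
        return d


@dataclass
class SimulationResult:
    """Virtual-electrode signals plus ground truth from one network run."""

    signals: np.ndarray        # (n_electrodes, n_samples) float32
    fs: float                  # sampling rate, Hz
    spike_neurons: np.ndarray  # ground-truth spike source indices
    spike_times: np.ndarray    # s, relative to the start of the retained window
    duration: float            # retained duration, s
    condition: str
    seed: int
    network_id: int
    config: dict

    @property
    def n_electrodes(self) -> int:
        return self.signals.shape[0]

    def spike_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"neuron_id": self.spike_neurons.astype(int), "time_s": self.spike_times}
        )


def network_seeds(master_seed: int, network_id: int) -> tuple[int, int]:
    """Deterministic (structure, noise) child seeds for one network.

    Spawned via :class:`numpy.random.SeedSequence` keyed on (master seed,
    network id), so every network is reproducible in isolation and a
    condition re-run of the same network id reuses both streams.
    """
    state = np.random.SeedSequence([int(master_seed), int(network_id)]).generate_state(2)
    return int(state[0]), int(state[1])


def _gate_tables(dt: float, VT: float, mod: RateModifier,
                 v_lo: float = -150.0, v_hi: float = 100.0, dv: float = 0.01):
    """Tabulate exponential-Euler gate factors x∞ and exp(−dt·(α+β)) on a grid."""
    v = np.arange(v_lo, v_hi + dv / 2, dv)
    am, bm, ah, bh, an, bn = biophysics.rate_constants(v, VT, mod)
    tabs = []
    for a, b in ((am, bm), (ah, bh), (an, bn)):
        tot = a + b
        tabs.append(a / tot)
        tabs.append(np.exp(-dt * tot))
    return v_lo, 1.0 / dv, len(v), tabs


def _edges_csr(layout: NetworkLayout, dt: float):
    """Sort edges by source and build CSR pointers plus delay steps."""
    E = len(layout.edges)
    if E == 0:
        return (
            np.zeros(layout.N + 1, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
        )
    order = np.argsort(layout.edges[:, 0], kind="stable")
    src = layout.edges[order, 0]
    tgt = layout.edges[order, 1].astype(np.int64)
    dsteps = np.round(layout.delays[order] / dt).astype(np.int64)
    ptr = np.searchsorted(src, np.arange(layout.N + 1)).astype(np.int64)
    return ptr, tgt, dsteps, order


def _electrodes_csr(weights: np.ndarray):
    ptr = [0]
    idx: list[int] = []
    val: list[float] = []
    for row in weights:
        nz = np.nonzero(row)[0]
        idx.extend(nz.tolist())
        val.extend(row[nz].tolist())
        ptr.append(len(idx))
    return (
        np.asarray(ptr, dtype=np.int64),
        np.asarray(idx, dtype=np.int64),
        np.asarray(val, dtype=float),
    )


def run_simulation(config: SimulationConfig, network_id: int = 0) -> SimulationResult:
    """Simulate one network under the configured condition.

    Gates are integrated with exponential Euler, the membrane potential with
    forward Euler plus the Euler-Maruyama noise term (noise held constant over
    each step, scaled by √dt).  The first ``transient_discard`` seconds are
    dropped from signals and ground-truth spike times.
    """
    struct_seed, noise_seed = network_seeds(config.seed, network_id)
    rng = np.random.default_rng(struct_seed)

    neuron, synapse, mod = apply_condition(
        config.neuron, config.synapse, config.condition
    )
    layout = build_layout(config.layout, rng, dt=config.dt)
    weights = (
        draw_weights(layout.edges, rng, synapse) if len(layout.edges) else np.zeros(0)
    )
    bias = biophysics.draw_bias_currents(layout.N, rng, neuron)

    # initial conditions: rest of the zero-drive control membrane (a neuron
    # driven above rheobase has no fixed point); the transient absorbs this
    rest = biophysics.resting_state(replace(config.neuron, I_app=0.0))
    V = np.full(layout.N, float(rest.Vm))
    g = biophysics.steady_state_gates(rest.Vm, neuron.VT, mod)
    m = np.full(layout.N, float(g.m))
    h = np.full(layout.N, float(g.h))
    n = np.full(layout.N, float(g.n))
    gAHP = np.zeros(layout.N)

    v_lo, inv_dv, n_tab, tabs = _gate_tables(config.dt, neuron.VT, mod)
    minf_t, mfac_t, hinf_t, hfac_t, ninf_t, nfac_t = tabs

    ptr, tgt, dsteps, order = _edges_csr(layout, config.dt)
    edge_Sw = (
        synapse.S * weights[order] if len(weights) else np.zeros(0)
    )
    eptr, enidx, ewv = _electrodes_csr(layout.electrode_weights)
    ring_len = int(dsteps.max()) + 1 if len(dsteps) else 2
    E = len(tgt)
    N = layout.N

    gNa_eff = neuron.gNa_max * mod.scale_gNa
    noise_coef = biophysics.noise_coefficient(neuron, config.dt)
    refrac_steps = int(round(neuron.refractory / config.dt))

    # persistent kernel state
    A = np.zeros(N)
    nm_sum = np.zeros(N)
    s_nm = np.zeros(E)
    x_nm = np.zeros(E)
    cw = np.zeros(E)
    x_std = np.ones(N)
    last_spk = np.full(N, -refrac_steps - 1, dtype=np.int64)
    bufA = np.zeros((ring_len, N))
    ev_cnt = np.zeros(ring_len, dtype=np.int64)
    ev_edge = np.zeros((ring_len, max(E, 1)), dtype=np.int64)
    ev_val = np.zeros((ring_len, max(E, 1)))
    flags = np.array([0, 0, -1], dtype=np.int64)
    rec = np.zeros((layout.n_electrodes, config.n_recorded_samples), dtype=np.float32)

    chunk = 20000
    cap = N * (chunk // (refrac_steps + 1) + 2)
    spk_n_buf = np.empty(cap, dtype=np.int32)
    spk_t_buf = np.empty(cap, dtype=np.int64)
    spike_chunks_n: list[np.ndarray] = []
    spike_chunks_t: list[np.ndarray] = []
    noise_rng = np.random.default_rng(noise_seed)

    t0 = 0
    n_steps = config.n_steps
    while t0 < n_steps:
        nc = min(chunk, n_steps - t0)
        if noise_coef > 0:
            noise = noise_coef * noise_rng.standard_normal((nc, N))
        else:
            noise = np.zeros((nc, N))
        ns = _integrate_chunk(
            t0,
            nc,
            config.dt,
            config.record_start_step,
            config.record_stride,
            neuron.Cm,
            neuron.gK_max,
            gNa_eff,
            neuron.gl,
            neuron.EK,
            neuron.ENa,
            neuron.El,
            1e-6 / neuron.area,
            neuron.I_app,
            neuron.alphaCa,
            float(np.exp(-config.dt / (neuron.tauAHP * 1000.0))),
            neuron.spike_threshold,
            refrac_steps,
            V,
            m,
            h,
            n,
            gAHP,
            bias,
            noise,
            v_lo,
            inv_dv,
            n_tab,
            minf_t,
            mfac_t,
            hinf_t,
            hfac_t,
            ninf_t,
            nfac_t,
            synapse.gAMPA_max,
            synapse.gNMDA_max,
            synapse.EAMPA,
            synapse.ENMDA,
            synapse.alphaNMDA,
            1.0 / synapse.tauNMDA_decay,
            float(np.exp(-config.dt / synapse.tauAMPA)),
            float(np.exp(-config.dt / synapse.tauNMDA_rise)),
            synapse.mg_conc / synapse.b_mg,
            synapse.a_mg,
            float(np.exp(-config.dt / synapse.tauD)),
            synapse.U,
            ptr,
            tgt,
            edge_Sw,
            dsteps,
            A,
            nm_sum,
            s_nm,
            x_nm,
            cw,
            x_std,
            last_spk,
            bufA,
            ev_cnt,
            ev_edge,
            ev_val,
            flags,
            eptr,
            enidx,
            ewv,
            rec,
            spk_n_buf,
            spk_t_buf,
        )
        spike_chunks_n.append(spk_n_buf[:ns].copy())
        spike_chunks_t.append(spk_t_buf[:ns].copy())
        if flags[FLAG_BLOWUP] >= 0:
            step = int(flags[FLAG_BLOWUP])
            raise RuntimeError(
                f"numerical blow-up (|Vm| > 200 mV) at step {step} "
                f"(t = {step * config.dt / 1000.0:.3f} s)"
            )
        t0 += nc

    spk_n = (
        np.concatenate(spike_chunks_n) if spike_chunks_n else np.zeros(0, np.int32)
    )
    spk_t = (
        np.concatenate(spike_chunks_t) if spike_chunks_t else np.zeros(0, np.int64)
    )
    t_s = spk_t * config.dt / 1000.0 - config.transient_discard
    keep = t_s >= 0.0
    return SimulationResult(
        signals=rec,
        fs=config.record_rate * 1e3,
        spike_neurons=spk_n[keep],
        spike_times=t_s[keep],
        duration=config.duration - config.transient_discard,
        condition=config.condition.name,
        seed=config.seed,
        network_id=network_id,
        config=config.to_dict(),
    )


def run_condition_battery(
    config: SimulationConfig,
    allocation: dict[str, int] | None = None,
    modifier: RateModifier | None = None,
) -> dict[str, list[SimulationResult]]:
    """Run baseline networks, then re-run subsets under each condition.

    ``allocation`` maps condition name to network count; condition networks
    reuse the network ids (hence connectivity, weights, heterogeneity and the
    noise stream) of the first baseline networks, so comparisons are paired.
    The default allocation is the full validation battery (30 baseline, then
    8/8/10/4 for sAHP-half / Na-block / NMDA-block / AMPA-block).
    """
    alloc = dict(allocation or FULL_BATTERY_ALLOCATION)
    n_base = alloc.pop("control", config.n_networks)
    out: dict[str, list[SimulationResult]] = {"control": []}
    base_cfg = replace(config, condition=ConditionSpec.from_name("control"))
    for i in range(n_base):
        out["control"].append(run_simulation(base_cfg, network_id=i))
    for name, count in alloc.items():
        if count > n_base:
            raise ValueError(f"{name}: cannot pair {count} networks with {n_base} baselines")
        cond = ConditionSpec.from_name(name, modifier=modifier)
        cfg = replace(config, condition=cond)
        out[name] = [run_simulation(cfg, network_id=i) for i in range(count)]
    return out


def sodium_scan(
    config: SimulationConfig,
    modifiers: dict[str, RateModifier],
    n_networks: int = 2,
) -> pd.DataFrame:
    """Feature table for a grid of sodium-channel modifications.

    Each modification runs on the same matched networks (ids 0..n−1); rows are
    one network under one modification, with NBR/NBD/PSIB/MFR computed by the
    standard analysis chain.  A ``control`` row set (identity modifier) is
    always included for reference.
    """
    if not modifiers:
        raise ValueError("modifier grid must be non-empty")
    from .mea_analysis import analyze_result

    grid = {"control": IDENTITY_MODIFIER}
    grid.update(modifiers)
    rows = []
    for label, mod in grid.items():
        cond = (
            ConditionSpec.from_name("control")
            if mod.is_identity
            else ConditionSpec.from_name("sodium_mod", modifier=mod)
        )
        cfg = replace(config, condition=cond)
        for i in range(n_networks):
            res = run_simulation(cfg, network_id=i)
            fv = analyze_result(res)
            rows.append(
                {
                    "label": label,
                    "network": i,
                    "seed": config.seed,
                    "NBR": fv.NBR,
                    "NBD": fv.NBD,
                    "PSIB": fv.PSIB,
                    "MFR": fv.MFR,
                    "n_spikes": int(len(res.spike_times)),
                }
            )
    return pd.DataFrame(rows)


def write_result(result: SimulationResult, path) -> None:
    """Store a result losslessly in one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=result.signals, compression="gzip")
        f.create_dataset("spike_neurons", data=result.spike_neurons.astype(np.int32))
        f.create_dataset("spike_times", data=result.spike_times)
        f.attrs["fs"] = result.fs
        f.attrs["duration"] = result.duration
        f.attrs["condition"] = result.condition
        f.attrs["seed"] = result.seed
        f.attrs["network_id"] = result.network_id
        f.attrs["config_json"] = json.dumps(result.config)


def read_result(path) -> SimulationResult:
    """Read a result written by :func:`write_result`."""
    try:
        with h5py.File(path, "r") as f:
            return SimulationResult(
                signals=f["signals"][()],
                fs=float(f.attrs["fs"]),
                spike_neurons=f["spike_neurons"][()],
                spike_times=f["spike_times"][()],
                duration=float(f.attrs["duration"]),
                condition=str(f.attrs["condition"]),
                seed=int(f.attrs["seed"]),
                network_id=int(f.attrs["network_id"]),
                config=json.loads(f.attrs["config_json"]),
            )
    except OSError as exc:
        raise IOError(f"cannot read simulation result from {path}: {exc}") from exc
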