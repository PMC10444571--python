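"""Network construction and the virtual multi-electrode array.

Neurons are placed on a square lattice and randomly connected (directed
Erdős–Rényi, no self-edges).  Conduction delays grow linearly with somatic
distance.  Twelve virtual electrodes, arranged like the 12-electrode wells of
a 24-well MEA plate (300 µm spacing), each record a weighted sum of the
membrane potentials of nearby neurons with an exponentially decaying pickup
profile — the in silico counterpart of extracellular MEA sensing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import LayoutParams


@dataclass
class NetworkLayout:
    """Geometry and connectivity of one simulated culture."""

    N: int
    positions: np.ndarray          # (N, 2) µm
    edges: np.ndarray              # (E, 2) int, (source, target)
    delays: np.ndarray             # (E,) ms, ≥ one timestep
    electrode_positions: np.ndarray  # (n_elec, 2) µm
    electrode_weights: np.ndarray    # (n_elec, N) pickup weights, ≥ 0

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_positions)


def build_topology(N: int, p_connect: float, rng: np.random.Generator) -> np.ndarray:
    """Directed Erdős–Rényi adjacency: each ordered pair (i≠j) with prob. p.

    Returns an (E, 2) array of (source, target) index pairs.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0.0 <= p_connect <= 1.0:
        raise ValueError("p_connect must be in [0, 1]")
    mask = rng.random((N, N)) < p_connect
    np.fill_diagonal(mask, False)
    src, tgt = np.nonzero(mask)
    return np.column_stack([src, tgt])


def place_on_grid(N: int, pitch: float) -> np.ndarray:
    """First N sites of a ⌈√N⌉×⌈√N⌉ square lattice (row-major, deterministic)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    side = int(np.ceil(np.sqrt(N)))
    idx = np.arange(N)
    return np.column_stack([(idx % side) * pitch, (idx // side) * pitch]).astype(float)


def compute_delays(
    positions: np.ndarray,
    edges: np.ndarray,
    velocity: float,
    dt: float = 0.1,
) -> np.ndarray:
    """Per-edge conduction delay distance/velocity, rounded up to whole steps.

    Coincident neurons still get the minimum delay of one timestep, so a spike
    never arrives in the step it was emitted.
    """
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    d = np.linalg.norm(
        positions[edges[:, 0]] - positions[edges[:, 1]], axis=1
    )
    steps = np.maximum(1, np.ceil(d / velocity / dt)).astype(int)
    return steps * dt


def electrode_grid(layout: LayoutParams, neuron_positions: np.ndarray) -> np.ndarray:
    """Electrode coordinates: a rows×cols grid centred on the neuron lattice."""
    xs = np.arange(layout.electrode_cols) * layout.electrode_pitch
    ys = np.arange(layout.electrode_rows) * layout.electrode_pitch
    gx, gy = np.meshgrid(xs, ys)
    pos = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    centre_n = neuron_positions.mean(axis=0)
    pos += centre_n - pos.mean(axis=0)
    return pos


def pickup_weights(
    electrode_positions: np.ndarray,
    neuron_positions: np.ndarray,
    decay_length: float,
    cutoff: float,
) -> np.ndarray:
    """Electrode×neuron mixing weights exp(−d/λ), zero beyond the cutoff."""
    d = np.linalg.norm(
        electrode_positions[:, None, :] - neuron_positions[None, :, :], axis=2
    )
    w = np.exp(-d / decay_length)
    w[d > cutoff] = 0.0
    return w


def build_layout(
    layout: LayoutParams,
    rng: np.random.Generator,
    dt: float = 0.1,
) -> NetworkLayout:
    """Assemble the full network geometry for one simulated culture."""
    positions = place_on_grid(layout.N, layout.grid_pitch)
    edges = build_topology(layout.N, layout.p_connect, rng)
    delays = (
        compute_delays(positions, edges, layout.velocity, dt)
        if len(edges)
        else np.zeros(0)
    )
    epos = electrode_grid(layout, positions)
    ew = pickup_weights(epos, positions, layout.pickup_lambda, layout.pickup_cutoff)
    return NetworkLayout(
        N=layout.N,
        positions=positions,
        edges=edges,
        delays=delays,
        electrode_positions=epos,
        electrode_weights=ew,
    )


def electrode_signal(Vm_traces: np.ndarray, electrode_weights: np.ndarray) -> np.ndarray:
    """Virtual-electrode signals: weighted sums of membrane-potential traces.

    ``Vm_traces`` is (neurons, samples); returns (electrodes, samples).
    """
    Vm_traces = np.asarray(Vm_traces)
    electrode_weights = np.asarray(electrode_weights)
    if Vm_traces.ndim != 2 or electrode_weights.ndim != 2:
        raise ValueError("expected 2-D traces and 2-D weight matrix")
    if electrode_weights.shape[1] != Vm_traces.shape[0]:
        raise ValueError("weight matrix does not match the number of neurons")
    return electrode_weights @ Vm_traces
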