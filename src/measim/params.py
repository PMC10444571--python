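"""Parameter containers for the neuron, synapse and network models.

Defaults reproduce the calibrated control model of hiPSC-derived excitatory
(*Ngn2*) neuronal networks on a 12-electrode MEA well: Hodgkin-Huxley sodium,
delayed-rectifier potassium and leak currents, a spike-triggered slow
afterhyperpolarization (sAHP) conductance, membrane noise, and conductance-based
AMPA/NMDA synapses with voltage-dependent magnesium block and short-term
depression (STD).

Unit conventions
----------------
HH conductances and ``Cm`` are per membrane area (mS·cm⁻², µF·cm⁻²); the sAHP
increment, synaptic conductances (nS) and applied currents (pA) are absolute
and are divided by ``area`` (cm²) before entering the per-area membrane
equation.  ``area`` is an effective electrotonic scale rather than a measured
cell size: it sets the strength of all absolute quantities relative to the
membrane leak, and its default is calibrated so the control network
reproduces the in vitro-like bursting phenotype (see docs/methods.md).
Voltages are mV; time constants are given in the unit stated per field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class NeuronParams:
    """Single-neuron membrane parameters (control values by default)."""

    Cm: float = 1.0            # membrane capacitance, µF·cm⁻²
    gK_max: float = 5.0        # delayed-rectifier K conductance, mS·cm⁻²
    gNa_max: float = 50.0      # voltage-gated Na conductance, mS·cm⁻²
    gl: float = 0.3            # leak conductance, mS·cm⁻²
    EK: float = -80.0          # K Nernst potential, mV
    ENa: float = 70.0          # Na Nernst potential, mV
    El: float = -39.2          # leak reversal, mV
    VT: float = -30.4          # spike-threshold adjustment potential, mV
    alphaCa: float = 0.0035    # sAHP conductance increment per spike, nS
    tauAHP: float = 6.0        # sAHP recovery time constant, s
    sigma: float = 4.1         # membrane-noise standard deviation, mV
    bias_range: float = 9.5    # half-width of the uniform bias-current spread, pA
    I_app: float = 0.0         # constant applied current common to all neurons, pA
    area: float = 3.2e-6       # effective membrane area for unit reconciliation, cm²
    spike_threshold: float = 0.0   # registration threshold for full spikes, mV
    refractory: float = 3.0        # spike-registration lockout, ms

    def __post_init__(self) -> None:
        if self.Cm <= 0 or self.area <= 0:
            raise ValueError("Cm and area must be positive")
        if min(self.gK_max, self.gNa_max, self.gl) < 0:
            raise ValueError("conductances must be non-negative")
        if self.tauAHP <= 0:
            raise ValueError("tauAHP must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not (self.EK < self.El < self.ENa):
            raise ValueError("require EK < El < ENa")


@dataclass(frozen=True)
class RateModifier:
    """Modification of sodium-gate kinetics (channelopathy scan axis).

    Multiplicative scales apply to the four Na rate constants; voltage shifts
    move the activation (m) and inactivation (h) curves; ``scale_gNa`` scales
    the maximal sodium conductance.  The identity modifier leaves the control
    model untouched.
    """

    scale_alpha_m: float = 1.0
    scale_beta_m: float = 1.0
    scale_alpha_h: float = 1.0
    scale_beta_h: float = 1.0
    shift_activation: float = 0.0    # mV, added to Vm in the m-gate rates
    shift_inactivation: float = 0.0  # mV, added to Vm in the h-gate rates
    scale_gNa: float = 1.0

    def __post_init__(self) -> None:
        scales = (self.scale_alpha_m, self.scale_beta_m, self.scale_alpha_h,
                  self.scale_beta_h, self.scale_gNa)
        if any(s < 0 for s in scales):
            raise ValueError("rate/conductance scales must be non-negative")

    @property
    def is_identity(self) -> bool:
        return self == RateModifier()


IDENTITY_MODIFIER = RateModifier()


@dataclass(frozen=True)
class SynapseParams:
    """AMPA/NMDA synapse, magnesium block and STD parameters."""

    gAMPA_max: float = 0.2808   # maximal AMPA conductance per synapse, nS
    gNMDA_max: float = 0.0981   # maximal NMDA conductance per synapse, nS
    EAMPA: float = 0.0          # AMPA reversal, mV
    ENMDA: float = 0.0          # NMDA reversal, mV
    alphaNMDA: float = 0.5      # NMDA gating rate constant, kHz
    tauAMPA: float = 2.0        # AMPA decay, ms
    tauNMDA_rise: float = 2.0   # NMDA rise, ms
    tauNMDA_decay: float = 100.0  # NMDA decay, ms
    mg_conc: float = 1.0        # extracellular [Mg2+], mM
    a_mg: float = 0.062         # Mg-block voltage sensitivity, mV⁻¹
    b_mg: float = 3.57          # Mg-block concentration scale, mM
    tauD: float = 813.0         # STD recovery time constant, ms
    U: float = 0.015            # STD utilization fraction per spike
    S: float = 1.0              # global synaptic scaling factor
    weight_mean: float = 1.0    # synaptic weight distribution mean
    weight_std: float = 0.7     # synaptic weight distribution std
    weight_clip: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        if min(self.tauAMPA, self.tauNMDA_rise, self.tauNMDA_decay, self.tauD) <= 0:
            raise ValueError("time constants must be positive")
        if not 0.0 <= self.U <= 1.0:
            raise ValueError("U must be in [0, 1]")
        if self.S < 0 or self.mg_conc < 0:
            raise ValueError("S and mg_conc must be non-negative")


@dataclass(frozen=True)
class LayoutParams:
    """Network geometry: neuron grid, connectivity and the virtual MEA well."""

    N: int = 100                 # neuron count
    p_connect: float = 0.3       # directed connection probability
    grid_pitch: float = 100.0    # neuron lattice pitch, µm
    velocity: float = 3000.0     # conduction velocity, µm·ms⁻¹
    electrode_rows: int = 3      # MEA well: 3 × 4 = 12 electrodes
    electrode_cols: int = 4
    electrode_pitch: float = 300.0  # µm, Multi Channel Systems 24-well layout
    pickup_lambda: float = 150.0    # electrode pickup decay length, µm
    pickup_cutoff: float = 300.0    # electrodes ignore neurons beyond this, µm

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.p_connect <= 1.0:
            raise ValueError("p_connect must be in [0, 1]")
        if self.velocity <= 0:
            raise ValueError("velocity must be positive")

    @property
    def n_electrodes(self) -> int:
        return self.electrode_rows * self.electrode_cols


# Parameter overrides that turn the control model into the Dravet-syndrome
# (DS) network model: weakened sAHP, downscaled synapses, reduced STD and
# slowed sodium-channel activation.  The factors are this package's defaults
# for the DS condition; each is exposed in the configuration.
DS_DEFAULTS: dict[str, float] = {
    "alphaCa_factor": 0.5,
    "S_factor": 0.62,
    "U_factor": 0.7,
    "na_activation_factor": 0.7,
}


def scaled(params, **factors):
    """Return a copy of a frozen params dataclass with fields multiplied.

    ``scaled(p, alphaCa=0.5)`` multiplies ``p.alphaCa`` by 0.5.
    """
    updates = {name: getattr(params, name) * f for name, f in factors.items()}
    return replace(params, **updates)
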