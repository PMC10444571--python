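"""Engine: condition application, integration behavior, I/O, batteries."""

from dataclasses import replace

import numpy as np
import pytest

from measim import (
    ConditionSpec,
    LayoutParams,
    NeuronParams,
    RateModifier,
    SimulationConfig,
    SynapseParams,
    apply_condition,
    read_result,
    run_condition_battery,
    run_simulation,
    write_result,
)
from measim.engine import network_seeds


def _quiet_config(**kw):
    """Small, silent, fast configuration for plumbing tests."""
    defaults = dict(
        duration=6.0,
        transient_discard=1.0,
        seed=5,
        neuron=NeuronParams(sigma=0.0, bias_range=0.0),
        layout=LayoutParams(p_connect=0.1),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestApplyCondition:
    def test_control_is_identity(self, neuron, synapse):
        n, s, mod = apply_condition(neuron, synapse, ConditionSpec.from_name("control"))
        assert n == neuron and s == synapse and mod.is_identity

    def test_sahp_half_touches_only_alphaca(self, neuron, synapse):
        n, s, _ = apply_condition(neuron, synapse, ConditionSpec.from_name("sAHP_half"))
        assert n.alphaCa == pytest.approx(0.00175)
        assert replace(n, alphaCa=neuron.alphaCa) == neuron
        assert s == synapse

    @pytest.mark.parametrize(
        "name, field, target",
        [
            ("Na_block", "gNa_max", "neuron"),
            ("NMDA_block", "gNMDA_max", "synapse"),
            ("AMPA_block", "gAMPA_max", "synapse"),
        ],
    )
    def test_blockades_zero_their_conductance(self, neuron, synapse, name, field, target):
        n, s, _ = apply_condition(neuron, synapse, ConditionSpec.from_name(name))
        assert getattr(n if target == "neuron" else s, field) == 0.0

    def test_ds_condition_reduces_sahp_synapses_std_and_na_activation(
        self, neuron, synapse
    ):
        cond = ConditionSpec.from_name("DS")
        n, s, mod = apply_condition(neuron, synapse, cond)
        assert n.alphaCa < neuron.alphaCa
        assert s.S < synapse.S
        assert s.U < synapse.U
        assert mod.scale_alpha_m < 1.0 and mod.scale_beta_m < 1.0

    def test_unknown_condition_rejected(self, neuron, synapse):
        with pytest.raises(ValueError):
            ConditionSpec.from_name("bogus")
        with pytest.raises(ValueError):
            apply_condition(neuron, synapse, ConditionSpec(name="bogus"))


class TestRunSimulation:
    def test_quiescent_network_stays_silent(self):
        res = run_simulation(_quiet_config())
        assert len(res.spike_times) == 0
        assert res.signals.shape == (12, 50_000)

    def test_signal_length_contract(self):
        cfg = _quiet_config(duration=3.5, transient_discard=1.5)
        res = run_simulation(cfg)
        assert res.signals.shape[1] == round((3.5 - 1.5) * 10_000)

    def test_determinism_under_fixed_seed(self):
        cfg = SimulationConfig(duration=8.0, transient_discard=1.0, seed=11)
        a = run_simulation(cfg, network_id=2)
        b = run_simulation(cfg, network_id=2)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.spike_neurons, b.spike_neurons)
        assert np.array_equal(a.signals, b.signals)

    def test_different_networks_differ(self):
        cfg = SimulationConfig(duration=6.0, transient_discard=1.0, seed=11)
        a = run_simulation(cfg, network_id=0)
        b = run_simulation(cfg, network_id=1)
        assert not np.array_equal(a.signals, b.signals)

    def test_suprathreshold_current_fires_and_adapts(self):
        """A deterministic neuron above rheobase fires a slowing AP train."""
        cfg = _quiet_config(
            duration=30.0,
            transient_discard=0.0,
            neuron=NeuronParams(sigma=0.0, bias_range=0.0, I_app=40.0),
            layout=LayoutParams(p_connect=0.0),
        )
        res = run_simulation(cfg)
        t0 = res.spike_times[res.spike_neurons == 0]
        assert len(t0) > 10
        isi = np.diff(t0)
        # spike-frequency adaptation: the instantaneous rate keeps falling
        assert isi[-1] > isi[0] * 2.0
        smooth = np.convolve(isi, np.ones(5) / 5, mode="valid")
        assert np.all(np.diff(smooth) > -1e-4)

    def test_no_adaptation_without_sahp_increment(self):
        cfg = _quiet_config(
            duration=20.0,
            transient_discard=0.0,
            neuron=NeuronParams(sigma=0.0, bias_range=0.0, I_app=40.0, alphaCa=0.0),
            layout=LayoutParams(p_connect=0.0),
        )
        res = run_simulation(cfg)
        isi = np.diff(res.spike_times[res.spike_neurons == 0])
        assert len(isi) > 10
        assert np.std(isi[2:]) < 1e-3  # regular train after onset

    def test_sodium_block_abolishes_spiking_with_noise_on(self):
        cfg = SimulationConfig(
            duration=12.0,
            transient_discard=1.0,
            seed=3,
            condition=ConditionSpec.from_name("Na_block"),
        )
        res = run_simulation(cfg)
        assert len(res.spike_times) == 0

    def test_sodium_conductance_is_what_makes_the_cell_fire(self):
        """A suprathreshold current fires the intact neuron but not gNa = 0."""
        counts = {}
        for gna in (50.0, 0.0):
            cfg = _quiet_config(
                duration=10.0,
                transient_discard=0.0,
                neuron=NeuronParams(
                    sigma=0.0, bias_range=0.0, I_app=30.0, gNa_max=gna
                ),
                layout=LayoutParams(p_connect=0.0),
            )
            counts[gna] = len(run_simulation(cfg).spike_times)
        assert counts[50.0] > 0
        assert counts[0.0] == 0


class TestTimestepRefinement:
    def test_halving_dt_leaves_burst_rate_within_ten_percent(self):
        """Scheme stability: control NBR changes < 10% under dt refinement."""
        from measim import analyze_signals

        nbr = {}
        for dt in (0.1, 0.05):
            cfg = SimulationConfig(
                duration=170.0, transient_discard=50.0, seed=7, dt=dt
            )
            res = run_simulation(cfg, network_id=0)
            _, _, fv = analyze_signals(res.signals, res.fs)
            nbr[dt] = fv.NBR
        assert nbr[0.1] > 0
        assert abs(nbr[0.05] - nbr[0.1]) / nbr[0.1] < 0.10


class TestSeedPairing:
    def test_child_seeds_are_deterministic_and_distinct(self):
        assert network_seeds(1, 0) == network_seeds(1, 0)
        assert network_seeds(1, 0) != network_seeds(1, 1)
        assert network_seeds(2, 0) != network_seeds(1, 0)
        for s in network_seeds(123, 7):
            assert 0 <= s < 2**32

    def test_paired_conditions_share_network_structure(self):
        """Blocked runs reuse the baseline adjacency, weights and bias draws."""
        from measim.network import build_layout
        from measim.synapses import draw_weights
        from measim.biophysics import draw_bias_currents

        for cond in ("control", "AMPA_block"):
            struct_seed, _ = network_seeds(9, 3)
            rng = np.random.default_rng(struct_seed)
            layout = build_layout(LayoutParams(), rng)
            w = draw_weights(layout.edges, rng)
            b = draw_bias_currents(layout.N, rng)
            if cond == "control":
                ref = (layout.edges.copy(), w.copy(), b.copy())
        assert np.array_equal(ref[0], layout.edges)
        assert np.array_equal(ref[1], w)
        assert np.array_equal(ref[2], b)


class TestBattery:
    def test_allocation_bookkeeping_and_pairing(self):
        cfg = _quiet_config()
        out = run_condition_battery(cfg, {"control": 2, "AMPA_block": 2})
        assert sorted(out) == ["AMPA_block", "control"]
        assert [r.network_id for r in out["control"]] == [0, 1]
        assert [r.network_id for r in out["AMPA_block"]] == [0, 1]
        assert all(r.condition == "AMPA_block" for r in out["AMPA_block"])

    def test_overallocated_condition_rejected(self):
        with pytest.raises(ValueError):
            run_condition_battery(_quiet_config(), {"control": 1, "Na_block": 2})

    def test_full_allocation_matches_validation_design(self):
        from measim.engine import FULL_BATTERY_ALLOCATION

        assert FULL_BATTERY_ALLOCATION == {
            "control": 30,
            "sAHP_half": 8,
            "Na_block": 8,
            "NMDA_block": 10,
            "AMPA_block": 4,
        }


class TestSodiumScan:
    def test_identity_row_equals_control_and_ttx_row_is_silent(self):
        from measim import RateModifier, sodium_scan

        cfg = SimulationConfig(duration=8.0, transient_discard=1.0, seed=6)
        table = sodium_scan(
            cfg,
            {"identity": RateModifier(),
             "gNa_x0": RateModifier(scale_gNa=0.0)},
            n_networks=2,
        )
        assert set(table["label"]) == {"control", "identity", "gNa_x0"}
        for nid in (0, 1):
            ctrl = table[(table.label == "control") & (table.network == nid)].iloc[0]
            ident = table[(table.label == "identity") & (table.network == nid)].iloc[0]
            # identity modifier on matched seeds reproduces control exactly
            assert ident["n_spikes"] == ctrl["n_spikes"]
            assert ident["MFR"] == ctrl["MFR"]
        assert (table[table.label == "gNa_x0"]["n_spikes"] == 0).all()

    def test_empty_grid_rejected(self):
        from measim import sodium_scan

        with pytest.raises(ValueError):
            sodium_scan(_quiet_config(), {})


class TestResultIO:
    def test_lossless_roundtrip(self, tmp_path):
        cfg = SimulationConfig(duration=4.0, transient_discard=1.0, seed=2)
        res = run_simulation(cfg, network_id=1)
        path = tmp_path / "net.h5"
        write_result(res, path)
        back = read_result(path)
        assert np.array_equal(back.signals, res.signals)
        assert np.array_equal(back.spike_times, res.spike_times)
        assert np.array_equal(back.spike_neurons, res.spike_neurons)
        assert back.condition == res.condition
        assert back.seed == res.seed
        assert back.config["condition"]["name"] == "control"
        assert back.config["seed"] == 2

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(IOError):
            read_result(tmp_path / "absent.h5")


class TestConfigValidation:
    def test_duration_must_exceed_transient(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration=40.0, transient_discard=50.0)

    def test_dt_must_divide_recording_interval(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.3)

    def test_modifier_validation(self):
        with pytest.raises(ValueError):
            RateModifier(scale_alpha_m=-1.0)
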