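"""Double-cable axon model: structure, dynamics and threshold search."""

import numpy as np
import pytest

import eesim.cable as cable_mod
from eesim.cable import (
    FLUT,
    MYSA,
    NODE,
    NOT_RECRUITED,
    STIN,
    MembraneTrace,
    StimulusProtocol,
    discretize_fiber,
    find_fiber_threshold,
    geometry_for_diameter,
    is_recruited,
    simulate_response,
)
from conftest import point_source_ve


class TestDiscretization:
    def test_every_internode_has_ten_compartments(self, motor_cable):
        kinds = motor_cable.kinds
        nodes = np.flatnonzero(kinds == NODE)
        for a, b in zip(nodes[:-1], nodes[1:]):
            inter = kinds[a + 1 : b]
            assert len(inter) == 10
            assert np.count_nonzero(inter == MYSA) == 2
            assert np.count_nonzero(inter == FLUT) == 2
            assert np.count_nonzero(inter == STIN) == 6

    def test_chain_starts_and_ends_with_node(self, motor_cable):
        assert motor_cable.kinds[0] == NODE
        assert motor_cable.kinds[-1] == NODE

    def test_node_count_follows_fiber_length(self, straight_xyz):
        cab = discretize_fiber(straight_xyz, 9.0, "motor")
        delta = geometry_for_diameter(9.0)["internode_length"] * 1e-3
        assert cab.n_nodes == int(np.floor(12.0 / delta)) + 1

    def test_arc_positions_strictly_increasing(self, motor_cable):
        assert np.all(np.diff(motor_cable.arc_centers_mm) > 0)

    def test_geometry_interpolates_between_table_rows(self):
        g87 = geometry_for_diameter(8.7)
        g9 = geometry_for_diameter(9.0)
        g10 = geometry_for_diameter(10.0)
        for k in g9:
            assert min(g87[k], g10[k]) <= g9[k] <= max(g87[k], g10[k])

    def test_diameter_outside_table_rejected(self, straight_xyz):
        with pytest.raises(ValueError, match="diameter"):
            discretize_fiber(straight_xyz, 20.0)

    def test_short_fiber_rejected(self):
        z = np.linspace(0, 1.5, 31)
        with pytest.raises(ValueError, match="internodal"):
            discretize_fiber(np.c_[0 * z, 0 * z, z], 9.0)


class TestProtocol:
    def test_waveform_is_charge_balanced(self):
        p = StimulusProtocol()
        t = np.linspace(-0.05, 1.0, 4201)
        w = p.waveform(t)
        assert abs(np.trapezoid(w, t)) < 1e-3
        assert set(np.unique(w)) <= {-1.0, 0.0, 1.0}

    def test_phases_have_equal_duration(self):
        p = StimulusProtocol(pulse_width_us=200.0)
        t = np.arange(0, 0.5, 1e-4)
        w = p.waveform(t)
        assert np.sum(w < 0) == np.sum(w > 0)

    def test_total_width_interpretation_switch(self):
        assert StimulusProtocol(per_phase=True).phase_ms == pytest.approx(0.2)
        assert StimulusProtocol(per_phase=False).phase_ms == pytest.approx(0.1)

    def test_train_interval_must_fit_pulse(self):
        with pytest.raises(ValueError, match="inter-pulse"):
            StimulusProtocol(rate_hz=3000.0, n_pulses=2)


class TestDynamics:
    def test_rest_is_stable_without_drive(self, motor_cable, default_protocol):
        ve = np.zeros(motor_cable.n_compartments)
        tr = simulate_response(
            motor_cable, ve, default_protocol, 0.0, early_abort=False
        )
        drift = np.abs(tr.node_vm - tr.node_vm[:, :1]).max()
        assert drift < 1.0  # mV over the whole run

    def test_mirrored_drive_gives_mirrored_spikes(self, motor_cable):
        prot = StimulusProtocol(window_ms=5.0)
        rng = np.random.default_rng(1)
        ve = np.interp(
            motor_cable.arc_centers_mm,
            np.linspace(0, 12, 13),
            rng.uniform(0, 0.3, 13),
        )
        a = simulate_response(motor_cable, ve, prot, 400.0, early_abort=False)
        b = simulate_response(motor_cable, ve[::-1], prot, 400.0, early_abort=False)
        fwd = [s[0] if s.size else np.nan for s in a.spike_times]
        rev = [s[0] if s.size else np.nan for s in b.spike_times]
        assert np.allclose(fwd, rev[::-1], atol=1e-6, equal_nan=True)

    def test_suprathreshold_latencies_grow_from_drive_center(
        self, motor_cable, default_protocol
    ):
        ve = point_source_ve(motor_cable)
        tr = simulate_response(
            motor_cable, ve, default_protocol, 900.0, early_abort=False
        )
        lat = np.array([s[0] for s in tr.spike_times])
        mid = int(np.argmin(lat))
        assert 0 < mid < len(lat) - 1
        assert np.all(np.diff(lat[mid:]) >= 0)
        assert np.all(np.diff(lat[: mid + 1]) <= 0)
        assert lat[0] > lat[mid] and lat[-1] > lat[mid]
        assert lat.max() <= default_protocol.window_ms

    def test_mismatched_ve_length_rejected(self, motor_cable, default_protocol):
        with pytest.raises(ValueError, match="compartments"):
            simulate_response(motor_cable, np.zeros(3), default_protocol, 10.0)


def _trace(spike_lists, n_pulses=1, window=10.0):
    return MembraneTrace(
        t_ms=np.empty(0),
        node_vm=np.empty((len(spike_lists), 0)),
        spike_times=[np.asarray(s, float) for s in spike_lists],
        pulse_times_ms=np.zeros(1),
        amplitude_ua=0.0,
        v_rest=-80.0,
    )


class TestRecruitmentDetection:
    def test_no_spikes_is_not_recruited(self, default_protocol):
        assert not is_recruited(_trace([[], [], []]), default_protocol)

    def test_decremental_conduction_is_not_recruited(self, default_protocol):
        assert not is_recruited(_trace([[0.2], [], []]), default_protocol)

    def test_full_propagation_is_recruited(self, default_protocol):
        tr = _trace([[0.2], [0.3], [0.4]])
        assert is_recruited(tr, default_protocol)

    def test_spike_outside_window_does_not_count(self):
        prot = StimulusProtocol(window_ms=5.0)
        assert not is_recruited(_trace([[0.2], [0.3], [12.0]]), prot)


class TestThresholdSearch:
    def test_bisection_matches_linear_scan_oracle(self, monkeypatch):
        grid = np.arange(25.0, 1000.0 + 1e-9, 25.0)
        for true_thr in (25.0, 375.0, 1000.0):
            def fake_sim(cable, ve, protocol, amp, record=True, early_abort=True):
                return amp

            def fake_rec(trace, protocol):
                return trace >= true_thr

            monkeypatch.setattr(cable_mod, "simulate_response", fake_sim)
            monkeypatch.setattr(cable_mod, "is_recruited", fake_rec)
            got = find_fiber_threshold(None, None, StimulusProtocol(), grid)
            oracle = next((a for a in grid if a >= true_thr), NOT_RECRUITED)
            assert got == oracle

    def test_never_recruited_returns_sentinel(self, monkeypatch):
        monkeypatch.setattr(cable_mod, "simulate_response", lambda *a, **k: None)
        monkeypatch.setattr(cable_mod, "is_recruited", lambda *a: False)
        assert find_fiber_threshold(None, None, StimulusProtocol()) == NOT_RECRUITED

    def test_descending_grid_rejected(self, motor_cable, default_protocol):
        with pytest.raises(ValueError, match="ascending"):
            find_fiber_threshold(
                motor_cable, np.zeros(motor_cable.n_compartments),
                default_protocol, [100.0, 50.0],
            )

    def test_real_threshold_consistent_with_direct_scan(self, sensory_cable):
        # verify the monotonicity assumption on a real fiber: the bisection
        # threshold agrees with checking its two neighbouring amplitudes
        prot = StimulusProtocol()
        ve = point_source_ve(sensory_cable)
        grid = np.arange(50.0, 500.0 + 1e-9, 50.0)
        thr = find_fiber_threshold(sensory_cable, ve, prot, grid)
        assert np.isfinite(thr)
        below = simulate_response(sensory_cable, ve, prot, thr - 50.0)
        at = simulate_response(sensory_cable, ve, prot, thr)
        assert not is_recruited(below, prot)
        assert is_recruited(at, prot)
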