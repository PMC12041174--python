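"""Steady solver: Ohmic limits, oracle equivalence, clamping, waveform."""

import dataclasses
import math

import numpy as np
import pytest

import hepanet as hp
from _oracles import random_tree_network, series_parallel_solve


def _single_segment_net(r_seg_target=0.5, r_out=0.5, pressure=100.0):
    # choose geometry that yields exactly the requested segment resistance
    radius, length = 2.0, 30.0
    base = hp.poiseuille_resistance(radius, length, 0.0035)
    seg = hp.VesselSegment(
        id="S", name="seg", proximal_node="A", distal_node="B",
        radius=radius, length=length * r_seg_target / base,
    )
    return hp.ArterialNetwork(
        segments=(seg,),
        inlet=hp.InletBC(node="A", pressure=pressure),
        outlets=(hp.WindkesselOutlet(node="B", resistance=r_out),),
    )


class TestSolveSteady:
    def test_ohmic_series_division(self):
        sol = hp.solve_steady(_single_segment_net())
        assert sol.flow("S") == pytest.approx(100.0, rel=1e-12)
        assert sol.node_pressures["B"] == pytest.approx(50.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_series_parallel_oracle_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        net = random_tree_network(rng)
        assert hp.validate_network(net) == []
        sol = hp.solve_steady(net)
        flows, pressures = series_parallel_solve(net)
        for sid, q in flows.items():
            assert sol.flow(sid) == pytest.approx(q, rel=1e-9, abs=1e-12)
        for node, p in pressures.items():
            assert sol.node_pressures[node] == pytest.approx(p, rel=1e-9)

    def test_conservation_inlet_equals_outlets(self, michels1):
        sol = hp.solve_steady(michels1)
        inlet_flow = sol.flow("CT") + sol.flow("SMA")
        assert inlet_flow == pytest.approx(sum(sol.outlet_flows.values()), rel=1e-9)
        assert sol.residual <= 1e-9 * max(abs(q) for q in sol.segment_flows.values())

    def test_deterministic_bit_identical(self, michels1):
        a = hp.solve_steady(michels1)
        b = hp.solve_steady(michels1)
        assert a.segment_flows == b.segment_flows
        assert a.node_pressures == b.node_pressures

    def test_invalid_network_rejected(self, michels1):
        net = dataclasses.replace(michels1, clamped_segments=frozenset({"NOPE"}))
        with pytest.raises(hp.NetworkValidationError):
            hp.solve_steady(net)


class TestClamp:
    def test_clamped_segment_flow_exactly_zero(self, michels1):
        sol = hp.solve_steady(hp.clamp(michels1, "GDA"))
        assert sol.flow("GDA") == 0.0

    def test_gda_clamp_raises_pha_flow(self, michels1):
        base = hp.solve_steady(michels1)
        clamped = hp.solve_steady(hp.clamp(michels1, "GDA"))
        assert clamped.flow("PHA") > base.flow("PHA")
        assert clamped.flow("CHA") < base.flow("CHA")

    def test_cha_clamp_reverses_gda_toward_liver(self, michels1):
        sol = hp.solve_steady(hp.clamp(michels1, "CHA"))
        assert sol.flow("CHA") == 0.0
        assert sol.flow("GDA") < 0
        # conservation at the bifurcation: liver inflow equals the reversed GDA
        assert sol.flow("PHA") == pytest.approx(-sol.flow("GDA"), rel=1e-9)

    def test_clamp_idempotent_and_unknown_rejected(self, michels1):
        once = hp.clamp(michels1, "GDA")
        assert hp.clamp(once, "GDA") == once
        with pytest.raises(KeyError):
            hp.clamp(michels1, "XYZ")

    def test_no_open_path_error_when_fully_clamped(self, michels1):
        net = hp.clamp(hp.clamp(michels1, "CT"), "SMA")
        with pytest.raises(hp.NoOpenPathError, match="no_open_path"):
            hp.solve_steady(net)

    def test_dead_end_subtree_is_determinate(self, michels1):
        # clamping both hepatic branches leaves the bifurcation a dead end fed
        # by the open CHA: zero flow, pressure equal to the celiac node
        net = hp.clamp(hp.clamp(michels1, "GDA"), "PHA")
        sol = hp.solve_steady(net)
        assert sol.flow("CHA") == pytest.approx(0.0, abs=1e-12)
        assert sol.node_pressures["HEP"] == pytest.approx(
            sol.node_pressures["CEL"], rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(200))
    def test_clamp_monotonicity_random_templates(self, seed):
        """Clamping never raises total inlet flow and never starves a sibling."""
        rng = np.random.default_rng(seed)
        overrides = {
            sid: {"radius": r * rng.uniform(0.9, 1.1)}
            for sid, r in [("CT", 3.2), ("SA", 2.6), ("CHA", 2.2), ("PHA", 2.0),
                           ("GDA", 1.7), ("ARCADE", 1.0), ("SMA", 3.0)]
        }
        resistances = {
            node: res * rng.uniform(0.5, 2.0)
            for node, res in [("SPL", 0.33), ("LIV", 0.37), ("PDA", 2.45),
                              ("SMAJ", 0.20)]
        }
        net = hp.build_template(hp.Variant.MICHELS_I, overrides,
                                outlet_resistances=resistances)
        base = hp.solve_steady(net)
        inlet0 = base.flow("CT") + base.flow("SMA")
        target = ["GDA", "PHA", "SA"][seed % 3]
        clamped = hp.solve_steady(hp.clamp(net, target))
        assert clamped.flow("CT") + clamped.flow("SMA") <= inlet0 * (1 + 1e-9)
        parent = net.segment(target).proximal_node
        for sib in net.segments:
            if sib.id != target and sib.proximal_node == parent:
                assert clamped.flow(sib.id) >= base.flow(sib.id) * (1 - 1e-9)


class TestStenosisSweep:
    def test_gda_reverses_beyond_some_severity(self, michels1):
        flows_gda, flows_cha = [], []
        for severity in np.linspace(0.0, 0.95, 20):
            net = hp.build_template(hp.Variant.CELIAC_STENOSIS,
                                    area_reduction=float(severity))
            sol = hp.solve_steady(net)
            flows_gda.append(sol.flow("GDA"))
            flows_cha.append(sol.flow("CHA"))
        assert flows_gda[0] > 0 and flows_gda[-1] < 0  # sign change occurs
        assert all(b <= a + 1e-9 for a, b in zip(flows_cha, flows_cha[1:]))


class TestWindkesselWaveform:
    OUTLET = hp.WindkesselOutlet("X", resistance=1.0, compliance=1.0 / 60.0,
                                 reference_pressure=5.0)

    def test_zero_compliance_is_scaled_inflow(self):
        rigid = hp.WindkesselOutlet("X", resistance=2.0, compliance=0.0,
                                    reference_pressure=5.0)
        t, p = hp.windkessel_waveform(rigid, amplitude=100.0, period=1.0,
                                      n_cycles=2)
        phase = np.mod(t, 1.0)
        q = np.where(phase < 1 / 3, 100.0 * np.sin(3 * np.pi * phase), 0.0)
        assert np.allclose(p, 5.0 + 2.0 * q, atol=1e-9)

    def test_constant_inflow_relaxes_to_q0_r(self):
        # approximate constant inflow via the analytic pieces' diastolic decay:
        # start from P0 and check the RC relaxation limit analytically instead
        tau = self.OUTLET.resistance * self.OUTLET.compliance * 60.0
        assert tau == pytest.approx(1.0)
        t, p = hp.windkessel_waveform(self.OUTLET, amplitude=60.0, period=2.0,
                                      n_cycles=14, systole_fraction=0.5)
        # after many time constants the trace is periodic: successive cycle
        # extrema agree
        per = int(round(2.0 / 1e-3))
        last, prev = p[-per:], p[-2 * per:-per]
        assert last.max() == pytest.approx(prev.max(), rel=1e-6)
        assert last.min() == pytest.approx(prev.min(), rel=1e-6)

    def test_matches_numerical_ode_oracle(self):
        from scipy import integrate as scipy_integrate

        amplitude, period, fsys = 240.0, 1.0, 1.0 / 3.0
        t, p = hp.windkessel_waveform(self.OUTLET, amplitude=amplitude,
                                      period=period, n_cycles=15,
                                      systole_fraction=fsys, dt=1e-3)

        def rhs(tt, y):
            ph = tt % period
            q = amplitude * math.sin(math.pi * ph / (fsys * period)) \
                if ph < fsys * period else 0.0
            return [(q - (y[0] - 5.0) / 1.0) / (1.0 / 60.0) / 60.0]

        sol = scipy_integrate.solve_ivp(rhs, (0, 15 * period), [5.0], t_eval=t,
                                        rtol=1e-10, atol=1e-10, max_step=1e-3)
        last = slice(-1000, None)
        ratio = p[last].max() / p[last].min()
        ratio_ode = sol.y[0][last].max() / sol.y[0][last].min()
        assert ratio == pytest.approx(ratio_ode, rel=1e-4)

    def test_invalid_pulse_parameters_rejected(self):
        with pytest.raises(ValueError):
            hp.windkessel_waveform(self.OUTLET, amplitude=-1.0, period=1.0)
        with pytest.raises(ValueError):
            hp.windkessel_waveform(self.OUTLET, amplitude=1.0, period=0.0)
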