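"""Network assembly, series/parallel reduction, nodal solution and outlet
calibration."""

import math
from dataclasses import replace

import numpy as np
import pytest

from coroflow import (
    CircuitNetwork,
    LumpedElement,
    SynthConfig,
    build_network,
    calibrate_outlet,
    generate_tree,
    nodal_solve,
    reduce_network,
    solve_tree,
)
from coroflow.circuit import GROUND_NODE, SOURCE_NODE, segment_element_id
from coroflow.elements import material_compliance_cgs, impedance, poiseuille_resistance
from coroflow.errors import CalibrationError, TopologyError
from coroflow.geometry import CoronaryTree, VesselSegment
from coroflow.synth import random_tree

from conftest import chain_tree


def resistor(eid, Z, a, b):
    return LumpedElement(eid, "resistor", Z, a, b)


def parallel(*zs):
    return 1.0 / sum(1.0 / z for z in zs)


class TestReduction:
    def test_two_equal_resistors_in_parallel(self):
        net = CircuitNetwork(
            [resistor("a", 100.0, SOURCE_NODE, GROUND_NODE),
             resistor("b", 100.0, SOURCE_NODE, GROUND_NODE)]
        )
        assert reduce_network(net) == pytest.approx(50.0, rel=1e-12)

    def test_series_pair_sums(self):
        net = CircuitNetwork(
            [resistor("a", 100.0, SOURCE_NODE, "mid"),
             resistor("b", 250.0, "mid", GROUND_NODE)]
        )
        assert reduce_network(net) == pytest.approx(350.0, rel=1e-12)

    def test_bridge_falls_back_to_nodal(self):
        # Wheatstone bridge with unequal arms is not series/parallel-reducible
        net = CircuitNetwork(
            [
                resistor("a", 100.0, SOURCE_NODE, "m1"),
                resistor("b", 200.0, SOURCE_NODE, "m2"),
                resistor("c", 300.0, "m1", GROUND_NODE),
                resistor("d", 400.0, "m2", GROUND_NODE),
                resistor("e", 500.0, "m1", "m2"),
            ]
        )
        # independent oracle: mesh algebra via numpy on the 2x2 node system
        G = np.array(
            [[1 / 100 + 1 / 300 + 1 / 500, -1 / 500],
             [-1 / 500, 1 / 200 + 1 / 400 + 1 / 500]]
        )
        b = np.array([1 / 100, 1 / 200])
        v = np.linalg.solve(G, b)  # node pressures at unit source
        total = (1 - v[0]) / 100 + (1 - v[1]) / 200
        assert reduce_network(net) == pytest.approx(1 / total, rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_nodal_oracle_on_random_trees(self, seed, hemo, chamber,
                                                  states):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, max_segments=30)
        net = build_network(tree, hemo, states["R"], chamber)
        z_reduce = reduce_network(net)
        sol = nodal_solve(net, hemo.mean_aortic_pressure_dyn_cm2)
        z_nodal = hemo.mean_aortic_pressure_dyn_cm2 / sol.total_source_flow_cc_s
        assert abs(z_reduce - z_nodal) / z_nodal < 1e-9


class TestNodalSolve:
    def test_single_resistor_ohms_law(self):
        net = CircuitNetwork([resistor("a", 2000.0, SOURCE_NODE, GROUND_NODE)])
        sol = nodal_solve(net, 133322.0)
        assert sol.per_element_flow_cc_s["a"] == pytest.approx(133322.0 / 2000.0)

    def test_series_pair_conserves_flow(self):
        net = CircuitNetwork(
            [resistor("a", 1000.0, SOURCE_NODE, "mid"),
             resistor("b", 3000.0, "mid", GROUND_NODE)]
        )
        sol = nodal_solve(net, 133322.0)
        assert sol.per_element_flow_cc_s["a"] == pytest.approx(
            sol.per_element_flow_cc_s["b"], rel=1e-12
        )
        # voltage divider
        assert sol.per_node_pressure_dyn_cm2["mid"] == pytest.approx(
            133322.0 * 3000.0 / 4000.0, rel=1e-12
        )

    def test_kirchhoff_current_law_at_internal_nodes(self, hemo, chamber, states):
        tree = random_tree(np.random.default_rng(42), max_segments=25)
        net = build_network(tree, hemo, states["E1"], chamber)
        sol = nodal_solve(net, hemo.mean_aortic_pressure_dyn_cm2)
        incidence = {}
        for e in net.elements:
            incidence.setdefault(e.node_a, []).append((e.element_id, +1))
            incidence.setdefault(e.node_b, []).append((e.element_id, -1))
        scale = sol.total_source_flow_cc_s
        for node, terms in incidence.items():
            if node in (SOURCE_NODE, GROUND_NODE):
                continue
            net_flow = sum(sign * sol.per_element_flow_cc_s[eid]
                           for eid, sign in terms)
            assert abs(net_flow) < 1e-9 * scale

    def test_node_pressures_within_source_and_ground(self, hemo, chamber, states):
        tree = random_tree(np.random.default_rng(3), max_segments=20)
        _, sol = solve_tree(tree, hemo, states["R"], chamber)
        P = hemo.mean_aortic_pressure_dyn_cm2
        for p in sol.per_node_pressure_dyn_cm2.values():
            assert -1e-9 * P <= p <= P * (1 + 1e-12)

    def test_disconnected_network_rejected(self):
        with pytest.raises(TopologyError):
            CircuitNetwork(
                [resistor("a", 100.0, SOURCE_NODE, "floating_mid"),
                 resistor("b", 100.0, "island1", "island2"),
                 resistor("c", 100.0, SOURCE_NODE, GROUND_NODE)]
            )


class TestBuildNetwork:
    def test_minimal_chain_structure(self, hemo, chamber, states):
        tree = chain_tree(1, site_on_last=False)
        with pytest.warns(UserWarning, match="absent from the tree"):
            net = build_network(tree, hemo, states["R"], chamber,
                                include_outlet=False)
        kinds = sorted(e.element_id.split(":")[0] for e in net.elements)
        assert kinds == ["chamber_c", "chamber_r", "distal", "seg"]
        # hand algebra: Z_seg + (R_chamber || Z_chamber_C) + R_distal
        R_seg = poiseuille_resistance(hemo.viscosity_poise, 10.0, 0.1)
        Z_seg = impedance(
            R_seg,
            material_compliance_cgs(hemo.material_area_compliance_mm2_mmhg),
            hemo.cardiac_period_s,
        )
        Z_ch = hemo.cardiac_period_s / (2 * math.pi * chamber.compliance_cgs)
        expected = (
            Z_seg
            + parallel(chamber.inherent_resistance("LAD"), Z_ch)
            + states["R"].resistance("LAD")
        )
        assert reduce_network(net) == pytest.approx(expected, rel=1e-12)

    def test_bifurcation_parallel_children(self, hemo, chamber, states):
        segs = [
            VesselSegment("p", None, "LAD", 5.0, 0.2),
            VesselSegment("c1", "p", "LAD", 5.0, 0.15),
            VesselSegment("c2", "p", "LAD", 5.0, 0.12),
        ]
        tree = CoronaryTree(segs)
        with pytest.warns(UserWarning):
            net = build_network(tree, hemo, states["R"], chamber,
                                include_outlet=False)

        def Z(l, r):
            return impedance(
                poiseuille_resistance(hemo.viscosity_poise, l, r),
                material_compliance_cgs(hemo.material_area_compliance_mm2_mmhg),
                hemo.cardiac_period_s,
            )

        Z_ch = hemo.cardiac_period_s / (2 * math.pi * chamber.compliance_cgs)
        chamber_block = parallel(chamber.inherent_resistance("LAD"), Z_ch)
        expected = (
            Z(5.0, 0.2)
            + parallel(Z(5.0, 0.15), Z(5.0, 0.12))
            + chamber_block
            + states["R"].resistance("LAD")
        )
        assert reduce_network(net) == pytest.approx(expected, rel=1e-12)

    def test_three_artery_element_count(self, three_artery_tree, hemo, chamber,
                                        states):
        net = build_network(three_artery_tree, hemo, states["R"], chamber)
        # segments + 3 arteries x (chamber pair + distal) + outlet
        assert len(net.elements) == 9 + 3 * 3 + 1

    def test_multiple_roots_attach_at_source(self, hemo, chamber, states):
        segs = [
            VesselSegment("r1", None, "LAD", 5.0, 0.2),
            VesselSegment("r2", None, "LAD", 5.0, 0.2),
        ]
        with pytest.warns(UserWarning):
            net = build_network(CoronaryTree(segs), hemo, states["R"], chamber,
                                include_outlet=False)
        for eid in ("seg:r1", "seg:r2"):
            assert net.element(eid).node_a == SOURCE_NODE


class TestCalibration:
    def test_total_flow_exact_after_calibration(self, hemo, chamber, states,
                                                three_artery_tree):
        _, sol = solve_tree(three_artery_tree, hemo, states["E2"], chamber)
        assert sol.total_source_flow_cc_s == pytest.approx(
            hemo.total_input_flow_cc_s, rel=1e-9
        )

    def test_symmetric_split(self, hemo):
        P = hemo.mean_aortic_pressure_dyn_cm2
        target = hemo.total_input_flow_cc_s
        Z_cor = 2 * P / target
        net = CircuitNetwork(
            [resistor("cor", Z_cor, SOURCE_NODE, GROUND_NODE),
             resistor("aortic_outlet", 12345.0, SOURCE_NODE, GROUND_NODE)]
        )
        calibrated = calibrate_outlet(net, hemo)
        assert calibrated.element("aortic_outlet").Z_dyn_s_cm5 == pytest.approx(
            Z_cor, rel=1e-12
        )

    def test_infeasible_when_coronary_exceeds_target(self, hemo, chamber,
                                                     states, three_artery_tree):
        greedy = replace(hemo, total_input_flow_cc_s=0.5)
        net = build_network(three_artery_tree, greedy, states["E2"], chamber)
        with pytest.raises(CalibrationError, match="exceeds"):
            calibrate_outlet(net, greedy)


class TestMonotonicity:
    def test_activity_increases_artery_inflow(self, hemo, chamber,
                                              ordered_states, three_artery_tree):
        inflows = []
        per_artery = []
        for state in ordered_states:
            _, sol = solve_tree(three_artery_tree, hemo, state, chamber)
            inflows.append(sol.coronary_inflow_cc_s)
            per_artery.append(sol.artery_inflow_cc_s("LAD"))
        assert inflows[0] < inflows[1] < inflows[2]
        assert per_artery[0] < per_artery[1] < per_artery[2]

    def test_stenosis_reduces_path_flow(self, hemo, chamber, states):
        def site_flow(radius):
            segs = [
                VesselSegment("a", None, "LAD", 5.0, 0.2),
                VesselSegment("b", "a", "LAD", 5.0, radius),
            ]
            tree = CoronaryTree(segs)
            with pytest.warns(UserWarning):
                _, sol = solve_tree(tree, hemo, states["R"], chamber,
                                    include_outlet=False, calibrate=False)
            return sol.per_element_flow_cc_s[segment_element_id("b")]

        assert site_flow(0.06) < site_flow(0.10) < site_flow(0.20)
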