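"""Three-method local flow determination and activity sweeps."""

from dataclasses import replace

import pytest

from coroflow import (
    ChamberParams,
    CoronaryTree,
    MMHG_TO_DYN_CM2,
    SiteMeasurement,
    VesselSegment,
    activity_sweep,
    benchtop_site_flow,
    invasive_site_flow,
    model_ffr,
    path_impedance,
    predicted_distal_pressure,
    solve_tree,
    windkessel_site_flow,
)
from coroflow.flow import load_measurements, measurements_to_frame

from conftest import chain_tree, radius_for_resistance


@pytest.fixture
def rigid_hemo(hemo):
    """Zero wall compliance: path impedance equals the Poiseuille sum."""
    return replace(hemo, material_area_compliance_mm2_mmhg=0.0)


@pytest.fixture
def r50k_tree(rigid_hemo):
    """Single-segment LAD whose ostium-to-site resistance is 50,000."""
    r = radius_for_resistance(50_000.0, mu=rigid_hemo.viscosity_poise, length=10.0)
    return CoronaryTree(
        [
            VesselSegment(
                "lad", None, "LAD", 10.0, r,
                is_measurement_site=True, site_distance_cm=10.0,
            )
        ]
    )


class TestInvasiveAndBenchtop:
    def test_reference_value(self, rigid_hemo, r50k_tree):
        # (1 - 0.8) * 133322 / 50000
        flow = invasive_site_flow(0.8, rigid_hemo, r50k_tree, "lad")
        assert flow == pytest.approx(0.533288, rel=1e-6)

    def test_ffr_one_gives_zero_with_warning(self, rigid_hemo, r50k_tree):
        with pytest.warns(UserWarning, match="no pressure gradient"):
            assert invasive_site_flow(1.0, rigid_hemo, r50k_tree, "lad") == 0.0

    def test_ffr_out_of_range_rejected(self, rigid_hemo, r50k_tree):
        with pytest.raises(ValueError):
            invasive_site_flow(0.0, rigid_hemo, r50k_tree, "lad")
        with pytest.raises(ValueError):
            invasive_site_flow(1.3, rigid_hemo, r50k_tree, "lad")

    @pytest.mark.parametrize("ffr", [0.3, 0.55, 0.8, 0.95])
    def test_benchtop_equals_invasive_at_matching_pressure(
        self, ffr, hemo, r50k_tree
    ):
        distal_mmhg = ffr * hemo.mean_aortic_pressure_mmhg
        assert benchtop_site_flow(
            distal_mmhg, hemo, r50k_tree, "lad"
        ) == pytest.approx(
            invasive_site_flow(ffr, hemo, r50k_tree, "lad"), rel=1e-12
        )

    def test_benchtop_reference_value(self, rigid_hemo, r50k_tree):
        flow = benchtop_site_flow(80.0, rigid_hemo, r50k_tree, "lad")
        assert flow == pytest.approx(0.533288, rel=1e-6)

    def test_distal_above_aortic_rejected(self, hemo, r50k_tree):
        with pytest.raises(ValueError, match="exceeds"):
            benchtop_site_flow(120.0, hemo, r50k_tree, "lad")

    def test_distal_equal_aortic_gives_zero(self, hemo, r50k_tree):
        assert benchtop_site_flow(
            hemo.mean_aortic_pressure_mmhg, hemo, r50k_tree, "lad"
        ) == 0.0

    def test_halving_path_resistance_doubles_flow(self, rigid_hemo):
        r_full = radius_for_resistance(50_000.0, length=10.0)
        r_half = radius_for_resistance(25_000.0, length=10.0)

        def tree_with(r):
            return CoronaryTree(
                [VesselSegment("lad", None, "LAD", 10.0, r,
                               is_measurement_site=True, site_distance_cm=10.0)]
            )

        f1 = invasive_site_flow(0.8, rigid_hemo, tree_with(r_full), "lad")
        f2 = invasive_site_flow(0.8, rigid_hemo, tree_with(r_half), "lad")
        assert f2 == pytest.approx(2 * f1, rel=1e-9)


class TestWindkesselFlowAndFfr:
    def test_single_path_site_flow_is_artery_inflow(self, hemo, chamber, states):
        tree = chain_tree(3)
        with pytest.warns(UserWarning):
            _, sol = solve_tree(tree, hemo, states["R"], chamber)
        assert windkessel_site_flow(sol, tree, "c2") == pytest.approx(
            sol.artery_inflow_cc_s("LAD"), rel=1e-12
        )

    def test_flow_proximal_to_bifurcation_is_sum_of_children(
        self, hemo, chamber, states, three_artery_tree
    ):
        _, sol = solve_tree(three_artery_tree, hemo, states["R"], chamber)
        f = sol.per_element_flow_cc_s
        assert f["seg:L0"] == pytest.approx(f["seg:L1"] + f["seg:L3"], rel=1e-9)

    def test_model_ffr_voltage_divider(self, hemo, states):
        # path resistance 100k against a distal 100k with a negligible
        # chamber block splits the source pressure in half
        r = radius_for_resistance(100_000.0, length=10.0)
        tree = CoronaryTree(
            [VesselSegment("lad", None, "LAD", 10.0, r,
                           is_measurement_site=True, site_distance_cm=10.0)]
        )
        # negligible chamber block (~2e-3 of the divider legs) that keeps the
        # conductance matrix well-conditioned
        tiny_chamber = ChamberParams(
            inherent_resistance_dyn_s_cm5={"LAD": 1e-2, "LCX": 1e-2, "RCA": 1e-2},
            V0_mm3=1e9,  # huge air cup -> chamber compliance shunt ~ 0 impedance
        )
        rigid = replace(hemo, material_area_compliance_mm2_mmhg=0.0)
        state = replace(
            states["R"],
            distal_resistance_dyn_s_cm5={"LAD": 100_000.0, "LCX": 100_000.0,
                                         "RCA": 100_000.0},
        )
        with pytest.warns(UserWarning):
            _, sol = solve_tree(tree, rigid, state, tiny_chamber)
        assert model_ffr(sol, tree, "lad") == pytest.approx(0.5, rel=1e-6)

    def test_tighter_stenosis_lowers_model_ffr(self, hemo, chamber, states):
        def ffr_at(radius):
            tree = CoronaryTree(
                [
                    VesselSegment("a", None, "LAD", 5.0, 0.2),
                    VesselSegment("b", "a", "LAD", 8.0, radius,
                                  has_stenosis=True),
                    VesselSegment("c", "b", "LAD", 4.0, 0.2,
                                  is_measurement_site=True,
                                  site_distance_cm=17.0),
                ]
            )
            with pytest.warns(UserWarning):
                _, sol = solve_tree(tree, hemo, states["R"], chamber)
            return model_ffr(sol, tree, "c")

        assert ffr_at(0.05) < ffr_at(0.08) < ffr_at(0.15) < 1.0


class TestRoundTripRecovery:
    def test_predicted_distal_pressure_recovers_windkessel_flow(
        self, hemo, chamber, states, noiseless_cohort
    ):
        _, cohort = noiseless_cohort
        tree, _ = cohort[0]
        _, sol = solve_tree(tree, hemo, states["E1"], chamber)
        for site in (s.segment_id for s in tree.measurement_sites):
            I_W = windkessel_site_flow(sol, tree, site)
            P_d = predicted_distal_pressure(sol, tree, site, hemo)
            recovered = benchtop_site_flow(
                P_d / MMHG_TO_DYN_CM2, hemo, tree, site
            )
            assert recovered == pytest.approx(I_W, rel=1e-6)

    def test_node_pressure_recovery_on_rigid_single_path(self, chamber, states,
                                                         rigid_hemo):
        """With zero wall compliance and no branching the site node pressure
        itself closes the loop: it reproduces the Windkessel flow."""
        tree = chain_tree(3, radius=0.08)
        with pytest.warns(UserWarning):
            _, sol = solve_tree(tree, rigid_hemo, states["R"], chamber)
        node_p = sol.downstream_pressure("seg:c2")
        recovered = benchtop_site_flow(
            node_p / MMHG_TO_DYN_CM2, rigid_hemo, tree, "c2"
        )
        assert recovered == pytest.approx(
            windkessel_site_flow(sol, tree, "c2"), rel=1e-9
        )


class TestActivitySweep:
    def test_cardinality_and_trend(self, hemo, chamber, ordered_states,
                                   noiseless_cohort):
        _, cohort = noiseless_cohort
        tree, meas = cohort[0]
        sites = [s.segment_id for s in tree.measurement_sites]
        reports = activity_sweep(tree, hemo, chamber, ordered_states, sites,
                                 measurements=meas)
        assert len(reports) == len(sites) * 3
        for site in sites:
            flows = [r.I_windkessel_cc_s for r in reports if r.segment_id == site]
            assert flows[0] < flows[1] < flows[2]

    def test_empty_site_list(self, hemo, chamber, ordered_states,
                             noiseless_cohort):
        _, cohort = noiseless_cohort
        tree, _ = cohort[0]
        assert activity_sweep(tree, hemo, chamber, ordered_states, []) == []

    def test_measurement_csv_roundtrip(self, tmp_path, noiseless_cohort):
        _, cohort = noiseless_cohort
        _, meas = cohort[0]
        path = tmp_path / "meas.csv"
        measurements_to_frame(meas).to_csv(path, index=False)
        back = load_measurements(path)
        assert len(back) == len(meas)
        for a, b in zip(back, meas):
            assert (a.segment_id, a.activity) == (b.segment_id, b.activity)
            assert a.invasive_ffr == pytest.approx(b.invasive_ffr, rel=1e-12)
            assert a.benchtop_distal_pressure_mmHg == pytest.approx(
                b.benchtop_distal_pressure_mmHg, rel=1e-12
            )

    def test_measurement_requires_one_value(self):
        with pytest.raises(ValueError, match="at least one"):
            SiteMeasurement("s", "R")
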