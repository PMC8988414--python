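"""Local flow determination at stenosis/measurement sites by three methods.

For a measurement site on the coronary tree the local mean flow is obtained

* from the solved Windkessel network (``I_W``): the flow through the site's
  own segment element;
* from an invasively measured FFR (``I_I``): the distal pressure is
  FFR x mean aortic pressure, and the flow is the ostium-to-site pressure
  drop divided by the cumulative path impedance;
* from a benchtop distal pressure reading (``I_B``): same formula with the
  measured pressure used directly.

The path impedance applies the cyclic-impedance magnitude to the *cumulative*
Poiseuille resistance and wall compliance of the ostium-to-site chain, so
``I_B`` at a distal pressure of FFR x P_a is identically ``I_I`` at that FFR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .circuit import FlowSolution, segment_element_id, solve_tree
from .elements import (
    ACTIVITY_ORDER,
    ActivityState,
    ChamberParams,
    HemodynamicParams,
    MMHG_TO_DYN_CM2,
    impedance,
    material_compliance_cgs,
    poiseuille_resistance,
)
from .errors import StateError
from .geometry import CoronaryTree, path_to_site

__all__ = [
    "SiteMeasurement",
    "SiteFlowReport",
    "path_impedance",
    "windkessel_site_flow",
    "invasive_site_flow",
    "benchtop_site_flow",
    "model_ffr",
    "predicted_distal_pressure",
    "activity_sweep",
    "reports_to_frame",
    "measurements_to_frame",
    "load_measurements",
]

#: FFR at or below this value flags a hemodynamically significant lesion.
FFR_SIGNIFICANCE_THRESHOLD = 0.8


@dataclass(frozen=True)
class SiteMeasurement:
    """One paired observation at a measurement site for one activity state.

    ``invasive_ffr`` is the pressure-wire distal/aortic pressure ratio
    (values slightly above 1 occur with sensor noise; hard cap 1.2).
    ``benchtop_distal_pressure_mmHg`` is the phantom's distal sensor reading.
    At least one of the two must be present.
    """

    segment_id: str
    activity: str
    invasive_ffr: float | None = None
    benchtop_distal_pressure_mmHg: float | None = None

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITY_ORDER:
            raise ValueError(f"activity must be one of {ACTIVITY_ORDER}")
        if self.invasive_ffr is None and self.benchtop_distal_pressure_mmHg is None:
            raise ValueError(
                f"site {self.segment_id}: at least one measurement required"
            )
        if self.invasive_ffr is not None and not (0 < self.invasive_ffr <= 1.2):
            raise ValueError(
                f"site {self.segment_id}: invasive_ffr must lie in (0, 1.2]"
            )
        if (
            self.benchtop_distal_pressure_mmHg is not None
            and self.benchtop_distal_pressure_mmHg <= 0
        ):
            raise ValueError(
                f"site {self.segment_id}: benchtop pressure must be positive"
            )


@dataclass(frozen=True)
class SiteFlowReport:
    """Three-method local flows at one site for one activity state."""

    model_id: str
    segment_id: str
    activity: str
    I_windkessel_cc_s: float
    model_ffr: float
    I_invasive_cc_s: float | None = None
    I_benchtop_cc_s: float | None = None
    significant: bool | None = None
    total_coronary_inflow_cc_s: float | None = None
    aortic_outlet_flow_cc_s: float | None = None


def path_impedance(
    tree: CoronaryTree, site: str, params: HemodynamicParams
) -> float:
    """Cyclic impedance of the ostium-to-site chain.

    Cumulative Poiseuille resistance of the chain, with the chain's summed
    wall compliance when ``compliance_mode`` is per-segment (in per-artery
    mode the wall compliance sits as a shunt at the artery outlet, not along
    the path, so the path is purely resistive).
    """
    chain = path_to_site(tree, site)
    R = math.fsum(
        poiseuille_resistance(params.viscosity_poise, s.length_cm, s.mean_radius_cm)
        for s in chain
    )
    if params.compliance_mode == "per_segment":
        C = len(chain) * material_compliance_cgs(
            params.material_area_compliance_mm2_mmhg
        )
    else:
        C = 0.0
    return impedance(R, C, params.cardiac_period_s)


def windkessel_site_flow(
    solution: FlowSolution, tree: CoronaryTree, site: str
) -> float:
    """Solved mean flow through the site's segment element (``I_W``)."""
    path_to_site(tree, site)  # validates the site id
    eid = segment_element_id(site)
    if eid not in solution.per_element_flow_cc_s:
        raise StateError(f"solution does not cover segment {site!r}")
    return solution.flow(eid)


def invasive_site_flow(
    ffr: float,
    params: HemodynamicParams,
    tree: CoronaryTree,
    site: str,
) -> float:
    """Local flow from an invasive FFR reading (``I_I``).

    Distal pressure is FFR x mean aortic pressure; the flow is the
    ostium-to-site pressure drop over the cumulative path impedance. FFR
    readings of 1 or more (no measurable gradient) are clamped to a zero
    drop with a warning rather than rejected.
    """
    if not (0 < ffr <= 1.2):
        raise ValueError(f"ffr must lie in (0, 1.2], got {ffr}")
    if ffr >= 1.0:
        warnings.warn(
            f"FFR {ffr:.3f} >= 1 at site {site!r}: no pressure gradient, "
            "flow clamped to 0",
            stacklevel=2,
        )
        path_to_site(tree, site)
        return 0.0
    drop = (1.0 - ffr) * params.mean_aortic_pressure_dyn_cm2
    return drop / path_impedance(tree, site, params)


def benchtop_site_flow(
    distal_pressure_mmHg: float,
    params: HemodynamicParams,
    tree: CoronaryTree,
    site: str,
) -> float:
    """Local flow from a benchtop distal pressure reading (``I_B``)."""
    if distal_pressure_mmHg <= 0:
        raise ValueError("distal pressure must be positive")
    distal = distal_pressure_mmHg * MMHG_TO_DYN_CM2
    Pa = params.mean_aortic_pressure_dyn_cm2
    if distal > Pa:
        raise ValueError(
            f"distal pressure {distal_pressure_mmHg:.2f} mmHg exceeds the "
            f"aortic pressure {Pa / MMHG_TO_DYN_CM2:.2f} mmHg"
        )
    return (Pa - distal) / path_impedance(tree, site, params)


def model_ffr(solution: FlowSolution, tree: CoronaryTree, site: str) -> float:
    """Model-predicted FFR: site downstream node pressure over source pressure."""
    path_to_site(tree, site)
    eid = segment_element_id(site)
    if eid not in solution.per_element_flow_cc_s:
        raise StateError(f"solution does not cover segment {site!r}")
    return solution.downstream_pressure(eid) / solution.source_pressure_dyn_cm2


def predicted_distal_pressure(
    solution: FlowSolution,
    tree: CoronaryTree,
    site: str,
    params: HemodynamicParams,
) -> float:
    """Distal pressure (dyn/cm^2) consistent with the path-impedance flow
    convention: P_d = P_a - I_W * Z_path.

    Feeding this pressure back into :func:`benchtop_site_flow` recovers the
    Windkessel site flow exactly; it coincides with the site's node pressure
    on single-path arteries with zero wall compliance.
    """
    I_W = windkessel_site_flow(solution, tree, site)
    Z = path_impedance(tree, site, params)
    return params.mean_aortic_pressure_dyn_cm2 - I_W * Z


def activity_sweep(
    tree: CoronaryTree,
    params: HemodynamicParams,
    chamber: ChamberParams,
    states: list[ActivityState],
    sites: list[str],
    measurements: list[SiteMeasurement] | None = None,
    model_id: str = "",
) -> list[SiteFlowReport]:
    """One report per site x state; the network is rebuilt and recalibrated
    for every state.

    When measurements are supplied, each (site, activity) pair is matched to
    at most one measurement and the invasive/benchtop flows are filled in.
    """
    by_key: dict[tuple[str, str], SiteMeasurement] = {}
    for m in measurements or []:
        by_key[(m.segment_id, m.activity)] = m

    reports: list[SiteFlowReport] = []
    for state in states:
        _, sol = solve_tree(tree, params, state, chamber)
        for site in sites:
            I_W = windkessel_site_flow(sol, tree, site)
            ffr_model = model_ffr(sol, tree, site)
            meas = by_key.get((site, state.name))
            I_I = I_B = None
            significant = None
            if meas is not None:
                if meas.invasive_ffr is not None:
                    I_I = invasive_site_flow(meas.invasive_ffr, params, tree, site)
                    significant = meas.invasive_ffr <= FFR_SIGNIFICANCE_THRESHOLD
                if meas.benchtop_distal_pressure_mmHg is not None:
                    I_B = benchtop_site_flow(
                        meas.benchtop_distal_pressure_mmHg, params, tree, site
                    )
            if significant is None:
                significant = ffr_model <= FFR_SIGNIFICANCE_THRESHOLD
            reports.append(
                SiteFlowReport(
                    model_id=model_id,
                    segment_id=site,
                    activity=state.name,
                    I_windkessel_cc_s=I_W,
                    model_ffr=ffr_model,
                    I_invasive_cc_s=I_I,
                    I_benchtop_cc_s=I_B,
                    significant=significant,
                    total_coronary_inflow_cc_s=sol.coronary_inflow_cc_s,
                    aortic_outlet_flow_cc_s=sol.aortic_outlet_flow_cc_s,
                )
            )
    return reports


# -- tabular I/O -----------------------------------------------------------


def reports_to_frame(reports: list[SiteFlowReport]) -> pd.DataFrame:
    """Site-flow reports as a table (one row per site x state)."""
    return pd.DataFrame(
        [
            {
                "model": r.model_id,
                "site": r.segment_id,
                "activity": r.activity,
                "I_invasive_cc_s": r.I_invasive_cc_s,
                "I_benchtop_cc_s": r.I_benchtop_cc_s,
                "I_windkessel_cc_s": r.I_windkessel_cc_s,
                "model_ffr": r.model_ffr,
                "significant": r.significant,
                "total_coronary_inflow_cc_s": r.total_coronary_inflow_cc_s,
                "aortic_outlet_flow_cc_s": r.aortic_outlet_flow_cc_s,
            }
            for r in reports
        ]
    )


def measurements_to_frame(measurements: list[SiteMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "segment_id": m.segment_id,
                "activity": m.activity,
                "invasive_ffr": m.invasive_ffr,
                "benchtop_distal_pressure_mmHg": m.benchtop_distal_pressure_mmHg,
            }
            for m in measurements
        ],
        columns=[
            "segment_id",
            "activity",
            "invasive_ffr",
            "benchtop_distal_pressure_mmHg",
        ],
    )


def load_measurements(path) -> list[SiteMeasurement]:
    """Read a measurement CSV (empty cell = missing value)."""
    df = pd.read_csv(path)
    expected = {
        "segment_id",
        "activity",
        "invasive_ffr",
        "benchtop_distal_pressure_mmHg",
    }
    missing = expected - set(df.columns)
    if missing:
        from .errors import FormatError

        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for rec in df.to_dict("records"):
        ffr = rec["invasive_ffr"]
        pres = rec["benchtop_distal_pressure_mmHg"]
        out.append(
            SiteMeasurement(
                segment_id=str(rec["segment_id"]),
                activity=str(rec["activity"]),
                invasive_ffr=None if pd.isna(ffr) else float(ffr),
                benchtop_distal_pressure_mmHg=None if pd.isna(pres) else float(pres),
            )
        )
    return out
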