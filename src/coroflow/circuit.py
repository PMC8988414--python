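"""Assembly and solution of the electrically-equivalent coronary network.

The vessel forest maps onto a two-terminal network between the aortic
pressure source and the venous ground:

* every vessel segment becomes one impedance element (Poiseuille resistance
  with its wall compliance folded in via the cyclic-impedance magnitude);
* children of a branching node sit in parallel, each in series with its
  parent;
* each artery's leaves drain into that artery's collection chamber — the
  chamber inherent resistance in parallel with the trapped-air compliance —
  followed in series by the activity-state distal resistance to ground;
* an aortic-outlet resistor from source to ground carries the non-coronary
  share of the total input flow, and can be calibrated in closed form so the
  source delivers exactly the configured total flow.

The analysis is steady mean-flow over impedance *magnitudes*: the network is
solved as a resistive circuit whose element values are cyclic impedances, so
Kirchhoff current/voltage laws hold exactly for the reported mean flows.
Two independent solution routes are provided — exact series/parallel graph
reduction and a general nodal (conductance-matrix) solver — and agree to
round-off on any tree-built network.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .elements import (
    ActivityState,
    ChamberParams,
    HemodynamicParams,
    impedance,
    material_compliance_cgs,
    poiseuille_resistance,
    segment_compliance,
)
from .errors import CalibrationError, StateError, TopologyError
from .geometry import Artery, CoronaryTree

__all__ = [
    "SOURCE_NODE",
    "GROUND_NODE",
    "LumpedElement",
    "CircuitNetwork",
    "FlowSolution",
    "build_network",
    "reduce_network",
    "nodal_solve",
    "calibrate_outlet",
    "solve_tree",
    "segment_element_id",
]

SOURCE_NODE = "AORTA"
GROUND_NODE = "GROUND"
OUTLET_ID = "aortic_outlet"


def segment_element_id(segment_id: str) -> str:
    return f"seg:{segment_id}"


@dataclass(frozen=True)
class LumpedElement:
    """One passive two-terminal element, oriented upstream -> downstream."""

    element_id: str
    kind: str  # "impedance" | "resistor"
    Z_dyn_s_cm5: float
    node_a: str  # upstream
    node_b: str  # downstream
    maps_to_segment: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("impedance", "resistor"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if not (self.Z_dyn_s_cm5 > 0) or not math.isfinite(self.Z_dyn_s_cm5):
            raise ValueError(
                f"element {self.element_id}: impedance must be positive and "
                f"finite, got {self.Z_dyn_s_cm5}"
            )
        if self.node_a == self.node_b:
            raise TopologyError(f"element {self.element_id}: self-loop")


@dataclass
class CircuitNetwork:
    """A two-terminal lumped network between the aortic source and ground."""

    elements: list[LumpedElement]
    source_node: str = SOURCE_NODE
    ground_node: str = GROUND_NODE

    def __post_init__(self) -> None:
        ids = [e.element_id for e in self.elements]
        if len(ids) != len(set(ids)):
            raise TopologyError("duplicate element ids in network")
        self._check_connected()

    def _check_connected(self) -> None:
        adj: dict[str, set[str]] = {}
        for e in self.elements:
            adj.setdefault(e.node_a, set()).add(e.node_b)
            adj.setdefault(e.node_b, set()).add(e.node_a)
        if self.source_node not in adj or self.ground_node not in adj:
            raise TopologyError("source or ground not attached to any element")
        seen = {self.source_node}
        stack = [self.source_node]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if self.ground_node not in seen:
            raise TopologyError("ground is not reachable from the source")
        missing = set(adj) - seen
        if missing:
            raise TopologyError(f"disconnected nodes: {sorted(missing)}")

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.elements:
            seen.setdefault(e.node_a)
            seen.setdefault(e.node_b)
        return list(seen)

    def element(self, element_id: str) -> LumpedElement:
        for e in self.elements:
            if e.element_id == element_id:
                return e
        raise KeyError(element_id)

    def has_element(self, element_id: str) -> bool:
        return any(e.element_id == element_id for e in self.elements)

    def without(self, element_id: str) -> "CircuitNetwork":
        return CircuitNetwork(
            [e for e in self.elements if e.element_id != element_id],
            self.source_node,
            self.ground_node,
        )


@dataclass
class FlowSolution:
    """Per-element mean flows and per-node pressures for one activity state.

    Flows are signed along each element's upstream->downstream orientation;
    for a passive tree-built network driven by a positive source pressure all
    flows are positive and Kirchhoff's current law holds at every internal
    node to round-off.
    """

    per_element_flow_cc_s: dict[str, float]
    per_node_pressure_dyn_cm2: dict[str, float]
    activity: str
    source_pressure_dyn_cm2: float
    element_nodes: dict[str, tuple[str, str]]
    root_segment_elements: list[str] = field(default_factory=list)
    artery_of_element: dict[str, str] = field(default_factory=dict)

    def flow(self, element_id: str) -> float:
        try:
            return self.per_element_flow_cc_s[element_id]
        except KeyError:
            raise StateError(f"no solved flow for element {element_id!r}") from None

    def pressure(self, node: str) -> float:
        return self.per_node_pressure_dyn_cm2[node]

    def downstream_pressure(self, element_id: str) -> float:
        return self.per_node_pressure_dyn_cm2[self.element_nodes[element_id][1]]

    @property
    def coronary_inflow_cc_s(self) -> float:
        return math.fsum(self.flow(e) for e in self.root_segment_elements)

    def artery_inflow_cc_s(self, artery: Artery | str) -> float:
        artery = Artery(artery).value
        return math.fsum(
            self.flow(e)
            for e in self.root_segment_elements
            if self.artery_of_element.get(e) == artery
        )

    @property
    def aortic_outlet_flow_cc_s(self) -> float:
        return self.per_element_flow_cc_s.get(OUTLET_ID, 0.0)

    @property
    def total_source_flow_cc_s(self) -> float:
        return self.coronary_inflow_cc_s + self.aortic_outlet_flow_cc_s

    def to_frame(self) -> pd.DataFrame:
        """Serializable table: one row per element with its flow and the
        pressures at its two terminals."""
        rows = []
        for eid, flow in self.per_element_flow_cc_s.items():
            na, nb = self.element_nodes[eid]
            seg = eid[4:] if eid.startswith("seg:") else ""
            rows.append(
                {
                    "element_id": eid,
                    "segment_id": seg,
                    "flow_cc_s": flow,
                    "upstream_pressure_dyn_cm2": self.per_node_pressure_dyn_cm2[na],
                    "downstream_pressure_dyn_cm2": self.per_node_pressure_dyn_cm2[nb],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "element_id",
                "segment_id",
                "flow_cc_s",
                "upstream_pressure_dyn_cm2",
                "downstream_pressure_dyn_cm2",
            ],
        )


# -- network assembly ------------------------------------------------------


def _chamber_inlet(artery: Artery) -> str:
    return f"chamber_in:{artery.value}"


def _chamber_outlet(artery: Artery) -> str:
    return f"chamber_out:{artery.value}"


def build_network(
    tree: CoronaryTree,
    params: HemodynamicParams,
    activity: ActivityState,
    chamber: ChamberParams,
    include_outlet: bool = True,
    outlet_resistance_dyn_s_cm5: float | None = None,
) -> CircuitNetwork:
    """Assemble the electrically-equivalent network for one activity state.

    One impedance element per segment; leaves of each artery drain into a
    common chamber inlet; chamber inherent resistance and trapped-air
    compliance in parallel, then the activity-state distal resistance to
    ground. If ``include_outlet``, an aortic-outlet resistor (placeholder
    value unless given; see :func:`calibrate_outlet`) spans source->ground.

    An artery named in the chamber map but absent from the tree produces a
    configuration warning and its chamber is omitted.
    """
    mu = params.viscosity_poise
    Tc = params.cardiac_period_s
    per_segment = params.compliance_mode == "per_segment"

    elements: list[LumpedElement] = []
    present = set(tree.arteries_present)
    for artery in chamber.inherent_resistance_dyn_s_cm5:
        if artery not in present:
            warnings.warn(
                f"artery {artery.value} expected by the chamber config is "
                "absent from the tree; chamber omitted",
                stacklevel=2,
            )

    has_children = {s.segment_id: bool(tree.children(s.segment_id)) for s in tree.segments}
    for seg in tree.segments:
        # a parent necessarily has children, so its downstream node is a junction
        upstream = SOURCE_NODE if seg.parent_id is None else f"n:{seg.parent_id}"
        downstream = (
            f"n:{seg.segment_id}"
            if has_children[seg.segment_id]
            else _chamber_inlet(seg.artery)
        )
        R = poiseuille_resistance(mu, seg.length_cm, seg.mean_radius_cm)
        # per-segment wall compliance is the material (area) compliance in
        # CGS, one quantum per segment, matching the units the impedance
        # formula is stated in (cm^4/dyn)
        C = (
            material_compliance_cgs(params.material_area_compliance_mm2_mmhg)
            if per_segment
            else 0.0
        )
        elements.append(
            LumpedElement(
                element_id=segment_element_id(seg.segment_id),
                kind="impedance",
                Z_dyn_s_cm5=impedance(R, C, Tc),
                node_a=upstream,
                node_b=downstream,
                maps_to_segment=seg.segment_id,
            )
        )

    C_chamber = chamber.compliance_cgs
    for artery in sorted(present, key=lambda a: a.value):
        inlet, outlet = _chamber_inlet(artery), _chamber_outlet(artery)
        elements.append(
            LumpedElement(
                f"chamber_r:{artery.value}",
                "resistor",
                chamber.inherent_resistance(artery),
                inlet,
                outlet,
            )
        )
        if C_chamber > 0:
            elements.append(
                LumpedElement(
                    f"chamber_c:{artery.value}",
                    "impedance",
                    Tc / (2.0 * math.pi * C_chamber),
                    inlet,
                    outlet,
                )
            )
        if not per_segment and params.material_area_compliance_mm2_mmhg > 0:
            # artery wall compliance lumped as a shunt across the chamber pair
            C_art = segment_compliance(
                params.material_area_compliance_mm2_mmhg,
                math.fsum(s.length_cm for s in tree.artery_segments(artery)),
            )
            elements.append(
                LumpedElement(
                    f"artery_c:{artery.value}",
                    "impedance",
                    Tc / (2.0 * math.pi * C_art),
                    inlet,
                    outlet,
                )
            )
        elements.append(
            LumpedElement(
                f"distal:{artery.value}",
                "resistor",
                activity.resistance(artery),
                outlet,
                GROUND_NODE,
            )
        )

    if include_outlet:
        if outlet_resistance_dyn_s_cm5 is None:
            # placeholder: carries the full target flow at source pressure;
            # replaced by calibrate_outlet for exact totals
            outlet_resistance_dyn_s_cm5 = (
                params.mean_aortic_pressure_dyn_cm2 / params.total_input_flow_cc_s
            )
        elements.append(
            LumpedElement(
                OUTLET_ID,
                "resistor",
                outlet_resistance_dyn_s_cm5,
                SOURCE_NODE,
                GROUND_NODE,
            )
        )

    return CircuitNetwork(elements)


# -- solution routes -------------------------------------------------------


def reduce_network(net: CircuitNetwork) -> float:
    """Equivalent impedance seen by the source, by exact series/parallel
    graph reduction (parallel-edge merging and elimination of internal
    degree-2 nodes). Falls back to the nodal solver for a topology the
    reduction cannot collapse.
    """
    edges: list[list] = [[e.node_a, e.node_b, e.Z_dyn_s_cm5] for e in net.elements]
    protected = {net.source_node, net.ground_node}

    while True:
        # merge parallel edges
        groups: dict[frozenset, list[int]] = {}
        for i, (a, b, _) in enumerate(edges):
            groups.setdefault(frozenset((a, b)), []).append(i)
        merged = False
        for pair, idxs in groups.items():
            if len(idxs) > 1:
                z = 1.0 / math.fsum(1.0 / edges[i][2] for i in idxs)
                a, b = tuple(pair)
                keep = [e for i, e in enumerate(edges) if i not in idxs]
                keep.append([a, b, z])
                edges = keep
                merged = True
                break
        if merged:
            continue

        if len(edges) == 1:
            a, b = edges[0][0], edges[0][1]
            if {a, b} == protected:
                return edges[0][2]

        # series-eliminate one internal degree-2 node
        degree: dict[str, list[int]] = {}
        for i, (a, b, _) in enumerate(edges):
            degree.setdefault(a, []).append(i)
            degree.setdefault(b, []).append(i)
        eliminated = False
        for node, idxs in degree.items():
            if node in protected or len(idxs) != 2:
                continue
            i, j = idxs
            (a1, b1, z1), (a2, b2, z2) = edges[i], edges[j]
            other1 = b1 if a1 == node else a1
            other2 = b2 if a2 == node else a2
            keep = [e for k, e in enumerate(edges) if k not in (i, j)]
            keep.append([other1, other2, z1 + z2])
            edges = keep
            eliminated = True
            break
        if not eliminated:
            break

    # non-reducible: derive the equivalent from the nodal solution
    sol = nodal_solve(net, 1.0)
    total = sol.total_source_flow_cc_s
    if total == 0 and not sol.per_element_flow_cc_s:
        raise TopologyError("cannot reduce an empty network")
    # total flow out of the source at unit pressure is the admittance
    source_flow = math.fsum(
        sol.per_element_flow_cc_s[e.element_id]
        * (1 if e.node_a == net.source_node else -1)
        for e in net.elements
        if net.source_node in (e.node_a, e.node_b)
    )
    return 1.0 / source_flow


def nodal_solve(net: CircuitNetwork, source_pressure_dyn_cm2: float,
                activity: str = "") -> FlowSolution:
    """Solve the linear conductance system with the source node held at the
    given pressure and ground at zero.

    Element flows follow the upstream->downstream orientation; Kirchhoff's
    current law holds at every internal node by construction of the
    conductance matrix.
    """
    nodes = net.nodes
    unknown = [n for n in nodes if n not in (net.source_node, net.ground_node)]
    idx = {n: i for i, n in enumerate(unknown)}

    G = np.zeros((len(unknown), len(unknown)))
    b = np.zeros(len(unknown))
    for e in net.elements:
        g = 1.0 / e.Z_dyn_s_cm5
        for n, other in ((e.node_a, e.node_b), (e.node_b, e.node_a)):
            if n not in idx:
                continue
            i = idx[n]
            G[i, i] += g
            if other in idx:
                G[i, idx[other]] -= g
            elif other == net.source_node:
                b[i] += g * source_pressure_dyn_cm2
    try:
        p = np.linalg.solve(G, b) if unknown else np.zeros(0)
    except np.linalg.LinAlgError:
        raise TopologyError("singular nodal system (floating subnetwork)") from None

    pressures = {net.source_node: source_pressure_dyn_cm2, net.ground_node: 0.0}
    pressures.update({n: float(p[idx[n]]) for n in unknown})

    flows = {
        e.element_id: (pressures[e.node_a] - pressures[e.node_b]) / e.Z_dyn_s_cm5
        for e in net.elements
    }
    root_elems = [
        e.element_id
        for e in net.elements
        if e.node_a == net.source_node and e.maps_to_segment is not None
    ]
    return FlowSolution(
        per_element_flow_cc_s=flows,
        per_node_pressure_dyn_cm2=pressures,
        activity=activity,
        source_pressure_dyn_cm2=source_pressure_dyn_cm2,
        element_nodes={e.element_id: (e.node_a, e.node_b) for e in net.elements},
        root_segment_elements=root_elems,
    )


def calibrate_outlet(net: CircuitNetwork, params: HemodynamicParams) -> CircuitNetwork:
    """Set the aortic-outlet resistance so the source delivers exactly the
    configured total input flow at the configured source pressure.

    Closed form: 1/R_out = I_target/P - 1/Z_coronary. Raises
    :class:`CalibrationError` if the coronary tree alone already draws the
    target flow or more.
    """
    if not net.has_element(OUTLET_ID):
        raise CalibrationError("network has no aortic outlet resistor")
    coronary = net.without(OUTLET_ID)
    Z_cor = reduce_network(coronary)
    P = params.mean_aortic_pressure_dyn_cm2
    I_target = params.total_input_flow_cc_s
    I_cor = P / Z_cor
    if I_cor >= I_target:
        raise CalibrationError(
            f"coronary flow {I_cor:.4f} cc/s already meets or exceeds the "
            f"target total {I_target:.4f} cc/s (excess {I_cor - I_target:.4f})"
        )
    R_out = 1.0 / (I_target / P - 1.0 / Z_cor)
    elements = [
        replace(e, Z_dyn_s_cm5=R_out) if e.element_id == OUTLET_ID else e
        for e in net.elements
    ]
    return CircuitNetwork(elements, net.source_node, net.ground_node)


def solve_tree(
    tree: CoronaryTree,
    params: HemodynamicParams,
    activity: ActivityState,
    chamber: ChamberParams,
    calibrate: bool = True,
    include_outlet: bool = True,
) -> tuple[CircuitNetwork, FlowSolution]:
    """Build, (optionally) calibrate and solve the network for one state."""
    net = build_network(tree, params, activity, chamber, include_outlet=include_outlet)
    if calibrate and include_outlet:
        net = calibrate_outlet(net, params)
    sol = nodal_solve(net, params.mean_aortic_pressure_dyn_cm2, activity=activity.name)
    sol.artery_of_element = {
        segment_element_id(s.segment_id): s.artery.value
        for s in tree.roots
    }
    return net, sol
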