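"""Element-level physics of the lumped-parameter (Windkessel) coronary model.

Hydraulic/electrical equivalences, all in CGS units:

* pressure drop [dyn/cm^2]  <->  voltage
* flow rate [cm^3/s]        <->  current
* viscous resistance [dyn*s/cm^5] <-> resistance
* volume compliance [cm^3 per dyn/cm^2 = cm^5/dyn] <-> capacitance

A vessel segment of length ``l`` and mean radius ``r`` carrying fluid of
viscosity ``mu`` has the Poiseuille resistance R = 8*mu*l/(pi*r^4). Its
compliance C (vessel wall storage) acts in parallel, giving the cyclic
impedance magnitude Z = 1/sqrt((1/R)^2 + (2*pi*C/Tc)^2) for a cardiac period
``Tc``. The distal boundary of each main artery is a collection chamber with
a fixed inherent resistance, a trapped-air (Boyle's law) compliance, and an
adjustable activity-state resistance representing the arteriolar/capillary
bed (vasodilation lowers it from rest through exercise).

Volume compliance is used everywhere; the area compliance of the vessel-wall
material (mm^2/mmHg per unit length) is converted to cm^5/dyn before use, so
that 2*pi*C/Tc is dimensionally commensurate with 1/R.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .geometry import Artery

__all__ = [
    "MMHG_TO_DYN_CM2",
    "convert_pressure",
    "poiseuille_resistance",
    "impedance",
    "chamber_compliance",
    "material_compliance_cgs",
    "segment_compliance",
    "HemodynamicParams",
    "ActivityState",
    "ChamberParams",
    "default_params",
    "default_activity_states",
    "load_params",
    "validate_state_ordering",
    "ACTIVITY_ORDER",
]

#: 1 mmHg in dyn/cm^2.
MMHG_TO_DYN_CM2 = 1333.22

#: Physiological ordering of the supported activity states: rest, light
#: exercise, moderate exercise. Distal resistance decreases along this order.
ACTIVITY_ORDER = ("R", "E1", "E2")

_DISTAL_RANGE = (50_000.0, 300_000.0)  # dyn*s/cm^5, achievable catheter range


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure between mmHg and dyn/cm^2 (1 mmHg = 1333.22 dyn/cm^2)."""
    units = {"mmHg", "dyn_cm2"}
    if from_unit not in units or to_unit not in units:
        raise ValueError(f"unknown pressure unit in ({from_unit!r}, {to_unit!r})")
    if not math.isfinite(value):
        raise ValueError("pressure must be finite")
    if from_unit == to_unit:
        return value
    if from_unit == "mmHg":
        return value * MMHG_TO_DYN_CM2
    return value / MMHG_TO_DYN_CM2


def poiseuille_resistance(mu: float, l: float, r: float) -> float:
    """Viscous resistance of laminar flow in a rigid tube, R = 8*mu*l/(pi*r^4).

    Parameters are in poise, cm, cm; the result is in dyn*s/cm^5. The r^-4
    dependence is what makes a stenosis (reduced mean radius) dominate the
    resistance of its artery.
    """
    if mu < 0 or l < 0 or r < 0:
        raise ValueError("viscosity, length and radius must be non-negative")
    if mu == 0 or l == 0:
        raise ValueError("viscosity and length must be positive")
    if r == 0:
        raise ValueError("radius 0 gives infinite resistance (domain error)")
    return 8.0 * mu * l / (math.pi * r**4)


def impedance(R: float, C: float, Tc: float) -> float:
    """Cyclic impedance magnitude of a resistance R with parallel compliance C.

    Z = 1/sqrt((1/R)^2 + (2*pi*C/Tc)^2); Z -> R as C -> 0 and
    Z -> Tc/(2*pi*C) as R -> inf, and Z <= min(R, Tc/(2*pi*C)) always.
    """
    if Tc <= 0:
        raise ValueError("cardiac period must be positive")
    if R <= 0:
        raise ValueError("resistance must be positive")
    if C < 0:
        raise ValueError("compliance must be non-negative")
    if C == 0:
        return R
    return 1.0 / math.hypot(1.0 / R, 2.0 * math.pi * C / Tc)


def chamber_compliance(P0: float, V0: float, Ps: float, Pd: float) -> float:
    """Compliance of a trapped-air chamber between systole and diastole.

    Boyle's law (P*V constant at P0, V0) eliminates the two volumes:
    C = P0*V0*(1/Pd - 1/Ps)/(Ps - Pd), in mm^3/mmHg for inputs in mmHg/mm^3.
    As Ps -> Pd the expression tends to P0*V0/Pd^2.
    """
    if P0 <= 0 or V0 <= 0:
        raise ValueError("P0 and V0 must be positive")
    if not (Ps > Pd > 0):
        raise ValueError("require systolic > diastolic pressure > 0")
    return P0 * V0 * (1.0 / Pd - 1.0 / Ps) / (Ps - Pd)


def material_compliance_cgs(area_compliance_mm2_mmhg: float) -> float:
    """Wall-material area compliance converted to CGS (cm^4/dyn, i.e. cm^2
    per dyn/cm^2).

    This is the compliance quantity that enters the cyclic-impedance formula
    for a vessel segment: one material compliance per segment, independent of
    segment length (numerically equal to the volume compliance of 1 cm of
    vessel). 1 mm^2 = 0.01 cm^2, 1 mmHg = 1333.22 dyn/cm^2.
    """
    if area_compliance_mm2_mmhg < 0:
        raise ValueError("area compliance must be non-negative")
    return area_compliance_mm2_mmhg * 0.01 / MMHG_TO_DYN_CM2


def segment_compliance(area_compliance_mm2_mmhg: float, length_cm: float) -> float:
    """Volume compliance of a vessel segment from its wall-material area
    compliance, converted to CGS (cm^5/dyn).

    C_vol = (area compliance per unit length) * length;
    1 mm^2 = 0.01 cm^2 and 1 mmHg = 1333.22 dyn/cm^2. This dimensionally
    consistent volume form describes the wall's total pulsatile volume
    storage and is used where that storage is lumped as a shunt (the
    per-artery compliance mode); the per-segment impedance itself takes the
    material (area) compliance, see :func:`material_compliance_cgs`.
    """
    if area_compliance_mm2_mmhg < 0 or length_cm < 0:
        raise ValueError("compliance and length must be non-negative")
    return area_compliance_mm2_mmhg * 0.01 * length_cm / MMHG_TO_DYN_CM2


# -- parameter containers --------------------------------------------------


def _artery_map(value: dict) -> dict[Artery, float]:
    return {Artery(k): float(v) for k, v in value.items()}


@dataclass(frozen=True)
class HemodynamicParams:
    """Global haemodynamic constants of one model run.

    Defaults: working-fluid viscosity 0.037 poise (3.7 cP, the 40% glycerol
    blood analogue), mean aortic pressure 100 mmHg, cardiac period 0.8 s
    (75 bpm), total aortic-root inflow 8.33 cc/s, and a wall-material area
    compliance of 0.0975 mm^2/mmHg (midpoint of the flexible-photopolymer
    range 0.075-0.120).
    """

    viscosity_poise: float = 0.037
    mean_aortic_pressure_dyn_cm2: float = 100.0 * MMHG_TO_DYN_CM2
    cardiac_period_s: float = 0.8
    total_input_flow_cc_s: float = 8.33
    material_area_compliance_mm2_mmhg: float = 0.0975
    #: "per_segment": each segment element carries its own wall compliance;
    #: "per_artery": segments are purely resistive and the artery's total
    #: wall compliance is lumped at its outlet.
    compliance_mode: str = "per_segment"

    def __post_init__(self) -> None:
        for name in (
            "viscosity_poise",
            "mean_aortic_pressure_dyn_cm2",
            "cardiac_period_s",
            "total_input_flow_cc_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.material_area_compliance_mm2_mmhg < 0:
            raise ValueError("material_area_compliance_mm2_mmhg must be >= 0")
        if self.compliance_mode not in ("per_segment", "per_artery"):
            raise ValueError(f"unknown compliance_mode {self.compliance_mode!r}")

    @property
    def mean_aortic_pressure_mmhg(self) -> float:
        return self.mean_aortic_pressure_dyn_cm2 / MMHG_TO_DYN_CM2


@dataclass(frozen=True)
class ActivityState:
    """Distal (arteriolar/capillary bed) resistance per artery for one
    activity level: R (rest), E1 (light exercise) or E2 (moderate exercise)."""

    name: str
    distal_resistance_dyn_s_cm5: dict[Artery, float]

    def __post_init__(self) -> None:
        if self.name not in ACTIVITY_ORDER:
            raise ValueError(f"activity name must be one of {ACTIVITY_ORDER}")
        object.__setattr__(
            self,
            "distal_resistance_dyn_s_cm5",
            _artery_map(self.distal_resistance_dyn_s_cm5),
        )
        lo, hi = _DISTAL_RANGE
        for artery, res in self.distal_resistance_dyn_s_cm5.items():
            if not (lo <= res <= hi):
                raise ValueError(
                    f"distal resistance for {artery.value} in state "
                    f"{self.name} must lie in [{lo:g}, {hi:g}] dyn*s/cm^5, "
                    f"got {res:g}"
                )

    def resistance(self, artery: Artery | str) -> float:
        return self.distal_resistance_dyn_s_cm5[Artery(artery)]


@dataclass(frozen=True)
class ChamberParams:
    """Distal three-chamber boundary: fixed inherent resistances per artery
    and the trapped-air compliance constants (P0 = 1 atm, V0 = air-cup
    volume), evaluated between systolic and diastolic chamber pressures."""

    inherent_resistance_dyn_s_cm5: dict[Artery, float] = field(
        default_factory=lambda: {
            Artery.LAD: 1671.0,
            Artery.LCX: 1820.0,
            Artery.RCA: 591.0,
        }
    )
    P0_mmHg: float = 760.0
    V0_mm3: float = 4.4e4
    Ps_mmHg: float = 120.0
    Pd_mmHg: float = 80.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "inherent_resistance_dyn_s_cm5",
            _artery_map(self.inherent_resistance_dyn_s_cm5),
        )
        if not (self.Ps_mmHg > self.Pd_mmHg > 0):
            raise ValueError("require Ps_mmHg > Pd_mmHg > 0")
        if self.P0_mmHg <= 0 or self.V0_mm3 <= 0:
            raise ValueError("P0_mmHg and V0_mm3 must be positive")

    def inherent_resistance(self, artery: Artery | str) -> float:
        return self.inherent_resistance_dyn_s_cm5[Artery(artery)]

    @property
    def compliance_mm3_mmhg(self) -> float:
        return chamber_compliance(
            self.P0_mmHg, self.V0_mm3, self.Ps_mmHg, self.Pd_mmHg
        )

    @property
    def compliance_cgs(self) -> float:
        """Chamber compliance in cm^5/dyn (1 mm^3 = 1e-3 cm^3)."""
        return self.compliance_mm3_mmhg * 1e-3 / MMHG_TO_DYN_CM2


def validate_state_ordering(states: dict[str, ActivityState]) -> None:
    """Check that distal resistance strictly decreases with activity
    (R > E1 > E2) for every artery present in all given states."""
    ordered = [states[n] for n in ACTIVITY_ORDER if n in states]
    for a, b in zip(ordered, ordered[1:]):
        for artery in a.distal_resistance_dyn_s_cm5:
            if artery in b.distal_resistance_dyn_s_cm5:
                if not a.resistance(artery) > b.resistance(artery):
                    raise ValueError(
                        f"distal resistance must decrease with activity: "
                        f"{artery.value} {a.name} <= {b.name}"
                    )


# -- configuration files ---------------------------------------------------


def _params_from_mapping(cfg: dict) -> tuple[
    HemodynamicParams, ChamberParams, dict[str, ActivityState]
]:
    hemo = HemodynamicParams(**cfg.get("hemodynamic", {}))
    chamber_cfg = dict(cfg.get("chamber", {}))
    chamber = ChamberParams(**chamber_cfg)
    states = {
        name: ActivityState(name, _artery_map(res))
        for name, res in cfg.get("activity", {}).items()
    }
    if states:
        validate_state_ordering(states)
    return hemo, chamber, states


def load_params(path: str | Path) -> tuple[
    HemodynamicParams, ChamberParams, dict[str, ActivityState]
]:
    """Load a TOML or JSON parameter config.

    Keys mirror the dataclass fields under three tables: ``[hemodynamic]``,
    ``[chamber]`` (with sub-table ``inherent_resistance_dyn_s_cm5``) and
    ``[activity.<R|E1|E2>]`` mapping artery to distal resistance.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            cfg = json.load(fh)
    else:
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
    return _params_from_mapping(cfg)


def _default_config() -> dict:
    data = resources.files("coroflow.data").joinpath("params.default.toml")
    return tomllib.loads(data.read_text(encoding="utf-8"))


def default_params() -> tuple[HemodynamicParams, ChamberParams]:
    """The shipped default hemodynamic and chamber parameters."""
    hemo, chamber, _ = _params_from_mapping(_default_config())
    return hemo, chamber


def default_activity_states() -> dict[str, ActivityState]:
    """Shipped default distal resistances per activity state.

    R = 250,000, E1 = 120,000, E2 = 60,000 dyn*s/cm^5 for every artery — all
    inside the achievable catheter range (50,000-300,000) and strictly
    decreasing with activity.
    """
    _, _, states = _params_from_mapping(_default_config())
    return states
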