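"""Synthetic patient-like coronary trees and noisy measurements.

The generator emulates the study conditions: a cohort of five coronary
systems with main-vessel diameters of 3-5 mm, a handful of daughter branches
per artery, and one diseased segment with a distal measurement site on each
of the LAD and LCX (the RCA is generated healthy, with no site).

Topology per artery: a proximal main trunk (root segment, then — for
diseased arteries — the stenosed segment and the measurement-site segment),
followed by a cascade of bifurcations where a daughter leaf branches off and
the trunk continues, both children tapering by the symmetric Murray factor
2^(-1/3). Placing the lesion and site on the proximal trunk, upstream of all
branching, reflects the common clinically significant phenotype
(proximal-vessel disease) and means the site flow is the artery inflow.

Synthetic "sensor" measurements are derived from the solved network: the
site's path-impedance-consistent distal pressure P_d = P_a - I_W * Z_path is
the ground truth; the invasive FFR is P_d/P_a plus Gaussian noise (clamped
to (0, 1.2]) and the benchtop reading is P_d in mmHg plus Gaussian noise.
With both noise SDs at zero the three flow methods agree identically.

Everything is driven by ``numpy.random.default_rng`` seeded from
``(seed, model_index, stream)``, so any tree or measurement set is
bit-reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circuit import solve_tree
from .elements import ActivityState, ChamberParams, HemodynamicParams, MMHG_TO_DYN_CM2
from .flow import SiteMeasurement, predicted_distal_pressure
from .geometry import Artery, CoronaryTree, VesselSegment

__all__ = ["SynthConfig", "generate_tree", "generate_measurements",
           "generate_cohort", "random_tree"]

_MURRAY = 2.0 ** (-1.0 / 3.0)  # symmetric-bifurcation radius taper


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generation settings.

    ``stenosis_radius_reduction`` is the fractional reduction of the mean
    lumen radius at the lesion (0.65 = severe, ~88% area stenosis — the
    predominant phenotype of the emulated cohort, where 7 of 10 lesions were
    hemodynamically significant); a small deterministic per-site jitter
    (+/- 0.04) spreads severity across models. The lesion segment's length is
    drawn from the upper half of ``length_range_cm`` (diffuse disease along
    the proximal vessel, whose mean radius is averaged along the lesion), so
    that ostium-to-site path impedances land in the tens of thousands of
    dyn*s/cm^5 — the regime implied by clinically observed severe-lesion
    flows (a rest flow of ~0.4 cc/s at FFR 0.8 and 100 mmHg corresponds to
    ~67,000 dyn*s/cm^5). Noise SDs describe the synthetic invasive FFR wire
    and benchtop pressure sensor.
    """

    n_models: int = 5
    seed: int = 0
    main_diameter_range_mm: tuple[float, float] = (3.0, 5.0)
    daughter_count_range: tuple[int, int] = (2, 5)
    length_range_cm: tuple[float, float] = (2.0, 12.0)
    stenosis_radius_reduction: float = 0.65
    ffr_noise_sd: float = 0.03
    pressure_noise_sd_mmHg: float = 2.0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        for name in ("main_diameter_range_mm", "daughter_count_range",
                     "length_range_cm"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be well-ordered")
        if not (0.2 < self.stenosis_radius_reduction < 0.7):
            raise ValueError("stenosis_radius_reduction must lie in (0.2, 0.7)")
        if self.ffr_noise_sd < 0 or self.pressure_noise_sd_mmHg < 0:
            raise ValueError("noise SDs must be non-negative")


def _rng(config: SynthConfig, model_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, model_index, stream])


def _artery_segments(
    rng: np.random.Generator,
    config: SynthConfig,
    model_index: int,
    artery: Artery,
    diseased: bool,
) -> list[VesselSegment]:
    d_lo, d_hi = config.main_diameter_range_mm
    r_main = rng.uniform(d_lo, d_hi) / 2.0 / 10.0  # diameter mm -> radius cm
    n_daughters = int(rng.integers(config.daughter_count_range[0],
                                   config.daughter_count_range[1] + 1))
    lengths = rng.uniform(*config.length_range_cm, size=3 + n_daughters + n_daughters)
    prefix = f"p{model_index}_{artery.value}"

    segs: list[VesselSegment] = []
    trunk_radius = r_main
    parent: str | None = None
    cum_length = 0.0

    def add_trunk(idx: int, radius: float, stenosed: bool, site: bool,
                  length: float | None = None) -> str:
        nonlocal parent, cum_length
        if length is None:
            length = float(lengths[len(segs)])
        cum_length += length
        seg_id = f"{prefix}_m{idx}"
        segs.append(
            VesselSegment(
                segment_id=seg_id,
                parent_id=parent,
                artery=artery,
                length_cm=length,
                mean_radius_cm=radius,
                has_stenosis=stenosed,
                is_measurement_site=site,
                site_distance_cm=cum_length if site else None,
            )
        )
        parent = seg_id
        return seg_id

    trunk_idx = 0
    add_trunk(trunk_idx, r_main, False, False)
    if diseased:
        jitter = float(rng.uniform(-0.04, 0.04))
        reduction = min(0.69, max(0.21, config.stenosis_radius_reduction + jitter))
        l_lo, l_hi = config.length_range_cm
        lesion_length = float(rng.uniform((l_lo + l_hi) / 2.0, l_hi))
        trunk_idx += 1
        add_trunk(trunk_idx, r_main * (1.0 - reduction), True, False,
                  length=lesion_length)
        trunk_idx += 1
        add_trunk(trunk_idx, r_main, False, True)

    # distal bifurcation cascade: at each junction a daughter leaf branches
    # off and the trunk continues, both tapering by 2^(-1/3)
    for j in range(n_daughters):
        junction_parent = parent
        trunk_radius = trunk_radius * _MURRAY
        segs.append(
            VesselSegment(
                segment_id=f"{prefix}_d{j}",
                parent_id=junction_parent,
                artery=artery,
                length_cm=float(lengths[len(segs)]),
                mean_radius_cm=trunk_radius,
            )
        )
        trunk_idx += 1
        add_trunk(trunk_idx, trunk_radius, False, False)
    return segs


def generate_tree(config: SynthConfig, model_index: int) -> CoronaryTree:
    """One synthetic patient coronary tree, deterministic in
    ``(config.seed, model_index)``. LAD and LCX carry a stenosis with a
    distal measurement site; the RCA is healthy."""
    rng = _rng(config, model_index, 0)
    segments: list[VesselSegment] = []
    for artery in (Artery.LAD, Artery.LCX, Artery.RCA):
        segments.extend(
            _artery_segments(
                rng, config, model_index, artery, diseased=artery is not Artery.RCA
            )
        )
    return CoronaryTree(segments)


def generate_measurements(
    tree: CoronaryTree,
    params: HemodynamicParams,
    chamber: ChamberParams,
    states: list[ActivityState],
    config: SynthConfig,
    model_index: int = 0,
) -> list[SiteMeasurement]:
    """Noisy synthetic invasive-FFR and benchtop-pressure readings for every
    measurement site and activity state, with ground truth taken from the
    solved Windkessel network."""
    rng = _rng(config, model_index, 1)
    sites = [s.segment_id for s in tree.measurement_sites]
    Pa = params.mean_aortic_pressure_dyn_cm2
    out: list[SiteMeasurement] = []
    for state in states:
        _, sol = solve_tree(tree, params, state, chamber)
        for site in sites:
            P_d = predicted_distal_pressure(sol, tree, site, params)
            ffr_true = P_d / Pa
            ffr = ffr_true + rng.normal(0.0, config.ffr_noise_sd)
            ffr = float(min(1.2, max(1e-6, ffr)))
            p_mmhg = P_d / MMHG_TO_DYN_CM2 + rng.normal(
                0.0, config.pressure_noise_sd_mmHg
            )
            p_mmhg = float(
                min(params.mean_aortic_pressure_mmhg, max(1e-6, p_mmhg))
            )
            out.append(
                SiteMeasurement(
                    segment_id=site,
                    activity=state.name,
                    invasive_ffr=ffr,
                    benchtop_distal_pressure_mmHg=p_mmhg,
                )
            )
    return out


def generate_cohort(
    config: SynthConfig,
    params: HemodynamicParams,
    chamber: ChamberParams,
    states: list[ActivityState],
) -> list[tuple[CoronaryTree, list[SiteMeasurement]]]:
    """The full synthetic cohort: ``n_models`` trees with their measurements."""
    return [
        (
            tree := generate_tree(config, i),
            generate_measurements(tree, params, chamber, states, config, i),
        )
        for i in range(config.n_models)
    ]


def random_tree(
    rng: np.random.Generator, max_segments: int = 30
) -> CoronaryTree:
    """A random valid coronary forest for property testing: random topology
    (each new segment attaches to the aortic root or to any earlier segment
    of its artery), random calibers and lengths. Not anatomically shaped —
    exercises the solver on arbitrary tree circuits."""
    n = int(rng.integers(1, max_segments + 1))
    arteries = [Artery(a) for a in rng.choice(["LAD", "LCX", "RCA"], size=n)]
    segments: list[VesselSegment] = []
    by_artery: dict[Artery, list[str]] = {a: [] for a in Artery}
    for i, artery in enumerate(arteries):
        prior = by_artery[artery]
        attach_root = not prior or rng.random() < 0.3
        parent = None if attach_root else str(rng.choice(prior))
        seg_id = f"s{i}"
        segments.append(
            VesselSegment(
                segment_id=seg_id,
                parent_id=parent,
                artery=artery,
                length_cm=float(rng.uniform(0.5, 12.0)),
                mean_radius_cm=float(rng.uniform(0.04, 0.25)),
            )
        )
        by_artery[artery].append(seg_id)
    return CoronaryTree(segments)
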