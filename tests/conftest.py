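import math

import pytest

from coroflow import (
    ActivityState,
    CoronaryTree,
    SynthConfig,
    VesselSegment,
    default_activity_states,
    default_params,
)

ACTIVITIES = ("R", "E1", "E2")


@pytest.fixture(scope="session")
def hemo():
    return default_params()[0]


@pytest.fixture(scope="session")
def chamber():
    return default_params()[1]


@pytest.fixture(scope="session")
def states():
    return default_activity_states()


@pytest.fixture(scope="session")
def ordered_states(states):
    return [states[n] for n in ACTIVITIES]


def chain_tree(n, artery="LAD", length=10.0, radius=0.1, site_on_last=True,
               prefix="c"):
    """A branch-free single-artery chain of n segments."""
    segs = []
    for i in range(n):
        segs.append(
            VesselSegment(
                segment_id=f"{prefix}{i}",
                parent_id=None if i == 0 else f"{prefix}{i - 1}",
                artery=artery,
                length_cm=length,
                mean_radius_cm=radius,
                is_measurement_site=site_on_last and i == n - 1,
                site_distance_cm=length * n if site_on_last and i == n - 1 else None,
            )
        )
    return CoronaryTree(segs)


def radius_for_resistance(R, mu=0.037, length=10.0):
    """Radius giving a prescribed Poiseuille resistance at fixed mu, l."""
    return (8.0 * mu * length / (math.pi * R)) ** 0.25


@pytest.fixture
def three_artery_tree():
    """Nine segments: LAD subtree of 4 (with a 3rd-generation site), LCX of
    3, RCA of 2."""

    def seg(sid, parent, artery, site=False, dist=None, radius=0.15):
        return VesselSegment(
            segment_id=sid,
            parent_id=parent,
            artery=artery,
            length_cm=4.0,
            mean_radius_cm=radius,
            is_measurement_site=site,
            site_distance_cm=dist,
        )

    return CoronaryTree(
        [
            seg("L0", None, "LAD"),
            seg("L1", "L0", "LAD"),
            seg("L2", "L1", "LAD", site=True, dist=12.0),
            seg("L3", "L0", "LAD", radius=0.10),
            seg("X0", None, "LCX"),
            seg("X1", "X0", "LCX", radius=0.10),
            seg("X2", "X0", "LCX", radius=0.10),
            seg("R0", None, "RCA"),
            seg("R1", "R0", "RCA"),
        ]
    )


@pytest.fixture(scope="session")
def noiseless_cohort(hemo, chamber, ordered_states):
    """Five synthetic models with noise-free measurements (shared across
    tests; generation is deterministic)."""
    from coroflow import generate_cohort

    config = SynthConfig(seed=1, ffr_noise_sd=0.0, pressure_noise_sd_mmHg=0.0)
    return config, generate_cohort(config, hemo, chamber, ordered_states)
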