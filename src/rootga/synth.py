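"""Synthetic biosensor datasets and wild-type fixtures.

The generator emulates the statistical structure of nuclear-localized GA4
biosensor measurements in the root growth zone: nuclei scattered over
0–500 μm from the tip, an emission ratio drawn from a known model
parameterization through the titration curve, and additive Gaussian
measurement noise on the ratio (noise acts on fluorescence ratios, not on
concentrations).  Datasets are fully reproducible from (parameters, seed)
and carry their generating truth in a JSON sidecar, which is what the
parameter-recovery experiments rely on.

The enzyme-activity and growth fixtures encode the documented wild-type
shapes: GA3ox low in the division zone and higher shootward, GA9/GA4
catabolism elevated in the elongation/maturation zones, and a relative
elongation rate that is low and flat in the meristem, ramps through the
EZ and vanishes at maturation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .growth import ez_kinematics
from .params import (
    EnzymeActivityProfile,
    GrowthProfile,
    ModelParams,
    ScenarioConfig,
    Zone,
    ZoneMap,
)
from .profiles import EmissionProfile, SteadyProfile
from .sensor import emission_ratio

__all__ = [
    "NoiseModel",
    "generate_emission_dataset",
    "make_fixture_enzyme_profile",
    "make_fixture_growth",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement model of a synthetic biosensor dataset."""

    sigma_ratio: float = 0.05      # additive Gaussian s.d. on the ratio
    nuclei_density: float = 60.0   # nuclei per 100 μm (used when n is not given)
    position_jitter: float = 0.0   # μm
    x_max: float = 500.0           # μm from the tip

    def __post_init__(self) -> None:
        if min(self.sigma_ratio, self.nuclei_density, self.position_jitter) < 0:
            raise ValueError("noise parameters must be >= 0")


def generate_emission_dataset(
    params: ModelParams,
    scenario: ScenarioConfig | None = None,
    noise: NoiseModel = NoiseModel(),
    n_nuclei: int | None = None,
    seed: int = 0,
    profile: SteadyProfile | None = None,
    solver: str = "continuum",
) -> EmissionProfile:
    """Solve the model and sample a noisy per-nucleus emission dataset.

    Nucleus positions are uniform on [0, x_max] plus optional jitter
    (positions pooled across cell layers); ratios are the titration curve
    evaluated on the GA4 field plus N(0, sigma_ratio²) noise.  A
    precomputed ``profile`` skips the solve.
    """
    from .scenarios import effective_params, run_scenario

    if profile is None:
        profile, _ = run_scenario(params, scenario, solver=solver)
    eff = effective_params(params, scenario)
    rng = np.random.default_rng(seed)
    if n_nuclei is None:
        n_nuclei = int(round(noise.nuclei_density * noise.x_max / 100.0))
    x = rng.uniform(0.0, noise.x_max, size=n_nuclei)
    if noise.position_jitter > 0:
        x = np.clip(x + rng.normal(0.0, noise.position_jitter, size=n_nuclei),
                    0.0, noise.x_max)
    ratio = emission_ratio(profile.interp(x), eff.sensor)
    if noise.sigma_ratio > 0:
        ratio = ratio + rng.normal(0.0, noise.sigma_ratio, size=n_nuclei)
    return EmissionProfile(
        x=x,
        ratio=ratio,
        sensor=eff.sensor.name,
        label=scenario.name if scenario else "wildtype",
        seed=seed,
        truth={
            "s_qcz": eff.supply.s_qcz,
            "d_phloem": eff.supply.d_phloem,
            "delta12": eff.catabolism.delta12,
            "delta9": eff.catabolism.delta9,
            "delta4": eff.catabolism.delta4,
            "sigma_ratio": noise.sigma_ratio,
        },
    )


def make_fixture_enzyme_profile() -> EnzymeActivityProfile:
    """Documented wild-type relative enzyme activities per zone.

    Shape constraints encoded: GA3ox is low in the DZ and rises shootward;
    GA9/GA4-directed GA2ox activity is elevated in the EZ and MZ.  The
    numbers are a transcript-shaped fixture, not measurements.
    """
    return EnzymeActivityProfile(
        ga20ox={Zone.QCZ: 0.6, Zone.DZ: 0.3, Zone.EZ: 1.0, Zone.MZ: 0.4},
        ga3ox={Zone.QCZ: 0.4, Zone.DZ: 0.15, Zone.EZ: 1.0, Zone.MZ: 0.8},
        ga2ox_ga12={Zone.QCZ: 0.9, Zone.DZ: 0.9, Zone.EZ: 1.0, Zone.MZ: 1.2},
        ga2ox_ga9ga4={Zone.QCZ: 0.9, Zone.DZ: 0.9, Zone.EZ: 1.0, Zone.MZ: 1.5},
    )


def make_fixture_growth(
    zones: ZoneMap | None = None,
    meristem_rer: float = 0.05,
) -> tuple[GrowthProfile, tuple[float, float]]:
    """Wild-type growth fixture: RER field and meristem birth lengths.

    The EZ relative elongation rate is tabulated from the self-consistent
    transit kinematics (cytoplasm at the meristem rate, vacuole five times
    faster), so it is low and constant in the meristem, ramps through the
    EZ and is zero in the MZ.  Returns (profile, (birth_min, birth_max)).
    """
    if zones is None:
        zones = ZoneMap()
    base = GrowthProfile(meristem_rer=meristem_rer)
    kin = ez_kinematics(base, zones)
    profile = replace(base, ez_rer_x=kin["x"], ez_rer=kin["rer"])
    return profile, (4.0, 10.0)
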