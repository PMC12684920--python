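"""Structured run configuration: YAML schema, validation and builders.

Every block is optional and defaults to the wild-type fixture; unknown
keys are rejected so typos fail loudly before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .params import (
    CatabolismRates,
    EnzymeActivityProfile,
    IonizationParams,
    MembranePermeabilities,
    ModelParams,
    PathwayKinetics,
    PlasmodesmataParams,
    ScenarioConfig,
    SENSOR_CALIBRATIONS,
    SensorCalibration,
    StepKinetics,
    SupplyRates,
    Zone,
    ZoneMap,
)
from .synth import NoiseModel, make_fixture_enzyme_profile, make_fixture_growth

__all__ = ["RunConfig", "load_config", "ConfigError", "config_hash"]


class ConfigError(ValueError):
    pass


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ZonesBlock(_Block):
    qcz_end: float = 43.0
    dz_end: float = 240.0
    ez_end: float = 950.0
    domain_end: float = 1100.0


class GrowthBlock(_Block):
    meristem_rer: float = 0.05
    vac_rgr_multiple: float = 5.0
    meristem_vac_fraction: float = 0.35


class ZoneTable(_Block):
    qcz: float
    dz: float
    ez: float
    mz: float

    def as_dict(self) -> dict[Zone, float]:
        return {Zone.QCZ: self.qcz, Zone.DZ: self.dz, Zone.EZ: self.ez, Zone.MZ: self.mz}


class EnzymesBlock(_Block):
    ga20ox: ZoneTable
    ga3ox: ZoneTable
    ga2ox_ga12: ZoneTable
    ga2ox_ga9ga4: ZoneTable


class StepBlock(_Block):
    vmax: float
    km: float


class KineticsBlock(_Block):
    ga20ox: list[StepBlock] = Field(default_factory=lambda: [StepBlock(vmax=150, km=100)] * 3)
    ga3ox: StepBlock = StepBlock(vmax=60, km=150)

    @field_validator("ga20ox")
    @classmethod
    def _three_steps(cls, v):
        if len(v) != 3:
            raise ValueError("ga20ox needs exactly 3 steps")
        return v


class CatabolismBlock(_Block):
    delta12: float = 0.4
    delta9: float = 0.4
    delta4: float = 0.4


class IonizationBlock(_Block):
    ph_apoplast: float = 5.3
    ph_cytoplasm: float = 7.2
    ph_vacuole: float = 5.5
    pka: list[float] = Field(default_factory=lambda: [4.2] * 5)


class MembranesBlock(_Block):
    p_passive_pm: list[float] = Field(default_factory=lambda: [360.0, 360.0, 36.0, 360.0, 36.0])
    p_passive_ton: list[float] = Field(default_factory=lambda: [360.0, 360.0, 36.0, 360.0, 36.0])
    p_npf_influx: list[float] = Field(default_factory=lambda: [3.6, 3.6, 36.0, 3.6, 36.0])
    p_npf214: list[float] = Field(default_factory=lambda: [0.36, 0.36, 3.6, 0.36, 3.6])


class PlasmodesmataBlock(_Block):
    p_plas: float = 180.0
    ez_factor: float = 1.0


class SupplyBlock(_Block):
    s_qcz: float = 3.0
    d_phloem: float = 150.0
    d_apo: float = 1.0e5
    apoplast_area_fraction: float = 0.02


class SensorBlock(_Block):
    name: str = "nlsGPS1"
    r_min: Optional[float] = None
    r_max: Optional[float] = None
    kd: Optional[float] = None
    hill: Optional[float] = None


class GeometryBlock(_Block):
    cross_area: float = 200.0
    wall_thickness: float = 0.2
    tonoplast_area_factor: float = 2.0
    birth_length_min: float = 4.0
    birth_length_max: float = 10.0


class NoiseBlock(_Block):
    sigma_ratio: float = 0.05
    nuclei_density: float = 60.0
    position_jitter: float = 0.0
    x_max: float = 500.0


class ScenarioBlock(_Block):
    oe: dict[str, float] = Field(default_factory=dict)
    lof: list[str] = Field(default_factory=list)
    inactivation_mode: str = "none"
    inactivation_region: str = "DZ"
    pplas_factor: float = 1.0
    pplas_ez_factor: Optional[float] = None
    npf_influx_on: bool = True
    npf214_on: bool = True
    s_qcz_factor: float = 1.0
    d_phloem_factor: float = 1.0
    uniform_supply: bool = False
    uniform_enzymes: bool = False
    rer_factor: float = 1.0
    ga2ox_hept: bool = False


class SurveyBlock(_Block):
    s_qcz: list[float]
    d_phloem: list[float]
    delta12: list[float]
    delta9: list[float]
    delta4: list[float]


class RunConfig(_Block):
    """Validated top-level configuration for the CLI and scripts."""

    zones: ZonesBlock = ZonesBlock()
    growth: GrowthBlock = GrowthBlock()
    enzymes: Optional[EnzymesBlock] = None     # default: wild-type fixture
    kinetics: KineticsBlock = KineticsBlock()
    catabolism: CatabolismBlock = CatabolismBlock()
    ionization: IonizationBlock = IonizationBlock()
    membranes: MembranesBlock = MembranesBlock()
    plasmodesmata: PlasmodesmataBlock = PlasmodesmataBlock()
    supply: SupplyBlock = SupplyBlock()
    sensor: SensorBlock = SensorBlock()
    geometry: GeometryBlock = GeometryBlock()
    noise: NoiseBlock = NoiseBlock()
    scenarios: dict[str, ScenarioBlock] = Field(default_factory=dict)
    survey: Optional[SurveyBlock] = None
    solver: str = "continuum"
    seed: int = 0
    output_dir: str = "rootga_out"
    verbosity: int = 1

    @field_validator("solver")
    @classmethod
    def _solver_ok(cls, v):
        if v not in ("continuum", "discrete"):
            raise ValueError("solver must be continuum|discrete")
        return v

    # ---- builders -------------------------------------------------------

    def to_params(self) -> ModelParams:
        z = ZoneMap(**self.zones.model_dump())
        growth_fixture, _ = make_fixture_growth(
            zones=z, meristem_rer=self.growth.meristem_rer
        )
        growth = growth_fixture.__class__(
            meristem_rer=self.growth.meristem_rer,
            vac_rgr_multiple=self.growth.vac_rgr_multiple,
            meristem_vac_fraction=self.growth.meristem_vac_fraction,
            ez_rer_x=growth_fixture.ez_rer_x,
            ez_rer=growth_fixture.ez_rer,
        )
        if self.enzymes is None:
            enzymes = make_fixture_enzyme_profile()
        else:
            enzymes = EnzymeActivityProfile(
                **{k: getattr(self.enzymes, k).as_dict()
                   for k in ("ga20ox", "ga3ox", "ga2ox_ga12", "ga2ox_ga9ga4")}
            )
        kinetics = PathwayKinetics(
            ga20ox_steps=tuple(StepKinetics(s.vmax, s.km) for s in self.kinetics.ga20ox),
            ga3ox_step=StepKinetics(self.kinetics.ga3ox.vmax, self.kinetics.ga3ox.km),
        )
        sensor = SENSOR_CALIBRATIONS.get(self.sensor.name, SENSOR_CALIBRATIONS["nlsGPS1"])
        overrides = {k: v for k, v in self.sensor.model_dump().items()
                     if k != "name" and v is not None}
        if overrides:
            sensor = SensorCalibration(name=self.sensor.name, **{
                "r_min": overrides.get("r_min", sensor.r_min),
                "r_max": overrides.get("r_max", sensor.r_max),
                "kd": overrides.get("kd", sensor.kd),
                "hill": overrides.get("hill", sensor.hill),
            })
        g = self.geometry
        return ModelParams(
            zones=z,
            growth=growth,
            enzymes=enzymes,
            kinetics=kinetics,
            catabolism=CatabolismRates(**self.catabolism.model_dump()),
            ionization=IonizationParams(
                ph_apoplast=self.ionization.ph_apoplast,
                ph_cytoplasm=self.ionization.ph_cytoplasm,
                ph_vacuole=self.ionization.ph_vacuole,
                pka=tuple(self.ionization.pka),
            ),
            membranes=MembranePermeabilities(
                p_passive_pm=tuple(self.membranes.p_passive_pm),
                p_passive_ton=tuple(self.membranes.p_passive_ton),
                p_npf_influx=tuple(self.membranes.p_npf_influx),
                p_npf214=tuple(self.membranes.p_npf214),
            ),
            plasmodesmata=PlasmodesmataParams(**self.plasmodesmata.model_dump()),
            supply=SupplyRates(**self.supply.model_dump()),
            sensor=sensor,
            cross_area=g.cross_area,
            wall_thickness=g.wall_thickness,
            tonoplast_area_factor=g.tonoplast_area_factor,
            birth_length_range=(g.birth_length_min, g.birth_length_max),
        )

    def scenario(self, name: str) -> ScenarioConfig:
        from .scenarios import builtin_scenarios

        if name in self.scenarios:
            blk = self.scenarios[name].model_dump()
            blk["lof"] = frozenset(blk["lof"])
            return ScenarioConfig(name=name, **blk)
        builtin = builtin_scenarios()
        if name in builtin:
            return builtin[name]
        raise ConfigError(f"unknown scenario {name!r}")

    def noise_model(self) -> NoiseModel:
        return NoiseModel(**self.noise.model_dump())


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; None gives the full default."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig(**raw)
    except Exception as exc:  # pydantic ValidationError and friends
        raise ConfigError(str(exc)) from exc


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a config for provenance logging."""
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
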