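"""Parameter containers and wild-type defaults for the root GA4 gradient model.

Units are hours (time), micrometres (length) and nanomolar (concentration)
throughout the package.  Permeabilities are μm/h, diffusivities μm²/h,
volumetric rates nM/h.

The numeric defaults below are a documented wild-type *fixture*: boundary
positions of the quiescent-centre zone (QCZ, 0–43 μm) and division zone
(DZ, 43–240 μm) follow published root anatomy; kinetic constants, membrane
permeabilities and pH/pKa values are literature-scale approximations chosen
once (see docs/methods.md), not measured ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Optional

import numpy as np

__all__ = [
    "Metabolite",
    "METABOLITES",
    "Zone",
    "ZONES",
    "ZoneMap",
    "GrowthProfile",
    "CellGeometry",
    "StepKinetics",
    "PathwayKinetics",
    "CatabolismRates",
    "EnzymeActivityProfile",
    "IonizationParams",
    "MembranePermeabilities",
    "PlasmodesmataParams",
    "SupplyRates",
    "SensorCalibration",
    "ScenarioConfig",
    "ModelParams",
    "default_params",
]


class Metabolite(IntEnum):
    """Pathway order: GA12 →(GA20ox)→ GA15 → GA24 → GA9 →(GA3ox)→ GA4."""

    GA12 = 0
    GA15 = 1
    GA24 = 2
    GA9 = 3
    GA4 = 4


METABOLITES = tuple(Metabolite)
N_MET = len(METABOLITES)


class Zone(IntEnum):
    QCZ = 0
    DZ = 1
    EZ = 2
    MZ = 3


ZONES = tuple(Zone)


@dataclass(frozen=True)
class ZoneMap:
    """Longitudinal zonation of the growth axis, x in μm from the QC.

    ``phloem_zone`` (where shoot-derived GA12 is unloaded) is the rootward
    half of the elongation zone, [dz_end, (dz_end + ez_end)/2).
    """

    qcz_end: float = 43.0
    dz_end: float = 240.0
    ez_end: float = 950.0
    domain_end: float = 1100.0

    def __post_init__(self) -> None:
        if not (0.0 < self.qcz_end < self.dz_end < self.ez_end <= self.domain_end):
            raise ValueError(
                "zone boundaries must satisfy 0 < qcz_end < dz_end < ez_end <= domain_end"
            )

    @property
    def phloem_zone(self) -> tuple[float, float]:
        return (self.dz_end, 0.5 * (self.dz_end + self.ez_end))

    def zone_at(self, x: float) -> Zone:
        """Total zone lookup on [0, domain_end]."""
        if x < 0.0 or x > self.domain_end:
            raise ValueError(f"x={x} outside domain [0, {self.domain_end}]")
        if x < self.qcz_end:
            return Zone.QCZ
        if x < self.dz_end:
            return Zone.DZ
        if x < self.ez_end:
            return Zone.EZ
        return Zone.MZ

    def zone_edges(self) -> np.ndarray:
        return np.array([0.0, self.qcz_end, self.dz_end, self.ez_end, self.domain_end])


@dataclass(frozen=True)
class GrowthProfile:
    """Prescribed cell-file growth kinematics.

    ``ez_rer_x``/``ez_rer`` tabulate the relative elongation rate through
    the elongation zone; meristem RER is constant and the maturation zone
    does not grow.  In the EZ the cytoplasm keeps expanding at the meristem
    rate while the vacuole expands ``vac_rgr_multiple`` times faster, which
    carries the vacuolar volume fraction from ``meristem_vac_fraction`` at
    EZ entry to ~90% at maturation entry.
    """

    meristem_rer: float = 0.05           # 1/h
    vac_rgr_multiple: float = 5.0        # dimensionless
    meristem_vac_fraction: float = 0.35  # dimensionless
    ez_rer_x: Optional[np.ndarray] = None   # μm grid (within EZ)
    ez_rer: Optional[np.ndarray] = None     # 1/h at ez_rer_x

    def __post_init__(self) -> None:
        if self.meristem_rer < 0:
            raise ValueError("meristem_rer must be >= 0")
        if self.vac_rgr_multiple <= 1:
            raise ValueError("vac_rgr_multiple must be > 1")
        if not (0.0 < self.meristem_vac_fraction < 1.0):
            raise ValueError("meristem_vac_fraction must lie in (0, 1)")
        if (self.ez_rer is not None) and np.any(np.asarray(self.ez_rer) < 0):
            raise ValueError("rer must be >= 0 everywhere")


@dataclass
class CellGeometry:
    """Geometry of a single cell in the file."""

    length: float          # μm
    birth_length: float    # μm
    cross_area: float      # μm²
    vac_fraction: float    # dimensionless, in (0, 1)
    apoplast_thickness: float = 0.2  # μm, shared interface wall

    def __post_init__(self) -> None:
        if not (self.length >= self.birth_length > 0):
            raise ValueError("need length >= birth_length > 0")
        if not (0.0 < self.vac_fraction < 1.0):
            raise ValueError("vac_fraction must lie in (0, 1)")

    @property
    def volume(self) -> float:
        return self.length * self.cross_area

    @property
    def vac_volume(self) -> float:
        return self.vac_fraction * self.volume

    @property
    def cyt_volume(self) -> float:
        return (1.0 - self.vac_fraction) * self.volume


@dataclass(frozen=True)
class StepKinetics:
    """Michaelis–Menten constants of one conversion step at unit activity."""

    vmax: float  # nM/h
    km: float    # nM

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be > 0")


@dataclass(frozen=True)
class PathwayKinetics:
    """Kinetics of the four conversion steps (three GA20ox, one GA3ox)."""

    ga20ox_steps: tuple[StepKinetics, StepKinetics, StepKinetics] = (
        StepKinetics(vmax=150.0, km=100.0),
        StepKinetics(vmax=150.0, km=100.0),
        StepKinetics(vmax=150.0, km=100.0),
    )
    ga3ox_step: StepKinetics = StepKinetics(vmax=60.0, km=150.0)

    @property
    def steps(self) -> tuple[StepKinetics, ...]:
        return (*self.ga20ox_steps, self.ga3ox_step)


@dataclass(frozen=True)
class CatabolismRates:
    """First-order GA2ox catabolism at unit activity (1/h).

    ``delta12`` belongs to the GA2ox7–10 grouping (degrades GA12);
    ``delta9``/``delta4`` to the GA2ox1–4,6 grouping (degrade GA9, GA4).
    """

    delta12: float = 0.4
    delta9: float = 0.4
    delta4: float = 0.4

    def __post_init__(self) -> None:
        if min(self.delta12, self.delta9, self.delta4) < 0:
            raise ValueError("catabolism rates must be >= 0")


ENZYMES = ("ga20ox", "ga3ox", "ga2ox_ga12", "ga2ox_ga9ga4")


@dataclass(frozen=True)
class EnzymeActivityProfile:
    """Zone-wise relative activity multipliers for the four enzyme groups.

    Keys of each dict are Zone members; values are dimensionless >= 0.
    """

    ga20ox: dict[Zone, float]
    ga3ox: dict[Zone, float]
    ga2ox_ga12: dict[Zone, float]
    ga2ox_ga9ga4: dict[Zone, float]

    def __post_init__(self) -> None:
        for name in ENZYMES:
            table = getattr(self, name)
            if set(table) != set(ZONES):
                raise ValueError(f"{name}: must define a multiplier for every zone")
            if any(v < 0 for v in table.values()):
                raise ValueError(f"{name}: multipliers must be >= 0")

    def multiplier(self, enzyme: str, zone: Zone) -> float:
        return getattr(self, enzyme)[zone]

    def as_array(self) -> np.ndarray:
        """(4 enzymes, 4 zones) multiplier array, ordered by ENZYMES/ZONES."""
        return np.array(
            [[getattr(self, e)[z] for z in ZONES] for e in ENZYMES], dtype=float
        )


@dataclass(frozen=True)
class IonizationParams:
    """Weak-acid chemistry: compartment pH and per-metabolite pKa."""

    ph_apoplast: float = 5.3
    ph_cytoplasm: float = 7.2
    ph_vacuole: float = 5.5
    pka: tuple[float, float, float, float, float] = (4.2, 4.2, 4.2, 4.2, 4.2)

    def __post_init__(self) -> None:
        for ph in (self.ph_apoplast, self.ph_cytoplasm, self.ph_vacuole):
            if not (3.0 < ph < 9.0):
                raise ValueError("compartment pH must lie in (3, 9)")
        for pka in self.pka:
            if not (2.0 < pka < 7.0):
                raise ValueError("pKa must lie in (2, 7)")


@dataclass(frozen=True)
class MembranePermeabilities:
    """Per-metabolite membrane permeabilities (μm/h).

    Passive entries act on the protonated (neutral) form across plasma
    membrane and tonoplast; NPF entries act on the anionic form
    (NPF3.1/NPF2.12 merged as plasma-membrane influx; NPF2.14 tonoplast
    cytoplasm→vacuole).  Wild-type ordering: GA12/GA15/GA9 diffuse
    passively faster than GA24/GA4, and NPF permeabilities are ordered the
    other way.
    """

    p_passive_pm: tuple[float, ...] = (360.0, 360.0, 36.0, 360.0, 36.0)
    p_passive_ton: tuple[float, ...] = (360.0, 360.0, 36.0, 360.0, 36.0)
    p_npf_influx: tuple[float, ...] = (3.6, 3.6, 36.0, 3.6, 36.0)
    p_npf214: tuple[float, ...] = (0.36, 0.36, 3.6, 0.36, 3.6)

    def __post_init__(self) -> None:
        for name in ("p_passive_pm", "p_passive_ton", "p_npf_influx", "p_npf214"):
            vals = getattr(self, name)
            if len(vals) != N_MET or any(v < 0 for v in vals):
                raise ValueError(f"{name}: need {N_MET} values >= 0")


@dataclass(frozen=True)
class PlasmodesmataParams:
    """Plasmodesmatal permeability per unit shared-wall area (μm/h)."""

    p_plas: float = 180.0
    ez_factor: float = 1.0   # optional EZ-only multiplier

    def __post_init__(self) -> None:
        if self.p_plas < 0 or self.ez_factor < 0:
            raise ValueError("plasmodesmatal permeabilities must be >= 0")


@dataclass(frozen=True)
class SupplyRates:
    """GA12 sources and apoplastic diffusivity.

    ``s_qcz``: local GA12 synthesis in QCZ cytoplasm (nM/h);
    ``d_phloem``: phloem delivery in the phloem-unloading zone (nM/h);
    ``d_apo``: apoplastic diffusivity (μm²/h);
    ``apoplast_area_fraction``: fraction of the cross-section occupied by
    longitudinal wall, scaling the apoplastic diffusion pathway.
    """

    s_qcz: float = 3.0
    d_phloem: float = 150.0
    d_apo: float = 1.0e5
    apoplast_area_fraction: float = 0.02

    def __post_init__(self) -> None:
        if min(self.s_qcz, self.d_phloem, self.d_apo, self.apoplast_area_fraction) < 0:
            raise ValueError("supply rates must be >= 0")


@dataclass(frozen=True)
class SensorCalibration:
    """Titration curve mapping GA4 (nM) to a FRET emission ratio.

    R(c) = r_min + (r_max - r_min) * c^h / (kd^h + c^h).
    """

    name: str = "nlsGPS1"
    r_min: float = 0.55
    r_max: float = 1.15
    kd: float = 25.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min > 0):
            raise ValueError("need r_max > r_min > 0")
        if self.kd <= 0 or self.hill <= 0:
            raise ValueError("kd and hill must be > 0")


#: Named sensor calibrations used in the package (fixture constants).
SENSOR_CALIBRATIONS = {
    "nlsGPS1": SensorCalibration("nlsGPS1", 0.55, 1.15, 15.0, 1.0),
    "nlsGPS2": SensorCalibration("nlsGPS2", 0.50, 1.30, 25.0, 1.0),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """A declarative perturbation of the wild-type model.

    ``oe`` maps enzyme name → uniform activity increment α (units of the
    wild-type maximum multiplier); ``lof`` zeroes an enzyme everywhere;
    ``inactivation`` rescales GA20ox+GA3ox in the DZ or the whole meristem
    (mode 'zero' or 'ten_percent').  Transport/supply/growth scalars apply
    multiplicatively to the wild-type parameters.
    """

    name: str = "wildtype"
    oe: dict[str, float] = field(default_factory=dict)
    lof: frozenset[str] = frozenset()
    inactivation_mode: str = "none"       # none | zero | ten_percent
    inactivation_region: str = "DZ"       # DZ | meristem
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

    def __post_init__(self) -> None:
        for enz in set(self.oe) | set(self.lof):
            if enz not in ENZYMES:
                raise ValueError(f"unknown enzyme {enz!r}")
        if any(a < 0 for a in self.oe.values()):
            raise ValueError("OE increments must be >= 0")
        if self.inactivation_mode not in ("none", "zero", "ten_percent"):
            raise ValueError("inactivation_mode must be none|zero|ten_percent")
        if self.inactivation_region not in ("DZ", "meristem"):
            raise ValueError("inactivation_region must be DZ|meristem")
        if min(self.pplas_factor, self.s_qcz_factor, self.d_phloem_factor, self.rer_factor) < 0:
            raise ValueError("scenario factors must be >= 0")
        if set(self.lof) & set(self.oe):
            raise ValueError("an enzyme cannot be both LOF and OE")
        if self.ga2ox_hept and any(e.startswith("ga2ox") for e in self.oe):
            raise ValueError("ga2ox_hept is incompatible with GA2ox overexpression")


@dataclass(frozen=True)
class ModelParams:
    """Bundle of every parameter block of the model."""

    zones: ZoneMap
    growth: GrowthProfile
    enzymes: EnzymeActivityProfile
    kinetics: PathwayKinetics
    catabolism: CatabolismRates
    ionization: IonizationParams
    membranes: MembranePermeabilities
    plasmodesmata: PlasmodesmataParams
    supply: SupplyRates
    sensor: SensorCalibration
    cross_area: float = 200.0          # μm², constant along the file (1-D)
    wall_thickness: float = 0.2        # μm, apoplast interface thickness
    tonoplast_area_factor: float = 2.0  # tonoplast area per cell = factor × cross_area
    birth_length_range: tuple[float, float] = (4.0, 10.0)  # μm across the meristem

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def default_params(sensor: str = "nlsGPS1") -> ModelParams:
    """Wild-type fixture parameterization (see module docstring)."""
    from .synth import make_fixture_enzyme_profile, make_fixture_growth

    growth, _birth = make_fixture_growth()
    return ModelParams(
        zones=ZoneMap(),
        growth=growth,
        enzymes=make_fixture_enzyme_profile(),
        kinetics=PathwayKinetics(),
        catabolism=CatabolismRates(),
        ionization=IonizationParams(),
        membranes=MembranePermeabilities(),
        plasmodesmata=PlasmodesmataParams(),
        supply=SupplyRates(),
        sensor=SENSOR_CALIBRATIONS[sensor],
    )
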