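"""Prescribed growth kinematics of the root cell file.

Cells divide in the meristem (QCZ + DZ) once they have doubled their birth
length, elongate rapidly in the EZ and stop growing in the MZ.  Growth is
kinematically prescribed, not mechanically modelled: in the meristem both
cytoplasm and vacuole expand at the meristem relative elongation rate
(RER), so the vacuolar volume fraction stays constant; in the EZ the
cytoplasm keeps the meristem rate while the vacuole expands
``vac_rgr_multiple`` times faster, so the cell RER rises as the vacuolar
fraction grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import CellGeometry, GrowthProfile, Zone, ZoneMap

__all__ = [
    "rer_at",
    "compartment_volume_rates",
    "advance_and_divide",
    "ez_kinematics",
    "SteadyTemplate",
    "build_steady_template",
    "birth_length_at",
]


def rer_at(x: float, profile: GrowthProfile, zones: ZoneMap) -> float:
    """Relative elongation rate (1/h) of the tissue at position x (μm).

    Piecewise: constant ``meristem_rer`` in QCZ+DZ, the tabulated ramp in
    the EZ, and zero in the MZ.  Raises ValueError outside [0, domain_end].
    """
    zone = zones.zone_at(x)  # raises on out-of-domain x
    if zone in (Zone.QCZ, Zone.DZ):
        return profile.meristem_rer
    if zone is Zone.MZ:
        return 0.0
    if profile.ez_rer_x is None or profile.ez_rer is None:
        # fall back to the self-consistent EZ ramp
        kin = ez_kinematics(profile, zones)
        return float(np.interp(x, kin["x"], kin["rer"]))
    return float(np.interp(x, profile.ez_rer_x, profile.ez_rer))


def compartment_volume_rates(
    cell: CellGeometry, zone: Zone, profile: GrowthProfile
) -> tuple[float, float]:
    """(dVcyt/dt, dVvac/dt) in μm³/h for a cell in the given zone.

    Meristem: both compartments at the meristem RER (vacuolar fraction
    preserved).  EZ: cytoplasm at the meristem RER, vacuole at
    ``vac_rgr_multiple`` times that.  MZ: no growth.
    """
    r = profile.meristem_rer
    if zone in (Zone.QCZ, Zone.DZ):
        return (r * cell.cyt_volume, r * cell.vac_volume)
    if zone is Zone.EZ:
        return (r * cell.cyt_volume, profile.vac_rgr_multiple * r * cell.vac_volume)
    return (0.0, 0.0)


def _cell_midpoints(file: list[CellGeometry]) -> np.ndarray:
    ends = np.cumsum([c.length for c in file])
    return ends - 0.5 * np.array([c.length for c in file])


def advance_and_divide(
    file: list[CellGeometry], dt: float, profile: GrowthProfile, zones: ZoneMap
) -> list[CellGeometry]:
    """One geometry step of the cell file: grow compartments, then divide.

    Any meristem cell reaching twice its birth length is replaced by two
    equal halves whose birth length is the half length; cells shootward of
    ``dz_end`` never divide.  Total file length is conserved at division.
    Raises ValueError if dt is large enough that a cell could more than
    double (enforced as ``dt * max RER < 0.1``).
    """
    max_rer = profile.vac_rgr_multiple * profile.meristem_rer
    if dt * max_rer >= 0.1:
        raise ValueError(f"dt={dt} too large: dt*max_RER must be < 0.1")

    mids = _cell_midpoints(file)
    r = profile.meristem_rer
    m = profile.vac_rgr_multiple
    grown: list[CellGeometry] = []
    for cell, x in zip(file, mids):
        zone = zones.zone_at(min(x, zones.domain_end))
        vc, vv = cell.cyt_volume, cell.vac_volume
        if zone in (Zone.QCZ, Zone.DZ):
            vc *= np.exp(r * dt)
            vv *= np.exp(r * dt)
        elif zone is Zone.EZ:
            vc *= np.exp(r * dt)
            vv *= np.exp(m * r * dt)
        length = (vc + vv) / cell.cross_area
        grown.append(
            CellGeometry(
                length=length,
                birth_length=cell.birth_length,
                cross_area=cell.cross_area,
                vac_fraction=vv / (vc + vv),
                apoplast_thickness=cell.apoplast_thickness,
            )
        )

    out: list[CellGeometry] = []
    mids = _cell_midpoints(grown)
    for cell, x in zip(grown, mids):
        in_meristem = x < zones.dz_end
        if in_meristem and cell.length >= 2.0 * cell.birth_length:
            half = 0.5 * cell.length
            for _ in range(2):
                out.append(
                    CellGeometry(
                        length=half,
                        birth_length=half,
                        cross_area=cell.cross_area,
                        vac_fraction=cell.vac_fraction,
                        apoplast_thickness=cell.apoplast_thickness,
                    )
                )
        else:
            out.append(cell)
    return out


def ez_kinematics(
    profile: GrowthProfile,
    zones: ZoneMap,
    entry_length: float | None = None,
    entry_velocity: float | None = None,
    n: int = 600,
) -> dict[str, np.ndarray]:
    """Self-consistent Lagrangian kinematics of a cell crossing the EZ.

    With the cytoplasm at RGR r and the vacuole at m*r from entry fraction
    φ0, a cell's length follows l(τ) = l0*g(τ), g = (1-φ0)e^{rτ} + φ0 e^{m r τ}.
    At steady state the cell flux F = v/l is uniform, so position follows
    dx/dτ = F l0 g(τ).  Returns arrays over the EZ transit: time ``tau``,
    position ``x``, length ``l``, vacuolar fraction ``phi``, cell RER
    ``rer`` and velocity ``v``, truncated at ``zones.ez_end``.
    """
    r = profile.meristem_rer
    m = profile.vac_rgr_multiple
    phi0 = profile.meristem_vac_fraction
    if r <= 0.0:
        # degenerate no-growth file: nothing moves or elongates
        x = np.linspace(zones.dz_end, zones.ez_end, n)
        flat = np.full(n, entry_length if entry_length else 2.0 * np.log(2.0) * 10.0)
        return {"tau": np.zeros(n), "x": x, "l": flat,
                "phi": np.full(n, phi0), "rer": np.zeros(n), "v": np.zeros(n)}
    if entry_length is None:
        # population-mean meristem exit length for birth length b1: 2 ln2 b1
        entry_length = 2.0 * np.log(2.0) * 10.0
    if entry_velocity is None:
        entry_velocity = r * zones.dz_end  # uniform meristem RER

    ez_len = zones.ez_end - zones.dz_end

    def g_int(u: float) -> float:
        # ∫0^u g du' with u = r τ
        return (1 - phi0) * (np.exp(u) - 1.0) + (phi0 / m) * (np.exp(m * u) - 1.0)

    def x_of_u(u: float) -> float:
        return (entry_velocity / r) * g_int(u)

    u_end = brentq(lambda u: x_of_u(u) - ez_len, 0.0, 50.0, xtol=1e-12)
    u = np.linspace(0.0, u_end, n)
    g = (1 - phi0) * np.exp(u) + phi0 * np.exp(m * u)
    dg = (1 - phi0) * np.exp(u) + phi0 * m * np.exp(m * u)
    x = zones.dz_end + np.array([x_of_u(ui) for ui in u])
    l = entry_length * g
    phi = phi0 * np.exp(m * u) / g
    rer = r * dg / g
    v = (entry_velocity / entry_length) * l
    return {"tau": u / r, "x": x, "l": l, "phi": phi, "rer": rer, "v": v}


def birth_length_at(x: float, zones: ZoneMap, birth_range: tuple[float, float]) -> float:
    """Birth length fixture: linear ramp across the meristem (μm)."""
    b0, b1 = birth_range
    frac = min(max(x / zones.dz_end, 0.0), 1.0)
    return b0 + (b1 - b0) * frac


@dataclass(frozen=True)
class SteadyTemplate:
    """Time-averaged steady geometry of the mature cell file.

    Arrays tabulate, versus position ``x`` (μm from the QC): mean cell
    length ``l``, tissue growth velocity ``v`` (= ∫ RER), vacuolar volume
    fraction ``phi`` and local RER.
    """

    x: np.ndarray
    l: np.ndarray
    v: np.ndarray
    phi: np.ndarray
    rer: np.ndarray

    def interp(self, field: str, xq: np.ndarray) -> np.ndarray:
        return np.interp(xq, self.x, getattr(self, field))


def build_steady_template(
    profile: GrowthProfile,
    zones: ZoneMap,
    birth_range: tuple[float, float] = (4.0, 10.0),
    n_meristem: int = 240,
    n_ez: int = 600,
) -> SteadyTemplate:
    """Steady cell-length and growth-velocity fields l(x), v(x).

    Meristem: v(x) = r x (uniform RER); mean cell length is the
    time-average of exponential growth between birth and division,
    l(x) = 2 ln2 · b(x) for birth-length profile b(x) (stable age structure).  EZ: the Lagrangian
    transit solution of :func:`ez_kinematics`.  MZ: frozen at EZ-exit
    values.
    """
    r = profile.meristem_rer
    xm = np.linspace(0.0, zones.dz_end, n_meristem, endpoint=False)
    lm = 2.0 * np.log(2.0) * np.array(
        [birth_length_at(x, zones, birth_range) for x in xm]
    )
    vm = r * xm
    phim = np.full_like(xm, profile.meristem_vac_fraction)
    rerm = np.full_like(xm, r)

    entry_length = 2.0 * np.log(2.0) * birth_length_at(zones.dz_end, zones, birth_range)
    kin = ez_kinematics(profile, zones, entry_length=entry_length, n=n_ez)

    xz = np.linspace(zones.ez_end, zones.domain_end, 50)
    x = np.concatenate([xm, kin["x"], xz])
    l = np.concatenate([lm, kin["l"], np.full(50, kin["l"][-1])])
    v = np.concatenate([vm, kin["v"], np.full(50, kin["v"][-1])])
    phi = np.concatenate([phim, kin["phi"], np.full(50, kin["phi"][-1])])
    rer = np.concatenate([rerm, kin["rer"], np.zeros(50)])
    return SteadyTemplate(x=x, l=l, v=v, phi=phi, rer=rer)
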