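"""The GA12→GA15→GA24→GA9→GA4 metabolic network.

Three GA20ox-mediated oxidation steps convert GA12 to GA9, one GA3ox step
produces the bioactive GA4; all follow Michaelis–Menten kinetics scaled by
a zone-dependent relative activity.  GA2ox catabolism is linear: one
enzyme grouping degrades GA12, the other degrades GA9 and GA4.  Metabolism
acts in the cytoplasm only.
"""

from __future__ import annotations

import numpy as np

from .params import (
    ENZYMES,
    N_MET,
    CatabolismRates,
    EnzymeActivityProfile,
    Metabolite,
    PathwayKinetics,
    ScenarioConfig,
    Zone,
    ZONES,
)

__all__ = [
    "mm_rate",
    "activity_vector",
    "source_terms",
    "source_terms_multi",
    "apply_enzyme_scenario",
]


def mm_rate(c, vmax: float, km: float, activity: float = 1.0):
    """Michaelis–Menten rate activity*vmax*c/(km + c), nM/h.

    Accepts scalar or array concentrations; negative input is a domain
    error.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = activity * vmax * c / (km + c)
    return float(out) if out.ndim == 0 else out


def activity_vector(activities: EnzymeActivityProfile, zone: Zone) -> np.ndarray:
    """Multipliers (ga20ox, ga3ox, ga2ox_ga12, ga2ox_ga9ga4) for one zone."""
    if zone not in ZONES:
        raise ValueError(f"unknown zone {zone!r}")
    return np.array([activities.multiplier(e, zone) for e in ENZYMES])


def source_terms_multi(
    conc: np.ndarray,
    mult: np.ndarray,
    kin: PathwayKinetics,
    cat: CatabolismRates,
) -> np.ndarray:
    """Net metabolic source S_j (nM/h) given explicit activity multipliers.

    ``conc``: (..., 5) concentrations; ``mult``: (..., 4) multipliers in
    ENZYMES order.  Vectorized over leading axes.  This is the kernel
    behind :func:`source_terms`; the cell-file model calls it with
    zone-overlap-weighted multipliers for cells straddling a boundary.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0 componentwise")
    mult = np.asarray(mult, dtype=float)
    a20, a3, a2_12, a2_94 = (mult[..., k] for k in range(4))

    steps = kin.steps
    # conversion fluxes out of GA12, GA15, GA24 (GA20ox) and GA9 (GA3ox)
    flux = np.empty(conc.shape[:-1] + (4,), dtype=float)
    for k in range(3):
        flux[..., k] = a20 * steps[k].vmax * conc[..., k] / (steps[k].km + conc[..., k])
    flux[..., 3] = a3 * steps[3].vmax * conc[..., 3] / (steps[3].km + conc[..., 3])

    s = np.zeros_like(conc)
    s[..., 0] = -flux[..., 0] - cat.delta12 * a2_12 * conc[..., 0]
    s[..., 1] = flux[..., 0] - flux[..., 1]
    s[..., 2] = flux[..., 1] - flux[..., 2]
    s[..., 3] = flux[..., 2] - flux[..., 3] - cat.delta9 * a2_94 * conc[..., 3]
    s[..., 4] = flux[..., 3] - cat.delta4 * a2_94 * conc[..., 4]
    return s


def source_terms(
    conc: np.ndarray,
    zone: Zone,
    activities: EnzymeActivityProfile,
    kin: PathwayKinetics,
    cat: CatabolismRates,
) -> np.ndarray:
    """Net source S_j (nM/h) for the 5 metabolites in one zone.

    S_j = conversion in − conversion out − catabolism; GA15 and GA24 have
    no catabolic sink.
    """
    return source_terms_multi(conc, activity_vector(activities, zone), kin, cat)


def degradation_rates_multi(
    conc: np.ndarray, mult: np.ndarray, cat: CatabolismRates
) -> np.ndarray:
    """Catabolic loss per metabolite (nM/h), same conventions as
    :func:`source_terms_multi`; used for mass-balance bookkeeping."""
    conc = np.asarray(conc, dtype=float)
    mult = np.asarray(mult, dtype=float)
    d = np.zeros_like(conc)
    d[..., 0] = cat.delta12 * mult[..., 2] * conc[..., 0]
    d[..., 3] = cat.delta9 * mult[..., 3] * conc[..., 3]
    d[..., 4] = cat.delta4 * mult[..., 3] * conc[..., 4]
    return d


def apply_enzyme_scenario(
    wild_type: EnzymeActivityProfile, scenario: ScenarioConfig
) -> EnzymeActivityProfile:
    """Transform a wild-type activity profile under a perturbation scenario.

    Applied in order: (1) LOF flags zero an enzyme in every zone; (2) OE
    adds a spatially uniform increment of α times the enzyme's wild-type
    maximum; (3) the inactivation mode rescales GA20ox and GA3ox by 0 or
    0.1 in the DZ or throughout the meristem; (4) ``uniform_enzymes``
    replaces every profile by its spatial mean.
    """
    tables = {e: dict(getattr(wild_type, e)) for e in ENZYMES}

    for enz in scenario.lof:
        tables[enz] = {z: 0.0 for z in ZONES}
    if scenario.ga2ox_hept:
        tables["ga2ox_ga12"] = {z: 0.0 for z in ZONES}
        tables["ga2ox_ga9ga4"] = {z: 0.0 for z in ZONES}

    for enz, alpha in scenario.oe.items():
        base = max(getattr(wild_type, enz).values())
        tables[enz] = {z: v + alpha * base for z, v in tables[enz].items()}

    if scenario.inactivation_mode != "none":
        factor = 0.0 if scenario.inactivation_mode == "zero" else 0.1
        region = (
            (Zone.DZ,) if scenario.inactivation_region == "DZ" else (Zone.QCZ, Zone.DZ)
        )
        for enz in ("ga20ox", "ga3ox"):
            for z in region:
                tables[enz][z] = factor * tables[enz][z]

    if scenario.uniform_enzymes:
        for enz in ENZYMES:
            mean = float(np.mean(list(tables[enz].values())))
            tables[enz] = {z: mean for z in ZONES}

    return EnzymeActivityProfile(**tables)
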