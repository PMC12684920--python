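"""Inter-compartment transport of gibberellin metabolites.

Gibberellins are weak acids: only the protonated (neutral) form crosses
membranes passively, while NPF carriers move the anionic form.  The
protonated fraction follows Henderson–Hasselbalch, f = 1/(1 + 10^(pH−pKa)),
so the acidic apoplast (pH ~5.3) leaves ~7% of GA4 membrane-permeant while
the neutral cytoplasm leaves >99% anionic — the classic weak-acid trap.
Plasmodesmata are modelled as a permeability × shared-wall-area ×
concentration-difference flux carrying all ionic forms.
"""

from __future__ import annotations

import numpy as np

from .params import ScenarioConfig, SupplyRates, Zone, ZoneMap

__all__ = [
    "protonated_fraction",
    "passive_flux",
    "npf_flux",
    "plasmodesmatal_flux",
    "ga12_supply",
]


def protonated_fraction(ph, pka):
    """Henderson–Hasselbalch protonated fraction, strictly decreasing in pH."""
    return 1.0 / (1.0 + 10.0 ** (np.asarray(ph, dtype=float) - pka))


def passive_flux(c_a, c_b, ph_a: float, ph_b: float, pka: float, p: float):
    """Passive membrane flux density (nM·μm/h), positive A→B.

    Only the protonated fraction on each side diffuses:
    P·(f(pH_A)·c_A − f(pH_B)·c_B); antisymmetric under swapping sides.
    """
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    if np.any(c_a < 0) or np.any(c_b < 0):
        raise ValueError("concentrations must be >= 0")
    return p * (protonated_fraction(ph_a, pka) * c_a - protonated_fraction(ph_b, pka) * c_b)


def npf_flux(c_source, ph_source: float, pka: float, p_npf: float):
    """Unidirectional NPF carrier flux density on the anionic form:
    P_npf·(1 − f(pH_source))·c_source (nM·μm/h)."""
    c_source = np.asarray(c_source, dtype=float)
    if np.any(c_source < 0):
        raise ValueError("concentration must be >= 0")
    return p_npf * (1.0 - protonated_fraction(ph_source, pka)) * c_source


def plasmodesmatal_flux(c_i, c_j, p_plas: float, area: float):
    """Symplastic amount flux P_plas·area·(c_i − c_j), nM·μm³/h, i→j
    positive; all ionic forms pass."""
    c_i = np.asarray(c_i, dtype=float)
    c_j = np.asarray(c_j, dtype=float)
    if np.any(c_i < 0) or np.any(c_j < 0):
        raise ValueError("concentrations must be >= 0")
    return p_plas * area * (c_i - c_j)


def ga12_supply(
    x,
    zones: ZoneMap,
    rates: SupplyRates,
    scenario: ScenarioConfig | None = None,
) -> np.ndarray:
    """GA12 source into the cytoplasm at position x (nM/h).

    Baseline: local synthesis ``s_qcz`` on [0, qcz_end) plus phloem
    delivery ``d_phloem`` on the phloem-unloading zone (rootward half of
    the EZ).  The uniform-supply scenario spreads the same total amount
    per unit time evenly over [0, domain_end).  Scenario supply
    multipliers apply in both modes.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > zones.domain_end):
        raise ValueError("x outside domain")
    s_fac = scenario.s_qcz_factor if scenario else 1.0
    d_fac = scenario.d_phloem_factor if scenario else 1.0
    s_qcz = rates.s_qcz * s_fac
    d_phloem = rates.d_phloem * d_fac

    p0, p1 = zones.phloem_zone
    if scenario is not None and scenario.uniform_supply:
        total = s_qcz * zones.qcz_end + d_phloem * (p1 - p0)
        return np.full_like(x, total / zones.domain_end)

    out = np.zeros_like(x)
    out = np.where(x < zones.qcz_end, s_qcz, out)
    out = np.where((x >= p0) & (x < p1), d_phloem, out)
    return out
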