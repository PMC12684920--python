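"""Root zonation and growth kinematics.

Builds the wild-type growth template and prints the zone boundaries, the
relative elongation rate (RER) in each zone, and the vacuolar volume
fraction a cell accumulates by the time it stops elongating.
"""

import numpy as np

import rootga as rg

params = rg.default_params()
zones = params.zones
tpl = rg.build_steady_template(params.growth, zones, params.birth_length_range)

print(f"QCZ: 0-{zones.qcz_end:.0f} um, DZ: to {zones.dz_end:.0f} um, "
      f"EZ: to {zones.ez_end:.0f} um, domain: {zones.domain_end:.0f} um")
print(f"phloem-unloading zone: {zones.phloem_zone[0]:.0f}-{zones.phloem_zone[1]:.0f} um")
for x in (100.0, 400.0, 700.0, 1000.0):
    print(f"x={x:6.0f} um  zone={zones.zone_at(x).name:3s}  "
          f"RER={rg.rer_at(x, params.growth, zones):.3f} /h  "
          f"cell length={tpl.interp('l', np.array([x]))[0]:6.1f} um  "
          f"velocity={tpl.interp('v', np.array([x]))[0]:6.1f} um/h")
phi_end = tpl.interp("phi", np.array([zones.ez_end]))[0]
print(f"vacuolar fraction at maturation entry: {100*phi_end:.1f} % "
      "(cells start the EZ at 35% and their vacuole expands 5x faster)")
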