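"""Wild-type steady GA4 gradient (continuum solver) and its biosensor image.

Solves the five-metabolite steady state and prints cytoplasmic GA4 and
the corresponding nlsGPS1 emission ratio along the root axis; the ratio
rises from the division zone into the elongation zone, which is the
gradient the biosensor reports.
"""

import numpy as np

import rootga as rg
from rootga.sensor import emission_ratio

params = rg.default_params()
sol = rg.solve_steady(params)
print("x(um)   GA4(nM)   nlsGPS1 ratio")
for x in (25, 100, 200, 300, 400, 500):
    ga4 = np.interp(x, sol.x, sol.ga4())
    print(f"{x:5d}   {ga4:7.2f}   {emission_ratio(ga4, params.sensor):.3f}")
mb = rg.mass_balance(params, sol)
print(f"hormone budget: supply {mb['supply']:.0f} = degradation {mb['degradation']:.0f}"
      f" + export {mb['export']:.0f} (nM um/h per unit cross-section; "
      f"relative error {mb['rel_error']:.1e})")
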