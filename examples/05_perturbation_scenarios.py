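"""Perturbation scenarios: transport, catabolism and enzyme changes.

Reproduces the qualitative responses of the GA4 gradient: more
plasmodesmatal diffusion flattens it, losing GA2ox catabolism raises GA4
everywhere, and GA3ox overexpression moves the biosensor readout more
than GA20ox overexpression (GA3ox is the pathway bottleneck).
"""

import numpy as np

import rootga as rg
from rootga.scenarios import builtin_scenarios, predict_ratio, run_scenario

params = rg.default_params()
scn = builtin_scenarios()
base, base_ratio = run_scenario(params)

def max_slope(prof):
    m = prof.x <= 500
    return np.max(np.gradient(prof.ga4(), prof.x)[m])

h2o2, _ = run_scenario(params, scn["h2o2"])
print(f"max GA4 slope: wild type {max_slope(base):.3f}, "
      f"plasmodesmata x3 {max_slope(h2o2):.3f} nM/um (shallower gradient)")

hept, _ = run_scenario(params, scn["ga2ox_hept"])
print(f"ga2ox heptuple: GA4 is {np.min(hept.ga4()-base.ga4()):.1f}-"
      f"{np.max(hept.ga4()-base.ga4()):.1f} nM above wild type everywhere")

_, r3 = run_scenario(params, scn["ga3ox_oe"])
_, r20 = run_scenario(params, scn["ga20ox_oe"])
l2 = lambda r: np.sqrt(np.trapezoid((r.ratio - base_ratio.ratio)**2, base.x))
print(f"ratio-profile change (L2): GA3ox OE {l2(r3):.2f} vs GA20ox OE {l2(r20):.2f}")

nonpf, _ = run_scenario(params, scn["npf_influx_off"])
rel = np.sqrt(np.trapezoid((nonpf.ga4()-base.ga4())**2, base.x)
              / np.trapezoid(base.ga4()**2, base.x))
print(f"removing NPF influx carriers changes the profile by {100*rel:.2f} % "
      "(apoplastic GA4 is too scarce to matter)")
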