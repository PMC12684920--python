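"""Weak-acid chemistry behind gibberellin membrane transport.

Gibberellins cross membranes passively only in the protonated (neutral)
form; NPF carriers move the anion.  The Henderson-Hasselbalch relation
sets how much of each pool is available in each compartment.
"""

import rootga as rg
from rootga.params import IonizationParams

ion = IonizationParams()
pka_ga4 = ion.pka[4]
f_apo = rg.protonated_fraction(ion.ph_apoplast, pka_ga4)
f_cyt = rg.protonated_fraction(ion.ph_cytoplasm, pka_ga4)
print(f"GA4 protonated in the apoplast (pH {ion.ph_apoplast}): {100*f_apo:.1f} %")
print(f"GA4 anionic in the cytoplasm  (pH {ion.ph_cytoplasm}): {100*(1-f_cyt):.1f} %")
flux = rg.passive_flux(10.0, 10.0, ion.ph_apoplast, ion.ph_cytoplasm, pka_ga4, 36.0)
print(f"passive flux at equal 10 nM totals, apoplast->cytoplasm: {flux:.2f} nM um/h")
print("positive flux = the acid trap: hormone accumulates in the neutral cytoplasm")
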