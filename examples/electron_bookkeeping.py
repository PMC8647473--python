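"""Convert carboxylate concentrations between mass, electron-equivalent and
COD currencies, and express undissociated-acid toxicity thresholds.

Electron equivalents (degree of reduction, 4C + H - 2O per mol) are the
common currency for selectivity and balance accounting; 1 e- eq is 8 g COD.
"""

import caproflux as cf
from caproflux.compounds import mM_to_g_per_L

reg = cf.Registry.default()
nc6 = reg["n-caproate"]

rate_emeq = 1421.0  # e- meq / L / d, a peak n-caproate production rate
print(f"n-caproate {rate_emeq} e- meq/L/d "
      f"= {cf.emeq_to_g_per_L(rate_emeq, nc6):.2f} g/L/d "
      f"= {cf.emeq_to_cod(rate_emeq):.1f} g COD/L/d")

print(f"1 g/L acetate carries {cf.g_per_L_to_emeq(1.0, reg['acetate']):.1f} e- meq "
      f"and {cf.conc_to_carbon_mmol(1.0, reg['acetate']):.1f} mmol C")

# Undissociated n-caproic acid drives product toxicity.  At pH 5.0 a total
# n-caproate concentration of 6.5 g/L leaves this much in the protonated form:
total = 6.5
ha = cf.undissociated_conc(total, 5.0, nc6)
print(f"{total} g/L total n-caproate at pH 5.0 -> {ha:.2f} g/L undissociated")
for mM in (7.5, 26.0, 37.0):
    print(f"  toxicity marker {mM:5.1f} mM undissociated acid = "
          f"{mM_to_g_per_L(mM, nc6):.2f} g/L")
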