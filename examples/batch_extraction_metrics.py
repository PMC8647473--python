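"""Score a two-phase batch extraction: K_D, P, recovery and specificity.

Models a 40-mL fermentation bottle with a 20% v/v solvent overlay at final
pH 4.8.  K_D is the organic/aqueous concentration ratio; P rescales it to the
undissociated (extractable) species; recovery is the solvent's share of each
compound; specificity is each compound's share of the solvent load.
"""

import caproflux as cf

reg = cf.Registry.default()
v_aq, v_org = 0.040, 0.008  # L

# final-timepoint concentrations, g/L
aqueous = {"n-butyrate": 4.0, "n-valerate": 0.5, "n-caproate": 6.5}
organic = {"n-butyrate": 0.8, "n-valerate": 0.3, "n-caproate": 16.25}

phases = cf.PhaseAmounts(
    amounts_org={k: c * v_org for k, c in organic.items()},
    amounts_aq={k: c * v_aq for k, c in aqueous.items()},
    v_aq=v_aq, v_org=v_org,
)
metrics = cf.batch_extraction_metrics(phases, pH=4.8, registry=reg)
print(cf.metrics_table(metrics).round(2))
print("\nA K_D of", metrics["n-caproate"].kd, "at 20% v/v solvent implies an")
print("equilibrium recovery of "
      f"{cf.equilibrium_recovery(metrics['n-caproate'].kd, v_org / v_aq):.1f}% "
      "for a closed system.")
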