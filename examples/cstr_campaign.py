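"""Simulate a two-phase chain-elongation campaign and account for it.

Phase 1 (0-99 d): continuous lactate + acetate fermentation at pH 5.0,
HRT 2 d, no solvent; the microbiome settles where undissociated n-caproic
acid attenuates elongation.  Phase 2 (99-114 d): a 20% v/v sunflower-oil
overlay extracts n-caproate and n-caprylate in situ, relieving inhibition.
The performance module then recomputes rates, selectivities, acid demand and
balance gaps from the sampled series alone.
"""

import dataclasses

import caproflux as cf

reg = cf.Registry.default()
params = cf.SimParams()

cfg1 = cf.ReactorConfig()                      # 1.2 L broth, no oil
run1 = cf.simulate_cstr(params, cfg1, t_end=99.0)
s1 = cf.build_period_summary(run1.timeseries, cfg1, (60, 90), reg, ledger=run1.ledger)

cfg2 = dataclasses.replace(cfg1, v_org=0.24)   # add the oil layer
init = {s: run1.timeseries.aq(s)[-1] / reg[s].molar_mass * 1000.0
        for s in ("lactate", "acetate", "propionate", "n-butyrate",
                  "n-caproate", "n-caprylate")}
params2 = dataclasses.replace(
    params, x0_emeq_per_L=float(run1.ledger["biomass_emeq_per_L"].iloc[-1]))
run2 = cf.simulate_cstr(params2, cfg2, t_end=114.0, t_start=99.0, initial_mM=init)
s2 = cf.build_period_summary(run2.timeseries, cfg2, (100, 113), reg, ledger=run2.ledger)

for label, s in [("non-extractive (60-90 d)", s1), ("extractive (100-113 d)", s2)]:
    r = s.rates["n-caproate"]
    print(f"{label}:")
    print(f"  nC6 rate            {r.g_per_L_d:6.2f} g/L/d  ({r.emeq_per_L_d:7.1f} e- meq/L/d)")
    print(f"  nC6 e- selectivity  {s.electron_selectivity_pct['n-caproate']:6.1f} %"
          f"   (MCC {s.mcc_selectivity_pct:.1f} %)")
    print(f"  acid demand         {s.acid_mol_per_mol_mcc:6.2f} mol H+/mol MCC")
    print(f"  electron gap        {s.gaps.electron_gap_pct:6.2f} % (assigned to biomass)")

oil_c6 = run2.timeseries.org("n-caproate")[-1]
oil_c8 = run2.timeseries.org("n-caprylate")[-1]
rep = cf.oil_composition_report({"n-caproate": oil_c6, "n-caprylate": oil_c8}, reg)
print(f"harvested oil: {oil_c6:.0f} g nC6/L, {oil_c8:.1f} g nC8/L "
      f"-> {rep.wt_pct_whole_oil:.1f} wt% MCC")
print("The rate/selectivity gain from phase 1 to phase 2 is the in-situ"
      " product-removal effect: extraction lowers the undissociated acid below"
      " its inhibitory range.")
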