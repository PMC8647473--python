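# Methods

## Scope and data model

The package analyses two-phase carboxylate fermentations: a stirred,
continuously fed broth (aqueous phase) under a static solvent overlay
(organic phase) that extracts medium-chain carboxylates (MCC) in situ. All
analysis operates on a `ReactorTimeSeries` — per-timepoint aqueous and
organic concentrations (g/L), pH, off-gas rates and acid dosing — plus a
`ReactorConfig` (volumes, HRT, vessel diameter, feed). A TSV-backed compound
registry supplies molar masses, formulas, electron equivalents and pKa
values; users can extend it (e.g. with C10/C12 acids) without code changes.

## Electron and carbon bookkeeping

Electron equivalents are computed from the degree-of-reduction identity
4C + H − 2O, which the registry enforces for every compound at load time, and
1 e⁻ eq is taken as 8 g COD (one O₂ accepts four electrons). Carboxylates
are always the sum of dissociated and undissociated forms and are represented
with the free acid's formula and mass. Registry molar masses are fixed
standard values (lactate 90.08, acetate 60.05 … n-caproate 116.16,
n-caprylate 144.21 g/mol); they must agree with the formula-derived mass to
0.5%. pKa defaults are the standard dilute-water values (lactic 3.86, acetic
4.76, propionic 4.87, n-butyric 4.82, n-valeric 4.84, n-caproic 4.88,
n-heptanoic and n-caprylic 4.89); no activity-coefficient or temperature
corrections are applied.

## Extraction metrics

K_D is the total-concentration ratio organic/aqueous at sampling pH. The
partition coefficient is implemented as P = f_HA(pH, pKa)/K_D — the
undissociated aqueous share over the total organic load. This definition is
a reconstruction (the convention is not uniquely fixed in the field) chosen
because it reproduces the reference batch-extraction P values for all four
carboxylates at pH 4.8 with the default pKa table; it is exposed behind an
explicit `definition` switch so alternatives can be added. Recovery always
uses measured amounts, never the K_D-implied closed form: sampling changes
phase volumes in real experiments, so measured recoveries need not equal
K_D·r/(1+K_D·r) (that identity is kept as a test oracle for the simulator,
where the system truly is closed). Specificity shares are on a mass basis
(the basis is ambiguous in published tables; mass is the documented default).
Back-extraction assumes complete transfer of carboxylates from the oil sample
into the alkaline phase at the given volume ratio (default 1:4 oil:alkali).

The oil composition report expresses each MCC as a percentage of the oil's
total carboxylic acids assuming those make up f_CA = 0.97 of the oil by
weight (sunflower-oil triglyceride content), plus a direct whole-oil basis
100·ΣC_i/(ρ·1000) with ρ = 0.902 kg/L, and the nC8-to-nC6 ratio in % mol
carbon.

## Performance accounting

Production rates use r_i = D·(C̄_aq,i − C_feed,i) + ΔM_org,i/(V_aq·Δt),
averaged arithmetically over sampling intervals inside a user-defined period
(steady-state sample sets are inherently a judgment call, so period
boundaries are explicit inputs, and the first point of a period is the
organic-inventory baseline). Negative organic increments (re-solubilization
from the oil) are kept with sign. Areal extraction fluxes divide by the
vessel cross-section π·d²/4 — 8.659×10⁻³ m² at the default 10.5 cm diameter.

Electron selectivity divides each net product's electron rate by the summed
electron rate of all net products, including H₂ and CH₄; net-consumed
species (normally lactate and acetate) are excluded from the denominator,
and acetate switches sides automatically if it is net-produced. Carbon
selectivity is reported both excluding and including CO₂, because published
treatments vary; when gas CO₂ is not measured it is estimated as one CO₂
per lactate consumed (exact for the elongation routes below, a mild
overestimate when the propionate branch is active) and flagged as estimated.
Acid demand per MCC converts each MCC electron rate with its own electron
equivalence rather than lumping everything as n-caproate.

Balance closure is gap = (inflow − outflow − accumulation)/inflow on both
electron and carbon bases; the positive gap is reported as the
biomass-assigned fraction. Two integration paths exist: from raw sampled
series the flow integrals are trapezoidal (O(Δt²) quadrature error, adequate
for real data), while simulator output carries a cumulative ledger integrated
inside the ODE solver, making closure exact to solver tolerance — this is the
path used to verify conservation by construction.

## The synthetic-data generator

The simulator emulates the study conditions of an MCC-selective
lactate-elongating microbiome: a 1.2-L CSTR (10.5 cm diameter) at HRT 2 d,
pH 5.0, fed 40 g/L l-lactate and 5 g/L acetate, optionally under a 20% v/v
sunflower-oil layer; batch mode reproduces 40-mL bottles with the same 20%
overlay, and zero-biomass mode reproduces abiotic extraction fed a synthetic
effluent (lactate 11, acetate 2.6, n-butyrate 1.3, n-caproate 6.1 g/L).

Catabolism is a fixed electron-flux allocation over six balanced routes
(each conserves electrons and carbon exactly, enforced at construction):

| route | stoichiometry (mol) |
|---|---|
| donor-only elongation | 3 lactate → nC6 + 2 H₂ + 3 CO₂ |
| acceptor elongation | 2 lactate + acetate → nC6 + 2 CO₂ |
| butyrate, donor-only | 2 lactate → nC4 + 2 H₂ + 2 CO₂ |
| butyrate from acetate | lactate + acetate → nC4 + CO₂ |
| caprylate | lactate + nC6 → nC8 + CO₂ |
| propionate branch | 3 lactate → 2 propionate + acetate + CO₂ |

Uptake is Monod in lactate (Ks 50 mM) with biomass tracked in e⁻ meq/L;
acceptor-gated routes carry an additional Monod term (Ks 5 mM). A fixed
fraction f = 0.05 of consumed lactate electrons is assimilated into biomass
(with lactate's 0.25 mol C per e⁻ eq), which is what the balance gap
recovers. Elongation routes are attenuated by the factor
clamp(1 − (HA − 26)/(37 − 26), 0, 1) of undissociated n-caproic acid — a
linear ramp between the reported threshold (26 mM, ~3 g/L) and
complete-inhibition (37 mM, ~4.3 g/L) concentrations; only the endpoints are
constrained by observation, the linear form is a modelling choice. Transfer
to the solvent is a linear two-film term J_i = kA_i·(C_aq,i − C_org,i/K_D,i)
applied to extractable compounds only; K_D is treated as a pH-specific
effective input (nC6 12, nC8 40 under continuous pH-5 conditions; 2.5 for
nC6 in the batch/abiotic examples) rather than decomposed into speciation ×
intrinsic partitioning. pH follows the configured setpoint or profile — it
is not solved from charge balance — and the acid ledger integrates a dose of
k_acid = 0.72 mol H⁺ per mol lactate consumed (the feed is a lactate salt,
so consumption liberates alkalinity the pH controller neutralizes); this
reproduces an acid demand of ~2.4–2.5 mol H⁺/mol MCC at the default
operating point. The default allocation (80% donor-only nC6, 8.5% acceptor
nC6, 4% + 4% nC4 routes, 0.5% nC8, 3% propionate) yields, at steady state,
residual lactate ~19–20 g/L, aqueous nC6 ~7.4 g/L, nC6 rates ~1030 e⁻
meq/L/d rising ~25% under extraction, electron selectivities ~77% nC6 / ~9%
nC4 / ~9% H₂, and an MCC-enriched oil of ~75 g nC6/L and ~2.7 g nC8/L
(~8.7 wt% MCC) after 15 days.

Numerics: LSODA with rtol 1e-8 / atol 1e-10 on a fixed output grid (default
cadence 0.5 d, the every-other-day sampling rhythm); states and all
cumulative ledgers are integrated together, so electron closure holds to
~1e-14 relative. Non-finite states abort with the solver diagnostic.
Measurement noise is multiplicative lognormal, x·exp(σZ) clipped at zero
(CV ≈ σ), applied to concentration/gas/acid observables only, seeded and
reproducible; the default σ is 0 and the acceptance script uses σ = 0.05,
a typical replicate-level CV of GC/HPLC carboxylate quantification. An
optional exponential activity-decay hook (default off) can emulate the
progressive rate loss sometimes seen after prolonged solvent contact.
K_D recovery (`fit_kd`) is the through-origin least-squares slope of C_org
vs C_aq over the equilibrated tail of a run.

## What the generator does and does not emulate

It reproduces the structure real campaign data have — two-phase inventories,
off-gas, acid dosing, inhibition-limited steady states, extraction relief,
re-solubilization when production declines — so every pipeline stage can be
tested closed-loop against known ground truth. It does **not** model
microbial community composition or shifts (the pH-7 product switch to
propionate/butyrate is a community phenomenon outside the kinetics), gas–
liquid transfer beyond a stoichiometric ledger, mechanistic pH/charge
balance, or solvent chemistry (reactive extractants, triglyceride
hydrolysis). One structural limitation is worth stating: within any closed,
electron-balanced reaction basis, the reported combination of ~10% H₂
selectivity, ~10% nC4, ~74% nC6 **and** a lactate:acetate consumption ratio
of ~6.4 cannot hold simultaneously (H₂-producing donor-only routes cannot
also consume acetate at that share); the defaults favour the MCC
selectivity/rate/acid figures, and the emergent lactate:acetate ratio is
~13–16. Passing tests therefore demonstrate correct accounting and solver
fidelity on data of realistic structure, not predictive accuracy for any
particular microbiome.

## Degenerate inputs and tie-breaks

Unknown compounds, non-monotone time, negative concentrations, zero
denominators (aqueous concentration for K_D, organic load for specificity,
MCC rate for acid metrics, lactate/acetate consumption for stoichiometric
ratios, inflow for closure) all raise with the offending name or row rather
than returning silent NaNs. Full precision is retained internally; rounding
to reported precision (1 dp for K_D/P/ratios, 1–2 dp for percentages)
happens only at presentation.

## Problem sizes

Default test and acceptance runs use 80–120 day campaigns at 0.5 d output
cadence (a few hundred ODE output points, ~30 integrator states), chosen as
representative of one full reactor campaign; a 120-day two-phase simulation
integrates in well under a second on one CPU.
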