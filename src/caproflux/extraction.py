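"""Two-phase liquid-liquid extraction metrics and oil-composition reports.

Quantifies how carboxylates partition between fermentation broth (aqueous
phase) and a vegetable-oil solvent layer (organic phase):

* ``K_D`` -- distribution ratio, total organic over total aqueous
  concentration at sampling pH.
* ``P`` -- partition coefficient referenced to the extractable
  (undissociated) species: implemented as f_HA(pH, pKa) / K_D.  The smaller
  P, the more of the undissociated acid pool has moved into the solvent.
* recovery -- percentage of a compound's total amount residing in the solvent.
* specificity -- a compound's share of the solvent's total carboxylate load.

Also covers back-extraction arithmetic (oil samples are shaken with alkaline
buffer at a known volume ratio, and carboxylates are quantified in the
aqueous back-extract) and the composition report for MCC-enriched oil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .compounds import MCC_NAMES, Compound, Registry
from .speciation import undissociated_fraction

__all__ = [
    "PhaseAmounts",
    "ExtractionMetrics",
    "OilCompositionReport",
    "distribution_ratio",
    "partition_coefficient",
    "recovery",
    "equilibrium_recovery",
    "specificity",
    "back_extraction_conc",
    "oil_composition_report",
    "batch_extraction_metrics",
    "metrics_table",
]


@dataclass(frozen=True)
class PhaseAmounts:
    """Per-compound masses (g) in each phase of a closed two-phase system."""

    amounts_org: Mapping[str, float]
    amounts_aq: Mapping[str, float]
    v_aq: float
    v_org: float

    def __post_init__(self) -> None:
        if self.v_aq <= 0 or self.v_org <= 0:
            raise ValueError("phase volumes must be > 0")
        for phase, amounts in (("organic", self.amounts_org), ("aqueous", self.amounts_aq)):
            for name, a in amounts.items():
                if a < 0:
                    raise ValueError(f"{phase} amount of {name} must be >= 0, got {a}")

    def conc_org(self, name: str) -> float:
        return self.amounts_org.get(name, 0.0) / self.v_org

    def conc_aq(self, name: str) -> float:
        return self.amounts_aq.get(name, 0.0) / self.v_aq


@dataclass(frozen=True)
class ExtractionMetrics:
    """Extraction performance of one carboxylate in one solvent."""

    compound: str
    kd: float
    p: float | None
    recovery_pct: float
    specificity_pct: float


def distribution_ratio(c_org: float, c_aq: float) -> float:
    """K_D = C_org / C_aq (total concentrations, any consistent unit)."""
    if c_org < 0 or c_aq < 0:
        raise ValueError("concentrations must be >= 0")
    if c_aq == 0:
        raise ZeroDivisionError("K_D undefined: aqueous concentration is zero")
    return c_org / c_aq


def partition_coefficient(
    kd: float,
    pH: float,
    compound: Compound,
    definition: str = "undissociated_over_kd",
) -> float:
    """Partition coefficient P referenced to the undissociated acid.

    The default (and only built-in) definition is
    ``P = undissociated_fraction(pH, pKa) / K_D`` -- the undissociated
    aqueous share relative to the total organic load.  ``definition`` is an
    explicit switch so alternative conventions can be added without changing
    call sites.
    """
    if definition != "undissociated_over_kd":
        raise ValueError(f"unknown P definition: {definition!r}")
    if compound.pKa is None:
        raise ValueError(f"{compound.name} has no pKa; P undefined")
    if kd <= 0:
        raise ValueError(f"K_D must be > 0 to compute P, got {kd}")
    return undissociated_fraction(pH, compound.pKa) / kd


def recovery(amount_org: float, amount_aq: float) -> float:
    """Percent of a compound's total amount residing in the organic phase."""
    if amount_org < 0 or amount_aq < 0:
        raise ValueError("amounts must be >= 0")
    total = amount_org + amount_aq
    if total == 0:
        raise ZeroDivisionError("recovery undefined: compound absent from both phases")
    return 100.0 * amount_org / total


def equilibrium_recovery(kd: float, volume_ratio: float) -> float:
    """Closed-form recovery of an equilibrated closed system.

    With r = V_org/V_aq, mass balance gives recovery = 100 * K_D r / (1 + K_D r).
    Used as an independent oracle against simulated batch extractions; actual
    experiment analysis always uses measured amounts (sampling changes
    volumes, so measured recoveries need not obey this identity).
    """
    if kd < 0 or volume_ratio <= 0:
        raise ValueError("need K_D >= 0 and volume ratio > 0")
    x = kd * volume_ratio
    return 100.0 * x / (1.0 + x)


def specificity(org_amounts: Mapping[str, float]) -> dict[str, float]:
    """Percent share of each carboxylate in the organic phase's total load.

    Basis is mass (g) in the organic phase; shares sum to 100 over the
    compounds present.  Raises on an empty organic phase.
    """
    total = sum(org_amounts.values())
    if total <= 0:
        raise ZeroDivisionError("specificity undefined: organic phase holds no carboxylates")
    for name, a in org_amounts.items():
        if a < 0:
            raise ValueError(f"negative organic amount for {name}")
    return {name: 100.0 * a / total for name, a in org_amounts.items()}


def back_extraction_conc(c_back: float, v_alkali: float, v_oil: float) -> float:
    """Concentration in the oil (g/L) from a back-extract measurement.

    Assumes complete transfer of carboxylates from the oil sample into the
    alkaline aqueous phase (e.g. 0.5 mL oil shaken with 2 mL sodium borate,
    a 1:4 oil-to-alkali ratio): C_oil = C_back * V_alkali / V_oil.
    """
    if v_alkali <= 0 or v_oil <= 0:
        raise ValueError("volumes must be > 0")
    if c_back < 0:
        raise ValueError("back-extract concentration must be >= 0")
    return c_back * v_alkali / v_oil


@dataclass(frozen=True)
class OilCompositionReport:
    """Composition of an MCC-enriched oil.

    ``pct_of_carboxylic_acids`` expresses each MCC as g per 100 g of the
    oil's total carboxylic acids (assumed to make up ``f_ca`` of the oil by
    weight, default 0.97); ``wt_pct_mcc`` is the MCC share of the whole oil
    on that same basis, and ``wt_pct_whole_oil`` is the direct whole-oil
    basis 100 * sum(C_i) / (density * 1000).
    """

    pct_of_carboxylic_acids: Mapping[str, float]
    wt_pct_mcc: float
    wt_pct_whole_oil: float
    nc8_to_nc6_pct_mol_c: float | None
    density_kg_per_L: float
    f_ca: float


def oil_composition_report(
    c_oil_g_per_L: Mapping[str, float],
    registry: Registry,
    density_kg_per_L: float = 0.902,
    f_ca: float = 0.97,
) -> OilCompositionReport:
    """Build an :class:`OilCompositionReport` from per-MCC oil concentrations.

    ``c_oil_g_per_L`` maps compound names to concentrations in the oil (g/L),
    typically back-extraction estimates.  The nC8-to-nC6 ratio is reported in
    % mol carbon and is ``None`` when n-caprylate is absent; a zero n-caproate
    concentration with nonzero n-caprylate is an error.
    """
    if density_kg_per_L <= 0:
        raise ValueError("oil density must be > 0")
    if not 0 < f_ca <= 1:
        raise ValueError("carboxylic-acid mass fraction must be in (0, 1]")
    oil_g_per_L = density_kg_per_L * 1000.0
    pct_ca = {
        name: 100.0 * c / (oil_g_per_L * f_ca) for name, c in c_oil_g_per_L.items()
    }
    mcc_pct = sum(v for k, v in pct_ca.items() if k in MCC_NAMES)
    wt_pct_mcc = mcc_pct * f_ca
    wt_pct_whole = 100.0 * sum(
        c for k, c in c_oil_g_per_L.items() if k in MCC_NAMES
    ) / oil_g_per_L

    c6 = c_oil_g_per_L.get("n-caproate", 0.0)
    c8 = c_oil_g_per_L.get("n-caprylate", 0.0)
    if c8 > 0 and c6 <= 0:
        raise ZeroDivisionError("nC8-to-nC6 ratio undefined: no n-caproate in oil")
    ratio = None
    if c6 > 0:
        mol_c8 = c8 / registry["n-caprylate"].molar_mass * 8
        mol_c6 = c6 / registry["n-caproate"].molar_mass * 6
        ratio = 100.0 * mol_c8 / mol_c6
    return OilCompositionReport(
        pct_of_carboxylic_acids=pct_ca,
        wt_pct_mcc=wt_pct_mcc,
        wt_pct_whole_oil=wt_pct_whole,
        nc8_to_nc6_pct_mol_c=ratio,
        density_kg_per_L=density_kg_per_L,
        f_ca=f_ca,
    )


def batch_extraction_metrics(
    phases: PhaseAmounts,
    pH: float,
    registry: Registry,
) -> dict[str, ExtractionMetrics]:
    """All extraction metrics of a (final-timepoint) two-phase batch system.

    K_D and P use concentrations; recovery and specificity use measured
    amounts.  Compounds absent from the organic phase get specificity 0; K_D
    is NaN where the aqueous concentration is zero.
    """
    names = sorted(set(phases.amounts_org) | set(phases.amounts_aq))
    spec = (
        specificity({n: phases.amounts_org.get(n, 0.0) for n in names})
        if sum(phases.amounts_org.values()) > 0
        else {n: 0.0 for n in names}
    )
    out: dict[str, ExtractionMetrics] = {}
    for name in names:
        c_aq, c_org = phases.conc_aq(name), phases.conc_org(name)
        kd = c_org / c_aq if c_aq > 0 else math.nan
        cpd = registry[name]
        p = None
        if kd > 0 and cpd.pKa is not None:
            p = partition_coefficient(kd, pH, cpd)
        rec = recovery(phases.amounts_org.get(name, 0.0), phases.amounts_aq.get(name, 0.0))
        out[name] = ExtractionMetrics(
            compound=name, kd=kd, p=p, recovery_pct=rec, specificity_pct=spec.get(name, 0.0)
        )
    return out


def metrics_table(metrics: Mapping[str, ExtractionMetrics]) -> pd.DataFrame:
    """Tidy table of extraction metrics, one row per compound, units in headers."""
    rows = [
        {
            "compound": m.compound,
            "K_D [-]": m.kd,
            "P [-]": m.p,
            "recovery [%]": m.recovery_pct,
            "specificity [%]": m.specificity_pct,
        }
        for m in metrics.values()
    ]
    return pd.DataFrame(rows).set_index("compound").sort_index()
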