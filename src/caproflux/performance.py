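"""Period-level CSTR performance accounting on electron and carbon bases.

Production rates combine the chemostat washout term with the inventory change
of the solvent overlay:

    r_i = D * (mean C_aq,i - C_feed,i) + dM_org,i / (V_aq dt)

normalized to the broth working volume.  Negative organic-phase increments
(re-solubilization from the oil back into the broth) are kept with sign.
Electron selectivities divide each net-produced species' electron rate by the
summed electron rate of all net products (carboxylates produced plus H2 and
CH4); net-consumed substrates are excluded from the denominator.  Balance
closure reports the gap between inflow and (outflow + accumulation); in a
reactor the unaccounted share is conventionally assigned to biomass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .compounds import (
    MCC_NAMES,
    Registry,
    g_per_L_to_emeq,
)
from .reactor import ReactorConfig, ReactorTimeSeries

__all__ = [
    "Rate",
    "BalanceGaps",
    "StoichiometricSummary",
    "PerformanceSummary",
    "production_rate",
    "extraction_flux",
    "areal_flux",
    "net_rates",
    "electron_selectivity",
    "mcc_selectivity",
    "carbon_selectivity_and_efficiency",
    "estimate_co2_mmol",
    "acid_dose_metrics",
    "stoichiometric_summary",
    "balance_closure",
    "build_period_summary",
]

GAS_ELECTRON_EQ = {"H2": 2, "CH4": 8, "CO2": 0}
GAS_COLUMNS = {"H2": "gas_h2_mmol_per_d", "CH4": "gas_ch4_mmol_per_d", "CO2": "gas_co2_mmol_per_d"}


@dataclass(frozen=True)
class Rate:
    """A net production rate in the three bookkeeping currencies."""

    compound: str
    g_per_L_d: float
    mmol_per_L_d: float
    emeq_per_L_d: float
    mmolC_per_L_d: float


def _window(ts: ReactorTimeSeries, period: tuple[float, float]) -> ReactorTimeSeries:
    t0, t1 = period
    if t1 <= t0:
        raise ValueError(f"period end {t1} must exceed start {t0}")
    return ts.window(t0, t1)


def _interval_mean(values: np.ndarray) -> np.ndarray:
    return 0.5 * (values[:-1] + values[1:])


def production_rate(
    ts: ReactorTimeSeries,
    cfg: ReactorConfig,
    period: tuple[float, float],
    compound: str,
    registry: Registry,
) -> Rate:
    """Period-averaged net production rate of one compound (per L broth).

    The period average is the arithmetic mean of per-interval rates; the
    first timepoint in the period serves as baseline for the organic-phase
    inventory.  Substrates come out negative (net consumption).
    """
    w = _window(ts, period)
    d = cfg.dilution_rate
    dt = np.diff(w.time)
    feed = cfg.feed.get(compound, 0.0)
    aq_term = d * (_interval_mean(w.aq(compound)) - feed)
    d_m_org = np.diff(w.org(compound)) * cfg.v_org
    rate_g = float(np.mean(aq_term + d_m_org / (cfg.v_aq * dt)))
    cpd = registry[compound]
    mmol = rate_g / cpd.molar_mass * 1000.0
    return Rate(
        compound=compound,
        g_per_L_d=rate_g,
        mmol_per_L_d=mmol,
        emeq_per_L_d=mmol * cpd.electron_eq,
        mmolC_per_L_d=mmol * cpd.n_carbon,
    )


def extraction_flux(
    ts: ReactorTimeSeries,
    cfg: ReactorConfig,
    period: tuple[float, float],
    compound: str,
) -> float:
    """Net flux into the solvent, g per L broth per day (signed).

    This is the quantity behind per-period extraction-rate figures: the
    organic-phase inventory change between consecutive samplings, normalized
    to broth volume and time.  Negative values mean re-solubilization.
    """
    w = _window(ts, period)
    d_m_org = np.diff(w.org(compound)) * cfg.v_org
    return float(np.mean(d_m_org / (cfg.v_aq * np.diff(w.time))))


def areal_flux(volumetric_flux_g_per_L_d: float, cfg: ReactorConfig) -> float:
    """Convert a broth-volumetric flux (g/L/d) to an areal one (g/m2/d).

    The transfer area is the broth-solvent interface, i.e. the vessel
    cross-section pi d^2/4 (8.659e-3 m2 for d = 10.5 cm).
    """
    return volumetric_flux_g_per_L_d * cfg.v_aq / cfg.interface_area_m2


def net_rates(
    ts: ReactorTimeSeries,
    cfg: ReactorConfig,
    period: tuple[float, float],
    registry: Registry,
) -> dict[str, Rate]:
    """Net rates for every tracked compound plus H2/CH4/CO2 off-gas."""
    rates = {
        name: production_rate(ts, cfg, period, name, registry)
        for name in ts.compounds
    }
    w = _window(ts, period)
    for gas, col in GAS_COLUMNS.items():
        mmol = float(np.mean(_interval_mean(w.rate(col)))) / cfg.v_aq
        cpd = registry[gas] if gas in registry else None
        rates[gas] = Rate(
            compound=gas,
            g_per_L_d=mmol * cpd.molar_mass / 1000.0 if cpd else np.nan,
            mmol_per_L_d=mmol,
            emeq_per_L_d=mmol * GAS_ELECTRON_EQ[gas],
            mmolC_per_L_d=mmol * (cpd.n_carbon if cpd else 0),
        )
    return rates


def acid_rate(ts: ReactorTimeSeries, cfg: ReactorConfig, period: tuple[float, float]) -> float:
    """Period-averaged acid dosing rate, mmol H+ per L broth per day."""
    w = _window(ts, period)
    return float(np.mean(_interval_mean(w.rate("acid_mmol_per_d")))) / cfg.v_aq


def electron_selectivity(rates_emeq: Mapping[str, float]) -> dict[str, float]:
    """Percent share of each net product in the total product electron flux.

    Input maps species to net electron rates (e- meq/L/d, signed).  Only
    net-produced species (rate > 0) enter numerator and denominator;
    net-consumed substrates are excluded.  Species without electrons (CO2)
    drop out naturally.
    """
    products = {k: v for k, v in rates_emeq.items() if v > 0}
    total = sum(products.values())
    if total <= 0:
        raise ZeroDivisionError("electron selectivity undefined: no net products")
    return {k: 100.0 * v / total for k, v in products.items()}


def mcc_selectivity(selectivities_pct: Mapping[str, float]) -> float:
    """Summed selectivity of the medium-chain carboxylates (nC6-nC8)."""
    return sum(selectivities_pct.get(n, 0.0) for n in MCC_NAMES)


def estimate_co2_mmol(lactate_consumed_mmol_per_L_d: float) -> float:
    """Stoichiometric CO2 estimate: ~1 CO2 released per lactate consumed.

    Every elongation step decarboxylates its lactate-derived C3 unit once, so
    absent gas-phase CO2 measurements the CO2 carbon rate is approximated by
    the lactate consumption rate (exact for the elongation routes; the
    propionate branch releases less, making this a mild upper bound).
    """
    if lactate_consumed_mmol_per_L_d < 0:
        raise ValueError("lactate consumption must be >= 0")
    return lactate_consumed_mmol_per_L_d


def carbon_selectivity_and_efficiency(
    rates_mmolC: Mapping[str, float],
    substrate_consumed_mmolC: float,
    compound: str,
    co2_mmolC: float | None = None,
) -> tuple[float, float]:
    """Carbon selectivity and conversion efficiency of one product, in %.

    Selectivity divides the product's carbon rate by the total product carbon
    (net-produced species, plus CO2 when supplied); efficiency divides it by
    the substrate carbon consumed.
    """
    if substrate_consumed_mmolC <= 0:
        raise ZeroDivisionError("carbon efficiency undefined: no substrate consumed")
    products = {k: v for k, v in rates_mmolC.items() if v > 0 and k != "CO2"}
    if compound not in products:
        raise ValueError(f"{compound!r} is not among the net products")
    denom = sum(products.values()) + (co2_mmolC or 0.0)
    sel = 100.0 * products[compound] / denom
    eff = 100.0 * products[compound] / substrate_consumed_mmolC
    return sel, eff


def acid_dose_metrics(
    acid_mmol_per_L_d: float,
    mcc_rates_emeq: Mapping[str, float],
    registry: Registry,
) -> float:
    """Acid demand per MCC produced, mol H+ per mol MCC.

    The MCC molar rate converts each compound's electron rate with its own
    electron equivalence (r_i / e_i), not an n-caproate lump.
    """
    if acid_mmol_per_L_d < 0:
        raise ValueError("acid rate must be >= 0")
    molar = sum(
        rate / registry[name].electron_eq
        for name, rate in mcc_rates_emeq.items()
        if name in MCC_NAMES and rate > 0
    )
    if molar <= 0:
        raise ZeroDivisionError("no net MCC production; acid-per-MCC undefined")
    return acid_mmol_per_L_d / molar


@dataclass(frozen=True)
class StoichiometricSummary:
    lactate_to_acetate_mol: float
    nc6_per_lactate_mol: float


def stoichiometric_summary(net_rates_mmol: Mapping[str, float]) -> StoichiometricSummary:
    """Molar consumption/production ratios from signed net rates (mmol/L/d)."""
    lac = net_rates_mmol.get("lactate", 0.0)
    ace = net_rates_mmol.get("acetate", 0.0)
    nc6 = net_rates_mmol.get("n-caproate", 0.0)
    if lac >= 0:
        raise ZeroDivisionError("no net lactate consumption; ratios undefined")
    if ace >= 0:
        raise ZeroDivisionError("no net acetate consumption; lactate:acetate undefined")
    return StoichiometricSummary(
        lactate_to_acetate_mol=lac / ace,
        nc6_per_lactate_mol=nc6 / (-lac),
    )


@dataclass(frozen=True)
class BalanceGaps:
    """Relative closure gaps, % of inflow, on electron and carbon bases.

    gap = (inflow - outflow - accumulation) / inflow.  In fermentation data a
    positive gap is conventionally assigned to biomass assimilation; negative
    gaps indicate measurement inconsistency and are reported with sign.
    """

    electron_gap_pct: float
    carbon_gap_pct: float


def _ledger_delta(ledger: pd.DataFrame, col: str, t0: float, t1: float) -> float:
    t = ledger["time_d"].to_numpy(float)
    v = ledger[col].to_numpy(float)
    return float(np.interp(t1, t, v) - np.interp(t0, t, v))


def balance_closure(
    ts: ReactorTimeSeries,
    cfg: ReactorConfig,
    period: tuple[float, float],
    registry: Registry,
    ledger: pd.DataFrame | None = None,
) -> BalanceGaps:
    """Electron and carbon balance closure over a period.

    With a simulator ledger (cumulative integrals carried inside the ODE
    solver) the gaps are exact to solver tolerance; from raw sampled data the
    flow integrals use trapezoidal quadrature, so the result carries an
    O(dt^2) quadrature error on top of measurement noise.
    """
    t0, t1 = period
    if ledger is not None:
        in_e = _ledger_delta(ledger, "cum_feed_emeq_per_L", t0, t1)
        out_e = _ledger_delta(ledger, "cum_eff_emeq_per_L", t0, t1) + _ledger_delta(
            ledger, "cum_gas_emeq_per_L", t0, t1
        )
        acc_e = _ledger_delta(ledger, "inv_emeq_per_L", t0, t1)
        in_c = _ledger_delta(ledger, "cum_feed_mmolC_per_L", t0, t1)
        out_c = _ledger_delta(ledger, "cum_eff_mmolC_per_L", t0, t1) + _ledger_delta(
            ledger, "cum_gas_mmolC_per_L", t0, t1
        )
        acc_c = _ledger_delta(ledger, "inv_mmolC_per_L", t0, t1)
    else:
        w = _window(ts, period)
        d = cfg.dilution_rate
        t = w.time
        span = t[-1] - t[0]
        e_aq = np.zeros(len(w))
        c_aq = np.zeros(len(w))
        e_inv = np.zeros(len(w))
        c_inv = np.zeros(len(w))
        r = cfg.v_org / cfg.v_aq
        for name in w.compounds:
            cpd = registry[name]
            aq, org = w.aq(name), w.org(name)
            e_aq += aq / cpd.molar_mass * cpd.electron_eq * 1000.0
            c_aq += aq / cpd.molar_mass * cpd.n_carbon * 1000.0
            e_inv += (aq + org * r) / cpd.molar_mass * cpd.electron_eq * 1000.0
            c_inv += (aq + org * r) / cpd.molar_mass * cpd.n_carbon * 1000.0
        feed_e = sum(
            g_per_L_to_emeq(cf, registry[n]) for n, cf in cfg.feed.items()
        )
        feed_c = sum(
            cf / registry[n].molar_mass * registry[n].n_carbon * 1000.0
            for n, cf in cfg.feed.items()
        )
        gas_e = (2 * w.rate("gas_h2_mmol_per_d") + 8 * w.rate("gas_ch4_mmol_per_d")) / cfg.v_aq
        gas_c = (w.rate("gas_co2_mmol_per_d") + w.rate("gas_ch4_mmol_per_d")) / cfg.v_aq
        in_e = d * feed_e * span
        in_c = d * feed_c * span
        out_e = float(np.trapezoid(d * e_aq + gas_e, t))
        out_c = float(np.trapezoid(d * c_aq + gas_c, t))
        acc_e = float(e_inv[-1] - e_inv[0])
        acc_c = float(c_inv[-1] - c_inv[0])
    if in_e <= 0 or in_c <= 0:
        raise ZeroDivisionError("balance closure undefined: zero inflow over period")
    return BalanceGaps(
        electron_gap_pct=100.0 * (in_e - out_e - acc_e) / in_e,
        carbon_gap_pct=100.0 * (in_c - out_c - acc_c) / in_c,
    )


@dataclass(frozen=True)
class PerformanceSummary:
    """Everything the per-period report table needs, full precision."""

    period: tuple[float, float]
    rates: dict[str, Rate]
    electron_selectivity_pct: dict[str, float]
    mcc_selectivity_pct: float
    nc6_carbon_selectivity_pct: float | None
    nc6_carbon_selectivity_with_co2_pct: float | None
    nc6_carbon_efficiency_pct: float | None
    co2_estimated: bool
    acid_mmol_per_L_d: float
    acid_mol_per_mol_mcc: float | None
    gaps: BalanceGaps
    stoichiometry: StoichiometricSummary | None
    nc6_extraction_flux_g_per_L_d: float
    nc6_areal_flux_g_per_m2_d: float


def build_period_summary(
    ts: ReactorTimeSeries,
    cfg: ReactorConfig,
    period: tuple[float, float],
    registry: Registry,
    ledger: pd.DataFrame | None = None,
) -> PerformanceSummary:
    """Assemble the full performance summary for one operating period."""
    rates = net_rates(ts, cfg, period, registry)
    emeq = {k: r.emeq_per_L_d for k, r in rates.items()}
    sel = electron_selectivity(emeq)

    lac_cons = -rates["lactate"].mmol_per_L_d if "lactate" in rates else 0.0
    substrate_c = sum(
        -r.mmolC_per_L_d for k, r in rates.items()
        if k in ("lactate", "acetate") and r.mmolC_per_L_d < 0
    )
    mmolc = {k: r.mmolC_per_L_d for k, r in rates.items()}
    co2 = rates["CO2"].mmol_per_L_d if rates.get("CO2") else 0.0
    co2_estimated = co2 <= 0 and lac_cons > 0
    co2_used = estimate_co2_mmol(lac_cons) if co2_estimated else co2
    nc6_sel = nc6_sel_co2 = nc6_eff = None
    if substrate_c > 0 and mmolc.get("n-caproate", 0.0) > 0:
        nc6_sel, nc6_eff = carbon_selectivity_and_efficiency(
            mmolc, substrate_c, "n-caproate", co2_mmolC=None
        )
        nc6_sel_co2, _ = carbon_selectivity_and_efficiency(
            mmolc, substrate_c, "n-caproate", co2_mmolC=co2_used
        )

    acid = acid_rate(ts, cfg, period)
    try:
        acid_per_mcc = acid_dose_metrics(acid, emeq, registry)
    except ZeroDivisionError:
        acid_per_mcc = None

    try:
        stoich = stoichiometric_summary({k: r.mmol_per_L_d for k, r in rates.items()})
    except ZeroDivisionError:
        stoich = None

    flux = extraction_flux(ts, cfg, period, "n-caproate") if ts.has_organic else 0.0
    return PerformanceSummary(
        period=period,
        rates=rates,
        electron_selectivity_pct=sel,
        mcc_selectivity_pct=mcc_selectivity(sel),
        nc6_carbon_selectivity_pct=nc6_sel,
        nc6_carbon_selectivity_with_co2_pct=nc6_sel_co2,
        nc6_carbon_efficiency_pct=nc6_eff,
        co2_estimated=co2_estimated,
        acid_mmol_per_L_d=acid,
        acid_mol_per_mol_mcc=acid_per_mcc,
        gaps=balance_closure(ts, cfg, period, registry, ledger=ledger),
        stoichiometry=stoich,
        nc6_extraction_flux_g_per_L_d=flux,
        nc6_areal_flux_g_per_m2_d=areal_flux(flux, cfg),
    )
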