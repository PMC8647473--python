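"""File formats, run configuration and the analysis pipeline.

Formats: reactor time series and report tables are CSV (UTF-8, comma,
``.`` decimal, header mandatory, time in days as float), the compound
registry is TSV, run configuration is YAML, and the simulator's ground truth
sidecar is JSON.  All emitted tables carry units in their column names.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .compounds import MCC_NAMES, Registry
from .extraction import (
    PhaseAmounts,
    batch_extraction_metrics,
    metrics_table,
    oil_composition_report,
)
from .performance import PerformanceSummary, build_period_summary
from .reactor import ReactorConfig, ReactorTimeSeries
from .simulator import SimOutput, SimParams, simulate_cstr

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_batch_csv",
    "batch_phase_amounts",
    "Period",
    "AnalysisOptions",
    "RunConfig",
    "load_config",
    "ReportBundle",
    "run_pipeline",
    "render_reports",
]


def read_timeseries(path: str | Path, registry: Registry | None = None) -> ReactorTimeSeries:
    """Read and validate a reactor time-series CSV.

    Rejects missing required columns, non-monotone time, negative
    concentrations and compound columns whose name is not in the registry
    (when one is given), naming the offending column/row.
    """
    data = pd.read_csv(path)
    return ReactorTimeSeries(data, registry=registry)


def write_timeseries(ts: ReactorTimeSeries, path: str | Path) -> None:
    ts.data.to_csv(path, index=False)


def read_batch_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy batch-experiment CSV.

    Expected columns: ``time_d, phase, compound, conc_g_per_L, pH`` with
    ``phase`` one of ``aqueous``/``organic``.
    """
    df = pd.read_csv(path)
    required = {"time_d", "phase", "compound", "conc_g_per_L", "pH"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"batch CSV missing columns: {sorted(missing)}")
    bad = set(df["phase"].unique()) - {"aqueous", "organic"}
    if bad:
        raise ValueError(f"unknown phase labels: {sorted(bad)}")
    if (df["conc_g_per_L"] < 0).any():
        raise ValueError("negative concentrations in batch CSV")
    return df


def batch_phase_amounts(df: pd.DataFrame, v_aq: float, v_org: float) -> tuple[PhaseAmounts, float]:
    """Final-timepoint phase amounts (g) and pH from a tidy batch table."""
    t_last = df["time_d"].max()
    last = df[df["time_d"] == t_last]
    aq = last[last["phase"] == "aqueous"]
    org = last[last["phase"] == "organic"]
    amounts = PhaseAmounts(
        amounts_org={r.compound: r.conc_g_per_L * v_org for r in org.itertuples()},
        amounts_aq={r.compound: r.conc_g_per_L * v_aq for r in aq.itertuples()},
        v_aq=v_aq,
        v_org=v_org,
    )
    return amounts, float(last["pH"].iloc[0])


@dataclass(frozen=True)
class Period:
    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError(f"period {self.label!r}: t_end must exceed t_start")

    @property
    def span(self) -> tuple[float, float]:
        return (self.t_start, self.t_end)


@dataclass(frozen=True)
class AnalysisOptions:
    oil_density_kg_per_L: float = 0.902
    f_ca: float = 0.97           # carboxylic-acid mass fraction of the oil
    specificity_basis: str = "mass"

    def __post_init__(self) -> None:
        if self.specificity_basis != "mass":
            raise ValueError("only the mass specificity basis is implemented")


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (see ``load_config`` for the YAML)."""

    reactor: ReactorConfig = field(default_factory=ReactorConfig)
    periods: tuple[Period, ...] = ()
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    timeseries_path: str | None = None
    registry_path: str | None = None
    sim_params: SimParams | None = None
    sim_t_end: float = 120.0
    sim_dt_out: float = 0.5
    seed: int = 1
    raw: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spans = sorted(p.span for p in self.periods)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"periods overlap: [{a0},{a1}] and [{b0},{b1}]")

    def registry(self) -> Registry:
        if self.registry_path:
            return Registry.from_tsv(self.registry_path)
        return Registry.default()

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(dict(self.raw), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration.

    Top-level keys (all optional unless noted): ``reactor`` (v_aq, v_org,
    hrt, diameter, ph_setpoint, feed), ``periods`` (list of {label, t_start,
    t_end}), ``analysis``, ``timeseries`` (CSV path; when absent the
    simulator block is used to generate one), ``registry`` (TSV path),
    ``simulator`` ({t_end, dt_out, params}), ``seed``.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    reactor = ReactorConfig(**raw.get("reactor", {}))
    periods = tuple(Period(**p) for p in raw.get("periods", []))
    analysis = AnalysisOptions(**raw.get("analysis", {}))
    sim = raw.get("simulator") or {}
    seed = int(raw.get("seed", 1))
    sim_params = None
    if sim or not raw.get("timeseries"):
        sim_params = SimParams(**{**sim.get("params", {}), "seed": seed})
    return RunConfig(
        reactor=reactor,
        periods=periods,
        analysis=analysis,
        timeseries_path=raw.get("timeseries"),
        registry_path=raw.get("registry"),
        sim_params=sim_params,
        sim_t_end=float(sim.get("t_end", 120.0)),
        sim_dt_out=float(sim.get("dt_out", 0.5)),
        seed=seed,
        raw=raw,
    )


@dataclass(frozen=True)
class ReportBundle:
    """All pipeline outputs, full precision, plus provenance."""

    performance: pd.DataFrame
    extraction: pd.DataFrame
    oil: pd.DataFrame
    flux: pd.DataFrame
    summaries: dict[str, PerformanceSummary]
    provenance: dict[str, str]


def _summary_row(label: str, s: PerformanceSummary) -> dict[str, Any]:
    sel = s.electron_selectivity_pct
    stoich = s.stoichiometry
    nc6 = s.rates.get("n-caproate")
    return {
        "period": label,
        "t_start_d": s.period[0],
        "t_end_d": s.period[1],
        "nC6_rate_g_per_L_d": nc6.g_per_L_d if nc6 else float("nan"),
        "nC6_rate_emeq_per_L_d": nc6.emeq_per_L_d if nc6 else float("nan"),
        "MCC_rate_emeq_per_L_d": sum(
            s.rates[n].emeq_per_L_d for n in MCC_NAMES if n in s.rates
        ),
        "nC6_electron_selectivity_pct": sel.get("n-caproate", 0.0),
        "MCC_electron_selectivity_pct": s.mcc_selectivity_pct,
        "nC4_electron_selectivity_pct": sel.get("n-butyrate", 0.0),
        "H2_electron_selectivity_pct": sel.get("H2", 0.0),
        "nC6_carbon_selectivity_pct": s.nc6_carbon_selectivity_pct,
        "nC6_carbon_selectivity_incl_CO2_pct": s.nc6_carbon_selectivity_with_co2_pct,
        "nC6_carbon_efficiency_pct": s.nc6_carbon_efficiency_pct,
        "CO2_estimated": s.co2_estimated,
        "acid_mmol_per_L_d": s.acid_mmol_per_L_d,
        "acid_mol_per_mol_MCC": s.acid_mol_per_mol_mcc,
        "lactate_to_acetate_mol_ratio": stoich.lactate_to_acetate_mol if stoich else None,
        "nC6_yield_mol_per_mol_lactate": stoich.nc6_per_lactate_mol if stoich else None,
        "electron_gap_pct": s.gaps.electron_gap_pct,
        "carbon_gap_pct": s.gaps.carbon_gap_pct,
        "nC6_extraction_flux_g_per_L_d": s.nc6_extraction_flux_g_per_L_d,
        "nC6_areal_flux_g_per_m2_d": s.nc6_areal_flux_g_per_m2_d,
    }


def _flux_rows(label: str, s: PerformanceSummary, v_aq: float) -> list[dict[str, Any]]:
    # Carbon flux triplets for Sankey rendering: substrates feed a conversion
    # pool; the pool feeds each net product, CO2 and a biomass residual.
    rows = []
    prod_c = 0.0
    cons_c = 0.0
    for name, r in s.rates.items():
        c = r.mmolC_per_L_d * v_aq
        if name in ("lactate", "acetate") and c < 0:
            rows.append({"period": label, "source": name, "target": "conversion",
                         "mmolC_per_d": -c})
            cons_c += -c
        elif c > 0 and name != "CO2":
            rows.append({"period": label, "source": "conversion", "target": name,
                         "mmolC_per_d": c})
            prod_c += c
    co2_c = s.rates["CO2"].mmolC_per_L_d * v_aq if "CO2" in s.rates else 0.0
    if co2_c > 0:
        rows.append({"period": label, "source": "conversion", "target": "CO2",
                     "mmolC_per_d": co2_c})
        prod_c += co2_c
    rows.append({"period": label, "source": "conversion", "target": "biomass",
                 "mmolC_per_d": cons_c - prod_c})
    return rows


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the extraction + performance stages for every period.

    Deterministic given config and inputs: the same configuration produces
    byte-identical tables.
    """
    registry = config.registry()
    ledger = None
    if config.timeseries_path:
        ts = read_timeseries(config.timeseries_path, registry)
    else:
        out: SimOutput = simulate_cstr(
            config.sim_params or SimParams(seed=config.seed),
            config.reactor,
            t_end=config.sim_t_end,
            dt_out=config.sim_dt_out,
            registry=registry,
        )
        ts, ledger = out.timeseries, out.ledger

    periods = list(config.periods) or [
        Period("global", float(ts.time[0]), float(ts.time[-1]))
    ]
    t0, t1 = ts.time[0], ts.time[-1]
    for p in periods:
        if p.t_start < t0 - 1e-9 or p.t_end > t1 + 1e-9:
            raise ValueError(
                f"period {p.label!r} [{p.t_start}, {p.t_end}] outside series "
                f"range [{t0}, {t1}]"
            )

    summaries: dict[str, PerformanceSummary] = {}
    perf_rows, flux_rows, extraction_frames, oil_rows = [], [], [], []
    for p in periods:
        try:
            s = build_period_summary(ts, config.reactor, p.span, registry, ledger=ledger)
        except Exception as exc:
            raise RuntimeError(f"period {p.label!r}: {exc}") from exc
        summaries[p.label] = s
        perf_rows.append(_summary_row(p.label, s))
        flux_rows.extend(_flux_rows(p.label, s, config.reactor.v_aq))

        if ts.has_organic and config.reactor.v_org > 0:
            w = ts.window(*p.span)
            amounts_org = {
                n: w.org(n)[-1] * config.reactor.v_org
                for n in w.compounds if w.org(n)[-1] > 0
            }
            if amounts_org:
                phases = PhaseAmounts(
                    amounts_org=amounts_org,
                    amounts_aq={n: w.aq(n)[-1] * config.reactor.v_aq
                                for n in amounts_org},
                    v_aq=config.reactor.v_aq,
                    v_org=config.reactor.v_org,
                )
                m = batch_extraction_metrics(phases, float(w.ph[-1]), registry)
                frame = metrics_table(m).reset_index()
                frame.insert(0, "period", p.label)
                extraction_frames.append(frame)

                rep = oil_composition_report(
                    {n: w.org(n)[-1] for n in amounts_org},
                    registry,
                    density_kg_per_L=config.analysis.oil_density_kg_per_L,
                    f_ca=config.analysis.f_ca,
                )
                row = {"period": p.label,
                       "wt_pct_MCC": rep.wt_pct_mcc,
                       "wt_pct_MCC_whole_oil_basis": rep.wt_pct_whole_oil,
                       "nC8_to_nC6_pct_mol_C": rep.nc8_to_nc6_pct_mol_c}
                for n, v in rep.pct_of_carboxylic_acids.items():
                    row[f"{n}_pct_of_carboxylic_acids"] = v
                oil_rows.append(row)

    extraction = (
        pd.concat(extraction_frames, ignore_index=True)
        if extraction_frames
        else pd.DataFrame(columns=["period", "compound", "K_D [-]", "P [-]",
                                   "recovery [%]", "specificity [%]"])
    )
    oil = pd.DataFrame(oil_rows) if oil_rows else pd.DataFrame(
        columns=["period", "wt_pct_MCC", "wt_pct_MCC_whole_oil_basis",
                 "nC8_to_nC6_pct_mol_C"]
    )
    return ReportBundle(
        performance=pd.DataFrame(perf_rows),
        extraction=extraction,
        oil=oil,
        flux=pd.DataFrame(flux_rows),
        summaries=summaries,
        provenance={"config_hash": config.config_hash, "version": __version__},
    )


def render_reports(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write the bundle as CSV tables plus a plain-text summary (5 files)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in [
        ("performance_summary.csv", bundle.performance),
        ("extraction_metrics.csv", bundle.extraction),
        ("oil_composition.csv", bundle.oil),
        ("carbon_flux.csv", bundle.flux),
    ]:
        p = outdir / name
        frame.to_csv(p, index=False)
        paths.append(p)
    txt = outdir / "summary.txt"
    with txt.open("w", encoding="utf-8") as fh:
        fh.write(f"caproflux {bundle.provenance['version']} report "
                 f"(config {bundle.provenance['config_hash']})\n\n")
        fh.write("Per-period performance\n")
        fh.write(bundle.performance.to_string(index=False, float_format="%.4g"))
        fh.write("\n\nExtraction metrics (final sample of each period)\n")
        fh.write(bundle.extraction.to_string(index=False, float_format="%.4g"))
        fh.write("\n\nMCC-enriched oil composition\n")
        fh.write(bundle.oil.to_string(index=False, float_format="%.4g"))
        fh.write("\n")
    paths.append(txt)
    return paths


def write_ground_truth(out: SimOutput, path: str | Path) -> None:
    """JSON sidecar with the generator's ground-truth parameters."""
    params = {
        k: (dict(v) if isinstance(v, Mapping) else v)
        for k, v in vars(out.params).items()
        if not callable(v)
    }
    payload = {"params": params, "ground_truth": out.ground_truth,
               "version": __version__}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True),
                          encoding="utf-8")
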