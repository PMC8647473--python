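"""Reactor configuration and the two-phase reactor time-series container."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .compounds import Registry

__all__ = ["ReactorConfig", "ReactorTimeSeries", "AQ_SUFFIX", "ORG_SUFFIX"]

AQ_SUFFIX = "_aq_g_per_L"
ORG_SUFFIX = "_org_g_per_L"

#: Non-compound columns of a reactor time series, with units in the names.
BASE_COLUMNS = ("time_d", "pH")
RATE_COLUMNS = (
    "acid_mmol_per_d",
    "gas_h2_mmol_per_d",
    "gas_ch4_mmol_per_d",
    "gas_co2_mmol_per_d",
)


def _default_feed() -> dict[str, float]:
    # l-lactate as electron donor, acetate as acceptor (g/L).
    return {"lactate": 40.0, "acetate": 5.0}


@dataclass(frozen=True)
class ReactorConfig:
    """Geometry and operating point of a (possibly two-phase) CSTR.

    Defaults mirror a 1.2-L working-volume vessel of 10.5 cm diameter run at
    an HRT of 2 d, fed 40 g/L lactate and 5 g/L acetate, with an optional
    static solvent layer of volume ``v_org`` on top of the broth.
    """

    v_aq: float = 1.2          # broth working volume, L
    v_org: float = 0.0         # solvent overlay volume, L (0 = single phase)
    hrt: float = 2.0           # hydraulic retention time, d
    diameter: float = 0.105    # vessel diameter, m
    feed: Mapping[str, float] = field(default_factory=_default_feed)  # g/L
    ph_setpoint: float = 5.0

    def __post_init__(self) -> None:
        if self.v_aq <= 0 or self.hrt <= 0 or self.diameter <= 0:
            raise ValueError("v_aq, hrt and diameter must be > 0")
        if self.v_org < 0:
            raise ValueError("v_org must be >= 0")
        for name, c in self.feed.items():
            if c < 0:
                raise ValueError(f"negative feed concentration for {name}")

    @property
    def dilution_rate(self) -> float:
        """D = 1/HRT (1/d)."""
        return 1.0 / self.hrt

    @property
    def interface_area_m2(self) -> float:
        """Broth-solvent interface area: the vessel cross-section, pi d^2/4."""
        return math.pi * self.diameter**2 / 4.0


class ReactorTimeSeries:
    """Ordered two-phase reactor observations backed by a pandas DataFrame.

    Columns: ``time_d`` (strictly increasing), ``pH``, optional gas/acid rate
    columns (mmol/d, whole reactor), and per-compound concentrations
    ``<name>_aq_g_per_L`` / ``<name>_org_g_per_L``.  Extra ``cum_*`` ledger
    columns (from the simulator) are carried through untouched.
    """

    def __init__(self, data: pd.DataFrame, registry: Registry | None = None) -> None:
        self._validate(data, registry)
        self.data = data.reset_index(drop=True)

    @staticmethod
    def _validate(data: pd.DataFrame, registry: Registry | None) -> None:
        for col in BASE_COLUMNS:
            if col not in data.columns:
                raise ValueError(f"time series missing required column {col!r}")
        t = data["time_d"].to_numpy(float)
        if len(t) == 0:
            raise ValueError("time series is empty")
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise ValueError(
                f"time must be strictly increasing; violation at row {i} "
                f"(time_d={t[i]!r} after {t[i - 1]!r})"
            )
        for col in data.columns:
            if col.endswith(AQ_SUFFIX) or col.endswith(ORG_SUFFIX):
                name = col.removesuffix(AQ_SUFFIX).removesuffix(ORG_SUFFIX)
                if registry is not None and name not in registry:
                    raise ValueError(f"column {col!r}: unknown compound {name!r}")
                vals = data[col].to_numpy(float)
                if np.any(vals < 0):
                    raise ValueError(f"negative concentration in column {col!r}")
            elif col not in BASE_COLUMNS and col not in RATE_COLUMNS and not col.startswith("cum_"):
                raise ValueError(f"unrecognized column {col!r} in time series")

    # -- accessors ---------------------------------------------------------
    @property
    def time(self) -> np.ndarray:
        return self.data["time_d"].to_numpy(float)

    @property
    def ph(self) -> np.ndarray:
        return self.data["pH"].to_numpy(float)

    @property
    def compounds(self) -> list[str]:
        return sorted(
            {
                c.removesuffix(AQ_SUFFIX)
                for c in self.data.columns
                if c.endswith(AQ_SUFFIX)
            }
        )

    @property
    def has_organic(self) -> bool:
        return any(c.endswith(ORG_SUFFIX) for c in self.data.columns)

    def aq(self, name: str) -> np.ndarray:
        col = name + AQ_SUFFIX
        if col not in self.data.columns:
            raise KeyError(f"no aqueous concentrations for {name!r}")
        return self.data[col].to_numpy(float)

    def org(self, name: str) -> np.ndarray:
        """Organic-phase concentration (g/L of solvent); zeros if untracked."""
        col = name + ORG_SUFFIX
        if col not in self.data.columns:
            return np.zeros(len(self.data))
        return self.data[col].to_numpy(float)

    def rate(self, column: str) -> np.ndarray:
        """A gas or acid rate column (mmol/d); zeros if absent."""
        if column not in RATE_COLUMNS:
            raise KeyError(f"unknown rate column {column!r}")
        if column not in self.data.columns:
            return np.zeros(len(self.data))
        return self.data[column].to_numpy(float)

    def window(self, t_start: float, t_end: float) -> "ReactorTimeSeries":
        """Subseries with t_start <= time_d <= t_end (at least two points)."""
        mask = (self.time >= t_start) & (self.time <= t_end)
        if mask.sum() < 2:
            raise ValueError(
                f"window [{t_start}, {t_end}] contains {int(mask.sum())} point(s); "
                "need at least 2"
            )
        return ReactorTimeSeries(self.data.loc[mask].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)
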