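"""Compound registry and the unit-conversion algebra for carboxylate bookkeeping.

All accounting in extractive chain-elongation analysis rests on three
interchangeable currencies for a compound: mass (g), moles, and electron
equivalents (the degree of reduction, 4C + H - 2O per mol for C/H/O
compounds).  Electron equivalents are the natural basis for selectivity and
balance calculations because every balanced fermentation reaction conserves
them; 1 e- eq is equivalent to 8 g COD (one O2 accepts 4 electrons, 32/4 = 8).

The default registry holds the ten compounds tracked in lactate-based chain
elongation (lactate, acetate, propionate, n-butyrate, n-valerate, n-caproate,
n-heptylate, n-caprylate, H2, CH4) plus CO2, with standard molar masses and
pKa values.  It is shipped as a TSV data file so users can extend it without
code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "Compound",
    "Registry",
    "COD_PER_ELECTRON_EQ",
    "MCC_NAMES",
    "degree_of_reduction",
    "formula_mass",
    "g_per_L_to_emeq",
    "emeq_to_g_per_L",
    "emeq_to_cod",
    "conc_to_carbon_mmol",
    "g_per_L_to_mM",
    "mM_to_g_per_L",
]

# Standard atomic weights (IUPAC 2021, abridged).
_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999}

#: g O2 per electron equivalent; one mole of O2 (32 g) accepts 4 electrons.
COD_PER_ELECTRON_EQ = 8.0

#: Medium-chain carboxylates (C6-C12 range tracked here).
MCC_NAMES = ("n-caproate", "n-heptylate", "n-caprylate")


def degree_of_reduction(c: int, h: int, o: int) -> int:
    """Electron equivalents per mole of a C/H/O compound: 4C + H - 2O.

    Raises ``ValueError`` for negative atom counts.
    """
    if c < 0 or h < 0 or o < 0:
        raise ValueError(f"negative atom counts not allowed: C={c} H={h} O={o}")
    return 4 * c + h - 2 * o


def formula_mass(c: int, h: int, o: int) -> float:
    """Molar mass (g/mol) computed from the formula and standard atomic weights."""
    return c * _ATOMIC_MASS["C"] + h * _ATOMIC_MASS["H"] + o * _ATOMIC_MASS["O"]


@dataclass(frozen=True)
class Compound:
    """A registry entry: identity, formula and derived bookkeeping constants.

    ``electron_eq`` must equal the degree-of-reduction identity 4C + H - 2O
    and ``molar_mass`` must lie within 0.5% of the formula-derived mass;
    both are enforced at construction.  ``pKa`` is ``None`` for non-acids.
    ``extractable`` marks compounds that partition into a vegetable-oil
    solvent phase under reactor conditions (medium-chain carboxylates).
    """

    name: str
    formula_c: int
    formula_h: int
    formula_o: int
    molar_mass: float
    n_carbon: int
    electron_eq: int
    pKa: float | None = None
    extractable: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("compound name must be non-empty")
        expected_e = degree_of_reduction(self.formula_c, self.formula_h, self.formula_o)
        if self.electron_eq != expected_e:
            raise ValueError(
                f"{self.name}: electron_eq {self.electron_eq} violates degree-of-"
                f"reduction identity 4C+H-2O = {expected_e}"
            )
        if self.n_carbon != self.formula_c:
            raise ValueError(f"{self.name}: n_carbon must equal formula C count")
        ref = formula_mass(self.formula_c, self.formula_h, self.formula_o)
        if self.molar_mass <= 0 or abs(self.molar_mass - ref) > 0.005 * ref:
            raise ValueError(
                f"{self.name}: molar mass {self.molar_mass} deviates >0.5% from "
                f"formula mass {ref:.3f}"
            )

    @property
    def is_acid(self) -> bool:
        return self.pKa is not None


class Registry:
    """Name -> :class:`Compound` map with loud failures on unknown lookups."""

    def __init__(self, compounds: Mapping[str, Compound] | None = None) -> None:
        self._compounds: dict[str, Compound] = {}
        for cpd in (compounds or {}).values():
            self.add(cpd)

    def add(self, compound: Compound) -> None:
        if compound.name in self._compounds:
            raise ValueError(f"duplicate compound name: {compound.name!r}")
        self._compounds[compound.name] = compound

    def __getitem__(self, name: str) -> Compound:
        try:
            return self._compounds[name]
        except KeyError:
            raise KeyError(
                f"unknown compound {name!r}; registry has: {sorted(self._compounds)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._compounds

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._compounds.values())

    def __len__(self) -> int:
        return len(self._compounds)

    @property
    def names(self) -> list[str]:
        return list(self._compounds)

    @property
    def carboxylates(self) -> list[str]:
        return [c.name for c in self if c.is_acid]

    @property
    def extractables(self) -> list[str]:
        return [c.name for c in self if c.extractable]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Registry":
        """Load a registry from a TSV file.

        Expected header: ``name formula_C formula_H formula_O molar_mass
        n_carbon electron_eq pKa extractable`` (tab-separated; pKa may be
        empty for non-acids, extractable is 0/1).
        """
        reg = cls()
        text = Path(path).read_text(encoding="utf-8")
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        expected = [
            "name", "formula_C", "formula_H", "formula_O", "molar_mass",
            "n_carbon", "electron_eq", "pKa", "extractable",
        ]
        if header != expected:
            raise ValueError(f"registry header {header} != expected {expected}")
        for ln in lines[1:]:
            f = ln.split("\t")
            reg.add(
                Compound(
                    name=f[0],
                    formula_c=int(f[1]),
                    formula_h=int(f[2]),
                    formula_o=int(f[3]),
                    molar_mass=float(f[4]),
                    n_carbon=int(f[5]),
                    electron_eq=int(f[6]),
                    pKa=float(f[7]) if f[7].strip() else None,
                    extractable=bool(int(f[8])),
                )
            )
        return reg

    @classmethod
    def default(cls) -> "Registry":
        """The shipped registry: the ten standard compounds plus CO2."""
        with resources.as_file(
            resources.files("caproflux").joinpath("data/compounds.tsv")
        ) as p:
            return cls.from_tsv(p)


def _check_nonneg(value: float, what: str) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{what} must be finite and >= 0, got {value}")


def g_per_L_to_emeq(conc_g_per_L: float, compound: Compound) -> float:
    """Convert a mass concentration (g/L) to electron milli-equivalents per L."""
    _check_nonneg(conc_g_per_L, "concentration")
    return conc_g_per_L / compound.molar_mass * compound.electron_eq * 1000.0


def emeq_to_g_per_L(emeq_per_L: float, compound: Compound) -> float:
    """Exact inverse of :func:`g_per_L_to_emeq`."""
    _check_nonneg(emeq_per_L, "electron milli-equivalents")
    if compound.electron_eq == 0:
        raise ValueError(f"{compound.name} carries no electron equivalents")
    return emeq_per_L * compound.molar_mass / compound.electron_eq / 1000.0


def emeq_to_cod(emeq_per_L: float) -> float:
    """Electron milli-equivalents per L to g COD per L (8 g O2 per e- eq)."""
    _check_nonneg(emeq_per_L, "electron milli-equivalents")
    return emeq_per_L * COD_PER_ELECTRON_EQ / 1000.0


def conc_to_carbon_mmol(conc_g_per_L: float, compound: Compound) -> float:
    """Mass concentration (g/L) to carbon content (mmol C per L)."""
    _check_nonneg(conc_g_per_L, "concentration")
    return conc_g_per_L / compound.molar_mass * compound.n_carbon * 1000.0


def g_per_L_to_mM(conc_g_per_L: float, compound: Compound) -> float:
    """Mass concentration (g/L) to molar concentration (mmol/L)."""
    _check_nonneg(conc_g_per_L, "concentration")
    return conc_g_per_L / compound.molar_mass * 1000.0


def mM_to_g_per_L(conc_mM: float, compound: Compound) -> float:
    """Molar concentration (mmol/L) to mass concentration (g/L)."""
    _check_nonneg(conc_mM, "concentration")
    return conc_mM * compound.molar_mass / 1000.0
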