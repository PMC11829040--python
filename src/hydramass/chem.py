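"""Elemental-composition arithmetic and mass/charge bookkeeping.

This is the numeric foundation of the package: integer element counts with
exact monoisotopic, average and nominal mass computation, conversion between
neutral mass and m/z for multiply charged cation adducts, and ppm mass error.

Conventions
-----------
* Positive-ion mode only.  m/z is computed as ``(M + sum(cation masses)) / z``
  where each cation contributes its *charged* monoisotopic mass (proton
  1.007276 Da, Na+ 22.989218, K+ 38.963158, NH4+ 18.033823).  The electron
  mass is absorbed into these constants rather than subtracted separately.
* Monoisotopic masses use the most abundant isotope of each element;
  average masses use IUPAC standard atomic weights; nominal masses are the
  integer mass numbers of the most abundant isotopes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Mapping, Tuple

__all__ = [
    "ELEMENTS",
    "MONO_MASS",
    "AVG_MASS",
    "NOMINAL_MASS",
    "PROTON_MASS",
    "CATION_MASS",
    "MassKind",
    "MassValue",
    "ElementalComposition",
    "IonDescriptor",
    "parse_formula",
    "mono_mass",
    "avg_mass",
    "nominal_mass",
    "mz_from_mass",
    "mass_from_mz",
    "ppm_error",
]

# Most-abundant-isotope masses (Da).  Values to >=6 decimals so that printed
# lockmass m/z reproduce to 5 decimal places.
MONO_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "F": 18.99840322,
}

# IUPAC standard atomic weights (conventional values).
AVG_MASS: Dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
    "S": 32.06,
    "F": 18.998403,
}

# Integer mass numbers of the most abundant isotopes.
NOMINAL_MASS: Dict[str, int] = {
    "C": 12, "H": 1, "N": 14, "O": 16, "P": 31, "S": 32, "F": 19,
}

ELEMENTS: Tuple[str, ...] = tuple(MONO_MASS)

# Charged cation masses; the electron mass is already folded in.
PROTON_MASS = 1.007276
CATION_MASS: Dict[str, float] = {
    "H": PROTON_MASS,
    "Na": 22.989218,
    "K": 38.963158,
    "NH4": 18.033823,
}


class MassKind(str, Enum):
    MONOISOTOPIC = "monoisotopic"
    AVERAGE = "average"
    NOMINAL = "nominal"


@dataclass(frozen=True)
class MassValue:
    """A mass in daltons tagged with how it was computed."""

    value: float
    kind: MassKind

    def __float__(self) -> float:
        return self.value


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Integer element counts.

    Counts are non-negative for stored chemical species; signed counts are
    allowed so that compositions can also express reaction deltas.  Addition
    and subtraction are element-wise and masses are linear in the counts.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in dict(self.counts).items():
            if el not in MONO_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            n = int(n)
            if n != 0:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return self + other.scaled(-1)

    def __mul__(self, k: int) -> "ElementalComposition":
        return self.scaled(k)

    __rmul__ = __mul__

    def scaled(self, k: int) -> "ElementalComposition":
        return ElementalComposition({el: k * n for el, n in self.counts.items()})

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        return self.counts == other.counts

    def __bool__(self) -> bool:
        return bool(self.counts)

    @property
    def is_nonnegative(self) -> bool:
        return all(n >= 0 for n in self.counts.values())

    @property
    def atom_count(self) -> int:
        return sum(self.counts.values())

    # -- masses -------------------------------------------------------------
    def mass(self, kind: MassKind = MassKind.MONOISOTOPIC) -> float:
        table = {
            MassKind.MONOISOTOPIC: MONO_MASS,
            MassKind.AVERAGE: AVG_MASS,
            MassKind.NOMINAL: NOMINAL_MASS,
        }[MassKind(kind)]
        return float(sum(n * table[el] for el, n in self.counts.items()))

    # -- formatting ---------------------------------------------------------
    def hill_formula(self) -> str:
        """Format in Hill order (C, H, then alphabetical)."""
        parts = []
        order = ["C", "H"] + sorted(el for el in self.counts if el not in ("C", "H"))
        for el in order:
            n = self.counts.get(el, 0)
            if n == 0:
                continue
            if n == 1:
                parts.append(el)
            else:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"ElementalComposition({self.hill_formula() or '∅'})"


def parse_formula(text: str) -> ElementalComposition:
    """Parse a molecular formula such as ``"C9H12N2O6"``.

    Hill order is not required on input; signed counts (``"C-3O-1"``) are
    accepted so deltas can be written as formulas too.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty formula")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in MONO_MASS:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return ElementalComposition(counts)


def mono_mass(c: ElementalComposition) -> MassValue:
    return MassValue(c.mass(MassKind.MONOISOTOPIC), MassKind.MONOISOTOPIC)


def avg_mass(c: ElementalComposition) -> MassValue:
    return MassValue(c.mass(MassKind.AVERAGE), MassKind.AVERAGE)


def nominal_mass(c: ElementalComposition) -> MassValue:
    return MassValue(c.mass(MassKind.NOMINAL), MassKind.NOMINAL)


@dataclass(frozen=True)
class IonDescriptor:
    """A positive-mode ion: total charge z carried by z singly charged cations.

    ``adducts`` maps cation name to multiplicity; the multiplicities must sum
    to ``charge``.  The default is all-proton charging.
    """

    charge: int
    adducts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")
        adducts = dict(self.adducts) or {"H": self.charge}
        for name in adducts:
            if name not in CATION_MASS:
                raise ValueError(f"unknown adduct cation {name!r}")
        if sum(adducts.values()) != self.charge:
            raise ValueError(
                f"adduct multiplicities {adducts} do not sum to charge {self.charge}"
            )
        object.__setattr__(self, "adducts", adducts)

    @classmethod
    def protonated(cls, z: int) -> "IonDescriptor":
        return cls(charge=z, adducts={"H": z})

    @property
    def cation_mass(self) -> float:
        return sum(CATION_MASS[name] * n for name, n in self.adducts.items())

    def label(self) -> str:
        inner = "+".join(
            f"{n if n > 1 else ''}{name}" for name, n in sorted(self.adducts.items())
        )
        return f"[M+{inner}]{self.charge}+"


def mz_from_mass(neutral_mass: float, ion: IonDescriptor) -> float:
    """m/z of a neutral species carrying the given cation adducts."""
    return (neutral_mass + ion.cation_mass) / ion.charge


def mass_from_mz(mz: float, ion: IonDescriptor) -> float:
    """Exact inverse of :func:`mz_from_mass`."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return mz * ion.charge - ion.cation_mass


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


# Frequently used small molecules.
WATER = parse_formula("H2O")
HPO3 = parse_formula("HPO3")
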