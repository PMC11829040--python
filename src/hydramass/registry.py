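"""Catalogue of ribonucleosides and their hydrazine reaction rules.

A :class:`Registry` maps short modification codes (MODOMICS-style: ``U``,
``Psi``, ``m5C``, ``s4U`` ...) to elemental compositions and to the reaction
rules that describe what hydrazine does to them: the composition change of the
product, the leaving group, and a log-logistic dose-response giving the
converted fraction as a function of hydrazine concentration.

The default registry ships as a YAML data file so that formulas, deltas and
dose-response parameters can be refitted or extended without touching code.
The dose-response parameters are anchored to the qualitative reactivity
ordering observed by isotope-dilution LC-MS/MS of hydrazine-treated total
tRNA: thiolated/acylated species (s4U, m3C, mcm5s2U) react almost completely
at 10% hydrazine, ac4C and dihydrouridine by 30%, m7G about three quarters at
30%, acp3U partially, uridine reaches ~50% conversion only at 50% hydrazine,
and s2C requires still higher concentrations.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import yaml

from .chem import (
    ElementalComposition,
    MassKind,
    parse_formula,
    HPO3,
    WATER,
)

__all__ = [
    "TreatmentCondition",
    "DoseResponseParams",
    "NucleosideSpec",
    "ReactionRule",
    "Registry",
    "load_registry",
    "REFERENCE_TEMPERATURE_C",
    "REFERENCE_TIME_H",
]

# Reference reaction condition for the registry dose-response parameters.
REFERENCE_TEMPERATURE_C = 0.0
REFERENCE_TIME_H = 1.0
# Incubation beyond 6 h gives no further conversion benefit in practice.
MAX_TIME_SCALING_H = 6.0


@dataclass(frozen=True)
class TreatmentCondition:
    """Hydrazine reaction condition: % v/v concentration, temperature, time."""

    concentration: float  # % v/v
    temperature_c: float = REFERENCE_TEMPERATURE_C
    time_h: float = REFERENCE_TIME_H

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("hydrazine concentration cannot be negative")
        if self.concentration > 50:
            warnings.warn(
                f"hydrazine concentration {self.concentration}% exceeds the "
                "50% v/v range the dose-response parameters were anchored on",
                stacklevel=2,
            )
        if self.time_h <= 0:
            raise ValueError("incubation time must be positive")


@dataclass(frozen=True)
class DoseResponseParams:
    """Log-logistic dose-response of the converted fraction.

    p(c) = ceiling / (1 + (ec50 / c)^hill), with p(0) = floor = 0.
    ``ec50`` is in hydrazine % v/v at the reference condition (0 degC, 1 h);
    ``hill`` is the dimensionless slope; ``ceiling`` caps partially reactive
    species (e.g. 2'-O-methyluridine at 0.5).
    """

    ec50: float
    hill: float
    ceiling: float = 1.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be positive")
        if not 0.0 <= self.floor <= self.ceiling <= 1.0:
            raise ValueError("need 0 <= floor <= ceiling <= 1")

    def converted_fraction(self, concentration: float) -> float:
        if concentration < 0:
            raise ValueError("concentration cannot be negative")
        if concentration == 0:
            return 0.0
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + (self.ec50 / concentration) ** self.hill
        )


@dataclass(frozen=True)
class NucleosideSpec:
    """A (possibly modified) ribonucleoside and its chain-residue composition."""

    code: str
    name: str
    nucleoside: ElementalComposition

    @property
    def residue(self) -> ElementalComposition:
        """Internal chain unit: nucleoside 5'-monophosphate minus water."""
        return self.nucleoside + HPO3 - WATER


@dataclass(frozen=True)
class ReactionRule:
    """One hydrazine reaction: composition delta and reactivity."""

    reactant: str
    product: str
    delta: Optional[ElementalComposition]  # None for unknown-loss products
    mechanism: str
    dose_response: DoseResponseParams
    leaving_group: Optional[str] = None

    @property
    def has_mass(self) -> bool:
        return self.delta is not None

    def delta_mass(self, kind: MassKind = MassKind.MONOISOTOPIC) -> float:
        if self.delta is None:
            raise ValueError(f"rule {self.reactant}->{self.product} has no known product mass")
        return self.delta.mass(kind)


class Registry:
    """Nucleoside specs plus hydrazine reaction rules, by short code."""

    def __init__(
        self,
        specs: Mapping[str, NucleosideSpec],
        rules: Mapping[str, Sequence[ReactionRule]],
        aliases: Optional[Mapping[str, str]] = None,
        version: str = "unversioned",
        organism: str = "human",
    ) -> None:
        self._specs: Dict[str, NucleosideSpec] = dict(specs)
        self._rules: Dict[str, List[ReactionRule]] = {
            code: list(rs) for code, rs in rules.items()
        }
        self._aliases: Dict[str, str] = dict(aliases or {})
        self.version = version
        self.organism = organism

    # -- lookup -------------------------------------------------------------
    def resolve(self, code: str) -> str:
        return self._aliases.get(code, code)

    def __contains__(self, code: str) -> bool:
        return self.resolve(code) in self._specs

    @property
    def codes(self) -> List[str]:
        return sorted(self._specs)

    def lookup(self, code: str) -> NucleosideSpec:
        key = self.resolve(code)
        if key not in self._specs:
            near = difflib.get_close_matches(code, list(self._specs) + list(self._aliases), n=3)
            hint = f"; did you mean {', '.join(near)}?" if near else ""
            raise KeyError(f"unknown nucleoside code {code!r}{hint}")
        return self._specs[key]

    def reaction_rules(self, code: str) -> List[ReactionRule]:
        key = self.resolve(code)
        if key not in self._specs:
            raise KeyError(f"unknown nucleoside code {code!r}")
        return list(self._rules.get(key, []))

    def mass_rules(self, code: str) -> List[ReactionRule]:
        """Rules with a known product composition (usable in mass ladders)."""
        return [r for r in self.reaction_rules(code) if r.has_mass]

    # -- reactivity ---------------------------------------------------------
    def reactivity(self, code: str, condition: TreatmentCondition) -> float:
        """Converted fraction of one residue under the given condition.

        Incubation time scales the effective concentration linearly up to 6 h
        (longer incubations plateau); temperatures away from the 0 degC
        reference are flagged as extrapolation but not modelled.
        Multiple rules on one code combine as independent losses.
        """
        rules = self.reaction_rules(code)
        if not rules:
            return 0.0
        if condition.temperature_c != REFERENCE_TEMPERATURE_C:
            warnings.warn(
                f"reactivity at {condition.temperature_c} degC extrapolates from "
                f"the {REFERENCE_TEMPERATURE_C} degC reference parameters",
                stacklevel=2,
            )
        scale = min(condition.time_h, MAX_TIME_SCALING_H) / REFERENCE_TIME_H
        c_eff = condition.concentration * scale
        survive = 1.0
        for rule in rules:
            survive *= 1.0 - rule.dose_response.converted_fraction(c_eff)
        return 1.0 - survive

    # -- mutation -----------------------------------------------------------
    def register(
        self,
        spec: NucleosideSpec,
        rules: Sequence[ReactionRule] = (),
        overwrite: bool = False,
    ) -> "Registry":
        if spec.code in self._specs and not overwrite:
            raise ValueError(
                f"code {spec.code!r} already registered (pass overwrite=True to replace)"
            )
        self._specs[spec.code] = spec
        self._rules[spec.code] = list(rules)
        return self


def _load_yaml(path: Optional[Path]) -> dict:
    if path is None:
        text = (resources.files("hydramass") / "data" / "registry.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def load_registry(
    path: Optional[Path] = None,
    organism: str = "human",
    d_product: str = "default",
) -> Registry:
    """Load a registry from YAML (the bundled default when ``path`` is None).

    ``organism`` selects organism-restricted rules (t6A is lost from E. coli
    tRNA but not from human tRNA, attributed to a cofactor rather than
    chemistry).  ``d_product`` selects among alternative dihydrouridine
    product compositions where the YAML offers them.
    """
    doc = _load_yaml(path)
    specs: Dict[str, NucleosideSpec] = {}
    aliases: Dict[str, str] = {}
    for code, entry in doc["nucleosides"].items():
        specs[code] = NucleosideSpec(
            code=code, name=entry["name"], nucleoside=parse_formula(entry["formula"])
        )
        for alias in entry.get("aliases", []):
            aliases[alias] = code

    rules: Dict[str, List[ReactionRule]] = {}
    for raw in doc.get("rules", []):
        orgs = raw.get("organisms")
        if orgs is not None and organism not in orgs:
            continue
        delta_text = raw.get("delta")
        alternatives = raw.get("delta_alternatives") or {}
        if d_product != "default" and d_product in alternatives:
            delta_text = alternatives[d_product]
        delta = parse_formula(delta_text) if delta_text else None
        code = raw["reactant"]
        if code not in specs:
            raise ValueError(f"rule references unregistered code {code!r}")
        if delta is not None and not (specs[code].nucleoside + delta).is_nonnegative:
            raise ValueError(f"rule for {code!r} removes atoms the reactant lacks")
        dr = raw["dose_response"]
        rules.setdefault(code, []).append(
            ReactionRule(
                reactant=code,
                product=raw["product"],
                delta=delta,
                mechanism=raw["mechanism"],
                leaving_group=raw.get("leaving_group"),
                dose_response=DoseResponseParams(
                    ec50=float(dr["ec50"]),
                    hill=float(dr["hill"]),
                    ceiling=float(dr.get("ceiling", 1.0)),
                ),
            )
        )
    return Registry(
        specs,
        rules,
        aliases=aliases,
        version=str(doc.get("version", "unversioned")),
        organism=organism,
    )
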