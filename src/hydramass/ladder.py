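"""Hydrazine conversion ladders, peak prediction and peak-list matching.

A hydrazine-treated oligonucleotide appears in MS as a *conversion ladder*:
the unreacted species plus one peak per number k of converted residues,
spaced by the reaction's mass delta (52 Da for the uridine -> urea-ribose
reaction, i.e. 13 m/z at charge +4).  This module enumerates those species,
predicts MALDI/ESI peaks for chosen charge states and cation adducts, matches
observed peak lists within a ppm or Da tolerance, infers how many
uridine-like positions did *not* react (pseudouridine candidates), and labels
MS2/MS3 neutral-loss mass differences.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .chem import (
    ElementalComposition,
    IonDescriptor,
    MassKind,
    mz_from_mass,
    ppm_error,
)
from .digest import Fragment, Oligo, oligo_composition
from .registry import (
    MAX_TIME_SCALING_H,
    REFERENCE_TIME_H,
    ReactionRule,
    Registry,
    TreatmentCondition,
)

__all__ = [
    "MALDI_TOLERANCE_DA",
    "PRECURSOR_TOLERANCE_PPM",
    "FRAGMENT_TOLERANCE_PPM",
    "NEUTRAL_LOSSES",
    "ConversionSpecies",
    "Peak",
    "TheoreticalPeak",
    "Assignment",
    "MatchResult",
    "PsiInference",
    "conversion_ladder",
    "theoretical_peaks",
    "match_peaks",
    "infer_nonreactive_sites",
    "annotate_neutral_losses",
]

# Matching tolerances mirroring common practice: reflector MALDI-TOF on
# 2-7 kDa oligonucleotides, and Orbitrap-class precursor/fragment windows.
MALDI_TOLERANCE_DA = 0.5
PRECURSOR_TOLERANCE_PPM = 10.0
FRAGMENT_TOLERANCE_PPM = 20.0

# Neutral-loss reference table (monoisotopic Da).
NEUTRAL_LOSSES: Dict[str, float] = {
    "NH3": 17.0265,
    "H2O": 18.0106,
    "N2H4": 32.0375,
    "H2S": 33.9877,
    "HNCO": 43.0058,
    "ribose": 132.0423,
}


@dataclass(frozen=True)
class ConversionSpecies:
    """One hydrazine conversion state of a fragment.

    ``applied`` records (0-based position, product name) for every converted
    residue of the representative subset; species whose total composition
    delta coincides are collapsed into one with summed probability.
    ``flagged_positions`` lists residues carrying an unknown-loss rule: they
    are reactive but contribute no mass state.
    """

    fragment: Fragment
    applied: Tuple[Tuple[int, str], ...]
    delta: ElementalComposition
    composition: ElementalComposition
    k: int
    probability: Optional[float] = None
    flagged_positions: Tuple[int, ...] = ()

    def mass(self, kind: MassKind = MassKind.MONOISOTOPIC) -> float:
        return self.composition.mass(kind)


@dataclass(frozen=True)
class Peak:
    """An observed peak: m/z with optional intensity and charge."""

    mz: float
    intensity: Optional[float] = None
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


@dataclass(frozen=True)
class TheoreticalPeak:
    mz: float
    species: ConversionSpecies
    ion: IonDescriptor
    mass_kind: MassKind


@dataclass(frozen=True)
class Assignment:
    peak: Peak
    species: ConversionSpecies
    ion: IonDescriptor
    ppm: float
    rank: int = 1
    ambiguous: bool = False


@dataclass(frozen=True)
class MatchResult:
    assignments: List[Assignment]
    unassigned: List[Peak]


@dataclass(frozen=True)
class PsiInference:
    """How many U-like positions of a fragment did not react.

    ``u`` counts positions written U or Psi (mass-identical isomers),
    ``kmax`` is the largest assigned conversion count, and their difference
    is the number of non-reactive (pseudouridine-candidate) sites.  The
    sites are localized only in the all-or-nothing cases.
    """

    fragment: Fragment
    u: int
    kmax: int
    n_nonreactive: int
    localized: bool
    confidence: str  # "high" | "low"


def _position_options(
    fragment: Fragment, registry: Registry
) -> Tuple[List[Tuple[int, List[ReactionRule]]], Tuple[int, ...]]:
    """Reactive positions with mass rules, plus unknown-loss positions."""
    reactive: List[Tuple[int, List[ReactionRule]]] = []
    flagged: List[int] = []
    for i, token in enumerate(fragment.tokens):
        rules = registry.reaction_rules(token)
        mass_rules = [r for r in rules if r.has_mass]
        if mass_rules:
            reactive.append((i, mass_rules))
        if any(not r.has_mass for r in rules):
            flagged.append(i)
    return reactive, tuple(flagged)


def conversion_ladder(
    fragment: Fragment,
    registry: Registry,
    condition: Optional[TreatmentCondition] = None,
) -> List[ConversionSpecies]:
    """Enumerate all conversion states of a fragment.

    Every subset of reactive positions is enumerated (with the choice of rule
    where a residue carries several mass rules); states with identical total
    composition delta are collapsed, probabilities summed.  The unreacted
    k=0 species is always present.  When a condition is given, each position
    converts independently with its dose-response probability (at most one
    reaction per residue) and the ladder probabilities sum to 1.
    """
    reactive, flagged = _position_options(fragment, registry)
    if flagged:
        tokens = [fragment.tokens[i] for i in flagged]
        warnings.warn(
            f"fragment {fragment.label}: positions {flagged} ({tokens}) react "
            "with unknown product mass; ladder omits their mass states",
            stacklevel=2,
        )
    base = oligo_composition(fragment.oligo, registry)

    # Per position: list of (rule-or-None, probability) choices.
    per_position: List[List[Tuple[Optional[ReactionRule], float]]] = []
    for _, rules in reactive:
        if condition is None:
            probs = [0.0] * len(rules)
            p_none = 0.0
        else:
            scale = min(condition.time_h, MAX_TIME_SCALING_H) / REFERENCE_TIME_H
            c_eff = condition.concentration * scale
            fractions = [r.dose_response.converted_fraction(c_eff) for r in rules]
            # at most one reaction per residue: normalise competing rules
            w_none = 1.0
            for f in fractions:
                w_none *= 1.0 - f
            weights = [
                f * (w_none / (1.0 - f) if f < 1.0 else 1.0) for f in fractions
            ]
            total = w_none + sum(weights)
            p_none = w_none / total
            probs = [w / total for w in weights]
        per_position.append(
            [(None, p_none)] + [(r, p) for r, p in zip(rules, probs)]
        )

    grouped: Dict[Tuple[Tuple[str, int], ...], ConversionSpecies] = {}
    for combo in itertools.product(*per_position):
        delta = ElementalComposition({})
        applied: List[Tuple[int, str]] = []
        prob = 1.0
        for (pos, _), (rule, p) in zip(reactive, combo):
            prob *= p
            if rule is not None:
                delta = delta + rule.delta
                applied.append((pos, rule.product))
        key = tuple(sorted(delta.counts.items()))
        if key in grouped:
            old = grouped[key]
            new_prob = (
                None if condition is None else (old.probability or 0.0) + prob
            )
            grouped[key] = ConversionSpecies(
                fragment=old.fragment,
                applied=old.applied,
                delta=old.delta,
                composition=old.composition,
                k=old.k,
                probability=new_prob,
                flagged_positions=flagged,
            )
        else:
            grouped[key] = ConversionSpecies(
                fragment=fragment,
                applied=tuple(applied),
                delta=delta,
                composition=base + delta,
                k=len(applied),
                probability=None if condition is None else prob,
                flagged_positions=flagged,
            )
    return sorted(grouped.values(), key=lambda s: (s.k, -s.mass()))


def theoretical_peaks(
    species: Sequence[ConversionSpecies],
    charges: Iterable[int] = (1,),
    adduct_profiles: Optional[Sequence[Dict[str, int]]] = None,
    mass_kind: MassKind = MassKind.MONOISOTOPIC,
) -> List[TheoreticalPeak]:
    """Predict one peak per (species, charge, adduct profile).

    ``adduct_profiles`` maps cation name to the number of *non-proton*
    charges it carries; remaining charges are protons.  The default is
    all-proton charging.
    """
    charges = sorted(set(charges))
    if not charges:
        raise ValueError("at least one charge state is required")
    profiles = adduct_profiles if adduct_profiles is not None else [{}]
    peaks: List[TheoreticalPeak] = []
    for sp in species:
        neutral = sp.mass(mass_kind)
        for z in charges:
            for profile in profiles:
                non_proton = sum(profile.values())
                if non_proton > z:
                    continue
                adducts = dict(profile)
                if z - non_proton:
                    adducts["H"] = adducts.get("H", 0) + (z - non_proton)
                ion = IonDescriptor(charge=z, adducts=adducts)
                peaks.append(
                    TheoreticalPeak(
                        mz=mz_from_mass(neutral, ion),
                        species=sp,
                        ion=ion,
                        mass_kind=MassKind(mass_kind),
                    )
                )
    return peaks


def match_peaks(
    observed: Sequence[Peak],
    theoretical: Sequence[TheoreticalPeak],
    tolerance: float = PRECURSOR_TOLERANCE_PPM,
    unit: str = "ppm",
) -> MatchResult:
    """Assign each observed peak to the nearest theoretical peak in tolerance.

    Ties are broken by smaller |ppm|, then lower conversion count k, then
    lower charge; exact ties are emitted for both candidates with the
    ``ambiguous`` flag set.  Peaks matching nothing are reported unassigned.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if unit not in ("ppm", "da"):
        raise ValueError("unit must be 'ppm' or 'da'")
    if not theoretical:
        raise ValueError("empty theoretical peak list")

    assignments: List[Assignment] = []
    unassigned: List[Peak] = []
    for peak in sorted(observed, key=lambda p: p.mz):
        candidates = []
        for th in theoretical:
            if peak.charge is not None and th.ion.charge != peak.charge:
                continue
            err = peak.mz - th.mz
            within = (
                abs(ppm_error(peak.mz, th.mz)) <= tolerance
                if unit == "ppm"
                else abs(err) <= tolerance
            )
            if within:
                candidates.append((abs(ppm_error(peak.mz, th.mz)), th))
        if not candidates:
            unassigned.append(peak)
            continue
        candidates.sort(key=lambda c: (c[0], c[1].species.k, c[1].ion.charge))
        best_ppm = candidates[0][0]
        ties = [c for c in candidates if abs(c[0] - best_ppm) < 1e-9]
        ambiguous = len(ties) > 1
        for rank, (_, th) in enumerate(ties if ambiguous else candidates[:1], start=1):
            assignments.append(
                Assignment(
                    peak=peak,
                    species=th.species,
                    ion=th.ion,
                    ppm=ppm_error(peak.mz, th.mz),
                    rank=1 if ambiguous else rank,
                    ambiguous=ambiguous,
                )
            )
    return MatchResult(assignments=assignments, unassigned=unassigned)


def infer_nonreactive_sites(
    assignments: Sequence[Assignment],
    fragment: Fragment,
    registry: Registry,
    condition: Optional[TreatmentCondition] = None,
) -> PsiInference:
    """Count pseudouridine-candidate sites from an assigned ladder.

    With u positions written U or Psi and a maximum assigned conversion count
    kmax, u - kmax positions did not react and are pseudouridine candidates.
    Individual sites are only localized when all or none reacted.  When the
    per-residue conversion probability under the supplied condition is below
    0.9 an unconverted U is a plausible alternative, so confidence is low.
    """
    u_positions = [
        i for i, t in enumerate(fragment.tokens) if registry.resolve(t) in ("U", "Psi")
    ]
    u = len(u_positions)
    relevant = [a for a in assignments if a.species.fragment.tokens == fragment.tokens]
    kmax = max((a.species.k for a in relevant), default=0)
    n_nonreactive = max(u - kmax, 0)
    confidence = "high"
    if n_nonreactive and condition is not None:
        p_u = registry.reactivity("U", condition)
        if p_u < 0.9:
            confidence = "low"
    elif n_nonreactive and condition is None:
        confidence = "low"
    return PsiInference(
        fragment=fragment,
        u=u,
        kmax=kmax,
        n_nonreactive=n_nonreactive,
        localized=n_nonreactive in (0, u),
        confidence=confidence,
    )


def annotate_neutral_losses(
    deltas: Sequence[float], tolerance: float = 0.01
) -> List[str]:
    """Label fragment-ion mass differences against known neutral losses."""
    labels = []
    for d in deltas:
        best, best_err = "unknown", tolerance
        for name, mass in NEUTRAL_LOSSES.items():
            err = abs(abs(d) - mass)
            if err <= best_err:
                best, best_err = name, err
        labels.append(best)
    return labels
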