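"""Bracket-notation RNA sequences and in-silico RNase T1 digestion.

Sequences use single letters for the canonical ribonucleotides (A, C, G, U)
and square brackets for modified residues (``[m5C]``, ``[Gm]``, ``[Psi]``);
the literal character ``Ψ`` is accepted as an alias for ``[Psi]``.

Terminus bookkeeping
--------------------
One convention, used everywhere: an internal residue is a nucleoside
5'-monophosphate minus water.  The neutral composition of a chain is then

    sum(residues) + H2O            (a 5'-phosphate / 3'-OH molecule)

with terminus corrections applied on top: a 5'-OH end removes HPO3; a
3'-phosphate end adds HPO3; a 2',3'-cyclic phosphate additionally removes
H2O.  This single formula avoids the classic +-80 / +-18 bookkeeping errors.

RNase T1 cleaves the phosphodiester 3' of unmodified guanosine, leaving a
5'-OH on the downstream fragment and a 3'-phosphate (ring-opened by default
here; 2',3'-cyclic selectable) on the upstream fragment.  Methylated
guanosines (Gm, m1G, m2G, m22G, m7G) resist cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, List, Optional, Sequence, Tuple

from .chem import ElementalComposition, HPO3, WATER, MassKind, MassValue
from .registry import Registry

__all__ = [
    "Oligo",
    "Fragment",
    "tokenize",
    "format_sequence",
    "t1_digest",
    "oligo_composition",
    "fragment_mass",
    "T1_RESISTANT_G",
]

FIVE_PRIME = ("OH", "phosphate")
THREE_PRIME = ("OH", "phosphate", "cyclic-phosphate")

# Guanosine variants whose 2'-O or base methylation blocks RNase T1.
T1_RESISTANT_G: FrozenSet[str] = frozenset({"Gm", "m1G", "m2G", "m22G", "m7G"})

_CANONICAL = {"A", "C", "G", "U"}
_LITERAL_ALIASES = {"Ψ": "Psi"}


@dataclass(frozen=True)
class Oligo:
    """An RNA chain as an ordered tuple of residue codes plus termini."""

    tokens: Tuple[str, ...]
    five_prime: str = "OH"
    three_prime: str = "OH"
    name: Optional[str] = None
    offset: int = 1  # 1-based position of the first residue in its parent

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("an oligo needs at least one residue")
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if self.five_prime not in FIVE_PRIME:
            raise ValueError(f"5' terminus must be one of {FIVE_PRIME}")
        if self.three_prime not in THREE_PRIME:
            raise ValueError(f"3' terminus must be one of {THREE_PRIME}")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def sequence(self) -> str:
        return format_sequence(self.tokens)


@dataclass(frozen=True)
class Fragment:
    """A digestion product with 1-based inclusive coordinates in its parent."""

    oligo: Oligo
    parent_name: Optional[str]
    start: int
    end: int
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.oligo):
            raise ValueError("fragment coordinates do not match its length")

    @property
    def tokens(self) -> Tuple[str, ...]:
        return self.oligo.tokens

    @property
    def label(self) -> str:
        first, last = self.oligo.tokens[0], self.oligo.tokens[-1]
        return f"{first}{self.start}-{last}{self.end}"


def tokenize(
    text: str,
    registry: Optional[Registry] = None,
    five_prime: str = "OH",
    three_prime: str = "OH",
    name: Optional[str] = None,
) -> Oligo:
    """Parse an extended sequence string into an :class:`Oligo`.

    Raises ``ValueError`` on unbalanced brackets or, when a registry is
    supplied, on unregistered tokens.
    """
    tokens: List[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise ValueError(f"unbalanced '[' at position {i} in {text!r}")
            token = text[i + 1 : j].strip()
            if not token:
                raise ValueError(f"empty brackets at position {i} in {text!r}")
            i = j + 1
        elif ch == "]":
            raise ValueError(f"unbalanced ']' at position {i} in {text!r}")
        elif ch in _LITERAL_ALIASES:
            token = _LITERAL_ALIASES[ch]
            i += 1
        elif ch in _CANONICAL:
            token = ch
            i += 1
        else:
            raise ValueError(f"unknown residue {ch!r} at position {i} in {text!r}")
        if registry is not None:
            token = registry.resolve(token)
            if token not in registry:
                registry.lookup(token)  # raises with nearest-candidate hint
        tokens.append(token)
    if not tokens:
        raise ValueError("empty sequence")
    return Oligo(tuple(tokens), five_prime=five_prime, three_prime=three_prime, name=name)


def format_sequence(tokens: Sequence[str]) -> str:
    """Inverse of :func:`tokenize`: canonical letters bare, others bracketed."""
    return "".join(t if t in _CANONICAL else f"[{t}]" for t in tokens)


def oligo_composition(oligo: Oligo, registry: Registry) -> ElementalComposition:
    """Neutral elemental composition under the terminus convention above."""
    total = ElementalComposition({})
    for token in oligo.tokens:
        total = total + registry.lookup(token).residue
    total = total + WATER
    if oligo.five_prime == "OH":
        total = total - HPO3
    if oligo.three_prime == "phosphate":
        total = total + HPO3
    elif oligo.three_prime == "cyclic-phosphate":
        total = total + HPO3 - WATER
    return total


def fragment_mass(
    fragment: Fragment | Oligo,
    registry: Registry,
    kind: MassKind = MassKind.MONOISOTOPIC,
) -> MassValue:
    """Neutral mass of a fragment (or bare oligo)."""
    oligo = fragment.oligo if isinstance(fragment, Fragment) else fragment
    return MassValue(oligo_composition(oligo, registry).mass(kind), MassKind(kind))


def t1_digest(
    parent: Oligo,
    missed_cleavages: int = 0,
    cyclic_phosphate: bool = False,
    cleavable: FrozenSet[str] = frozenset({"G"}),
) -> List[Fragment]:
    """In-silico RNase T1 digestion.

    Cleaves 3' of every residue in ``cleavable`` (unmodified G by default).
    Complete-digestion fragments tile the parent; with ``missed_cleavages=k``
    every contiguous union of up to k+1 adjacent fragments is emitted as well.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages cannot be negative")
    product_3p = "cyclic-phosphate" if cyclic_phosphate else "phosphate"

    # Base tiling at zero missed cleavages.
    cut_after = [i for i, t in enumerate(parent.tokens) if t in cleavable]
    bounds: List[Tuple[int, int]] = []  # 0-based inclusive spans
    start = 0
    for cut in cut_after:
        if cut == len(parent.tokens) - 1:
            break  # a 3'-terminal G produces no extra fragment
        bounds.append((start, cut))
        start = cut + 1
    bounds.append((start, len(parent.tokens) - 1))

    def make(span_first: int, span_last: int, n_missed: int) -> Fragment:
        lo = bounds[span_first][0]
        hi = bounds[span_last][1]
        five = parent.five_prime if lo == 0 else "OH"
        # A 3'-terminal G has no downstream phosphodiester to cleave, so the
        # last fragment always keeps the parent's own 3' terminus.
        three = product_3p if hi < len(parent.tokens) - 1 else parent.three_prime
        oligo = Oligo(
            parent.tokens[lo : hi + 1],
            five_prime=five,
            three_prime=three,
            name=parent.name,
            offset=parent.offset + lo,
        )
        return Fragment(
            oligo,
            parent_name=parent.name,
            start=parent.offset + lo,
            end=parent.offset + hi,
            missed_cleavages=n_missed,
        )

    fragments: List[Fragment] = []
    for k in range(missed_cleavages + 1):
        for first in range(len(bounds) - k):
            fragments.append(make(first, first + k, k))
    return fragments
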