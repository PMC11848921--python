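"""Exact mass arithmetic for PNA oligomers.

PNA (peptide nucleic acid) is an achiral DNA mimic built on an
N-(2-aminoethyl)glycine (aeg) amide backbone; oligomers are written
C-terminus to N-terminus throughout this package.  Everything that touches a
mass — ladder simulation, spectrum generation, base calling — routes through
this module: integer elemental compositions, monoisotopic masses from the
pinned isotope table, aggregated isotope envelopes, and the small set of
adduct / terminator deltas the decoder relies on.

The residue, terminus and linker compositions live in a user-overridable
table (``data/residues.yaml``); see :class:`ResidueRegistry`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

from .elements import ISOTOPES, MONOISOTOPIC_MASS, PROTON_MASS
from .errors import ConfigurationError, DomainError

__all__ = [
    "ElementalComposition",
    "ResidueSpec",
    "TerminusState",
    "OligomerSpecies",
    "ResidueRegistry",
    "DEFAULT_REGISTRY",
    "compose_oligomer",
    "monoisotopic_mass",
    "isotope_envelope",
    "adduct_mz",
    "terminator_delta",
    "ADDUCT_OFFSETS",
    "OXIDATION_DELTA",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Integer atom counts per element; exact, hashable, non-negative.

    Addition/subtraction are element-wise on integers; subtraction raises
    :class:`DomainError` rather than produce a negative count.
    """

    _items: tuple[tuple[str, int], ...] = ()

    @staticmethod
    def from_counts(counts: Mapping[str, int]) -> "ElementalComposition":
        items = []
        for el, n in counts.items():
            if not isinstance(n, int):
                raise DomainError(f"atom count for {el} must be an integer, got {n!r}")
            if n < 0:
                raise DomainError(f"negative atom count for {el}: {n}")
            if n:
                items.append((el, n))
        return ElementalComposition(tuple(sorted(items)))

    @staticmethod
    def from_formula(formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula such as ``C11H13N7O2``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if m.start() != pos:
                raise DomainError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
            pos = m.end()
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(formula):
            raise DomainError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        return ElementalComposition.from_counts(counts)

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._items)

    def __bool__(self) -> bool:
        return bool(self._items)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = self.counts
        for el, n in other._items:
            counts[el] = counts.get(el, 0) + n
        return ElementalComposition.from_counts(counts)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = self.counts
        for el, n in other._items:
            new = counts.get(el, 0) - n
            if new < 0:
                raise DomainError(
                    f"subtraction yields negative count for {el} "
                    f"({counts.get(el, 0)} - {n})"
                )
            counts[el] = new
        return ElementalComposition.from_counts(counts)

    def __mul__(self, n: int) -> "ElementalComposition":
        if not isinstance(n, int) or n < 0:
            raise DomainError("composition may only be scaled by a non-negative integer")
        return ElementalComposition.from_counts({el: c * n for el, c in self._items})

    __rmul__ = __mul__

    def formula(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self._items
        )

    def total_atoms(self) -> int:
        return sum(n for _, n in self._items)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ElementalComposition({self.formula()!r})"


# Fixed small deltas used throughout.
_H = ElementalComposition.from_formula("H")
_O = ElementalComposition.from_formula("O")
_H2O = ElementalComposition.from_formula("H2O")

#: Monoisotopic mass added by one oxidation event (+O), ~+16 Da nominal.
OXIDATION_DELTA = MONOISOTOPIC_MASS["O"]

#: m/z offsets of singly charged adducts relative to the neutral mass.
ADDUCT_OFFSETS = {
    "M+H": PROTON_MASS,
    "M+Na": PROTON_MASS + (MONOISOTOPIC_MASS["Na"] - MONOISOTOPIC_MASS["H"]),
    "M+K": PROTON_MASS + (MONOISOTOPIC_MASS["K"] - MONOISOTOPIC_MASS["H"]),
}


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Sum of most-abundant-isotope atomic masses, in Da."""
    total = 0.0
    for el, n in composition._items:
        try:
            total += MONOISOTOPIC_MASS[el] * n
        except KeyError:
            raise ConfigurationError(f"no atomic mass registered for element {el!r}")
    return total


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged adduct ion of a neutral of the given mass."""
    if neutral_mass <= 0:
        raise DomainError(f"neutral mass must be positive, got {neutral_mass}")
    try:
        return neutral_mass + ADDUCT_OFFSETS[adduct]
    except KeyError:
        raise DomainError(
            f"unknown adduct {adduct!r}; expected one of {sorted(ADDUCT_OFFSETS)}"
        )


def terminator_delta() -> float:
    """Signed mass change (Da) of the azide -> free-amine reduction.

    The N-terminal azide (N3-CH2-) loses N2 and gains H2 upon reduction to
    the free amine (H2N-CH2-); the species gets lighter by ~25.99 Da.
    """
    return 2 * MONOISOTOPIC_MASS["H"] - 2 * MONOISOTOPIC_MASS["N"]


# ---------------------------------------------------------------------------
# Isotope envelopes
# ---------------------------------------------------------------------------

def _element_single_atom(el: str) -> tuple[np.ndarray, np.ndarray]:
    """(probability, probability-weighted mass offset) arrays over the
    extra-nucleon index k for a single atom of ``el``."""
    try:
        isos = ISOTOPES[el]
    except KeyError:
        raise ConfigurationError(f"no isotope data registered for element {el!r}")
    base = isos[0][0]
    kmax = max(int(round(m - base)) for m, _ in isos)
    p = np.zeros(kmax + 1)
    mom = np.zeros(kmax + 1)
    for m, ab in isos:
        k = int(round(m - base))
        p[k] += ab
        mom[k] += ab * (m - base)
    return p, mom


def _conv(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray],
          prune: float) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two (probability, first-moment) distributions."""
    pa, ma = a
    pb, mb = b
    p = np.convolve(pa, pb)
    mom = np.convolve(ma, pb) + np.convolve(pa, mb)
    # Trim the negligible high-k tail to keep arrays short.
    keep = np.nonzero(p > prune)[0]
    if len(keep):
        end = keep[-1] + 1
        p, mom = p[:end], mom[:end]
    return p, mom


def _power(dist: tuple[np.ndarray, np.ndarray], n: int,
           prune: float) -> tuple[np.ndarray, np.ndarray]:
    """n-fold self-convolution by binary exponentiation."""
    result: tuple[np.ndarray, np.ndarray] | None = None
    base = dist
    while n:
        if n & 1:
            result = base if result is None else _conv(result, base, prune)
        n >>= 1
        if n:
            base = _conv(base, base, prune)
    assert result is not None
    return result


def isotope_envelope(
    composition: ElementalComposition, max_peaks: int = 12
) -> list[tuple[float, float]]:
    """Aggregated isotope distribution of a neutral molecule.

    Isotopologues are grouped by total nucleon-number offset k (the usual
    "aggregated" envelope; peaks are spaced ~1.003 Da apart for C-dominated
    species).  Returns up to ``max_peaks`` ``(mass offset from monoisotopic,
    relative abundance)`` pairs in ascending offset order.  Abundances are
    normalized over the *untruncated* distribution, so a truncated return
    sums to less than 1.
    """
    if max_peaks < 1:
        raise DomainError("max_peaks must be >= 1")
    if not composition:
        return [(0.0, 1.0)]
    prune = 1e-15
    dist: tuple[np.ndarray, np.ndarray] | None = None
    for el, n in composition._items:
        elem = _power(_element_single_atom(el), n, prune)
        dist = elem if dist is None else _conv(dist, elem, prune)
    assert dist is not None
    p, mom = dist
    out: list[tuple[float, float]] = []
    for k in range(min(len(p), max_peaks)):
        if p[k] <= 0:
            continue
        out.append((float(mom[k] / p[k]), float(p[k])))
    return out


# ---------------------------------------------------------------------------
# Residues, termini, oligomer species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueSpec:
    """One PNA residue as incorporated in a chain (no free water)."""

    token: str
    base: str
    backbone: str  # "aeg" or "serine-modified"
    composition: ElementalComposition

    def mass(self) -> float:
        return monoisotopic_mass(self.composition)


@dataclass(frozen=True)
class _Delta:
    """Signed composition delta: add minus sub, applied to a residue sum."""

    add: ElementalComposition = ElementalComposition()
    sub: ElementalComposition = ElementalComposition()

    def apply(self, comp: ElementalComposition) -> ElementalComposition:
        return comp + self.add - self.sub

    def mass(self) -> float:
        return monoisotopic_mass(self.add) - monoisotopic_mass(self.sub)


@dataclass(frozen=True)
class TerminusState:
    """N- and C-terminal chemistry of an oligomer.

    ``linker_composition`` is the full C-terminal delta for the
    ``linker-biotin`` state; if omitted the registry default linker is used.
    """

    n_terminus: str = "free-amine"
    c_terminus: str = "amide"
    linker_composition: ElementalComposition | None = None


@dataclass(frozen=True)
class OligomerSpecies:
    """A PNA chain (sequence written C->N) with termini and oxidation state."""

    sequence: str
    termini: TerminusState = field(default_factory=TerminusState)
    oxidation_count: int = 0
    label: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    def composition(self, registry: "ResidueRegistry | None" = None) -> ElementalComposition:
        registry = registry or DEFAULT_REGISTRY
        return compose_oligomer(
            self.sequence, self.termini, self.oxidation_count, registry
        )

    def mass(self, registry: "ResidueRegistry | None" = None) -> float:
        return monoisotopic_mass(self.composition(registry))

    def reduced(self) -> "OligomerSpecies":
        """The same species after azide -> free-amine reduction (idempotent)."""
        if self.termini.n_terminus != "azide":
            return self
        return OligomerSpecies(
            self.sequence,
            TerminusState("free-amine", self.termini.c_terminus,
                          self.termini.linker_composition),
            self.oxidation_count,
            self.label,
        )


class ResidueRegistry:
    """Residue / terminus / linker composition tables.

    Built from a YAML mapping (see ``data/residues.yaml`` for the schema);
    ``ResidueRegistry.default()`` loads the table shipped with the package.
    """

    def __init__(self, residues: Mapping[str, ResidueSpec],
                 n_termini: Mapping[str, _Delta],
                 c_termini: Mapping[str, _Delta],
                 default_linker: _Delta | None = None):
        self.residues = dict(residues)
        self.n_termini = dict(n_termini)
        self.c_termini = dict(c_termini)
        self.default_linker = default_linker
        self._validate()

    @staticmethod
    def from_mapping(data: Mapping) -> "ResidueRegistry":
        def delta(entry: Mapping) -> _Delta:
            return _Delta(
                add=ElementalComposition.from_formula(entry.get("add", "")),
                sub=ElementalComposition.from_formula(entry.get("sub", "")),
            )

        residues = {}
        for token, entry in data["residues"].items():
            residues[token] = ResidueSpec(
                token=token,
                base=entry["base"],
                backbone=entry["backbone"],
                composition=ElementalComposition.from_formula(entry["composition"]),
            )
        n_t = {name: delta(s) for name, s in data["termini"]["n"].items()}
        c_t = {name: delta(s) for name, s in data["termini"]["c"].items()}
        linkers = data.get("linkers", {})
        default_linker = delta(linkers["biotin-default"]) if "biotin-default" in linkers else None
        return ResidueRegistry(residues, n_t, c_t, default_linker)

    @staticmethod
    def from_yaml(path) -> "ResidueRegistry":
        with open(path) as fh:
            return ResidueRegistry.from_mapping(yaml.safe_load(fh))

    @staticmethod
    def default() -> "ResidueRegistry":
        text = resources.files("pnaseq").joinpath("data/residues.yaml").read_text()
        return ResidueRegistry.from_mapping(yaml.safe_load(text))

    def _validate(self) -> None:
        aeg = [r for r in self.residues.values() if r.backbone == "aeg"]
        masses = {r.base: r.mass() for r in aeg}
        if len(set(r.composition for r in aeg)) != len(aeg):
            raise ConfigurationError("aeg residue compositions are not distinct")
        bases = sorted(masses)
        for i, b1 in enumerate(bases):
            for b2 in bases[i + 1:]:
                if abs(masses[b1] - masses[b2]) <= 8.0:
                    raise ConfigurationError(
                        f"residues {b1}/{b2} differ by "
                        f"{abs(masses[b1] - masses[b2]):.3f} Da (<= 8); "
                        "ladder increments would be ambiguous"
                    )
        for token, res in self.residues.items():
            if res.backbone == "serine-modified":
                partner = self.residues.get(token.upper())
                if partner is not None:
                    diff = res.composition - partner.composition
                    if diff != ElementalComposition.from_formula("CH2O"):
                        raise ConfigurationError(
                            f"serine-modified residue {token!r} does not differ "
                            "from its aeg partner by CH2O"
                        )

    def residue(self, token: str) -> ResidueSpec:
        try:
            return self.residues[token]
        except KeyError:
            raise ConfigurationError(f"unknown residue token {token!r}")

    def residue_mass(self, token: str) -> float:
        return self.residue(token).mass()

    def aeg_masses(self) -> dict[str, float]:
        """base -> monoisotopic residue mass for the four aeg residues."""
        return {
            r.base: r.mass() for r in self.residues.values() if r.backbone == "aeg"
        }


def compose_oligomer(
    sequence: Iterable[str] | str,
    termini: TerminusState,
    oxidations: int = 0,
    registry: ResidueRegistry | None = None,
) -> ElementalComposition:
    """Exact neutral-molecule composition of a PNA oligomer.

    Strictly additive: sum of residue compositions (sequence given C->N),
    plus the N- and C-terminus deltas, plus ``oxidations`` extra O atoms.
    """
    registry = registry or DEFAULT_REGISTRY
    tokens = list(sequence)
    if not tokens:
        raise DomainError("oligomer sequence must be non-empty")
    if oxidations < 0:
        raise DomainError("oxidation count must be >= 0")
    comp = ElementalComposition()
    for tok in tokens:
        comp = comp + registry.residue(tok).composition
    try:
        n_delta = registry.n_termini[termini.n_terminus]
    except KeyError:
        raise ConfigurationError(f"unknown N-terminus state {termini.n_terminus!r}")
    comp = n_delta.apply(comp)
    if termini.c_terminus == "linker-biotin":
        if termini.linker_composition is not None:
            comp = comp + termini.linker_composition
        elif registry.default_linker is not None:
            comp = registry.default_linker.apply(comp)
        else:
            raise ConfigurationError(
                "c_terminus is linker-biotin but no linker composition is "
                "supplied and the registry has no default linker"
            )
    else:
        try:
            c_delta = registry.c_termini[termini.c_terminus]
        except KeyError:
            raise ConfigurationError(f"unknown C-terminus state {termini.c_terminus!r}")
        comp = c_delta.apply(comp)
    if oxidations:
        comp = comp + oxidations * _O
    return comp


#: Registry built from the table shipped with the package.
DEFAULT_REGISTRY = ResidueRegistry.default()
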