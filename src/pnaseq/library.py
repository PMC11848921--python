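"""4-mer reagent combinatorics.

The extension chemistry uses tetrameric PNA probes ("4-mers"), C-terminally
activated as esters and N-terminally capped with an azide that acts as the
reversible terminator.  This module enumerates the full 256-member repertoire,
computes PNA antiparallel complements, expands wildcard masks into
complement-closed sublibraries, and (de)serializes reagent mixes as TSV.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DesignError, DomainError

__all__ = [
    "BASES",
    "WC_COMPLEMENT",
    "FourMer",
    "ReagentMix",
    "enumerate_full_repertoire",
    "pna_complement",
    "build_paired_sublibrary",
    "expand_mask",
]

BASES = "ACGT"
WC_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_N_CAPS = {"azide", "Fmoc", "acetyl"}
_ACTIVATIONS = {"free-acid", "sNHS-ester", "pNP-ester", "hydrolyzed"}
_ESTERS = {"sNHS-ester", "pNP-ester"}


@dataclass(frozen=True)
class FourMer:
    """A tetrameric PNA reagent, sequence written C->N."""

    sequence: str
    n_cap: str = "azide"
    activation: str = "sNHS-ester"

    def __post_init__(self):
        if len(self.sequence) != 4:
            raise DomainError(f"4-mer must have length 4, got {self.sequence!r}")
        for b in self.sequence:
            if b not in WC_COMPLEMENT:
                raise DomainError(f"unknown base {b!r} in 4-mer {self.sequence!r}")
        if self.n_cap not in _N_CAPS:
            raise DomainError(f"unknown N-cap {self.n_cap!r}")
        if self.activation not in _ACTIVATIONS:
            raise DomainError(f"unknown activation state {self.activation!r}")

    def activate(self, ester: str = "sNHS-ester") -> "FourMer":
        """free-acid -> activated ester; any other transition is invalid."""
        if self.activation != "free-acid":
            raise DomainError(
                f"cannot activate a 4-mer in state {self.activation!r}"
            )
        if ester not in _ESTERS:
            raise DomainError(f"unknown ester {ester!r}")
        return replace(self, activation=ester)

    def hydrolyze(self) -> "FourMer":
        """activated ester -> hydrolyzed (inactive); only esters hydrolyze."""
        if self.activation not in _ESTERS:
            raise DomainError(
                f"cannot hydrolyze a 4-mer in state {self.activation!r}"
            )
        return replace(self, activation="hydrolyzed")

    @property
    def reactive(self) -> bool:
        return self.activation in _ESTERS


@dataclass
class ReagentMix:
    """A mixture of 4-mers with concentrations in μM."""

    members: list[tuple[FourMer, float]]

    def __post_init__(self):
        for fm, conc in self.members:
            if conc <= 0:
                raise DomainError(
                    f"concentration for {fm.sequence} must be > 0, got {conc}"
                )

    @property
    def total_concentration(self) -> float:
        return sum(conc for _, conc in self.members)

    def sequences(self) -> set[str]:
        return {fm.sequence for fm, _ in self.members}

    def contains(self, sequence: str) -> bool:
        return sequence in self.sequences()

    def reactive_members(self) -> list[tuple[FourMer, float]]:
        return [(fm, c) for fm, c in self.members if fm.reactive]

    # -- TSV serialization --------------------------------------------------

    _COLUMNS = ("sequence", "cap", "activation", "concentration_uM")

    def write_tsv(self, destination) -> None:
        path = Path(destination)
        lines = ["\t".join(self._COLUMNS)]
        for fm, conc in self.members:
            lines.append(f"{fm.sequence}\t{fm.n_cap}\t{fm.activation}\t{conc:g}")
        path.write_text("\n".join(lines) + "\n")

    @staticmethod
    def read_tsv(source) -> "ReagentMix":
        lines = Path(source).read_text().splitlines()
        if not lines or lines[0].split("\t") != list(ReagentMix._COLUMNS):
            raise DomainError(f"{source}: missing or malformed reagent-mix header")
        members = []
        for line in lines[1:]:
            if not line.strip():
                continue
            seq, cap, act, conc = line.split("\t")
            members.append((FourMer(seq, cap, act), float(conc)))
        return ReagentMix(members)


def enumerate_full_repertoire() -> list[str]:
    """All 256 distinct 4-mer sequences over ACGT, lexicographic."""
    return ["".join(p) for p in itertools.product(BASES, repeat=4)]


def pna_complement(sequence: str) -> str:
    """Antiparallel Watson-Crick partner of a PNA sequence, same C->N convention.

    Position i of the output complements position L-i+1 of the input, so the
    mask AxxC maps to GxxT and the operation is an involution.
    """
    if not sequence:
        raise DomainError("cannot complement an empty sequence")
    try:
        return "".join(WC_COMPLEMENT[b] for b in reversed(sequence))
    except KeyError as exc:
        raise DomainError(f"unknown base {exc.args[0]!r} in {sequence!r}")


def expand_mask(mask: str) -> list[str]:
    """Expand a 4-mer mask with wildcard ``x`` over all bases, lexicographic."""
    if len(mask) != 4:
        raise DomainError(f"mask must have length 4, got {mask!r}")
    choices = []
    for ch in mask:
        if ch == "x":
            choices.append(BASES)
        elif ch in WC_COMPLEMENT:
            choices.append(ch)
        else:
            raise DomainError(f"mask letter {ch!r} not in {{A,C,G,T,x}}")
    return ["".join(p) for p in itertools.product(*choices)]


def build_paired_sublibrary(
    masks: Sequence[str],
    concentration_um: float = 2.0,
    n_cap: str = "azide",
    activation: str = "sNHS-ester",
) -> ReagentMix:
    """Expand wildcard masks into a complement-closed reagent mix.

    Every member must have its antiparallel complement in the expanded set
    (the mix-and-split design constraint); a non-closed design raises
    :class:`DesignError` listing the unpaired members.
    """
    sequences: list[str] = []
    for mask in masks:
        sequences.extend(expand_mask(mask))
    if len(set(sequences)) != len(sequences):
        seen, dups = set(), set()
        for s in sequences:
            (dups if s in seen else seen).add(s)
        raise DesignError(f"masks expand to duplicate members: {sorted(dups)}")
    members = set(sequences)
    unpaired = sorted(s for s in members if pna_complement(s) not in members)
    if unpaired:
        raise DesignError(
            "sublibrary is not closed under PNA complementation; unpaired "
            f"members: {', '.join(unpaired)}"
        )
    return ReagentMix(
        [(FourMer(s, n_cap, activation), concentration_um) for s in sequences]
    )


def full_repertoire_mix(
    concentration_um: float = 3.0 / 256,
    total_um: float | None = None,
) -> ReagentMix:
    """The complete 256-member mix; either per-member or total concentration."""
    seqs = enumerate_full_repertoire()
    if total_um is not None:
        concentration_um = total_um / len(seqs)
    return ReagentMix([(FourMer(s), concentration_um) for s in seqs])
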