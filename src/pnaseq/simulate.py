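"""Kinetic simulation of cyclic, enzyme-free primer extension.

The chemistry being modeled: a template strand (d- or l-DNA, LNA, or PNA) is
captured by a set of four biotinylated PNA primers — the full-length primer P
and its N-terminal deletions P-1, P-2, P-3 — immobilized on streptavidin
beads.  Each cycle, C-terminally activated 4-mer PNA probes hybridize
adjacent to a primer's free N-terminal amine and ligate; their N-terminal
azide blocks further addition until it is reduced back to an amine between
cycles (reversible termination).  Because the four primers are offset by one
residue, the union of their extension products forms a mass ladder whose
consecutive increments are single residues.

The simulator runs in expectation mode (deterministic population fractions,
the default: MALDI intensities are population averages) or in a seeded
per-molecule stochastic mode.  Fidelity is governed by a small set of
calibrated competition weights (see :class:`KineticsConfig`); mass
bookkeeping is delegated entirely to :mod:`pnaseq.chem`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import OligomerSpecies, ResidueRegistry, TerminusState, DEFAULT_REGISTRY
from .errors import DomainError
from .library import FourMer, ReagentMix, WC_COMPLEMENT, pna_complement

__all__ = [
    "Template",
    "PrimerSet",
    "KineticsConfig",
    "SpeciesAbundance",
    "CaptureResult",
    "SimState",
    "check_capture",
    "extension_conversion",
    "competition_weights",
    "run_cycle",
    "run_protocol",
    "design_primer_set",
    "pm_cycle_mixes",
]

_POLYMERS = {"DNA", "LNA", "PNA"}
_CHIRALITIES = {"D", "L", "achiral"}

#: Extension half-life preset (minutes) for p-nitrophenyl esters, which give
#: roughly half conversion only after three hours (vs ~2 min for s-NHS).
PNP_T_HALF_MIN = 180.0


@dataclass(frozen=True)
class Template:
    """A template strand to be sequenced.

    ``sequence`` is written 5'->3' for DNA/LNA and N->C for PNA templates.
    The capture site is the last ``primer_length`` bases; the read window is
    the ``read_length`` bases immediately upstream of it, reported in reading
    order (the order in which extension traverses them, i.e. descending
    template index).
    """

    sequence: str
    polymer: str = "DNA"
    chirality: str = "D"
    primer_length: int = 14
    read_length: int = 8

    def __post_init__(self):
        if self.polymer not in _POLYMERS:
            raise DomainError(f"unknown polymer {self.polymer!r}")
        if self.chirality not in _CHIRALITIES:
            raise DomainError(f"unknown chirality {self.chirality!r}")
        if self.polymer == "PNA" and self.chirality != "achiral":
            raise DomainError("PNA templates are achiral")
        if self.polymer != "PNA" and self.chirality == "achiral":
            raise DomainError(f"{self.polymer} templates must be D or L")
        for b in self.sequence:
            if b not in WC_COMPLEMENT:
                raise DomainError(f"unknown base {b!r} in template")
        if len(self.sequence) < self.primer_length + self.read_length:
            raise DomainError(
                "template shorter than primer_length + read_length "
                f"({len(self.sequence)} < {self.primer_length + self.read_length})"
            )

    @property
    def read_window(self) -> list[int]:
        """Template indices to be sequenced, in reading order."""
        start = len(self.sequence) - self.primer_length - 1
        return [start - i for i in range(self.read_length)]

    def read_bases(self) -> str:
        """Template bases over the read window, in reading order."""
        return "".join(self.sequence[p] for p in self.read_window)


@dataclass(frozen=True)
class PrimerSet:
    """The primer deletion ladder P, P-1, P-2, P-3.

    ``primers[k]`` is P with its k N-terminal residues removed; all four
    share termini configuration.  ``dead_fraction`` is the bead-bound
    fraction that never reacts — it guarantees anchor peaks at the
    unextended primer masses.
    """

    primers: dict[int, OligomerSpecies]
    chirality_preference: str = "binds-D"
    loading: float = 1.0
    dead_fraction: float = 0.3

    def __post_init__(self):
        if sorted(self.primers) != [0, 1, 2, 3]:
            raise DomainError("primer set must contain offsets 0..3")
        if self.chirality_preference not in {"binds-D", "binds-L"}:
            raise DomainError(
                f"unknown chirality preference {self.chirality_preference!r}"
            )
        if not (0 <= self.dead_fraction < 1):
            raise DomainError("dead_fraction must be in [0, 1)")
        full = self.primers[0]
        for k in (1, 2, 3):
            p = self.primers[k]
            # sequences are written C->N: the k N-terminal residues are the
            # last k tokens of the full primer.
            if p.sequence != full.sequence[: len(full.sequence) - k]:
                raise DomainError(
                    f"primer P-{k} is not P with its {k} N-terminal residues removed"
                )
            if p.termini != full.termini:
                raise DomainError("all four primers must share termini config")

    def lineage_label(self, k: int) -> str:
        return "P" if k == 0 else f"P-{k}"


@dataclass(frozen=True)
class KineticsConfig:
    """Tunable rate and fidelity parameters of one extension protocol.

    Times are minutes, concentrations μM.  The fidelity weights are
    calibrated on the observed product ratios of small-scale competition
    experiments: a lone mismatch at the ligation-distal terminus (the N-ter
    of the incoming 4-mer) incorporates as well as the perfect match
    (weight 1), complement sequestration suppresses it fourfold
    (factor 0.25), and a strand carrying a terminal mismatch extends six
    times less in the following cycle (penalty 6, applied to the extension
    extent).  Internal and multiple mismatches are below detection
    (weight 0), as is a single mismatch at the ligation site itself (the
    C-ter, ``ligation_mm_weight``), where it disrupts the stacking that
    drives the amide-forming step.
    K_D and k_off describe 4-mer:template binding and are retained for a
    future explicit-equilibrium mode; the present model folds binding into
    the calibrated weights.
    """

    t_half_extension: float = 2.0
    t_half_hydrolysis: float = 300.0
    reaction_time: float = 4.0
    K_D: float = 8.0
    k_off: float = 1.0
    internal_mm_weight: float = 0.0
    multi_mm_weight: float = 0.0
    terminal_mm_weight: float = 1.0
    ligation_mm_weight: float = 0.0
    cm_sequestration_factor: float = 0.25
    post_mm_extension_penalty: float = 6.0
    helper_factor: float = 2.0
    nonadjacent_weight: float = 0.0
    reduction_efficiency: float = 1.0
    reference_concentration_um: float = 3.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.t_half_extension <= 0 or self.t_half_hydrolysis <= 0:
            raise DomainError("half-lives must be > 0")
        if self.reaction_time < 0:
            raise DomainError("reaction_time must be >= 0")
        for name in (
            "internal_mm_weight", "multi_mm_weight", "terminal_mm_weight",
            "ligation_mm_weight", "cm_sequestration_factor", "helper_factor",
            "nonadjacent_weight",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.post_mm_extension_penalty < 1:
            raise DomainError("post_mm_extension_penalty must be >= 1")
        if not (0 <= self.reduction_efficiency <= 1):
            raise DomainError("reduction_efficiency must be in [0, 1]")
        if self.reference_concentration_um <= 0:
            raise DomainError("reference_concentration_um must be > 0")

    @staticmethod
    def pnp_ester() -> "KineticsConfig":
        """Preset for the slow p-nitrophenyl ester chemistry."""
        return KineticsConfig(t_half_extension=PNP_T_HALF_MIN)


@dataclass(frozen=True)
class CaptureResult:
    captured: bool
    reason: str = ""


@dataclass
class SpeciesAbundance:
    """Map species -> relative abundance; the simulator's exported product."""

    entries: dict[OligomerSpecies, float]

    def total(self) -> float:
        return sum(self.entries.values())

    def lineage_totals(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for sp, ab in self.entries.items():
            totals[sp.label] = totals.get(sp.label, 0.0) + ab
        return totals

    # -- TSV serialization --------------------------------------------------

    _COLUMNS = ("label", "sequence", "n_cap", "oxidation", "abundance")

    def write_tsv(self, destination) -> None:
        lines = ["\t".join(self._COLUMNS)]
        for sp, ab in sorted(
            self.entries.items(), key=lambda e: (e[0].label, len(e[0].sequence))
        ):
            lines.append(
                f"{sp.label}\t{sp.sequence}\t{sp.termini.n_terminus}\t"
                f"{sp.oxidation_count}\t{ab:.10g}"
            )
        Path(destination).write_text("\n".join(lines) + "\n")

    @staticmethod
    def read_tsv(source, c_terminus: str = "linker-biotin") -> "SpeciesAbundance":
        lines = Path(source).read_text().splitlines()
        if not lines or lines[0].split("\t") != list(SpeciesAbundance._COLUMNS):
            raise DomainError(f"{source}: missing or malformed species header")
        entries: dict[OligomerSpecies, float] = {}
        for line in lines[1:]:
            if not line.strip():
                continue
            label, seq, cap, ox, ab = line.split("\t")
            sp = OligomerSpecies(
                seq, TerminusState(cap, c_terminus), int(ox), label
            )
            entries[sp] = entries.get(sp, 0.0) + float(ab)
        return SpeciesAbundance(entries)


# ---------------------------------------------------------------------------
# Internal per-strand state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _StrandKey:
    lineage: int
    sequence: str           # full oligomer sequence, C->N
    cap: str                # "free-amine" | "azide" | ...
    frontier: int           # next template index to pair (moving toward 5')
    post_mm: bool           # last added 4-mer contained a mismatch
    mm_count: int
    dead: bool


@dataclass
class SimState:
    """Population state between protocol steps: strand record -> amount."""

    template: Template
    primers: PrimerSet
    strands: dict[_StrandKey, float] = field(default_factory=dict)

    def add(self, key: _StrandKey, amount: float) -> None:
        if amount > 0:
            self.strands[key] = self.strands.get(key, 0.0) + amount

    def to_abundance(self, normalization: float = 1.0) -> SpeciesAbundance:
        c_term = self.primers.primers[0].termini
        entries: dict[OligomerSpecies, float] = {}
        for key, amount in self.strands.items():
            sp = OligomerSpecies(
                key.sequence,
                TerminusState(key.cap, c_term.c_terminus, c_term.linker_composition),
                0,
                self.primers.lineage_label(key.lineage),
            )
            entries[sp] = entries.get(sp, 0.0) + amount / normalization
        return SpeciesAbundance(entries)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _base_of(token: str) -> str:
    return token.upper()


def check_capture(template: Template, primers: PrimerSet,
                  registry: ResidueRegistry | None = None) -> CaptureResult:
    """Binary capture decision: chirality gate plus capture-site complementarity.

    Capture succeeds iff the template is achiral or the primer chirality
    preference matches the template chirality, and the full primer is
    antiparallel-complementary to the capture site.
    """
    registry = registry or DEFAULT_REGISTRY
    if template.chirality != "achiral":
        wanted = "binds-D" if template.chirality == "D" else "binds-L"
        if primers.chirality_preference != wanted:
            return CaptureResult(
                False,
                f"primer set {primers.chirality_preference} cannot hybridize a "
                f"{template.chirality}-{template.polymer} template",
            )
    full = primers.primers[0]
    if len(full.sequence) != template.primer_length:
        return CaptureResult(False, "primer length does not match capture site")
    L = len(template.sequence)
    for j, token in enumerate(full.sequence):
        # primer position j (C->N, 0-based) pairs template index L-1-j
        t_base = template.sequence[L - 1 - j]
        base = registry.residue(token).base if token in registry.residues else _base_of(token)
        if base != WC_COMPLEMENT[t_base]:
            return CaptureResult(
                False, f"primer not complementary to capture site at position {j + 1}"
            )
    return CaptureResult(True, "captured")


def extension_conversion(t: float, t_half: float,
                         t_half_hydrolysis: float = math.inf) -> float:
    """Fraction of extendable primer converted after ``t`` minutes.

    First-order in the activated ester: conversion = 1 - 2^(-t/t_half).
    Hydrolysis competes as a parallel first-order channel depleting the
    ester pool, which caps the attainable conversion:
    1 - exp(-(ke/kh) (1 - e^{-kh t})).
    """
    if t < 0:
        raise DomainError("time must be >= 0")
    if t_half <= 0 or t_half_hydrolysis <= 0:
        raise DomainError("half-lives must be > 0")
    ke = math.log(2.0) / t_half
    if math.isinf(t_half_hydrolysis):
        return 1.0 - math.exp(-ke * t)
    kh = math.log(2.0) / t_half_hydrolysis
    return 1.0 - math.exp(-(ke / kh) * (1.0 - math.exp(-kh * t)))


def competition_weights(
    site: str,
    mix: ReagentMix,
    cfg: KineticsConfig,
    downstream: str | None = None,
) -> dict[FourMer, float]:
    """Relative incorporation weights of the mix members at one template site.

    ``site`` is the 4-base template window in template orientation (5'->3');
    the perfect match is its antiparallel PNA complement.  A single mismatch
    at a terminal position of the 4-mer (C-ter, ligation-proximal, or N-ter,
    ligation-distal) incorporates at ``terminal_mm_weight``, suppressed by
    ``cm_sequestration_factor`` when that 4-mer's own complement is present
    in the mix; internal and multiple mismatches use their (default zero)
    weights.  When ``downstream`` (the next 4-base window) is given and its
    perfect match is present in the mix, the perfect-match candidate gains
    ``helper_factor`` (downstream hybridization stabilizes the reactive
    complex, improving both rate and fidelity).  Weights scale with
    concentration; incorporation probabilities are proportional to weights.
    """
    if len(site) != 4:
        raise DomainError(f"site window must have 4 bases, got {site!r}")
    pm = pna_complement(site)
    sequences = mix.sequences()
    helper_present = (
        downstream is not None
        and len(downstream) == 4
        and pna_complement(downstream) in sequences
    )
    weights: dict[FourMer, float] = {}
    for fm, conc in mix.reactive_members():
        mismatches = [j for j in range(4) if fm.sequence[j] != pm[j]]
        if not mismatches:
            w = 1.0
            if helper_present:
                w *= cfg.helper_factor
        elif len(mismatches) == 1:
            if mismatches[0] == 3:
                # ligation-distal terminal (N-ter of the 4-mer): the only
                # mismatch that incorporates appreciably
                w = cfg.terminal_mm_weight
                if pna_complement(fm.sequence) in sequences:
                    w *= cfg.cm_sequestration_factor
            elif mismatches[0] == 0:
                # ligation-proximal terminal (C-ter): disrupts stacking at
                # the reaction site itself
                w = cfg.ligation_mm_weight
                if pna_complement(fm.sequence) in sequences:
                    w *= cfg.cm_sequestration_factor
            else:
                w = cfg.internal_mm_weight
        else:
            w = cfg.multi_mm_weight
        w *= conc
        if w > 0:
            weights[fm] = w
    return weights


def _site_window(template: Template, frontier: int, gap: int = 0) -> str | None:
    lo = frontier - gap - 3
    if lo < 0:
        return None
    return template.sequence[lo: frontier - gap + 1]


def run_cycle(
    state: SimState,
    mix: ReagentMix,
    cfg: KineticsConfig,
    rng: np.random.Generator | None = None,
) -> SimState:
    """One extension cycle: each free-amine strand gains at most one 4-mer.

    Azide-capped strands are blocked; strands whose last addition carried a
    mismatch extend with their conversion divided by
    ``post_mm_extension_penalty``.  In expectation mode (``rng=None``)
    amounts split deterministically in proportion to weights; with an rng,
    integer molecule counts are drawn binomially/multinomially.
    """
    template = state.template
    if not mix.reactive_members():
        warnings.warn("reagent mix contains no reactive esters; no extension")
        return state
    new = SimState(template, state.primers)
    for key, amount in state.strands.items():
        extendable = (
            not key.dead
            and key.cap == "free-amine"
            and _site_window(template, key.frontier) is not None
        )
        if not extendable:
            new.add(key, amount)
            continue
        # candidate registers: adjacent, plus 1-2 nt gaps if enabled
        candidates: list[tuple[FourMer, int, float, int]] = []
        gaps = [0] if cfg.nonadjacent_weight == 0 else [0, 1, 2]
        for gap in gaps:
            site = _site_window(template, key.frontier, gap)
            if site is None:
                continue
            downstream = _site_window(template, key.frontier, gap + 4)
            w = competition_weights(site, mix, cfg, downstream)
            scale = 1.0 if gap == 0 else cfg.nonadjacent_weight
            pm = pna_complement(site)
            for fm, wt in w.items():
                n_mm = sum(fm.sequence[j] != pm[j] for j in range(4))
                candidates.append((fm, gap, wt * scale, n_mm))
        total_w = sum(c[2] for c in candidates)
        if total_w <= 0:
            new.add(key, amount)
            continue
        # each candidate contributes a pseudo-first-order channel, so the
        # extension extent scales with the total weight relative to one
        # perfect-match 4-mer at the reference concentration
        scale = total_w / cfg.reference_concentration_um
        conv = extension_conversion(
            cfg.reaction_time, cfg.t_half_extension / scale,
            cfg.t_half_hydrolysis,
        )
        if key.post_mm:
            conv /= cfg.post_mm_extension_penalty
        if rng is None:
            extended = amount * conv
            splits = [extended * c[2] / total_w for c in candidates]
            remainder = amount - extended
        else:
            n = int(round(amount))
            n_ext = rng.binomial(n, conv)
            probs = np.array([c[2] for c in candidates]) / total_w
            splits = rng.multinomial(n_ext, probs).astype(float)
            remainder = float(n - n_ext)
        new.add(key, remainder)
        for (fm, gap, _, n_mm), amt in zip(candidates, splits):
            if amt <= 0:
                continue
            new_key = _StrandKey(
                lineage=key.lineage,
                sequence=key.sequence + fm.sequence,
                cap=fm.n_cap if fm.n_cap != "azide" else "azide",
                frontier=key.frontier - 4 - gap,
                post_mm=n_mm > 0,
                mm_count=key.mm_count + n_mm,
                dead=False,
            )
            new.add(new_key, amt)
    return new


def _reduce_azides(state: SimState, efficiency: float,
                   rng: np.random.Generator | None = None) -> SimState:
    new = SimState(state.template, state.primers)
    for key, amount in state.strands.items():
        if key.cap != "azide" or efficiency == 0:
            new.add(key, amount)
            continue
        if rng is None:
            reduced = amount * efficiency
        else:
            reduced = float(rng.binomial(int(round(amount)), efficiency))
        new.add(replace(key, cap="free-amine"), reduced)
        new.add(key, amount - reduced)
    return new


def _initial_state(template: Template, primers: PrimerSet,
                   n_molecules: int | None = None,
                   rng: np.random.Generator | None = None) -> SimState:
    L = len(template.sequence)
    state = SimState(template, primers)
    for k, primer in primers.primers.items():
        frontier = L - template.primer_length + k - 1
        loading = primers.loading if n_molecules is None else float(n_molecules)
        if rng is None:
            dead = loading * primers.dead_fraction
        else:
            dead = float(rng.binomial(int(loading), primers.dead_fraction))
        live = loading - dead
        base = dict(
            lineage=k, sequence=primer.sequence, cap=primer.termini.n_terminus,
            frontier=frontier, post_mm=False, mm_count=0,
        )
        state.add(_StrandKey(dead=True, **base), dead)
        state.add(_StrandKey(dead=False, **base), live)
    return state


def run_protocol(
    template: Template,
    primers: PrimerSet,
    mixes: Sequence[ReagentMix],
    n_cycles: int | None = None,
    cfg: KineticsConfig | None = None,
    mode: str = "expectation",
    n_molecules: int = 100_000,
    registry: ResidueRegistry | None = None,
) -> SpeciesAbundance:
    """Full protocol: capture, then alternating extension and azide reduction.

    Reduction is applied between cycles only, so final-cycle products retain
    their azide caps while earlier products carry free amines.  The dead
    primer fraction never reacts and guarantees the four anchor peaks.  On
    capture failure the primers are returned unreacted.
    """
    cfg = cfg or KineticsConfig()
    if n_cycles is None:
        n_cycles = len(mixes)
    if n_cycles < 1:
        raise DomainError("n_cycles must be >= 1")
    if len(mixes) != n_cycles:
        raise DomainError(f"expected {n_cycles} mixes, got {len(mixes)}")
    if mode not in {"expectation", "stochastic"}:
        raise DomainError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(cfg.rng_seed) if mode == "stochastic" else None

    capture = check_capture(template, primers, registry)
    if not capture.captured:
        state = _initial_state(template, primers)
        # collapse dead/live distinction: nothing reacted
        return state.to_abundance()

    state = _initial_state(
        template, primers,
        n_molecules if mode == "stochastic" else None, rng,
    )
    for c in range(n_cycles):
        state = run_cycle(state, mixes[c], cfg, rng)
        if c < n_cycles - 1:
            state = _reduce_azides(state, cfg.reduction_efficiency, rng)
    norm = float(n_molecules) if mode == "stochastic" else 1.0
    return state.to_abundance(norm)


# ---------------------------------------------------------------------------
# Construction helpers
# ---------------------------------------------------------------------------

def design_primer_set(
    template: Template,
    dead_fraction: float = 0.3,
    loading: float = 1.0,
    serine_positions: Sequence[int] = (),
    c_terminus: str = "linker-biotin",
) -> PrimerSet:
    """Build the P/P-1/P-2/P-3 deletion ladder complementary to the capture site.

    ``serine_positions`` are 0-based positions (C->N) carrying the
    serine-modified backbone (mass +CH2O); the chirality preference is set
    to match the template so that capture succeeds.
    """
    L = len(template.sequence)
    pl = template.primer_length
    tokens = [
        WC_COMPLEMENT[template.sequence[L - 1 - j]] for j in range(pl)
    ]
    for pos in serine_positions:
        tokens[pos] = tokens[pos].lower()
    full = "".join(tokens)
    termini = TerminusState("free-amine", c_terminus)
    pref = "binds-L" if template.chirality == "L" else "binds-D"
    primers = {
        k: OligomerSpecies(full[: pl - k], termini, 0, "P" if k == 0 else f"P-{k}")
        for k in range(4)
    }
    return PrimerSet(primers, pref, loading, dead_fraction)


def pm_cycle_mixes(
    template: Template,
    n_cycles: int = 2,
    concentration_um: float = 3.0,
) -> list[ReagentMix]:
    """Per-cycle perfect-match mixes: for each cycle, the four 4-mers that
    extend each primer lineage at its current frontier (the minimal-mix
    workflow used for protocol validation)."""
    L = len(template.sequence)
    mixes = []
    for c in range(n_cycles):
        seqs: list[str] = []
        for k in range(4):
            frontier = L - template.primer_length + k - 1 - 4 * c
            site = _site_window_for_mix(template, frontier)
            if site is not None:
                seq = pna_complement(site)
                if seq not in seqs:
                    seqs.append(seq)
        mixes.append(ReagentMix([(FourMer(s), concentration_um) for s in seqs]))
    return mixes


def _site_window_for_mix(template: Template, frontier: int) -> str | None:
    return _site_window(template, frontier)
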