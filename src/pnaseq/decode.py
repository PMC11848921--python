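"""The sequencer: from a centroided peak list to base calls.

Decoding proceeds in three stages.  ``collapse_to_neutral`` reduces the peak
list to neutral monoisotopic masses: isotope clusters are grouped by their
~1.003 Da spacing keeping the monoisotopic member, Na/K adduct satellites are
folded into their protonated parents, and +16 Da oxidation satellites are
retained but annotated (they are the decoder's hardest confound, because the
G and A residues differ by exactly one oxygen).  ``anchor_primers`` locates
the four unextended primers P, P-1, P-2, P-3 — the unreactive bead fraction
guarantees their peaks — and decoding proceeds with at least two anchors.
``call_ladder`` then walks the product ladder above the full primer: each
single-residue mass increment between consecutive rungs is a base call, with
the azide terminator delta accounted for at the final-cycle boundary.
Ambiguity policy: never guess — truncate at a missing rung, flag an
unresolved call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import (
    ADDUCT_OFFSETS,
    OXIDATION_DELTA,
    PROTON_MASS,
    ResidueRegistry,
    DEFAULT_REGISTRY,
    terminator_delta,
)
from .errors import ConfigurationError, DecodingError
from .library import WC_COMPLEMENT
from .msgen import PeakList
from .simulate import PrimerSet

__all__ = [
    "DecoderConfig",
    "Neutral",
    "LadderCall",
    "SequenceRead",
    "collapse_to_neutral",
    "anchor_primers",
    "call_ladder",
    "decode_spectrum",
    "format_report",
]

# Aggregated-envelope centroid spacing for PNA-sized CHNOS molecules: the
# 13C step (1.00336 Da) pulled down by 15N/2H/17O contributions.  Measured
# 1.0012-1.0025 Da across 4-22-mers; a tight window around it keeps distinct
# species ~0.995 Da apart (residue-substitution near-coincidences) from being
# absorbed as isotope members.
_ISOTOPE_SPACING = 1.0020


@dataclass(frozen=True)
class DecoderConfig:
    """Decoder parameters.

    ``tolerance`` (Da) and ``ppm`` are mutually exclusive; the default
    0.25 Da suits linear MALDI-TOF of 3-6 kDa oligomers.  ``primers`` holds
    the declared primer species whose masses anchor the ladder;
    ``max_cycles`` bounds the read length at 4 bases per cycle;
    ``final_cap`` states whether the last cycle's products are still
    azide-capped (no post-run reduction, the default workflow).
    """

    primers: PrimerSet
    tolerance: float = 0.25
    ppm: float | None = None
    max_cycles: int = 2
    final_cap: str = "azide"
    isotope_spacing_tol: float = 0.004
    satellite_tol: float = 0.05
    ambiguity_ratio: float = 2.0
    registry: ResidueRegistry = field(default_factory=lambda: DEFAULT_REGISTRY)

    def __post_init__(self):
        if self.ppm is not None:
            if self.ppm <= 0:
                raise ConfigurationError("ppm must be > 0")
        else:
            gaps = sorted(self.registry.aeg_masses().values())
            min_gap = min(b - a for a, b in zip(gaps, gaps[1:]))
            if not (0 < self.tolerance < min_gap / 2):
                raise ConfigurationError(
                    f"tolerance must be in (0, {min_gap / 2:.3f}) Da to keep "
                    "single-residue increments distinguishable"
                )
        if self.max_cycles < 1:
            raise ConfigurationError("max_cycles must be >= 1")
        if self.final_cap not in {"azide", "free-amine"}:
            raise ConfigurationError(f"unknown final cap {self.final_cap!r}")

    def tol(self, mass: float) -> float:
        return mass * self.ppm * 1e-6 if self.ppm is not None else self.tolerance


@dataclass
class Neutral:
    """One deconvolved neutral species candidate.

    ``intensity`` is the total with Na/K satellites folded in; ``score`` is
    the protonated cluster's own summed intensity, which the ladder walk
    ranks on — satellite folding can absorb a coincident interloper (the
    azide-minus-amine delta exceeds the Na-adduct offset by almost exactly
    four isotope spacings), and that contamination must not sway base calls.
    """

    mass: float
    intensity: float
    score: float = 0.0
    n_isotope_peaks: int = 1
    ox_satellite_of: float | None = None  # parent neutral mass, if annotated
    orphan: bool = True  # cleared when used as anchor or rung

    def __post_init__(self):
        if self.score == 0.0:
            self.score = self.intensity

    @property
    def is_ox_satellite(self) -> bool:
        return self.ox_satellite_of is not None


@dataclass
class LadderCall:
    """One base call with its mass-increment evidence."""

    position: int
    base: str  # A/C/G/T or "N" for ambiguous
    observed_increment: float  # Da, between supporting rungs
    increment_error: float  # mDa, observed minus expected
    supporting_offsets: tuple[str, ...]
    flags: tuple[str, ...] = ()


@dataclass
class SequenceRead:
    """Ordered base calls plus provenance and confidence summary."""

    calls: list[LadderCall]
    chirality: str  # template chirality implied by the anchoring primer set
    anchors: dict[str, float]
    status: str  # "ok" | "truncated" | "no-extension"
    orphans: list[Neutral] = field(default_factory=list)
    truncated_at: int | None = None  # position of the missing rung, if any

    def pna_sequence(self) -> str:
        """Called PNA residues, C->N (extension order)."""
        return "".join(c.base for c in self.calls)

    def template_sequence(self) -> str:
        """Template bases in reading order (complement of the PNA calls)."""
        return "".join(WC_COMPLEMENT.get(c.base, "N") for c in self.calls)

    @property
    def confidence(self) -> dict[str, int]:
        return {
            "n_called": len(self.calls),
            "n_flagged": sum(1 for c in self.calls if c.flags),
            "n_ambiguous": sum(1 for c in self.calls if c.base == "N"),
            "n_anchors": len(self.anchors),
        }


# ---------------------------------------------------------------------------
# Stage 1: peak list -> neutral masses
# ---------------------------------------------------------------------------

def collapse_to_neutral(peaks: PeakList, cfg: DecoderConfig) -> list[Neutral]:
    """Deisotope, fold adduct satellites, and convert to neutral masses.

    Unassignable peaks pass through as orphan neutrals rather than raising.
    """
    # isotope clustering: a peak extends whichever open cluster it continues
    clusters: list[list[tuple[float, float]]] = []
    tol = cfg.isotope_spacing_tol
    for mz, inten in peaks.peaks:
        best = None
        best_err = tol
        for cl in clusters:
            err = abs(mz - cl[-1][0] - _ISOTOPE_SPACING)
            if err <= best_err:
                best, best_err = cl, err
        if best is None:
            clusters.append([(mz, inten)])
        else:
            best.append((mz, inten))

    mono = [(cl[0][0], sum(i for _, i in cl), len(cl)) for cl in clusters]
    mono.sort()

    # fold Na/K satellites into their protonated parents (lightest first, so
    # a satellite can never itself act as a parent)
    sat_offsets = [
        ADDUCT_OFFSETS["M+Na"] - ADDUCT_OFFSETS["M+H"],
        ADDUCT_OFFSETS["M+K"] - ADDUCT_OFFSETS["M+H"],
    ]
    consumed = [False] * len(mono)
    folded: list[Neutral] = []
    for i, (mz, inten, npk) in enumerate(mono):
        if consumed[i]:
            continue
        total = inten
        for off in sat_offsets:
            target = mz + off
            best_j, best_err = None, cfg.satellite_tol
            for j in range(i + 1, len(mono)):
                if consumed[j]:
                    continue
                err = abs(mono[j][0] - target)
                # an adduct satellite is always weaker than its parent
                # cluster (minor adduct fractions); never let a small
                # cluster swallow a large one
                if err <= best_err and mono[j][1] < inten:
                    best_j, best_err = j, err
                if mono[j][0] > target + cfg.satellite_tol:
                    break
            if best_j is not None:
                consumed[best_j] = True
                total += mono[best_j][1]
        folded.append(Neutral(mass=mz - PROTON_MASS, intensity=total,
                              score=inten, n_isotope_peaks=npk))

    # annotate +16 oxidation satellites (parent must be the stronger peak)
    for n in folded:
        for parent in folded:
            if (
                abs(n.mass - parent.mass - OXIDATION_DELTA) <= cfg.satellite_tol
                and parent.score > n.score
            ):
                n.ox_satellite_of = parent.mass
                break
    return folded


# ---------------------------------------------------------------------------
# Stage 2: anchors
# ---------------------------------------------------------------------------

def anchor_primers(
    neutrals: list[Neutral], cfg: DecoderConfig
) -> dict[str, float]:
    """Match the declared primer masses; at least two anchors are required."""
    anchors: dict[str, float] = {}
    for k in range(4):
        primer = cfg.primers.primers[k]
        declared = primer.mass(cfg.registry)
        best, best_err = None, cfg.tol(declared)
        for n in neutrals:
            err = abs(n.mass - declared)
            if err <= best_err:
                best, best_err = n, err
        if best is not None:
            anchors[cfg.primers.lineage_label(k)] = best.mass
            best.orphan = False
    if len(anchors) < 2:
        raise DecodingError(
            f"no ladder origin: only {len(anchors)} of 4 primer anchors found"
        )
    return anchors


# ---------------------------------------------------------------------------
# Stage 3: ladder walk
# ---------------------------------------------------------------------------

def _offset_label(j: int) -> str:
    k = (4 - (j % 4)) % 4
    return "P" if k == 0 else f"P-{k}"


def _find_all(neutrals: list[Neutral], target: float, tol: float) -> list[Neutral]:
    return [n for n in neutrals if abs(n.mass - target) <= tol]


@dataclass
class _Node:
    neutral: Neutral | None  # None for the chain origin (the full primer P)
    base: str
    parent: "_Node | None"
    fwd: float  # best cumulative log-intensity from the origin
    mass: float
    bwd: float = 0.0  # best cumulative log-intensity of any continuation


def call_ladder(
    neutrals: list[Neutral],
    anchors: dict[str, float],
    cfg: DecoderConfig,
) -> SequenceRead:
    """Best-path walk of single-residue mass increments above the full primer.

    The chain base is the declared mass of P; rung p's expected mass adds one
    residue, plus the azide terminator delta once at the entry into the final
    (unreduced) cycle.  Candidate rungs at each position form a layered graph
    and the call sequence is the maximum log-intensity path through it, so a
    candidate is judged together with its continuation — consecutive rungs
    come from different primer-offset ladders, making chain continuation a
    cross-ladder consistency vote.  This resolves the G vs A+16 confound
    (an oxidation-satellite chain shadows its parent chain at the satellite
    intensity ratio and always loses the path competition) and demotes
    mismatch-extension products, which continue poorly.  A position whose
    best alternative call comes within ``ambiguity_ratio`` of the chosen
    path is re-called as ambiguous ("N") and flagged; a gap matching no
    residue truncates the read — the decoder never guesses.
    """
    import math

    residue_masses = cfg.registry.aeg_masses()
    azide_delta = -terminator_delta()  # azide is heavier than the free amine
    n_pos = 4 * cfg.max_cycles
    boundary = 4 * (cfg.max_cycles - 1) + 1 if cfg.final_cap == "azide" else None

    def targets(mass: float, p: int):
        cap_delta = azide_delta if p == boundary else 0.0
        for base, rmass in residue_masses.items():
            yield base, mass + rmass + cap_delta

    origin = _Node(None, "", None, 0.0, cfg.primers.primers[0].mass(cfg.registry))
    layers: list[list[_Node]] = [[origin]]
    for p in range(1, n_pos + 1):
        cur: dict[int, _Node] = {}
        for node in layers[p - 1]:
            for base, expected in targets(node.mass, p):
                for n in _find_all(neutrals, expected, cfg.tol(expected)):
                    sc = node.fwd + math.log(max(n.score, 1e-300))
                    key = id(n)
                    if key not in cur or sc > cur[key].fwd:
                        cur[key] = _Node(n, base, node, sc, n.mass)
        if not cur:
            break
        layers.append(list(cur.values()))

    reached = len(layers) - 1
    status = "ok" if reached == n_pos else (
        "no-extension" if reached == 0 else "truncated"
    )
    truncated_at = reached + 1 if status == "truncated" else None
    chirality = {"binds-D": "D", "binds-L": "L"}[cfg.primers.chirality_preference]
    if reached == 0:
        orphans = [n for n in neutrals if n.orphan and not n.is_ox_satellite]
        return SequenceRead([], chirality, dict(anchors), "no-extension", orphans)

    # backward pass: best continuation score of each node
    for p in range(reached - 1, 0, -1):
        nxt = {id(n.neutral): n for n in layers[p + 1]}
        for node in layers[p]:
            best = -math.inf
            for base, expected in targets(node.mass, p + 1):
                for n in _find_all(neutrals, expected, cfg.tol(expected)):
                    child = nxt.get(id(n))
                    if child is not None:
                        sc = math.log(max(n.score, 1e-300)) + child.bwd
                        best = max(best, sc)
            # a node whose chain dies before the deepest layer cannot carry
            # a full-length interpretation: -inf total removes it from the
            # ambiguity comparison
            node.bwd = best

    # chosen path: maximum forward score in the deepest layer
    tip = max(layers[reached], key=lambda n: n.fwd)
    path: list[_Node] = []
    node: _Node | None = tip
    while node is not None and node.neutral is not None:
        path.append(node)
        node = node.parent
    path.reverse()

    log_ratio = math.log(cfg.ambiguity_ratio)
    max_intensity = max((n.intensity for n in neutrals), default=0.0)
    calls: list[LadderCall] = []
    for p, node in enumerate(path, start=1):
        flags: tuple[str, ...] = ()
        base = node.base
        total = node.fwd + node.bwd
        alt_total = -math.inf
        alt_node = None
        for other in layers[p]:
            if other.base != base:
                t = other.fwd + other.bwd
                if t > alt_total:
                    alt_total, alt_node = t, other
        if alt_node is not None and total - alt_total < log_ratio:
            if abs(abs(alt_node.mass - node.mass) - OXIDATION_DELTA) <= cfg.satellite_tol:
                flags = ("ambiguous", "oxidation-confounded")
            else:
                flags = ("ambiguous",)
            if total - alt_total <= 0:
                # a genuinely tied alternative path: refuse to guess
                base = "N"
        rung = node.neutral
        assert rung is not None
        if rung.intensity < 0.001 * max_intensity:
            flags = flags + ("low-intensity",)
        prev_mass = node.parent.mass if node.parent is not None else origin.mass
        expected = next(e for b, e in targets(prev_mass, p) if b == node.base)
        calls.append(
            LadderCall(
                position=p,
                base=base,
                observed_increment=rung.mass - prev_mass,
                increment_error=(rung.mass - expected) * 1000.0,
                supporting_offsets=(_offset_label(p - 1), _offset_label(p)),
                flags=flags,
            )
        )
        rung.orphan = False
    orphans = [n for n in neutrals if n.orphan and not n.is_ox_satellite]
    return SequenceRead(calls, chirality, dict(anchors), status, orphans,
                        truncated_at)


def decode_spectrum(peaks: PeakList, cfg: DecoderConfig) -> SequenceRead:
    """collapse_to_neutral -> anchor_primers -> call_ladder."""
    neutrals = collapse_to_neutral(peaks, cfg)
    anchors = anchor_primers(neutrals, cfg)
    return call_ladder(neutrals, anchors, cfg)


def format_report(read: SequenceRead) -> str:
    """Human-readable per-call evidence table."""
    lines = [
        f"anchors found : {len(read.anchors)} "
        f"({', '.join(sorted(read.anchors))})",
        f"template chirality tag : {read.chirality}",
        f"status : {read.status}",
    ]
    if read.truncated_at is not None:
        lines.append(f"missing rung at position {read.truncated_at}; read truncated")
    if not read.calls:
        lines.append("no extension products detected (read is empty)")
        return "\n".join(lines)
    lines.append("pos\tbase\tincrement_Da\terror_mDa\toffsets\tflags")
    for c in read.calls:
        lines.append(
            f"{c.position}\t{c.base}\t{c.observed_increment:.4f}\t"
            f"{c.increment_error:+.1f}\t{'+'.join(c.supporting_offsets)}\t"
            f"{','.join(c.flags) if c.flags else '-'}"
        )
    lines.append(f"PNA read (C->N) : {read.pna_sequence()}")
    lines.append(f"template bases  : {read.template_sequence()}")
    return "\n".join(lines)


def write_read_tsv(read: SequenceRead, destination) -> None:
    """Machine-readable read: one row per call."""
    from pathlib import Path

    lines = ["position\tbase\ttemplate_base\tincrement_Da\terror_mDa\toffsets\tflags"]
    for c in read.calls:
        lines.append(
            f"{c.position}\t{c.base}\t{WC_COMPLEMENT.get(c.base, 'N')}\t"
            f"{c.observed_increment:.5f}\t{c.increment_error:.2f}\t"
            f"{'+'.join(c.supporting_offsets)}\t"
            f"{','.join(c.flags) if c.flags else '-'}"
        )
    Path(destination).write_text("\n".join(lines) + "\n")
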