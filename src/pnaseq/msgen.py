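"""Synthetic centroided MALDI peak lists from species abundances.

Each species contributes one isotope-envelope cluster per adduct (M+H, M+Na,
M+K) and, for biotinylated species, a +16 Da oxidation satellite cluster.
Intensities follow abundance x length-dependent ionization decay x adduct
fraction x envelope abundance, with optional multiplicative lognormal noise
(MALDI shot-to-shot variation is relative).  Output is centroid-only; the
decoder consumes centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import (
    OXIDATION_DELTA,
    ResidueRegistry,
    DEFAULT_REGISTRY,
    adduct_mz,
    isotope_envelope,
    monoisotopic_mass,
)
from .errors import ConfigurationError, DomainError, PeakListParseError
from .simulate import SpeciesAbundance

__all__ = ["SpectrumConfig", "PeakList", "species_to_peaks",
           "write_peaklist", "read_peaklist"]

#: envelope peaks below this fraction of the species' strongest isotope are
#: not emitted (keeps clusters compact; abundances remain unnormalized).
_ENVELOPE_FLOOR = 1e-4
_MERGE_EPS = 0.002  # Da; centroids closer than this are one peak (linear
                    # MALDI cannot resolve low-mDa splits at 3-6 kDa)


@dataclass(frozen=True)
class SpectrumConfig:
    """Knobs of the synthetic MALDI instrument.

    ``adduct_fractions`` must sum to 1 (protonated species dominate in
    positive-mode MALDI of PNA); ``ionization_decay`` multiplies intensity
    once per residue (longer species ionize less efficiently);
    ``oxidation_fraction`` is the fraction of biotinylated species carrying
    +O; ``noise_sd`` is the sigma of multiplicative lognormal intensity
    noise; ``fwhm`` is informational (profile rendering is out of scope).
    """

    adduct_fractions: dict[str, float] = field(
        default_factory=lambda: {"M+H": 0.8, "M+Na": 0.15, "M+K": 0.05}
    )
    oxidation_fraction: float = 0.05
    ionization_decay: float = 0.9
    fwhm: float = 0.5
    noise_sd: float = 0.0
    min_rel_intensity: float = 0.001
    mz_range: tuple[float, float] | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if not self.adduct_fractions:
            raise ConfigurationError("adduct_fractions must be non-empty")
        for a, f in self.adduct_fractions.items():
            if not (0 <= f <= 1):
                raise ConfigurationError(f"adduct fraction {a}={f} outside [0, 1]")
        if abs(sum(self.adduct_fractions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("adduct fractions must sum to 1")
        if not (0 <= self.oxidation_fraction <= 1):
            raise ConfigurationError("oxidation_fraction must be in [0, 1]")
        if not (0 < self.ionization_decay <= 1):
            raise ConfigurationError("ionization_decay must be in (0, 1]")
        if self.noise_sd < 0 or self.min_rel_intensity < 0:
            raise ConfigurationError("noise_sd / min_rel_intensity must be >= 0")


@dataclass
class PeakList:
    """Centroided (m/z, intensity) pairs with strictly increasing m/z."""

    peaks: list[tuple[float, float]]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for i, (mz, inten) in enumerate(self.peaks):
            if inten < 0:
                raise DomainError(f"negative intensity at peak {i}")
            if i and mz <= self.peaks[i - 1][0]:
                raise DomainError("m/z values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


def species_to_peaks(
    abundances: SpeciesAbundance,
    cfg: SpectrumConfig | None = None,
    registry: ResidueRegistry | None = None,
) -> PeakList:
    """Render species abundances into a merged, sorted centroid peak list."""
    cfg = cfg or SpectrumConfig()
    registry = registry or DEFAULT_REGISTRY
    if not abundances.entries:
        raise DomainError("species abundances are empty")
    rng = np.random.default_rng(cfg.rng_seed)
    raw: list[tuple[float, float]] = []
    for species, abundance in sorted(
        abundances.entries.items(),
        key=lambda e: (e[0].label, len(e[0].sequence), e[0].termini.n_terminus),
    ):
        if abundance <= 0:
            continue
        comp = species.composition(registry)
        envelope = isotope_envelope(comp, max_peaks=40)
        env_max = max(ab for _, ab in envelope)
        envelope = [(off, ab) for off, ab in envelope
                    if ab >= _ENVELOPE_FLOOR * env_max]
        mass = monoisotopic_mass(comp)
        base_intensity = abundance * cfg.ionization_decay ** len(species)
        biotinylated = species.termini.c_terminus == "linker-biotin"
        ox_states = [(0, 1.0)]
        if biotinylated and cfg.oxidation_fraction > 0:
            ox_states = [
                (0, 1.0 - cfg.oxidation_fraction),
                (1, cfg.oxidation_fraction),
            ]
        for n_ox, ox_frac in ox_states:
            neutral = mass + n_ox * OXIDATION_DELTA
            for adduct, adduct_frac in cfg.adduct_fractions.items():
                if adduct_frac <= 0:
                    continue
                cluster_mz = adduct_mz(neutral, adduct)
                for offset, env_ab in envelope:
                    inten = base_intensity * ox_frac * adduct_frac * env_ab
                    if cfg.noise_sd > 0:
                        inten *= float(np.exp(rng.normal(0.0, cfg.noise_sd)))
                    raw.append((cluster_mz + offset, inten))
    raw.sort()
    merged: list[tuple[float, float]] = []
    for mz, inten in raw:
        if merged and mz - merged[-1][0] < _MERGE_EPS:
            merged[-1] = (merged[-1][0], merged[-1][1] + inten)
        else:
            merged.append((mz, inten))
    if merged:
        floor = cfg.min_rel_intensity * max(i for _, i in merged)
        merged = [(mz, i) for mz, i in merged if i >= floor]
    if cfg.mz_range is not None:
        lo, hi = cfg.mz_range
        merged = [(mz, i) for mz, i in merged if lo <= mz <= hi]
    return PeakList(merged, metadata={"generator": "pnaseq.msgen",
                                      "noise_sd": str(cfg.noise_sd),
                                      "seed": str(cfg.rng_seed)})


def write_peaklist(peaks: PeakList, destination) -> None:
    """TSV with ``#``-prefixed header lines; m/z fixed to 5 decimals."""
    lines = [f"# {k}: {v}" for k, v in sorted(peaks.metadata.items())]
    lines.append("# mz\tintensity")
    for mz, inten in peaks.peaks:
        lines.append(f"{mz:.5f}\t{inten:.6g}")
    Path(destination).write_text("\n".join(lines) + "\n")


def read_peaklist(source) -> PeakList:
    """Parse the msgen TSV dialect; malformed rows raise with a line number."""
    metadata: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    for lineno, line in enumerate(Path(source).read_text().splitlines(), start=1):
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body and "\t" not in body:
                k, v = body.split(":", 1)
                metadata[k.strip()] = v.strip()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise PeakListParseError(
                f"expected 2 tab-separated fields, got {len(parts)}", lineno
            )
        try:
            mz, inten = float(parts[0]), float(parts[1])
        except ValueError:
            raise PeakListParseError(f"non-numeric field in {line!r}", lineno)
        if peaks and mz <= peaks[-1][0]:
            raise PeakListParseError(
                f"m/z {mz} not greater than previous {peaks[-1][0]}", lineno
            )
        if inten < 0:
            raise PeakListParseError(f"negative intensity {inten}", lineno)
        peaks.append((mz, inten))
    return PeakList(peaks, metadata)
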