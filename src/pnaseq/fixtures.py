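"""Seeded fixture generation and the end-to-end round-trip workflow.

Everything here is synthetic: templates are drawn from a seeded RNG (or
picked from a small set of edge cases — G-rich for the +16 oxidation
confound, AT-only for the weak-pairing regime flagged as under-tested),
spectra are produced by the simulator + spectrum generator, and the
round-trip compares the decoded read against the template it came from.
No external data is needed at any stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .decode import DecoderConfig, SequenceRead, decode_spectrum, write_read_tsv
from .errors import DecodingError, DomainError
from .library import ReagentMix, build_paired_sublibrary, full_repertoire_mix
from .msgen import SpectrumConfig, species_to_peaks, write_peaklist
from .simulate import (
    KineticsConfig,
    PrimerSet,
    Template,
    design_primer_set,
    pm_cycle_mixes,
    run_protocol,
)

__all__ = ["RoundTripResult", "random_template", "build_mixes",
           "run_roundtrip", "generate_fixtures"]

_POLYMER_CHOICES = [("DNA", "D"), ("DNA", "L"), ("LNA", "D"), ("PNA", "achiral")]


def random_template(
    rng: np.random.Generator,
    length: int = 22,
    polymer: str = "DNA",
    chirality: str = "D",
    read_length: int = 8,
) -> Template:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Template(seq, polymer, chirality, read_length=read_length)


def build_mixes(template: Template, cycles: int, kind: str = "pm",
                concentration_um: float = 3.0) -> list[ReagentMix]:
    """Per-cycle reagent mixes: minimal perfect-match, 64-member paired, or
    the full 256-member repertoire."""
    if kind in ("pm", "pm+cm", "pm+cm+helper"):
        base = pm_cycle_mixes(template, cycles, concentration_um)
        if kind == "pm":
            return base
        from .library import FourMer, pna_complement

        out = []
        for c, mix in enumerate(base):
            seqs = set(mix.sequences())
            if kind == "pm+cm+helper" and c + 1 < cycles:
                # downstream-adjacent 4-mers from the next cycle stabilize
                # the reactive complex and raise fidelity
                seqs |= base[c + 1].sequences()
            seqs |= {pna_complement(s) for s in seqs}
            out.append(ReagentMix(
                [(FourMer(s), concentration_um) for s in sorted(seqs)]
            ))
        return out
    if kind == "paired64":
        mix = build_paired_sublibrary(
            ["AxxC", "GxxT", "CxxA", "TxxG"], concentration_um=2.0
        )
        return [mix] * cycles
    if kind == "full256":
        return [full_repertoire_mix(total_um=128.0)] * cycles
    raise DomainError(f"unknown mix kind {kind!r}")


@dataclass
class RoundTripResult:
    template: Template
    read: SequenceRead
    expected: str  # template bases over the read window, reading order
    called: str    # decoded template bases
    accuracy: float
    n_expected: int
    n_correct: int


def run_roundtrip(
    seed: int = 0,
    cycles: int = 2,
    noise_sd: float = 0.0,
    dead_fraction: float = 0.3,
    oxidation_fraction: float = 0.05,
    polymer: str = "DNA",
    chirality: str = "D",
    mix: str = "pm+cm+helper",
    template: Template | None = None,
    primers: PrimerSet | None = None,
    primer_chirality: str | None = None,
    kinetics: KineticsConfig | None = None,
    tolerance: float = 0.25,
) -> RoundTripResult:
    """simulate -> spectrum -> decode on one seeded template; score per-base.

    ``primer_chirality`` forces a primer set of the wrong handedness to
    exercise the chirality gate (the read should then be empty).
    """
    rng = np.random.default_rng(seed)
    if template is None:
        template = random_template(
            rng, 14 + 4 * cycles, polymer, chirality, read_length=4 * cycles
        )
    if primers is None:
        primers = design_primer_set(template, dead_fraction=dead_fraction)
    if primer_chirality is not None:
        primers = PrimerSet(
            primers.primers, primer_chirality, primers.loading,
            primers.dead_fraction,
        )
    kinetics = kinetics or KineticsConfig(rng_seed=seed)
    mixes = build_mixes(template, cycles, mix)
    species = run_protocol(template, primers, mixes, cycles, kinetics)
    spec_cfg = SpectrumConfig(
        oxidation_fraction=oxidation_fraction,
        noise_sd=noise_sd,
        rng_seed=seed,
    )
    peaks = species_to_peaks(species, spec_cfg)
    dec_cfg = DecoderConfig(primers=primers, tolerance=tolerance,
                            max_cycles=cycles)
    try:
        read = decode_spectrum(peaks, dec_cfg)
    except DecodingError:
        read = SequenceRead([], "D", {}, "no-extension")
    expected = template.read_bases()[: 4 * cycles]
    called = read.template_sequence()
    n_correct = sum(
        1 for e, c in zip(expected, called) if e == c
    )
    accuracy = n_correct / len(expected) if expected else 0.0
    return RoundTripResult(
        template, read, expected, called, accuracy, len(expected), n_correct
    )


# ---------------------------------------------------------------------------
# Fixture directories
# ---------------------------------------------------------------------------

def generate_fixtures(outdir, n: int = 4, seed: int = 0) -> list[dict]:
    """Write a reproducible fixture directory: templates, configs, spectra.

    Includes one random template per polymer type / chirality combination
    plus two edge cases: a G-rich template (exercises the G vs A+16
    oxidation confound) and an AT-only template (weak-pairing,
    reduced-fidelity regime).  Same seed => byte-identical output.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries: list[dict] = []
    for i in range(n):
        polymer, chirality = _POLYMER_CHOICES[i % len(_POLYMER_CHOICES)]
        tpl = random_template(rng, 22, polymer, chirality)
        entries.append({
            "name": f"random_{i}_{polymer}_{chirality}",
            "template": tpl, "note": "random",
        })
    # read window is the 8 bases upstream of the 14-base capture site,
    # i.e. the first 8 characters of a 22-mer: make those G-rich
    g_rich = "CGGAGGAC" + "".join(rng.choice(list("ACGT"), size=14))
    entries.append({
        "name": "g_rich", "template": Template(g_rich, "DNA", "D"),
        "note": "G-rich read window; exercises the G vs A+16 confound",
    })
    at_only = "".join(rng.choice(list("AT"), size=22))
    entries.append({
        "name": "at_only", "template": Template(at_only, "DNA", "D"),
        "note": "reduced-fidelity regime (AT-only, weak pairing)",
    })

    rows = ["name\tsequence\tpolymer\tchirality\tnote"]
    (out / "spectra").mkdir(exist_ok=True)
    for j, entry in enumerate(entries):
        tpl: Template = entry["template"]
        rows.append(
            f"{entry['name']}\t{tpl.sequence}\t{tpl.polymer}\t"
            f"{tpl.chirality}\t{entry['note']}"
        )
        sub_seed = (seed * 1009 + j) % (2**31)
        primers = design_primer_set(tpl)
        mixes = build_mixes(tpl, 2, "pm")
        species = run_protocol(tpl, primers, mixes, 2,
                               KineticsConfig(rng_seed=sub_seed))
        peaks = species_to_peaks(
            species, SpectrumConfig(noise_sd=0.15, rng_seed=sub_seed)
        )
        write_peaklist(peaks, out / "spectra" / f"{entry['name']}.tsv")
    (out / "templates.tsv").write_text("\n".join(rows) + "\n")
    (out / "README.txt").write_text(
        "Synthetic fixtures generated by pnaseq (seed-deterministic).\n"
        "templates.tsv lists each template; spectra/ holds the matching\n"
        "simulated MALDI peak lists (2 cycles, per-cycle perfect-match\n"
        "mixes, default noise). The at_only fixture is flagged as the\n"
        "reduced-fidelity regime.\n"
    )
    return entries


def decode_to_files(peaks, dec_cfg: DecoderConfig, read_path) -> SequenceRead:
    read = decode_spectrum(peaks, dec_cfg)
    write_read_tsv(read, read_path)
    return read
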