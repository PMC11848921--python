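"""Kinetic simulator: capture gating, conversion kinetics, competition
weights, cycle structure and population bookkeeping."""

import numpy as np
import pytest

from pnaseq.chem import DEFAULT_REGISTRY
from pnaseq.errors import DomainError
from pnaseq.fixtures import build_mixes, random_template
from pnaseq.library import FourMer, ReagentMix, pna_complement
from pnaseq.simulate import (
    KineticsConfig,
    PrimerSet,
    SpeciesAbundance,
    Template,
    check_capture,
    competition_weights,
    design_primer_set,
    extension_conversion,
    run_protocol,
)

# A fixed 22-nt template whose per-cycle perfect-match 4-mers do not
# cross-react (no window is within one terminal mismatch of another).
CLEAN = Template("TGTACGGAACATGTGGCCAATC", "DNA", "D")


def pm_mm_mix(site_pm, mm, with_cms=False, conc=3.0):
    seqs = [site_pm, mm]
    if with_cms:
        seqs += [pna_complement(site_pm), pna_complement(mm)]
    return ReagentMix([(FourMer(s), conc) for s in seqs])


# ---------------------------------------------------------------------------
# Capture
# ---------------------------------------------------------------------------

def test_capture_requires_matching_chirality():
    l_dna = Template("TGTACGGAACATGTGGCCAATC", "DNA", "L")
    binds_l = design_primer_set(l_dna)
    assert binds_l.chirality_preference == "binds-L"
    assert check_capture(l_dna, binds_l).captured
    binds_d = PrimerSet(binds_l.primers, "binds-D",
                        binds_l.loading, binds_l.dead_fraction)
    assert not check_capture(l_dna, binds_d).captured


def test_achiral_pna_template_captured_by_either_primer_set():
    pna = Template("TGTACGGAACATGTGGCCAATC", "PNA", "achiral")
    pr = design_primer_set(pna)
    for pref in ("binds-D", "binds-L"):
        ps = PrimerSet(pr.primers, pref, pr.loading, pr.dead_fraction)
        assert check_capture(pna, ps).captured


def test_capture_requires_complementary_primer():
    other = random_template(np.random.default_rng(99), 22)
    wrong_primers = design_primer_set(other)
    res = check_capture(CLEAN, wrong_primers)
    assert not res.captured
    assert "complementary" in res.reason


def test_template_validation():
    with pytest.raises(DomainError):
        Template("ACGT" * 6, "PNA", "D")  # PNA must be achiral
    with pytest.raises(DomainError):
        Template("ACGT" * 6, "DNA", "achiral")
    with pytest.raises(DomainError):
        Template("ACGT", "DNA", "D")  # too short


def test_primer_set_validation(template):
    ps = design_primer_set(template)
    full = ps.primers[0]
    bad = dict(ps.primers)
    bad[1] = full  # not a deletion
    with pytest.raises(DomainError):
        PrimerSet(bad, "binds-D")


# ---------------------------------------------------------------------------
# Extension kinetics
# ---------------------------------------------------------------------------

def test_extension_conversion_closed_form():
    assert extension_conversion(0.0, 2.0) == 0.0
    assert extension_conversion(2.0, 2.0) == pytest.approx(0.5)
    assert extension_conversion(4.0, 2.0) == pytest.approx(0.75)
    with pytest.raises(DomainError):
        extension_conversion(-1.0, 2.0)
    with pytest.raises(DomainError):
        extension_conversion(1.0, 0.0)


def test_hydrolysis_competes_with_extension():
    free = extension_conversion(4.0, 2.0)
    with_hyd = extension_conversion(4.0, 2.0, 300.0)
    assert with_hyd < free
    assert with_hyd == pytest.approx(free, rel=0.01)  # slow hydrolysis, small loss
    # when hydrolysis is as fast as extension the pool runs out and the
    # attainable conversion saturates at 1 - exp(-ke/kh)
    import math
    assert extension_conversion(1e6, 2.0, 2.0) == pytest.approx(1 - math.exp(-1))


def test_conversion_monotone_in_time():
    vals = [extension_conversion(t, 2.0, 300.0) for t in (0, 1, 2, 4, 8, 30)]
    assert vals == sorted(vals)


# ---------------------------------------------------------------------------
# Competition weights
# ---------------------------------------------------------------------------

SITE = "TTGG"           # template window, 5'->3'
PM = pna_complement(SITE)  # = "CCAA"


def weights_by_seq(site, mix, cfg, downstream=None):
    return {fm.sequence: w
            for fm, w in competition_weights(site, mix, cfg, downstream).items()}


def test_perfect_match_weight():
    cfg = KineticsConfig()
    w = weights_by_seq(SITE, pm_mm_mix(PM, "CCAG"), cfg)
    assert w[PM] == pytest.approx(3.0)  # weight 1 x 3 uM


def test_terminal_mismatch_equal_weight_without_cm():
    cfg = KineticsConfig()
    mm = PM[:3] + "G"  # ligation-distal (N-ter) mismatch
    w = weights_by_seq(SITE, pm_mm_mix(PM, mm), cfg)
    assert w[mm] == pytest.approx(w[PM])  # the 1:1 worst case


def test_cm_sequestration_suppresses_terminal_mismatch():
    cfg = KineticsConfig()
    mm = PM[:3] + "G"
    w = weights_by_seq(SITE, pm_mm_mix(PM, mm, with_cms=True), cfg)
    assert w[PM] / w[mm] == pytest.approx(4.0)


def test_internal_multiple_and_ligation_site_mismatches_do_not_incorporate():
    cfg = KineticsConfig()
    internal = PM[0] + ("G" if PM[1] != "G" else "A") + PM[2:]
    double = "GG" + PM[2:] if not PM.startswith("GG") else "TT" + PM[2:]
    ligation = ("G" if PM[0] != "G" else "A") + PM[1:]
    w = weights_by_seq(SITE, pm_mm_mix(PM, internal), cfg)
    assert internal not in w
    w = weights_by_seq(SITE, pm_mm_mix(PM, double), cfg)
    assert double not in w
    w = weights_by_seq(SITE, pm_mm_mix(PM, ligation), cfg)
    assert ligation not in w


def test_helper_boosts_perfect_match_only():
    cfg = KineticsConfig()
    mm = PM[:3] + "G"
    downstream = "ACGT"
    mix = ReagentMix([
        (FourMer(PM), 3.0), (FourMer(mm), 3.0),
        (FourMer(pna_complement(downstream)), 3.0),
    ])
    w = weights_by_seq(SITE, mix, cfg, downstream=downstream)
    assert w[PM] / w[mm] == pytest.approx(cfg.helper_factor)


def test_weights_scale_with_concentration():
    cfg = KineticsConfig()
    mix = ReagentMix([(FourMer(PM), 1.0)])
    mix2 = ReagentMix([(FourMer(PM), 2.0)])
    w1 = weights_by_seq(SITE, mix, cfg)
    w2 = weights_by_seq(SITE, mix2, cfg)
    assert w2[PM] == pytest.approx(2 * w1[PM])


def test_pm_mm_ratio_monotone_in_sequestration():
    mm = PM[:3] + "G"
    ratios = []
    for f in (1.0, 0.5, 0.25, 0.1):
        cfg = KineticsConfig(cm_sequestration_factor=f)
        w = weights_by_seq(SITE, pm_mm_mix(PM, mm, with_cms=True), cfg)
        ratios.append(w[PM] / w[mm])
    assert ratios == sorted(ratios)


# ---------------------------------------------------------------------------
# Cycles and protocols
# ---------------------------------------------------------------------------

def test_zero_reaction_time_leaves_state_unchanged():
    primers = design_primer_set(CLEAN)
    mixes = build_mixes(CLEAN, 1, "pm")
    out = run_protocol(CLEAN, primers, mixes, 1,
                       KineticsConfig(reaction_time=0.0))
    assert len(out.entries) == 4  # primers only
    assert all(len(sp.sequence) <= 14 for sp in out.entries)


def test_two_pm_cycles_extend_each_primer_by_eight():
    primers = design_primer_set(CLEAN)
    mixes = build_mixes(CLEAN, 2, "pm")
    out = run_protocol(CLEAN, primers, mixes, 2, KineticsConfig())
    assert len(out.entries) == 12  # 4 anchors + 4 cycle-1 + 4 cycle-2
    for k in range(4):
        label = primers.lineage_label(k)
        lengths = sorted(len(sp.sequence) for sp in out.entries
                         if sp.label == label)
        base = 14 - k
        assert lengths == [base, base + 4, base + 8]
    # cycle-1 products were reduced, final-cycle products keep the azide
    for sp in out.entries:
        expected = "azide" if len(sp.sequence) >= 19 else "free-amine"
        assert sp.termini.n_terminus == expected


def test_dead_fraction_one_returns_primers_only():
    primers = design_primer_set(CLEAN, dead_fraction=0.999999)
    primers = PrimerSet(primers.primers, primers.chirality_preference,
                        1.0, 0.9999999)
    mixes = build_mixes(CLEAN, 2, "pm")
    out = run_protocol(CLEAN, primers, mixes, 2, KineticsConfig())
    meaningful = {sp for sp, ab in out.entries.items() if ab > 1e-5}
    assert all(len(sp.sequence) <= 14 for sp in meaningful)


def test_wrong_chirality_returns_primers_only():
    l_dna = Template(CLEAN.sequence, "DNA", "L")
    primers = design_primer_set(CLEAN)  # binds-D
    mixes = build_mixes(l_dna, 2, "pm")
    out = run_protocol(l_dna, primers, mixes, 2, KineticsConfig())
    assert len(out.entries) == 4
    assert all(ab == pytest.approx(1.0) for ab in out.entries.values())


@pytest.mark.parametrize("mix_kind", ["pm", "pm+cm+helper", "full256"])
def test_lineage_abundance_is_conserved(mix_kind):
    tpl = random_template(np.random.default_rng(3), 22)
    primers = design_primer_set(tpl)
    mixes = build_mixes(tpl, 2, mix_kind)
    out = run_protocol(tpl, primers, mixes, 2, KineticsConfig())
    for label, total in out.lineage_totals().items():
        assert total == pytest.approx(1.0, abs=1e-9), label


def test_consecutive_ladder_products_differ_by_one_residue():
    primers = design_primer_set(CLEAN)
    mixes = build_mixes(CLEAN, 2, "pm")
    out = run_protocol(CLEAN, primers, mixes, 2, KineticsConfig())
    masses = sorted(sp.mass() for sp in out.entries)
    residues = set(DEFAULT_REGISTRY.aeg_masses().values())
    azide = 25.990498
    for lo, hi in zip(masses, masses[1:]):
        gap = hi - lo
        ok = any(abs(gap - r) < 1e-6 or abs(gap - r - azide) < 1e-6
                 for r in residues)
        assert ok, f"gap {gap:.4f} is not a single-residue increment"


def test_stochastic_mode_matches_expectation_within_3_se():
    tpl = random_template(np.random.default_rng(5), 22)
    primers = design_primer_set(tpl)
    mixes = build_mixes(tpl, 2, "pm+cm+helper")
    n = 100_000
    exp = run_protocol(tpl, primers, mixes, 2, KineticsConfig(rng_seed=5))
    sto = run_protocol(tpl, primers, mixes, 2, KineticsConfig(rng_seed=5),
                       mode="stochastic", n_molecules=n)
    for sp, p in exp.entries.items():
        if p < 1e-4:
            continue
        se = np.sqrt(p * (1 - min(p, 0.999)) / n)
        assert abs(sto.entries.get(sp, 0.0) - p) <= 3 * se + 1e-9, sp.label


def test_species_abundance_tsv_round_trip(tmp_path):
    primers = design_primer_set(CLEAN)
    mixes = build_mixes(CLEAN, 2, "pm")
    out = run_protocol(CLEAN, primers, mixes, 2, KineticsConfig())
    path = tmp_path / "species.tsv"
    out.write_tsv(path)
    back = SpeciesAbundance.read_tsv(path)
    assert len(back.entries) == len(out.entries)
    assert back.total() == pytest.approx(out.total())


def test_design_primer_set_geometry():
    ps = design_primer_set(CLEAN, serine_positions=(0, 5))
    full = ps.primers[0]
    assert len(full.sequence) == 14
    assert full.sequence[0].islower() and full.sequence[5].islower()
    for k in (1, 2, 3):
        assert ps.primers[k].sequence == full.sequence[:14 - k]
    assert check_capture(CLEAN, ps).captured
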