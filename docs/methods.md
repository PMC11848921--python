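# Methods

## The chemistry being modeled

A template strand is captured by four biotinylated 14-mer PNA primers (the
full primer P and its N-terminal deletions P−1, P−2, P−3) immobilized on
streptavidin beads. Each cycle, 4-mer PNA probes — C-terminally activated
as s-NHS esters, N-terminally azide-capped — hybridize adjacent to a
primer's free N-terminal amine and ligate; the azide blocks further
addition until a phosphine reduction between cycles restores the amine
(reversible termination). Capture is treated as binary: it succeeds iff
the primer set's chirality preference matches the template (achiral PNA
templates accept either handedness) and the full primer is
antiparallel-complementary to the capture site; primer:template melting is
assumed strong enough that no partial-occupancy model is needed.

Orientation conventions, fixed package-wide: PNA sequences are written
C→N; a PNA written C→N pairs a template read 5′→3′ in antiparallel
register, so the complement of a 4-mer is its reverse WC complement
(`AxxC` ↔ `GxxT`). Extension proceeds from the primer's N-terminus toward
the template's 5′ end; the read window is reported in reading order
(template 3′→5′).

## Mass arithmetic

All masses derive from integer elemental compositions and a pinned isotope
table (`elements.py`, versioned). The four aeg-PNA residue compositions are
built from the standard residue structure — backbone fragment C4H7N2O,
acetyl linker C2H2O, plus the nucleobase radical — giving C 251.1018,
T 266.1015, A 275.1131, G 291.1080 Da. They are stored in a
user-overridable YAML table together with terminus deltas (free amine +H;
azide +N2−H; Fmoc; acetyl; C-terminal amide/free acid) and the biotin
linker. The shipped linker composition (C16H28N5O3S, a biotinylated lysine
amide) is a synthetic stand-in for the real construct: only its mass
enters, and it cancels in every ladder difference. Serine-modified
(underlined) residues are modeled as aeg + CH2O and written as lowercase
tokens; the exact substitution position is mass-silent and not modeled.

Isotope envelopes are aggregated distributions: isotopologues grouped by
nucleon-number offset, computed by per-element polynomial convolution with
binary exponentiation, pruned at 1e-15, and reported as
(abundance-weighted centroid offset, abundance). Tests verify them against
an exhaustive per-atom enumeration oracle at 1e-9 on molecules of ≤ 10
atoms. All ions are singly charged (linear MALDI of 3–6 kDa species);
adducts are M+H, M+Na (+21.9819 from M+H), M+K (+37.9559).

## Kinetics and fidelity calibration

Extension of a strand is pseudo-first-order. Each reagent candidate at the
strand's frontier contributes a parallel channel whose rate is its
fidelity weight × concentration; the total determines the conversion
1 − 2^(−t·s/t½) with s = total weight / (one perfect match at the 3 μM
reference concentration), so a site served only by weak candidates extends
slowly, not merely differently. Ester hydrolysis (t½ > 250 min, vs
t½ ≈ 2 min extension for s-NHS; a 180 min preset stands in for the slow
p-nitrophenyl esters) competes by depleting the ester pool, capping the
attainable conversion at 1 − exp(−ke/kh). Incorporation splits among
candidates in proportion to their weights.

The fidelity weights are calibrated directly on observed product ratios of
pairwise competition experiments rather than fitted equilibria (K_D and
k_off are carried in the config for a future explicit-equilibrium mode):

- perfect match: weight 1; × helper_factor (2.0) when the next downstream
  4-mer is present in the mix, since downstream hybridization stabilizes
  the reactive complex and raises both rate and fidelity;
- single mismatch at the ligation-distal terminus (the 4-mer's N-ter):
  weight 1.0 — the 1:1 worst case — suppressed ×0.25 when that 4-mer's own
  complement is present (complement sequestration, giving the 4:1 ratio);
- single mismatch at the ligation site itself (the C-ter): weight 0 by
  default, a deliberate asymmetry: a mismatch at the reacting terminus
  disrupts the stacking that drives amide formation, whereas the distal
  terminus can accommodate one;
- internal or multiple mismatches, and candidates hybridizing with a 1–2 nt
  gap: weight 0 (config-extensible).
- a strand whose last addition carried a mismatch extends 6× less in the
  next cycle; the penalty divides the extension *extent*, because the
  calibrating observation is a ratio of extension, and a rate-constant
  divisor of 6 would predict only 3.6:1 at 4 min.

Expectation mode (deterministic population fractions) is the default,
since MALDI intensities are population averages; a seeded per-molecule
stochastic mode (binomial/multinomial draws) agrees with it within three
standard errors at 10⁵ molecules per primer, which the suite asserts.
Lineage totals (unreacted + extended + mismatch-extended per primer) are
conserved exactly across cycles.

The default protocol for round-trip studies supplies, per cycle, each
lineage's perfect-match 4-mer plus its complement plus the next cycle's
4-mers as downstream helpers ("pm+cm+helper"). This mirrors the practice
of sequencing with pure 4-mers accompanied by their complements: without
complements, a cross-reactive template window (one terminal mismatch away
from another window's 4-mer) yields genuinely ambiguous 1:1 products —
faithfully reproduced, but not a useful default. Minimal per-cycle
perfect-match mixes (`pm`), the 64-member paired library (`paired64`) and
the full 256-member repertoire (`full256`, 2 μM per member) are also
available.

## Spectrum generation

Each species contributes one isotope-envelope cluster per adduct, plus a
+15.9949 Da oxidation-satellite cluster when biotinylated
(oxidation_fraction, default 0.05). Intensity = abundance ×
ionization_decay^length (default 0.9/residue — longer species ionize less
efficiently) × adduct fraction (default H 0.8 / Na 0.15 / K 0.05) ×
envelope abundance, with optional multiplicative lognormal noise (seeded;
MALDI shot-to-shot variation is relative). Peaks below 0.1% of the base
peak are dropped; centroids closer than 2 mDa are merged, since linear
MALDI cannot resolve them. Output is centroid-only TSV; peak positions
never depend on intensities, and with zero noise the output is
seed-independent.

## Decoding

1. **Collapse.** Peaks are grouped into isotope chains using a tight window
   (1.0020 ± 0.004 Da) around the measured aggregated-envelope spacing of
   PNA-sized CHNOS ions; the tightness matters because residue-substitution
   products can sit ~0.995 Da apart and must not be absorbed as isotopes.
   The lowest-mass chain member is taken as monoisotopic (never the most
   intense). Na/K satellites are folded into their protonated parents, with
   the constraint that a satellite must be weaker than its parent — the
   azide−amine delta (25.9905) exceeds the Na offset (21.9819) by almost
   exactly four isotope spacings, an intrinsic near-degeneracy that would
   otherwise let small clusters swallow rungs. Each neutral keeps two
   intensities: the folded total (reported) and its own protonated-cluster
   sum (used for ranking, immune to folding contamination). +15.9949
   satellites are retained and annotated when a stronger parent exists.
2. **Anchoring.** The four declared primer masses are matched within
   tolerance (default 0.25 Da, or ppm; validated to be below half the
   minimum residue gap). At least two anchors are required; calibration
   drift beyond tolerance is a hard "no ladder origin" failure, not
   something the decoder corrects.
3. **Ladder walk.** Candidate rungs above the full primer's declared mass
   form a layered graph: at position p, each residue mass (plus the azide
   terminator delta once, on entering the final unreduced cycle) is sought
   within tolerance. The read is the maximum log-intensity path, so every
   call is judged together with its continuation; since consecutive rungs
   come from different primer-offset ladders, chain continuation is a
   cross-ladder consistency vote. This resolves the G vs A+16 confound (a
   satellite chain shadows its parent chain at the satellite ratio and
   loses the path competition) and demotes mismatch products, which extend
   poorly after incorporation. A position whose best alternative lies
   within a factor 2 of the chosen path is flagged `ambiguous`
   (`oxidation-confounded` when the rivals differ by +O); an exact tie is
   called `N`; a gap matching no residue truncates the read. The decoder
   never emits a call without a supporting increment.

Unassigned neutrals are reported as orphans — in full-repertoire runs these
are the minority mismatch rungs.

## What the synthetic data does and does not show

The generator reproduces the structural features of the real spectra:
ladder species with single-residue spacing, unreacted-primer anchors,
adduct and oxidation satellites, length-dependent intensity decay, and
relative (lognormal) intensity noise. It does not model profile peak
shapes, baseline, matrix clusters, detector saturation, calibration drift,
or m/z-dependent centroid error — peak positions are exact. Passing
round-trips therefore demonstrate the correctness of the ladder logic and
the robustness of the calls to intensity perturbation and satellite
confounds, not robustness to mass-axis error beyond what the tolerance
parameter absorbs.

## Problem sizes and defaults used by the shipped checks

Round-trip suites use 22-nt templates (14-base capture site + 8-base read
window), two cycles, 200 noiseless seeded runs spanning d-DNA, l-DNA, LNA
and PNA templates, and 100 noisy runs (noise 0.15, oxidation 0.08, dead
fraction 0.2–0.6). The acceptance script's competition fixtures use a
single template whose first extension site is GGTT (perfect match AACC,
terminal mismatch AACG) with complements verified not to cross-react.

## Known limitations

- Mismatch taxonomy is coarse ({distal-terminal, ligation-site, internal,
  multiple}); real position- and identity-dependent penalties vary.
- Complement sequestration is a single multiplicative factor, not an
  explicit 4-mer:4-mer duplex equilibrium.
- Reads cannot exceed 4 bases × cycles, and mixtures of co-captured
  distinct templates are not deconvolved.
- AT-rich windows are the weak-pairing regime; the fixture generator flags
  an AT-only template for exactly this reason, but the kinetics carry no
  explicit base-composition dependence.
- Capping side products of in-situ activation are not simulated
  (pre-activation protocol assumed).
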