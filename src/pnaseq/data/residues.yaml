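# Default residue / termini / linker table for aeg-PNA oligomers.
#
# Schema
# ------
# residues: token -> {base: A|C|G|T, backbone: aeg|serine-modified,
#                     composition: molecular formula of the residue as
#                     incorporated in the chain (one amide bond formed,
#                     no free water)}
#   Uppercase tokens are plain aeg residues; lowercase tokens are the
#   serine-modified variants (aeg + CH2O).
# termini.n / termini.c: state -> {add: formula, sub: formula}
#   Deltas applied to the residue sum to realise each terminus state.
#   The residue composition already contains the backbone N-H at the
#   N-terminal position and the acyl C=O at the C-terminal position.
# linkers: name -> {add: formula}
#   Full C-terminal delta for the linker-biotin state (replaces the
#   free-acid / amide delta).  The default below is a synthetic
#   stand-in (biotinylated lysine amide); override with the composition
#   of your own construct.  It cancels in all ladder mass differences.
table_version: 1
residues:
  A: {base: A, backbone: aeg, composition: C11H13N7O2}
  C: {base: C, backbone: aeg, composition: C10H13N5O3}
  G: {base: G, backbone: aeg, composition: C11H13N7O3}
  T: {base: T, backbone: aeg, composition: C11H14N4O4}
  a: {base: A, backbone: serine-modified, composition: C12H15N7O3}
  c: {base: C, backbone: serine-modified, composition: C11H15N5O4}
  g: {base: G, backbone: serine-modified, composition: C12H15N7O4}
  t: {base: T, backbone: serine-modified, composition: C12H16N4O5}
termini:
  n:
    free-amine: {add: H}
    azide: {add: N2, sub: H}
    Fmoc: {add: C15H11O2}
    acetyl: {add: C2H3O}
  c:
    free-acid: {add: HO}
    amide: {add: H2N}
linkers:
  biotin-default: {add: C16H28N5O3S}
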