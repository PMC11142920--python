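"""Bundled TM sequences used by examples, fixtures and tests.

These are synthetic stand-in constructs, built to satisfy the
documented sequence constraints of the EpoR/binder system rather than
copied from any database:

* the murine EpoR core TM span carries its small-X6-small motif at
  native positions 230-237-244 (serine, serine, alanine);
* the human EpoR core TM differs from the murine one at exactly three
  mid-spanning positions (235, 237 and 238), which removes the central
  serine of the motif;
* the two designed binders differ only at positions 11 and 12 (VM vs
  AA) and carry their small-X6-small motif at positions 1-8-15-22;
* the photosystem-II-like donor helix used to derive the no-design
  control has its small residues at positions 3-10-17 so that the
  C-terminal Ala-Leu extension rule yields a fourth motif position.

Numbering helpers return 1-based indices; ``MEPOR_TM_START`` maps the
core span onto native receptor numbering.
"""

MEPOR_TM_START = 226  # native residue number of the first core TM position

#: murine EpoR core TM span (native 226-250), synthetic stand-in
MEPOR_TM = "ILTLSLILVLISLLLTVLALLSHRR"

#: human EpoR core TM span: murine with L235V, S237L, L238V
HEPOR_TM = "ILTLSLILVVILVLLTVLALLSHRR"

#: NMR peptide construct: core TM with a polar N-terminal flank;
#: peptide position i corresponds to native residue 217 + i
MEPOR_TM2_OFFSET = 217
MEPOR_TM2 = "GEHWNLPL" + MEPOR_TM

#: designed binder, 24 residues, motif S1-S8-G15-G22
CHAMP1 = "SLILVLFSLIVMLLGVLFTLIGLL"

#: second designed binder: positions 11-12 are AA instead of VM
CHAMP2 = "SLILVLFSLIAALLGVLFTLIGLL"

#: synthetic donor helix standing in for the natural TM1 used to derive
#: the no-design control (smalls at 3-10-17)
PSII_TM1_LIKE = "WFSYTLIWMAVYVLTWGFYILTW"

#: interface positions of the donor helix copied verbatim into the control
PSII_TM1_INTERFACE = (3, 5, 6, 7, 10, 12, 13, 14, 17, 20, 21)


def validate_bundled() -> None:
    """Internal consistency checks for the bundled constructs."""
    assert len(MEPOR_TM) == 25
    assert MEPOR_TM[230 - MEPOR_TM_START] == "S"
    assert MEPOR_TM[237 - MEPOR_TM_START] == "S"
    assert MEPOR_TM[244 - MEPOR_TM_START] == "A"
    diffs = [i for i, (a, b) in enumerate(zip(MEPOR_TM, HEPOR_TM)) if a != b]
    assert [MEPOR_TM_START + i for i in diffs] == [235, 237, 238]
    assert [i + 1 for i, (a, b) in enumerate(zip(CHAMP1, CHAMP2)) if a != b] == [11, 12]
    for seq in (CHAMP1, CHAMP2):
        assert all(seq[p - 1] in "GAS" for p in (1, 8, 15, 22))
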