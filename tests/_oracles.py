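"""Independent reference implementations used only for cross-checking."""


def acmg_table_verdict(pvs: int, ps: int, pm: int, pp: int, ba: int, bs: int, bp: int) -> str:
    """Literal transcription of the published ACMG/AMP combining table,
    written as an explicit pattern lookup (independent of the package's
    counting-based implementation).

    Pathogenic:
      (i)   1 PVS AND (>=1 PS | >=2 PM | 1 PM + 1 PP | >=2 PP)
      (ia)  >=2 PVS (sequence-variant-interpretation refinement)
      (ii)  >=2 PS
      (iii) 1 PS AND (>=3 PM | 2 PM + >=2 PP | 1 PM + >=4 PP)
    Likely pathogenic:
      1 PVS + 1 PM | 1 PS + 1-2 PM | 1 PS + >=2 PP | >=3 PM |
      2 PM + >=2 PP | 1 PM + >=4 PP
    Benign: 1 BA | >=2 BS.  Likely benign: 1 BS + 1 BP | >=2 BP.
    Both sides satisfied -> VUS.
    """
    pathogenic = False
    if pvs >= 2:
        pathogenic = True
    if pvs == 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2):
        pathogenic = True
    if ps >= 2:
        pathogenic = True
    if ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        pathogenic = True

    likely = False
    if pvs == 1 and pm == 1:
        likely = True
    if ps == 1 and 1 <= pm <= 2:
        likely = True
    if ps == 1 and pp >= 2:
        likely = True
    if pm >= 3:
        likely = True
    if pm == 2 and pp >= 2:
        likely = True
    if pm == 1 and pp >= 4:
        likely = True
    # supersets of the pathogenic patterns still reach at least LP
    if pvs >= 1 and pm >= 1:
        likely = True
    if ps >= 1 and (pm >= 1 or pp >= 2):
        likely = True
    if pm >= 2 and pp >= 2:
        likely = True

    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_side = "P" if pathogenic else ("LP" if likely else None)
    benign_side = "B" if benign else ("LB" if likely_benign else None)
    if path_side and benign_side:
        return "VUS"
    return path_side or benign_side or "VUS"
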