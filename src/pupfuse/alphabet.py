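"""Residue alphabet shared by every module.

The 20 standard amino acids are kept in the PSI-BLAST PSSM column order
(A R N D C Q E G H I L K M F P S T W Y V), which fixes both profile-column
semantics and the feature-name ordering of every encoder.
"""

AA_ORDER: str = "ARNDCQEGHILKMFPSTWYV"
AA_TO_COL: dict[str, int] = {a: i for i, a in enumerate(AA_ORDER)}

#: Rare codes tolerated on input; every encoder treats them like padding
#: (zero contribution).
AMBIGUOUS: frozenset[str] = frozenset("BZXUO")

#: Reserved padding symbol for window positions outside the protein.
PAD: str = "-"

STANDARD: frozenset[str] = frozenset(AA_ORDER)
TOLERATED: frozenset[str] = STANDARD | AMBIGUOUS


def is_standard(residue: str) -> bool:
    return residue in STANDARD
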