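"""Protein-level constants and composition utilities for calmodulin.

Mature human calmodulin (CaM) is 148 residues (the initiator Met is cleaved
in E. coli), M ~ 16706 g/mol, with 2 Tyr, no Trp, and no Cys — hence the
small molar extinction coefficient used for concentration determination.
"""

from __future__ import annotations

__all__ = [
    "CAM_SEQUENCE",
    "CAM_MASS",
    "CAM_CDZ_UNASSIGNED",
    "extinction_coefficient",
]

# Mature human calmodulin, 148 residues, numbered 1-148 (Ala1 after Met cleavage).
CAM_SEQUENCE = (
    "ADQLTEEQIAEFKEAFSLFDKDGDGTITTKELGTVMRSLGQNPTEAELQDMINEVDADGNGTIDFPEFLTMMARKM"
    "KDTDSEEEIREAFRVFDKDGNGYISAAELRHVMTNLGEKLTDEEVDEMIREADIDGDGQVNYEEFVQMMTAK"
)

CAM_MASS = 16706.03  # g/mol, intact-mass value for the mature chain

# Amide resonances unassigned in the CaM:calmidazolium complex (exchange
# broadening on the us-ms time scale); residue numbering as above.
CAM_CDZ_UNASSIGNED = (
    [8, 12, 14, 16, 38]
    + [51, 52]
    + [72]
    + list(range(75, 80))
    + [82, 83, 88, 92]
    + [106, 107, 112, 114, 124]
    + [126, 127, 129, 130, 139]
    + list(range(143, 147))
)

# Per-residue molar absorptivities at 280 nm (M^-1 cm^-1), Pace convention.
_EPS_280 = {"Y": 1490, "W": 5500}
_EPS_CYSTINE = 125


def extinction_coefficient(sequence: str, oxidized_cys: bool = False) -> int:
    """Molar extinction coefficient at 280 nm from composition.

    eps = 1490 nTyr + 5500 nTrp (+ 125 per cystine when *oxidized_cys*,
    counting Cys pairs).  For calmodulin (2 Tyr, 0 Trp, 0 Cys) this gives
    2980 M^-1 cm^-1.
    """
    seq = sequence.upper()
    eps = sum(_EPS_280.get(a, 0) for a in seq)
    if oxidized_cys:
        eps += _EPS_CYSTINE * (seq.count("C") // 2)
    return eps
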