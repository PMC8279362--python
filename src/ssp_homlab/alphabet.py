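"""Residue and secondary-structure alphabets and the 8-to-3-state mapping.

The eight DSSP states are collapsed into three classes with the common
convention: 3-10, alpha and pi helices count as helix (H); extended strand
and isolated bridge as strand (E); turn, bend and coil as coil (C).
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SS8_STATES = "HGIEBTSC"
SS3_STATES = "HEC"

SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C",
}

_SS8_TRANSLATION = str.maketrans(SS8_TO_SS3)


def ss8_to_ss3(ss8: str) -> str:
    """Collapse an 8-state secondary-structure string to 3 states."""
    validate_ss8(ss8)
    return ss8.translate(_SS8_TRANSLATION)


def validate_residues(residues: str) -> None:
    bad = set(residues) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"illegal amino-acid letters: {sorted(bad)}")


def validate_ss8(ss8: str) -> None:
    bad = set(ss8) - set(SS8_STATES)
    if bad:
        raise ValueError(f"illegal 8-state labels: {sorted(bad)}")


def validate_ss3(ss3: str) -> None:
    bad = set(ss3) - set(SS3_STATES)
    if bad:
        raise ValueError(f"illegal 3-state labels: {sorted(bad)}")
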