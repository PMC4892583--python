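"""Atomic masses (amu) for the elements this toolkit encounters.

Unknown elements raise rather than defaulting silently.
"""

from __future__ import annotations

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "CA": 40.078,  # calcium (element symbol), not a C-alpha atom name
    "NA": 22.990,
    "K": 39.098,
    "CL": 35.45,
}


class UnknownElementError(ValueError):
    """Raised when an element symbol has no entry in the mass table."""


def mass_of(element: str) -> float:
    key = element.strip().upper()
    try:
        return ATOMIC_MASSES[key]
    except KeyError:
        raise UnknownElementError(f"no mass tabulated for element {element!r}") from None


def guess_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name when columns 77-78 are blank.

    Follows PDB convention: a name starting in column 13 means a two-letter
    element only if the first two characters form a known symbol; otherwise
    the first alphabetic character is the element.
    """
    name = atom_name.strip()
    if not name:
        raise UnknownElementError("empty atom name")
    stripped = "".join(ch for ch in name if ch.isalpha())
    if len(stripped) >= 2 and stripped[:2].upper() in ATOMIC_MASSES and stripped[:2].upper() not in ("CA", "NA"):
        # Two-letter symbols like FE/ZN/SE; CA/NA in a protein context are
        # almost always C-alpha / side-chain N, so prefer the one-letter read.
        return stripped[:2].upper()
    return stripped[0].upper()
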