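"""Element data: atomic weights and the valence model.

Atomic weights are the IUPAC 2007 conventional values (the vintage against
which the reference tables for the study compounds were printed; newer
IUPAC revisions shift some weights by up to 0.02 g/mol for large molecules).
"""

from __future__ import annotations

# symbol -> conventional atomic weight, g/mol (IUPAC 2007)
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.00794,
    "B": 10.811,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "F": 18.9984032,
    "Na": 22.98976928,
    "Mg": 24.3050,
    "Si": 28.0855,
    "P": 30.973762,
    "S": 32.065,
    "Cl": 35.453,
    "K": 39.0983,
    "Ca": 40.078,
    "Zn": 65.409,
    "Br": 79.904,
    "I": 126.90447,
}

# Allowed valences (ascending).  Implicit hydrogens fill the smallest
# allowed valence that accommodates the explicit bond order sum.
DEFAULT_VALENCES: dict[str, tuple[int, ...]] = {
    "H": (1,),
    "B": (3,),
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "F": (1,),
    "Na": (1,),
    "Mg": (2,),
    "Si": (4,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "Cl": (1,),
    "K": (1,),
    "Ca": (2,),
    "Zn": (2,),
    "Br": (1,),
    "I": (1,),
}

# Metals never receive implicit hydrogens; bare ions are legitimate
# (zinc stearate is a Zn2+ / carboxylate salt).
METALS = {"Na", "Mg", "K", "Ca", "Zn"}

# Elements accepted without brackets in SMILES ("organic subset").
ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}

# Elements that may carry the aromatic (lowercase) flag.
AROMATIC_CAPABLE = {"B", "C", "N", "O", "P", "S"}


def charge_adjusted_valences(element: str, charge: int) -> tuple[int, ...]:
    """Allowed valences of an atom after formal-charge adjustment.

    Cations of N/P/O/S gain a bond (e.g. N+ is tetravalent), anions of
    O/N/S/C lose one per unit charge (carboxylate O- is monovalent).
    """
    base = DEFAULT_VALENCES.get(element)
    if base is None:
        raise KeyError(f"element without valence entry: {element!r}")
    if charge == 0:
        return base
    if charge > 0 and element in {"N", "P", "O", "S", "C"}:
        return tuple(v + charge for v in base)
    if charge < 0 and element in {"O", "N", "S", "C", "P"}:
        return tuple(max(0, v + charge) for v in base)
    # metals and halide ions: charge satisfied ionically, no H filling
    return (0,)
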