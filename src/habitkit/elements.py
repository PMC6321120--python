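"""Per-element radius and generic Lennard-Jones tables.

Covalent radii: Cordero et al. consensus values (single-bond, Å).
Van der Waals radii: Bondi set, with Rowland & Taylor's revised H.
LJ parameters: UFF-style nonbond well depths (kcal/mol) and van der
Waals distances x (Å, the LJ minimum r_min = x), for the elements that
occur in organic molecular crystals.  These are generic parameters for
a transferable atom-atom potential, not a fitted force field.
"""

from __future__ import annotations

COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Na": 1.66, "Mg": 1.41, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02,
    "K": 2.03, "Ca": 1.76, "Br": 1.20, "I": 1.39,
    "X": 0.76,  # generic placeholder atom, carbon-sized
}

VDW_RADII: dict[str, float] = {
    "H": 1.10, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Na": 2.27, "Mg": 1.73, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75,
    "K": 2.75, "Ca": 2.31, "Br": 1.85, "I": 1.98,
    "X": 1.70,
}

# UFF nonbond parameters: (well depth D, kcal/mol; vdW distance x = r_min, Å)
UFF_LJ: dict[str, tuple[float, float]] = {
    "H": (0.044, 2.886), "B": (0.180, 4.083), "C": (0.105, 3.851),
    "N": (0.069, 3.660), "O": (0.060, 3.500), "F": (0.050, 3.364),
    "Na": (0.030, 2.983), "Mg": (0.111, 3.021), "Si": (0.402, 4.295),
    "P": (0.305, 4.147), "S": (0.274, 4.035), "Cl": (0.227, 3.947),
    "K": (0.035, 3.812), "Ca": (0.238, 3.399), "Br": (0.251, 4.189),
    "I": (0.339, 4.50), "X": (0.105, 3.851),
}

#: Coulomb conversion: e²/Å → kcal/mol
COULOMB_KCAL = 332.0637


def covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element]
    except KeyError:
        raise KeyError(f"no tabulated covalent radius for element {element!r}")


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element]
    except KeyError:
        raise KeyError(f"no tabulated van der Waals radius for element {element!r}")
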