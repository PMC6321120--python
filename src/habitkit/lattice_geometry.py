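"""Metric-tensor lattice geometry.

Interplanar spacings, cell volume, interfacial angles, Laue-class face
multiplicities and enumeration of candidate growth forms — everything the
habit stage needs that depends only on the cell and the point symmetry.

Miller indices transform covariantly: an operator with fractional-coordinate
rotation R sends (h k l) to (h k l)·R.  The Laue class is the parsed rotation
set augmented with the inversion, so multiplicities come out of the actual
operator list rather than a space-group symbol table.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .structure_io import CellParameters, SymmetryOperator

#: Safety cap on the number of (h,k,l) triples visited by enumerate_forms.
ENUMERATION_CAP = 2_000_000


@dataclass(frozen=True)
class MillerIndex:
    """Integer plane indices (h k l), not all zero.

    The raw triple is kept for form naming — (002) stays (002) — while
    :attr:`reduced` gives the gcd-reduced direction, e.g. (001).
    """

    h: int
    k: int
    l: int

    def __post_init__(self) -> None:
        if self.h == self.k == self.l == 0:
            raise ValueError("(0,0,0) is not a valid Miller index")

    @property
    def reduced(self) -> tuple[int, int, int]:
        g = math.gcd(math.gcd(abs(self.h), abs(self.k)), abs(self.l))
        return (self.h // g, self.k // g, self.l // g)

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)

    def __str__(self) -> str:  # compact "11-1" style used in face tables
        return "".join(str(i) for i in self.as_tuple())

    @classmethod
    def from_string(cls, text: str) -> "MillerIndex":
        """Parse '110', '11-1', '1,1,-1' or '(1 1 -1)'."""
        s = text.strip().strip("(){}")
        if "," in s or " " in s:
            parts = [p for p in re.split(r"[,\s]+", s) if p]
        else:
            parts = re.findall(r"-?\d", s)
        if len(parts) != 3:
            raise ValueError(f"cannot parse Miller index from {text!r}")
        return cls(*(int(p) for p in parts))


@dataclass
class FaceForm:
    """One crystallographic form {hkl}: representative, orbit, d-spacing."""

    hkl: MillerIndex
    multiplicity: int
    d_hkl: float
    equivalents: list[MillerIndex] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.equivalents and len(self.equivalents) != self.multiplicity:
            raise ValueError("multiplicity must equal the number of equivalents")


def reciprocal_vector(cell: CellParameters, hkl: MillerIndex | tuple[int, int, int]) -> np.ndarray:
    """Cartesian g = h·a* + k·b* + l·c* (Å⁻¹); the plane normal direction."""
    h, k, l = hkl.as_tuple() if isinstance(hkl, MillerIndex) else hkl
    rec = cell.reciprocal_vectors
    return h * rec[0] + k * rec[1] + l * rec[2]


def d_spacing(cell: CellParameters, hkl: MillerIndex | tuple[int, int, int]) -> float:
    """Interplanar spacing d_hkl = 1/|g| in Å."""
    if not isinstance(hkl, MillerIndex):
        hkl = MillerIndex(*hkl)
    return 1.0 / float(np.linalg.norm(reciprocal_vector(cell, hkl)))


def cell_volume(cell: CellParameters) -> float:
    """Unit-cell volume in Å³."""
    v = cell.volume
    if not v > 0:
        raise ValueError("degenerate cell: non-positive volume")
    return v


def interfacial_angle(
    cell: CellParameters,
    hkl1: MillerIndex | tuple[int, int, int],
    hkl2: MillerIndex | tuple[int, int, int],
) -> float:
    """Angle (degrees, in [0, 180]) between the normals of two plane families."""
    g1 = reciprocal_vector(cell, hkl1 if isinstance(hkl1, MillerIndex) else MillerIndex(*hkl1))
    g2 = reciprocal_vector(cell, hkl2 if isinstance(hkl2, MillerIndex) else MillerIndex(*hkl2))
    # atan2 form is well conditioned near 0° and 180°
    return math.degrees(math.atan2(float(np.linalg.norm(np.cross(g1, g2))), float(np.dot(g1, g2))))


def laue_rotations(ops: list[SymmetryOperator]) -> list[np.ndarray]:
    """Point-group rotations of the operator set, closed under inversion.

    Returns distinct 3×3 integer matrices (fractional basis).
    """
    if not ops:
        raise ValueError("empty operator set")
    seen: dict[bytes, np.ndarray] = {}
    for op in ops:
        r = op.rot_array
        for m in (r, -r):
            seen.setdefault(m.tobytes(), m)
    return list(seen.values())


def hkl_orbit(laue_ops: list[np.ndarray], hkl: MillerIndex) -> list[tuple[int, int, int]]:
    """Orbit of (h k l) under the Laue class; h' = h·R (covariant)."""
    v = np.array(hkl.as_tuple())
    members = {tuple(int(x) for x in v @ r) for r in laue_ops}
    return sorted(members)


def face_multiplicity(
    laue_ops: list[np.ndarray] | list[SymmetryOperator], hkl: MillerIndex
) -> FaceForm:
    """FaceForm for one orbit; d_hkl is filled in by the caller or left NaN."""
    if not laue_ops:
        raise ValueError("empty operator set")
    if isinstance(laue_ops[0], SymmetryOperator):
        laue_ops = laue_rotations(laue_ops)  # type: ignore[arg-type]
    orbit = hkl_orbit(laue_ops, hkl)  # type: ignore[arg-type]
    rep = max(orbit)
    return FaceForm(
        hkl=MillerIndex(*rep) if rep != hkl.as_tuple() else hkl,
        multiplicity=len(orbit),
        d_hkl=float("nan"),
        equivalents=[MillerIndex(*m) for m in orbit],
    )


def enumerate_forms(
    cell: CellParameters,
    laue_ops: list[np.ndarray] | list[SymmetryOperator],
    d_min: float,
) -> list[FaceForm]:
    """All symmetry-distinct forms with d_hkl ≥ d_min, sorted by decreasing d.

    The index search bound is exact: h = g·a, so |h| ≤ a/d_min (and likewise
    for k, l), which guarantees completeness for any cell shape.  One
    representative per Laue orbit — the lexicographically greatest member.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    if laue_ops and isinstance(laue_ops[0], SymmetryOperator):
        laue_ops = laue_rotations(laue_ops)  # type: ignore[arg-type]
    if not laue_ops:
        raise ValueError("empty operator set")
    hmax = int(math.floor(cell.a / d_min))
    kmax = int(math.floor(cell.b / d_min))
    lmax = int(math.floor(cell.c / d_min))
    n_candidates = (2 * hmax + 1) * (2 * kmax + 1) * (2 * lmax + 1)
    if n_candidates > ENUMERATION_CAP:
        raise ValueError(
            f"enumeration of {n_candidates} index triples exceeds the cap of {ENUMERATION_CAP}; "
            "raise d_min"
        )
    rec = cell.reciprocal_vectors
    forms: dict[tuple[int, int, int], FaceForm] = {}
    for h in range(-hmax, hmax + 1):
        for k in range(-kmax, kmax + 1):
            for l in range(-lmax, lmax + 1):
                if h == k == l == 0:
                    continue
                g = h * rec[0] + k * rec[1] + l * rec[2]
                d = 1.0 / float(np.linalg.norm(g))
                if d < d_min:
                    continue
                mi = MillerIndex(h, k, l)
                orbit = hkl_orbit(laue_ops, mi)  # type: ignore[arg-type]
                rep = max(orbit)
                if rep in forms:
                    continue
                forms[rep] = FaceForm(
                    hkl=MillerIndex(*rep),
                    multiplicity=len(orbit),
                    d_hkl=d,
                    equivalents=[MillerIndex(*m) for m in orbit],
                )
    return sorted(forms.values(), key=lambda f: (-f.d_hkl, f.hkl.as_tuple()))
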