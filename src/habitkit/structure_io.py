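"""Crystal-structure I/O and symmetry bookkeeping.

Reads and writes a minimal core-CIF subset (cell, symmetry operators or a
space-group symbol, fractional atom sites, optional partial charges),
expands the asymmetric unit to the full cell, and partitions the expanded
cell into bonded molecular units.

Conventions fixed here and used throughout the package:

* fractional coordinates; a symmetry operator acts as ``x' = R·x + t``;
* Cartesian frame with **a** along x, **b** along y, **c** in the xz
  plane (the standard monoclinic-capable orthogonalization);
* bond criterion ``d(i,j) ≤ r_cov(i) + r_cov(j) + 0.4 Å`` with periodic
  minimum-image distances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np

from .elements import covalent_radius

logger = logging.getLogger(__name__)

#: Cartesian tolerance (Å) below which two symmetry images of one atom are
#: merged as a special-position duplicate.
SPECIAL_POSITION_TOL = 0.3

#: Extra margin (Å) added to the sum of covalent radii in the bond criterion.
BOND_TOLERANCE = 0.4


class CifFormatError(ValueError):
    """A required CIF block is missing or malformed."""


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CellParameters:
    """Unit-cell lengths (Å) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {ang} outside (0, 180)")
        if self.volume <= 0 or math.isnan(self.volume):
            raise ValueError("degenerate cell: non-positive volume")

    @property
    def volume(self) -> float:
        """Cell volume in Å³ from the general triclinic formula."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return float("nan")
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def frac_to_cart(self) -> np.ndarray:
        """3×3 matrix M with lattice vectors as columns; x_cart = M @ x_frac."""
        alpha, beta, gamma = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg, sg = math.cos(alpha), math.cos(beta), math.cos(gamma), math.sin(gamma)
        cy = (ca - cb * cg) / sg
        cz = math.sqrt(max(1.0 - cb * cb - cy * cy, 0.0))
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * cy],
                [0.0, 0.0, self.c * cz],
            ]
        )

    @property
    def reciprocal_vectors(self) -> np.ndarray:
        """Rows are a*, b*, c* (Å⁻¹, crystallographic convention, no 2π)."""
        return np.linalg.inv(self.frac_to_cart)

    def to_cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.frac_to_cart.T


@dataclass(frozen=True)
class SymmetryOperator:
    """Space-group operator x' = R·x + t on fractional coordinates."""

    rotation: tuple[tuple[int, ...], ...]
    translation: tuple[float, float, float]

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymmetryOperator":
        try:
            op = gemmi.Op(triplet)
        except (RuntimeError, ValueError) as exc:
            raise ValueError(f"unparsable symmetry operator string {triplet!r}") from exc
        rot = tuple(tuple(v // gemmi.Op.DEN for v in row) for row in op.rot)
        tran = tuple((v / gemmi.Op.DEN) % 1.0 for v in op.tran)
        return cls(rot, tran)

    @classmethod
    def identity(cls) -> "SymmetryOperator":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rotation, dtype=int)

    @property
    def tran_array(self) -> np.ndarray:
        return np.array(self.translation, dtype=float)

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return self.rot_array @ np.asarray(frac, dtype=float) + self.tran_array

    def compose(self, other: "SymmetryOperator") -> "SymmetryOperator":
        """self ∘ other, translation reduced mod 1."""
        rot = self.rot_array @ other.rot_array
        tran = (self.rot_array @ other.tran_array + self.tran_array) % 1.0
        return SymmetryOperator(
            tuple(tuple(int(v) for v in row) for row in rot),
            tuple(round(float(t), 12) % 1.0 for t in tran),
        )

    def triplet(self) -> str:
        op = gemmi.Op()
        op.rot = [[int(v) * gemmi.Op.DEN for v in row] for row in self.rotation]
        op.tran = [int(round(t * gemmi.Op.DEN)) for t in self.translation]
        return op.triplet()

    def __post_init__(self) -> None:
        det = round(np.linalg.det(self.rot_array))
        if det not in (1, -1):
            raise ValueError(f"operator rotation determinant {det}, expected ±1")


@dataclass(frozen=True)
class AtomSite:
    """One atom of the asymmetric unit in fractional coordinates."""

    label: str
    element: str
    frac: tuple[float, float, float]
    occupancy: float = 1.0
    charge: float = 0.0

    def __post_init__(self) -> None:
        covalent_radius(self.element)  # raises for unknown elements
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside (0, 1]")


@dataclass(frozen=True)
class ExpandedSite:
    """One symmetry image of an asymmetric-unit atom, wrapped into the cell."""

    label: str
    element: str
    frac: tuple[float, float, float]
    charge: float
    sym_code: str          # operator triplet that generated the image
    asym_index: int        # index into CrystalStructure.asym_atoms


@dataclass
class MolecularUnit:
    """A bonded connected component of the expanded cell.

    Coordinates are unwrapped Cartesian (Å): periodic bonds are followed so
    the unit is geometrically contiguous even when it crosses cell walls.
    """

    indices: list[int]               # into the expanded-site list
    labels: list[str]
    elements: list[str]
    cart: np.ndarray                 # (n, 3) unwrapped
    charges: np.ndarray

    @property
    def centroid(self) -> np.ndarray:
        return self.cart.mean(axis=0)

    def distance_set(self) -> np.ndarray:
        """Sorted internal pairwise distances (a rigid-shape fingerprint)."""
        d = np.linalg.norm(self.cart[:, None] - self.cart[None, :], axis=-1)
        iu = np.triu_indices(len(self.cart), 1)
        return np.sort(d[iu])


class InfiniteNetworkError(ValueError):
    """A bonded component closes on itself through the lattice (a polymer)."""


@dataclass
class CrystalStructure:
    """Cell + symmetry operators + asymmetric unit: the universal input record."""

    cell: CellParameters
    ops: list[SymmetryOperator]
    asym_atoms: list[AtomSite]
    z_value: int | None = None
    z_prime: float | None = None
    name: str = "structure"

    def __post_init__(self) -> None:
        if not self.ops:
            raise ValueError("structure needs at least the identity operator")

    def check_group_closure(self) -> bool:
        """True if the operator set is closed under composition mod lattice."""
        keys = {(op.rotation, _tran_key(op)) for op in self.ops}
        for p in self.ops:
            for q in self.ops:
                c = p.compose(q)
                if (c.rotation, _tran_key(c)) not in keys:
                    return False
        return True


def _tran_key(op: SymmetryOperator) -> tuple[int, int, int]:
    return tuple(int(round(t * 24)) % 24 for t in op.translation)


# --------------------------------------------------------------------------
# CIF read / write

_CELL_TAGS = ("_cell_length_a", "_cell_length_b", "_cell_length_c",
              "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma")

_SYMOP_TAGS = ("_space_group_symop_operation_xyz", "_symmetry_equiv_pos_as_xyz")
_SG_NAME_TAGS = ("_space_group_name_H-M_alt", "_symmetry_space_group_name_H-M")


def _numeric(value: str) -> float:
    """CIF number, stripping a parenthesised s.u. like 19.9960(5)."""
    return float(value.split("(")[0])


def parse_cif(path: str | Path) -> CrystalStructure:
    """Read a small-molecule CIF into a :class:`CrystalStructure`.

    Supports explicit operator loops and, failing that, a Hermann–Mauguin
    space-group symbol resolvable by the conventional symbol table.
    Unknown tags are ignored (logged at DEBUG); a missing cell or atom-site
    loop raises :class:`CifFormatError` naming the absent block.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()

    cell_vals = {}
    for tag in _CELL_TAGS:
        v = block.find_value(tag)
        if v is None and tag.startswith("_cell_length"):
            raise CifFormatError(f"missing cell block: {tag} not found in {path.name}")
        cell_vals[tag] = _numeric(v) if v is not None else 90.0
    cell = CellParameters(
        cell_vals["_cell_length_a"], cell_vals["_cell_length_b"], cell_vals["_cell_length_c"],
        cell_vals["_cell_angle_alpha"], cell_vals["_cell_angle_beta"], cell_vals["_cell_angle_gamma"],
    )

    ops: list[SymmetryOperator] = []
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        if len(col) > 0:
            ops = [SymmetryOperator.from_triplet(gemmi.cif.as_string(s)) for s in col]
            break
    if not ops:
        for tag in _SG_NAME_TAGS:
            v = block.find_value(tag)
            if v is not None:
                symbol = gemmi.cif.as_string(v)
                sg = gemmi.SpaceGroup(symbol)
                ops = [SymmetryOperator.from_triplet(op.triplet()) for op in sg.operations()]
                break
    if not ops:
        raise CifFormatError(f"missing symmetry block: no operator loop or space-group symbol in {path.name}")

    table = block.find("_atom_site_", ["label", "type_symbol", "fract_x", "fract_y", "fract_z"])
    if len(table) == 0:
        raise CifFormatError(f"missing atom_site loop in {path.name}")
    occ_col = block.find_loop("_atom_site_occupancy")
    chg_col = block.find_loop("_atom_site_charge")
    occ = [_numeric(v) for v in occ_col] if len(occ_col) else None
    chg = [_numeric(v) for v in chg_col] if len(chg_col) else None

    atoms = []
    for i, row in enumerate(table):
        atoms.append(
            AtomSite(
                label=gemmi.cif.as_string(row[0]),
                element=gemmi.cif.as_string(row[1]),
                frac=tuple(_numeric(row[j]) for j in (2, 3, 4)),
                occupancy=occ[i] if occ else 1.0,
                charge=chg[i] if chg else 0.0,
            )
        )

    z_val = block.find_value("_cell_formula_units_Z")
    structure = CrystalStructure(
        cell=cell,
        ops=ops,
        asym_atoms=atoms,
        z_value=int(_numeric(z_val)) if z_val is not None else None,
        name=block.name or path.stem,
    )
    return structure


def write_cif(structure: CrystalStructure, path: str | Path) -> None:
    """Write the minimal CIF subset that :func:`parse_cif` reads back."""
    cell = structure.cell
    lines = [f"data_{structure.name}"]
    for tag, val in zip(_CELL_TAGS, (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)):
        lines.append(f"{tag}   {val:.6f}")
    if structure.z_value is not None:
        lines.append(f"_cell_formula_units_Z   {structure.z_value}")
    lines.append("loop_")
    lines.append("_space_group_symop_operation_xyz")
    for op in structure.ops:
        lines.append(f"  '{op.triplet()}'")
    lines.append("loop_")
    for sub in ("label", "type_symbol", "fract_x", "fract_y", "fract_z", "occupancy", "charge"):
        lines.append(f"_atom_site_{sub}")
    for at in structure.asym_atoms:
        x, y, z = at.frac
        lines.append(
            f"  {at.label} {at.element} {x:.8f} {y:.8f} {z:.8f} {at.occupancy:.4f} {at.charge:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# symmetry expansion

def expand_symmetry(structure: CrystalStructure) -> list[ExpandedSite]:
    """Map every asymmetric-unit atom through every operator.

    Images of the *same* source atom closer than ``SPECIAL_POSITION_TOL``
    (Cartesian, minimum-image) are merged as special-position duplicates;
    the first generating operator is kept.
    """
    cell = structure.cell
    M = cell.frac_to_cart
    expanded: list[ExpandedSite] = []
    for ia, atom in enumerate(structure.asym_atoms):
        kept_fracs: list[np.ndarray] = []
        for op in structure.ops:
            frac = op.apply(np.array(atom.frac)) % 1.0
            dup = False
            for prev in kept_fracs:
                delta = frac - prev
                delta -= np.round(delta)
                if np.linalg.norm(M @ delta) < SPECIAL_POSITION_TOL:
                    dup = True
                    break
            if dup:
                continue
            kept_fracs.append(frac)
            expanded.append(
                ExpandedSite(
                    label=atom.label,
                    element=atom.element,
                    frac=tuple(float(x) for x in frac),
                    charge=atom.charge,
                    sym_code=op.triplet(),
                    asym_index=ia,
                )
            )
    return expanded


# --------------------------------------------------------------------------
# molecule identification

def _bond_graph(sites: list[ExpandedSite], cell: CellParameters):
    """Graph on expanded sites; each edge stores every bonding image shift of j.

    Multiple distinct shifts for the same pair mean the pair is bonded both
    directly and through the lattice — the signature of an infinite network.
    """
    M = cell.frac_to_cart
    frac = np.array([s.frac for s in sites])
    n = len(sites)
    radii = np.array([covalent_radius(s.element) for s in sites])
    g = nx.Graph()
    g.add_nodes_from(range(n))
    shifts = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])
    for i in range(n):
        delta = frac[None, i] - frac  # (n,3): frac_i - frac_j
        base = np.round(delta)
        cutoffs = radii[i] + radii + BOND_TOLERANCE
        for j in range(i + 1, n):
            bonded = []
            for s in shifts:
                d = np.linalg.norm(M @ (frac[j] + base[j] + s - frac[i]))
                if 1e-6 < d <= cutoffs[j]:
                    bonded.append(tuple(base[j] + s))
            if bonded:
                g.add_edge(i, j, shifts=bonded)
        # an atom bonded to its own lattice image is itself an infinite chain
        for s in shifts:
            if s.any() and np.linalg.norm(M @ s.astype(float)) <= 2 * radii[i] + BOND_TOLERANCE:
                raise InfiniteNetworkError(
                    f"atom {sites[i].label} bonds to its own lattice image"
                )
    return g, frac


def identify_molecules(sites: list[ExpandedSite], cell: CellParameters) -> list[MolecularUnit]:
    """Partition expanded sites into bonded molecular units.

    Bonds use periodic minimum-image distances; each unit is unwrapped by
    following bond image shifts so its geometry is contiguous.  A component
    that reaches one of its own atoms through two different lattice offsets
    is an infinite periodic network and raises
    :class:`InfiniteNetworkError` rather than being silently split.
    """
    g, frac = _bond_graph(sites, cell)
    M = cell.frac_to_cart
    units: list[MolecularUnit] = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        root = comp[0]
        offset: dict[int, np.ndarray] = {root: np.zeros(3)}
        stack = [root]
        while stack:
            i = stack.pop()
            for j in g.neighbors(i):
                # edge stored as (min(i,j), max(i,j)); shifts apply to the larger index
                for shift in g.edges[i, j]["shifts"]:
                    shift = np.asarray(shift, dtype=float)
                    off_j = offset[i] + (shift if j > i else -shift)
                    if j in offset:
                        if not np.allclose(off_j, offset[j], atol=1e-6):
                            raise InfiniteNetworkError(
                                f"bonded component containing {sites[root].label} "
                                "spans the cell periodically"
                            )
                    else:
                        offset[j] = off_j
                        stack.append(j)
        cart = np.array([M @ (frac[i] + offset[i]) for i in comp])
        units.append(
            MolecularUnit(
                indices=list(comp),
                labels=[sites[i].label for i in comp],
                elements=[sites[i].element for i in comp],
                cart=cart,
                charges=np.array([sites[i].charge for i in comp]),
            )
        )
    units.sort(key=lambda u: u.indices[0])
    return units


def bond_graph_for_unit(unit: MolecularUnit) -> nx.Graph:
    """Intra-unit bond graph recomputed on unwrapped Cartesian coordinates."""
    g = nx.Graph()
    n = len(unit.labels)
    g.add_nodes_from(range(n))
    for i in range(n):
        ri = covalent_radius(unit.elements[i])
        for j in range(i + 1, n):
            cut = ri + covalent_radius(unit.elements[j]) + BOND_TOLERANCE
            if 1e-6 < np.linalg.norm(unit.cart[i] - unit.cart[j]) <= cut:
                g.add_edge(i, j)
    return g
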