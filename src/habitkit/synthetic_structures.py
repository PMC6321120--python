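"""Deterministic synthetic crystal structures with known ground truth.

Every analysis stage in this package is testable without any deposited
coordinates: these generators build structures whose answers are known by
construction — simple-cubic Lennard-Jones crystals with closed-form
neighbour shells, molecular crystals in a chosen space group with an exact
molecule count, rings built by inverse Cremer–Pople displacement so the
puckering analysis must recover the requested (q₂, φ₂), and two-molecule
boxes realizing an exact hydrogen-bond or stacking geometry.

All fixtures are exact and seed-free by default; a seed only drives the
optional coordinate jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import (
    AtomSite,
    CellParameters,
    CrystalStructure,
    SymmetryOperator,
)

# canonical general-position operator sets for the supported space groups
SPACE_GROUP_OPS: dict[str, list[str]] = {
    "P1": ["x,y,z"],
    "P-1": ["x,y,z", "-x,-y,-z"],
    "P21/c": ["x,y,z", "-x,y+1/2,-z+1/2", "-x,-y,-z", "x,-y+1/2,z+1/2"],
    "C2/c": [
        "x,y,z", "-x,y,-z+1/2", "-x,-y,-z", "x,-y,z+1/2",
        "x+1/2,y+1/2,z", "-x+1/2,y+1/2,-z+1/2", "-x+1/2,-y+1/2,-z", "x+1/2,-y+1/2,z+1/2",
    ],
}


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request: kind + geometric parameters + seed."""

    kind: str                      # lj_crystal | molecular_crystal | ring | contact_pair
    params: tuple = ()
    seed: int | None = None


def _ops(space_group: str) -> list[SymmetryOperator]:
    try:
        trips = SPACE_GROUP_OPS[space_group]
    except KeyError:
        raise ValueError(
            f"unsupported space group {space_group!r}; choose from {sorted(SPACE_GROUP_OPS)}"
        )
    return [SymmetryOperator.from_triplet(t) for t in trips]


# --------------------------------------------------------------------------
# LJ crystal


def make_lj_crystal(spacing: float, n_cells: int = 1, element: str = "X") -> CrystalStructure:
    """Simple-cubic single-atom crystal in P1.

    With ``n_cells`` > 1 the P1 cell is an n×n×n block of the primitive
    spacing, which leaves the lattice (and all lattice sums) unchanged.
    """
    if spacing <= 0:
        raise ValueError("lattice spacing must be positive")
    a = spacing * n_cells
    atoms = []
    idx = 0
    for i in range(n_cells):
        for j in range(n_cells):
            for k in range(n_cells):
                idx += 1
                atoms.append(
                    AtomSite(
                        label=f"{element}{idx}",
                        element=element,
                        frac=(i / n_cells, j / n_cells, k / n_cells),
                    )
                )
    return CrystalStructure(
        cell=CellParameters(a, a, a, 90, 90, 90),
        ops=[SymmetryOperator.identity()],
        asym_atoms=atoms,
        z_value=len(atoms),
        z_prime=len(atoms),
        name="lj_cubic",
    )


# --------------------------------------------------------------------------
# molecular crystal

#: default rigid template: bent three-atom molecule (water-like geometry),
#: pre-oriented so the default C2/c packing below is dispersion-bound
DEFAULT_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    ("O1", "O", (0.0000, 0.0000, 0.0000)),
    ("H1", "H", (0.9413, -0.0191, 0.1715)),
    ("H2", "H", (-0.0903, 0.5435, -0.7832)),
]

#: default monoclinic cell and general positions: roomy enough that the
#: expanded C2/c packing has no clashes and a negative cohesive energy
DEFAULT_CELL = (14.0, 11.0, 13.0, 90.0, 105.0, 90.0)
DEFAULT_POSITIONS = [(0.430, 0.084, 0.353), (0.858, 0.640, 0.643)]

# minimum allowed distance between atoms of different molecules; kept above
# the covalent bond criterion so separate molecules can never fuse
CLASH_DISTANCE = 2.0


def make_molecular_crystal(
    template: list[tuple[str, str, tuple[float, float, float]]] | None = None,
    cell: CellParameters | None = None,
    space_group: str = "C2/c",
    z_prime: int = 1,
    positions: list[tuple[float, float, float]] | None = None,
    jitter: float = 0.0,
    seed: int | None = None,
) -> CrystalStructure:
    """Rigid-molecule crystal: template placed at general position(s), expanded.

    The default geometry puts one (or two, for Z′ = 2) copies of a small
    bent triatomic in a monoclinic cell roomy enough that symmetry images
    do not clash; the expansion is validated and a clash raises with the
    offending pair.  Label suffixes distinguish the Z′ copies.
    """
    from .structure_io import expand_symmetry, identify_molecules  # cycle-free local import

    template = template or DEFAULT_TEMPLATE
    cell = cell or CellParameters(*DEFAULT_CELL)
    ops = _ops(space_group)
    positions = positions or DEFAULT_POSITIONS[:z_prime]
    if len(positions) < z_prime:
        raise ValueError("need one placement position per independent molecule")
    rng = np.random.default_rng(seed)
    Minv = np.linalg.inv(cell.frac_to_cart)
    atoms: list[AtomSite] = []
    for mol_i in range(z_prime):
        origin = np.array(positions[mol_i])
        for label, element, xyz in template:
            frac = origin + Minv @ np.array(xyz)
            if jitter:
                frac = frac + Minv @ rng.uniform(-jitter, jitter, 3)
            atoms.append(
                AtomSite(label=f"{label}{'' if z_prime == 1 else chr(97 + mol_i)}",
                         element=element, frac=tuple(frac % 1.0))
            )
    structure = CrystalStructure(
        cell=cell,
        ops=ops,
        asym_atoms=atoms,
        z_value=len(ops) * z_prime,
        z_prime=z_prime,
        name=f"synthetic_{space_group.replace('/', '_')}",
    )
    # validate: no intermolecular clash in the expanded cell (3x3x3 images)
    sites = expand_symmetry(structure)
    units = identify_molecules(sites, cell)
    expected = len(ops) * z_prime
    if len(units) != expected:
        raise ValueError(
            f"clash after expansion: {len(units)} molecular units instead of {expected} "
            "(symmetry images overlap or fuse)"
        )
    M = cell.frac_to_cart
    shifts = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])
    for ua in units:
        for ub in units:
            for s in shifts:
                t = M @ s.astype(float)
                if ua is ub and not s.any():
                    continue
                d = np.linalg.norm(ua.cart[:, None] - (ub.cart + t)[None, :], axis=-1)
                if d.min() < CLASH_DISTANCE:
                    i, j = np.unravel_index(int(d.argmin()), d.shape)
                    raise ValueError(
                        f"clash after expansion: {ua.labels[i]}–{ub.labels[j]} at {d.min():.2f} Å"
                    )
    return structure


# --------------------------------------------------------------------------
# ring fixtures


def make_ring_fixture(
    n: int = 5,
    q2: float = 0.0,
    phi2: float = 0.0,
    q3: float = 0.0,
    bond_length: float = 1.53,
    jitter: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Ordered ring coordinates built by inverse Cremer–Pople construction.

    Atoms sit on a circle of radius L/(2 sin π/n) with out-of-plane
    displacements z_j = √(2/n)·q₂·cos(φ₂ + 4πj/n) (+ alternating q₃ term
    for even n), so the puckering analysis must return exactly the
    requested amplitudes and phase.
    """
    if n not in (4, 5, 6):
        raise ValueError("ring size must be 4, 5 or 6")
    radius = bond_length / (2.0 * math.sin(math.pi / n))
    if abs(q2) + abs(q3) > 0.6 * radius:
        raise ValueError(
            f"puckering amplitude {abs(q2) + abs(q3):.3f} Å infeasible for bond length {bond_length} Å"
        )
    j = np.arange(n)
    theta = 2.0 * np.pi * j / n
    z = math.sqrt(2.0 / n) * q2 * np.cos(math.radians(phi2) + 2.0 * theta)
    if n % 2 == 0:
        z = z + q3 / math.sqrt(n) * np.cos(np.pi * j)
    # clockwise placement puts the analysis mean-plane normal along +z,
    # so the requested (q2, phi2) are recovered with the same sign convention
    coords = np.stack([radius * np.cos(-theta), radius * np.sin(-theta), z], axis=1)
    if jitter:
        rng = np.random.default_rng(seed)
        coords = coords + rng.uniform(-jitter, jitter, coords.shape)
    return coords


# --------------------------------------------------------------------------
# contact pairs


def _box(atoms: list[AtomSite], edge: float = 30.0, name: str = "contact_pair") -> CrystalStructure:
    return CrystalStructure(
        cell=CellParameters(edge, edge, edge, 90, 90, 90),
        ops=[SymmetryOperator.identity()],
        asym_atoms=atoms,
        z_value=1,
        name=name,
    )


def _frac(cell_edge: float, xyz: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(v) for v in (np.asarray(xyz) / cell_edge) % 1.0)


def _hexagon(center: np.ndarray, normal: np.ndarray, radius: float = 1.39,
             labels_prefix: str = "C", start: int = 1) -> list[tuple[str, np.ndarray]]:
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    out = []
    for i in range(6):
        ang = math.pi * i / 3.0
        pos = center + radius * (math.cos(ang) * u + math.sin(ang) * v)
        out.append((f"{labels_prefix}{start + i}", pos))
    return out


def make_contact_pair(kind: str, **params) -> CrystalStructure:
    """Two-molecule P1 box realizing an exact contact geometry.

    kinds and their parameters:

    * ``hbond``: ``d_dh`` (default 0.84), ``d_ha`` (1.97), ``angle`` (170°);
      a C–O–H donor fragment facing a C=O acceptor.
    * ``pi_pi``: ``perp`` (3.4) perpendicular separation, ``offset`` (0.0)
      lateral slip between two parallel six-membered carbon rings.
    * ``t_shaped``: ``cg`` (5.2) centroid distance, ``dihedral`` (70°).
    """
    edge = float(params.get("edge", 30.0))
    center = np.full(3, edge / 2.0)
    if kind == "hbond":
        d_dh = float(params.get("d_dh", 0.84))
        d_ha = float(params.get("d_ha", 1.97))
        angle = float(params.get("angle", 170.0))
        if d_dh <= 0 or d_ha <= 0 or not 0 < angle <= 180:
            raise ValueError("contradictory hydrogen-bond parameters")
        a = math.radians(angle)
        d_pos = center
        h_pos = center + np.array([d_dh, 0.0, 0.0])
        # D-H...A angle measured at H; H->D points along -x
        a_pos = h_pos + d_ha * np.array([-math.cos(a), math.sin(a), 0.0])
        c_don = d_pos + 1.40 * np.array([-0.94, -0.34, 0.0])
        # acceptor C on the far side of A from H
        away = (a_pos - h_pos) / np.linalg.norm(a_pos - h_pos)
        c_acc = a_pos + 1.22 * away
        atoms = [
            AtomSite("C1", "C", _frac(edge, c_don)),
            AtomSite("O1", "O", _frac(edge, d_pos)),
            AtomSite("H1", "H", _frac(edge, h_pos)),
            AtomSite("O2", "O", _frac(edge, a_pos)),
            AtomSite("C2", "C", _frac(edge, c_acc)),
        ]
        return _box(atoms, edge, "hbond_pair")

    if kind == "pi_pi":
        perp = float(params.get("perp", 3.4))
        offset = float(params.get("offset", 0.0))
        if perp <= 0:
            raise ValueError("perpendicular separation must be positive")
        ring1 = _hexagon(center, np.array([0.0, 0.0, 1.0]), start=1)
        c2 = center + np.array([offset, 0.0, perp])
        ring2 = _hexagon(c2, np.array([0.0, 0.0, 1.0]), start=7)
        atoms = [AtomSite(lbl, "C", _frac(edge, pos)) for lbl, pos in ring1 + ring2]
        return _box(atoms, edge, "pi_pi_pair")

    if kind == "t_shaped":
        cg = float(params.get("cg", 5.2))
        dihedral = float(params.get("dihedral", 70.0))
        if cg <= 0 or not 0 <= dihedral <= 90:
            raise ValueError("contradictory T-shaped parameters")
        ring1 = _hexagon(center, np.array([0.0, 0.0, 1.0]), start=1)
        d = math.radians(dihedral)
        n2 = np.array([0.0, math.sin(d), math.cos(d)])
        c2 = center + np.array([0.0, 0.0, cg])
        ring2 = _hexagon(c2, n2, start=7)
        atoms = [AtomSite(lbl, "C", _frac(edge, pos)) for lbl, pos in ring1 + ring2]
        return _box(atoms, edge, "t_shaped_pair")

    raise ValueError(f"unknown contact kind {kind!r}")


def make_fixture(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to its generator."""
    params = dict(spec.params)
    if spec.seed is not None:
        params.setdefault("seed", spec.seed)
    if spec.kind == "lj_crystal":
        return make_lj_crystal(**params)
    if spec.kind == "molecular_crystal":
        return make_molecular_crystal(**params)
    if spec.kind == "ring":
        return make_ring_fixture(**params)
    if spec.kind == "contact_pair":
        return make_contact_pair(**params)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
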