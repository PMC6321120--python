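"""Non-covalent contact geometry, ring puckering and rigid superposition.

The classical small-molecule structure-report suite:

* hydrogen-bond tables (D–H···A distances and angle, with the generating
  symmetry code of the acceptor image);
* ring perception (smallest set of smallest rings) with centroids (Cg),
  least-squares plane normals and planarity RMS;
* π–π / T-shaped stacking classification between ring centroids across
  symmetry images, with slippage (the in-plane offset of one centroid
  relative to the other ring's plane);
* Cremer–Pople puckering amplitudes and phases, with envelope/twist
  labelling for five-membered rings;
* Kabsch least-squares superposition and RMSD.

Conventions: dihedral angles between ring planes are folded into [0°, 90°];
stacking records are directional (the slippage of Cg_i···Cg_j uses ring i's
normal, so the i→j and j→i records generally differ); the Cremer–Pople
phase origin is the first atom of the ring ordering passed in, so a cyclic
relabelling shifts φ₂ by the corresponding multiple of 144°.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import numpy as np

from .structure_io import (
    CrystalStructure,
    MolecularUnit,
    SymmetryOperator,
    bond_graph_for_unit,
    expand_symmetry,
    identify_molecules,
)

# --------------------------------------------------------------------------
# records


@dataclass
class ContactRecord:
    """One D–H···A hydrogen bond."""

    donor: str
    hydrogen: str
    acceptor: str
    intra: bool
    d_dh: float
    d_ha: float
    d_da: float
    angle_dha: float
    symmetry_code: str

    def __post_init__(self) -> None:
        if self.d_da > self.d_dh + self.d_ha + 1e-9:
            raise ValueError("D···A exceeds D–H + H···A (triangle violation)")
        if not 0.0 < self.angle_dha <= 180.0:
            raise ValueError(f"D–H···A angle {self.angle_dha} outside (0, 180]")


@dataclass
class HBondCriteria:
    """Geometric acceptance window for hydrogen bonds.

    Conventional defaults: H···A ≤ 2.7 Å (relaxed to 2.8 Å for the weaker
    C–H donors), D–H···A ≥ 100°, N/O/F/S acceptors.
    """

    max_ha: float = 2.7
    max_ha_carbon: float = 2.8
    min_angle: float = 100.0
    donor_elements: frozenset[str] = frozenset({"N", "O", "F", "S", "C"})
    acceptor_elements: frozenset[str] = frozenset({"N", "O", "F", "S"})


@dataclass
class RingDescriptor:
    """One perceived ring: ordered atoms, centroid (Cg), plane normal."""

    ring_id: int
    atom_labels: list[str]
    atom_indices: list[int]          # into the parent unit
    coords: np.ndarray               # ordered, (n, 3) Cartesian Å
    unit_index: int = 0

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def normal(self) -> np.ndarray:
        _, _, vt = np.linalg.svd(self.coords - self.centroid)
        return vt[2]

    @property
    def planarity_rms(self) -> float:
        z = (self.coords - self.centroid) @ self.normal
        return float(np.sqrt(np.mean(z**2)))


@dataclass
class StackingRecord:
    """One directional Cg_i···Cg_j ring–ring contact."""

    ring_i: int
    ring_j: int
    cg_distance: float
    dihedral: float
    slippage: float | None
    klass: str                       # 'pi-pi' | 't-shaped' | 'unclassified'
    symmetry_code: str


@dataclass
class StackingCutoffs:
    max_cg: float = 6.0
    pi_pi_max_angle: float = 20.0
    t_shaped_min_angle: float = 60.0


@dataclass
class PuckerResult:
    """Cremer–Pople puckering: amplitudes q_m (Å) and phases φ_m (deg)."""

    n: int
    q: dict[int, float]
    phi: dict[int, float]
    q_total: float
    z: np.ndarray
    conformer: str

    @property
    def q2(self) -> float:
        return self.q.get(2, 0.0)

    @property
    def phi2(self) -> float:
        return self.phi.get(2, 0.0)


@dataclass
class SuperpositionResult:
    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    pairing: list[tuple[int, int]]


# --------------------------------------------------------------------------
# symmetry-code formatting

_AXES = ("x", "y", "z")


def format_symmetry_code(op: SymmetryOperator, extra_shift=(0, 0, 0)) -> str:
    """Crystallographic code like '1-x, 2-y, 1-z' (translation written first)."""
    parts = []
    for row, t0, ex in zip(op.rotation, op.translation, extra_shift):
        t = Fraction(round((t0 + ex) * 24), 24)
        term = ""
        if t != 0:
            term += str(t)
        for coef, ax in zip(row, _AXES):
            if coef == 0:
                continue
            if coef > 0:
                term += ("+" if term else "") + (ax if coef == 1 else f"{coef}{ax}")
            else:
                term += "-" + (ax if coef == -1 else f"{-coef}{ax}")
        parts.append(term or "0")
    return ", ".join(parts)


# --------------------------------------------------------------------------
# hydrogen bonds


def detect_hbonds(structure: CrystalStructure, criteria: HBondCriteria | None = None
                  ) -> list[ContactRecord]:
    """All D–H···A contacts of the home-cell molecules with any symmetry image.

    Donor–H bonds come from the covalent bond graph; acceptor images are
    searched over every space-group operator combined with lattice
    translations of up to two cells (home molecules are unwrapped and may
    straddle cell walls).  Each record carries the generating
    symmetry code of its acceptor.  Structures with no hydrogen atoms are
    rejected: the D–H···A geometry is undefined without them.
    """
    criteria = criteria or HBondCriteria()
    sites = expand_symmetry(structure)
    if not any(s.element == "H" for s in sites):
        raise ValueError("structure contains no hydrogen atoms; cannot evaluate D-H...A contacts")
    units = identify_molecules(sites, structure.cell)
    M = structure.cell.frac_to_cart

    # donor–H pairs from home units (unwrapped geometry)
    donors = []  # (unit_idx, donor local idx, H local idx)
    for uidx, unit in enumerate(units):
        g = bond_graph_for_unit(unit)
        for h_local in range(len(unit.labels)):
            if unit.elements[h_local] != "H":
                continue
            for nb in g.neighbors(h_local):
                if unit.elements[nb] in criteria.donor_elements:
                    donors.append((uidx, nb, h_local))

    # acceptor images: asymmetric-unit acceptors through every op ± two cells
    asym = [(i, a) for i, a in enumerate(structure.asym_atoms)
            if a.element in criteria.acceptor_elements]
    shifts = [np.array([i, j, k]) for i in (-2, -1, 0, 1, 2)
              for j in (-2, -1, 0, 1, 2) for k in (-2, -1, 0, 1, 2)]

    records: list[ContactRecord] = []
    seen: set[tuple] = set()
    for uidx, d_local, h_local in donors:
        unit = units[uidx]
        d_pos, h_pos = unit.cart[d_local], unit.cart[h_local]
        max_ha = criteria.max_ha_carbon if unit.elements[d_local] == "C" else criteria.max_ha
        for op in structure.ops:
            for _, atom in asym:
                base = op.apply(np.array(atom.frac))
                for s in shifts:
                    a_pos = M @ (base + s)
                    d_ha = float(np.linalg.norm(a_pos - h_pos))
                    if not 0.5 < d_ha <= max_ha:
                        continue
                    v1 = d_pos - h_pos
                    v2 = a_pos - h_pos
                    cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                    if angle < criteria.min_angle:
                        continue
                    d_da = float(np.linalg.norm(a_pos - d_pos))
                    if d_da < 1e-6:      # acceptor image is the donor itself
                        continue
                    # intra: the acceptor image belongs to the donor's own unit
                    intra = any(
                        np.linalg.norm(a_pos - unit.cart[i]) < 1e-6 for i in range(len(unit.labels))
                    )
                    code = format_symmetry_code(op, tuple(int(x) for x in s))
                    key = (unit.labels[d_local], unit.labels[h_local], atom.label,
                           round(d_ha, 4), round(angle, 2))
                    if key in seen:
                        continue
                    seen.add(key)
                    records.append(
                        ContactRecord(
                            donor=unit.labels[d_local],
                            hydrogen=unit.labels[h_local],
                            acceptor=atom.label,
                            intra=intra,
                            d_dh=float(np.linalg.norm(h_pos - d_pos)),
                            d_ha=d_ha,
                            d_da=d_da,
                            angle_dha=angle,
                            symmetry_code=code,
                        )
                    )
    records.sort(key=lambda r: (r.donor, r.hydrogen, r.acceptor, r.d_ha))
    return records


# --------------------------------------------------------------------------
# ring perception


def _sssr(g: nx.Graph, max_size: int) -> list[list[int]]:
    """Smallest set of smallest rings by greedy GF(2)-independent selection."""
    cycles = [c for c in nx.simple_cycles(g, length_bound=max_size)]
    cycles.sort(key=len)
    n_target = g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)
    edge_index = {frozenset(e): i for i, e in enumerate(g.edges())}
    basis: list[np.ndarray] = []
    chosen: list[list[int]] = []
    for cyc in cycles:
        vec = np.zeros(len(edge_index), dtype=np.uint8)
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            vec[edge_index[frozenset((a, b))]] = 1
        # Gaussian elimination over GF(2)
        v = vec.copy()
        for b_vec in basis:
            pivot = int(np.argmax(b_vec))
            if v[pivot]:
                v ^= b_vec
        if v.any():
            basis.append(v)
            chosen.append(cyc)
        if len(chosen) == n_target:
            break
    return chosen


def perceive_rings(unit: MolecularUnit, max_size: int = 6, unit_index: int = 0,
                   start_id: int = 1) -> list[RingDescriptor]:
    """SSSR rings of one molecular unit, ordered as found along each cycle."""
    g = bond_graph_for_unit(unit)
    rings = []
    for rid, cyc in enumerate(_sssr(g, max_size), start=start_id):
        rings.append(
            RingDescriptor(
                ring_id=rid,
                atom_labels=[unit.labels[i] for i in cyc],
                atom_indices=list(cyc),
                coords=unit.cart[cyc],
                unit_index=unit_index,
            )
        )
    return rings


# --------------------------------------------------------------------------
# stacking


def _stack_pair(ring_i: RingDescriptor, cg_j: np.ndarray, normal_j: np.ndarray,
                cutoffs: StackingCutoffs) -> tuple[float, float, float | None, str] | None:
    delta = cg_j - ring_i.centroid
    cg = float(np.linalg.norm(delta))
    if not 1e-6 < cg < cutoffs.max_cg:
        return None
    cosd = abs(float(ring_i.normal @ normal_j))
    dihedral = math.degrees(math.acos(min(1.0, cosd)))
    if dihedral < cutoffs.pi_pi_max_angle:
        d_perp = abs(float(delta @ ring_i.normal))
        slippage = math.sqrt(max(cg * cg - d_perp * d_perp, 0.0))
        return cg, dihedral, slippage, "pi-pi"
    if dihedral >= cutoffs.t_shaped_min_angle:
        return cg, dihedral, None, "t-shaped"
    return cg, dihedral, None, "unclassified"


def classify_stacking(rings: list[RingDescriptor], structure: CrystalStructure | None = None,
                      cutoffs: StackingCutoffs | None = None) -> list[StackingRecord]:
    """Directional ring–ring contacts among `rings` and their symmetry images.

    With a structure, ring j is replicated through every operator and one
    shell of lattice translations; without one, only the rings as given are
    paired (identity code).  π–π pairs (dihedral < 20°) get a slippage;
    pairs at intermediate dihedrals stay unclassified with no slippage, the
    plane angle being outside the π–π calculation window.
    """
    cutoffs = cutoffs or StackingCutoffs()
    records: list[StackingRecord] = []
    if structure is None:
        images = [(r, SymmetryOperator.identity(), (0, 0, 0), r.coords) for r in rings]
    else:
        M = structure.cell.frac_to_cart
        Minv = np.linalg.inv(M)
        shifts = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        images = []
        for r in rings:
            frac = r.coords @ Minv.T
            for op in structure.ops:
                base = frac @ op.rot_array.T + op.tran_array
                for s in shifts:
                    images.append((r, op, s, (base + np.array(s)) @ M.T))
    for ri in rings:
        for rj, op, s, coords_j in images:
            cg_j = coords_j.mean(axis=0)
            _, _, vt = np.linalg.svd(coords_j - cg_j)
            res = _stack_pair(ri, cg_j, vt[2], cutoffs or StackingCutoffs())
            if res is None:
                continue
            cg, dihedral, slippage, klass = res
            records.append(
                StackingRecord(
                    ring_i=ri.ring_id,
                    ring_j=rj.ring_id,
                    cg_distance=cg,
                    dihedral=dihedral,
                    slippage=slippage,
                    klass=klass,
                    symmetry_code=format_symmetry_code(op, s),
                )
            )
    records.sort(key=lambda r: (r.ring_i, r.ring_j, r.cg_distance))
    return records


# --------------------------------------------------------------------------
# Cremer–Pople puckering


def cremer_pople(coords: np.ndarray) -> PuckerResult:
    """Generalized ring-puckering coordinates of an ordered N-ring (N ≥ 4).

    Mean plane per the original prescription: origin at the geometric
    center, normal along R'×R'' with R' = Σ r_j sin(2πj/N),
    R'' = Σ r_j cos(2πj/N) (j zero-based), which makes Σ z_j = 0 exact.
    Amplitude–phase pairs (q_m, φ_m) for m = 2 … ⌊(N−1)/2⌋, plus the
    alternating q_{N/2} for even N.  Parseval: Σ q_m² = Σ z_j².
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 4:
        raise ValueError("ring must have at least 4 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate ring: atoms are collinear")
    j = np.arange(n)
    rp = (centered * np.sin(2 * np.pi * j / n)[:, None]).sum(axis=0)
    rpp = (centered * np.cos(2 * np.pi * j / n)[:, None]).sum(axis=0)
    normal = np.cross(rp, rpp)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise ValueError("degenerate ring: cannot define a mean plane")
    normal /= nn
    z = centered @ normal

    q: dict[int, float] = {}
    phi: dict[int, float] = {}
    for m in range(2, (n - 1) // 2 + 1):
        qc = math.sqrt(2.0 / n) * float((z * np.cos(2 * np.pi * m * j / n)).sum())
        qs = -math.sqrt(2.0 / n) * float((z * np.sin(2 * np.pi * m * j / n)).sum())
        q[m] = math.hypot(qc, qs)
        phi[m] = math.degrees(math.atan2(qs, qc)) % 360.0
    if n % 2 == 0:
        q[n // 2] = float((z * np.cos(np.pi * j)).sum()) / math.sqrt(n)
    q_total = float(np.sqrt((z**2).sum()))

    conformer = _conformer_label(n, q, phi, z)
    return PuckerResult(n=n, q=q, phi=phi, q_total=q_total, z=z, conformer=conformer)


def _conformer_label(n: int, q: dict[int, float], phi: dict[int, float], z: np.ndarray) -> str:
    if n != 5:
        return "planar" if max((abs(v) for v in q.values()), default=0.0) < 1e-4 else ""
    if q.get(2, 0.0) < 1e-4:
        return "planar"
    # envelope phases sit at multiples of 36°, twists at odd multiples of 18°
    frac = phi[2] % 36.0
    if frac <= 9.0 or frac >= 27.0:
        apex = int(np.argmax(np.abs(z)))
        return f"envelope (atom {apex + 1})"
    order = np.argsort(-np.abs(z))[:2]
    a, b = sorted(int(i) + 1 for i in order)
    return f"twist (atoms {a}-{b})"


# --------------------------------------------------------------------------
# Kabsch superposition


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                pairing: list[tuple[int, int]] | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition of b onto a (proper rotation only)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if pairing is None:
        if len(a) != len(b):
            raise ValueError("unequal coordinate sets require an explicit pairing")
        pairing = [(i, i) for i in range(len(a))]
    ia = [p[0] for p in pairing]
    ib = [p[1] for p in pairing]
    pa, pb = a[ia], b[ib]
    if len(pa) < 3:
        raise ValueError("need at least 3 paired points")
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    qa, qb = pa - ca, pb - cb
    if np.linalg.matrix_rank(qa, tol=1e-10) < 2:
        raise ValueError("points are collinear; rotation is underdetermined")
    h = qb.T @ qa
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = qb @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - qa) ** 2, axis=1))))
    translation = ca - rot @ cb
    return SuperpositionResult(rmsd=rmsd, rotation=rot, translation=translation, pairing=pairing)
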