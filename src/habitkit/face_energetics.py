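"""Crystallization, slice and attachment energies per face form.

The energy bookkeeping follows the periodic-bond-chain picture of crystal
growth: the crystallization energy of a growth unit (one molecule) splits,
for any face (hkl), into the lateral interaction within one d_hkl-thick
slab (E_slice) and the interaction with all other slabs (E_att),

    E_cr = E_slice + E_att,

with E_cr a constant of the structure.  Faces with large |E_att| grow fast
and end up small; the habit stage consumes these values.

The pair potential is a generic transferable atom–atom model: 12-6
Lennard-Jones with UFF-style parameters plus optional point-charge
electrostatics, both shifted to zero at a real-space cutoff.  Absolute
energies therefore depend on this parametrization; the decomposition
identity and the relative face ordering are the meaningful outputs, and the
habit stage equally accepts externally computed attachment energies.

Molecules are never split across slabs: slab membership is decided by the
fractional projection of each molecular centroid on the face normal, the
growth unit being the whole molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .elements import COULOMB_KCAL, UFF_LJ
from .lattice_geometry import FaceForm, reciprocal_vector
from .structure_io import (
    CrystalStructure,
    MolecularUnit,
    expand_symmetry,
    identify_molecules,
)

OVERLAP_TOL = 0.5  # Å; closer pairs indicate a broken structure


@dataclass(frozen=True)
class PotentialParams:
    """Generic LJ(+Coulomb) parameters.

    ``lj`` maps element → (well depth ε, kcal/mol; LJ minimum distance r_min, Å).
    Combining rules: 'geometric' (UFF convention) or 'lorentz-berthelot'.
    """

    lj: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(UFF_LJ))
    combining: str = "geometric"
    coulomb: bool = True
    dielectric: float = 1.0
    cutoff: float = 25.0

    def __post_init__(self) -> None:
        if self.cutoff < 10.0:
            raise ValueError("real-space cutoff must be at least 10 Å")
        if any(eps < 0 for eps, _ in self.lj.values()):
            raise ValueError("LJ well depths must be non-negative")
        if self.combining not in ("geometric", "lorentz-berthelot"):
            raise ValueError(f"unknown combining rule {self.combining!r}")

    def mixed(self, el_i: str, el_j: str) -> tuple[float, float]:
        eps_i, rm_i = self.lj[el_i]
        eps_j, rm_j = self.lj[el_j]
        eps = math.sqrt(eps_i * eps_j)
        rm = math.sqrt(rm_i * rm_j) if self.combining == "geometric" else 0.5 * (rm_i + rm_j)
        return eps, rm


@dataclass
class FaceEnergyRecord:
    """Energy decomposition for one form, kcal/mol per growth unit."""

    form: FaceForm
    e_slice: float
    e_att: float
    e_cr: float


def pair_energy(el_i: str, el_j: str, q_i: float, q_j: float, r: float,
                potential: PotentialParams) -> float:
    """Shifted-truncated LJ 12-6 (+ Coulomb) energy of one atom pair, kcal/mol."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    rc = potential.cutoff
    if r >= rc:
        return 0.0
    eps, rm = potential.mixed(el_i, el_j)
    x6 = (rm / r) ** 6
    xc6 = (rm / rc) ** 6
    e = eps * (x6 * x6 - 2.0 * x6) - eps * (xc6 * xc6 - 2.0 * xc6)
    if potential.coulomb and q_i != 0.0 and q_j != 0.0:
        e += COULOMB_KCAL * q_i * q_j / potential.dielectric * (1.0 / r - 1.0 / rc)
    return e


def _pair_energy_matrix(elems_a, q_a, cart_a, elems_b, q_b, cart_b,
                        potential: PotentialParams) -> float:
    """Vectorized Σ pair_energy over all (a, b) atom pairs."""
    d = np.linalg.norm(cart_a[:, None, :] - cart_b[None, :, :], axis=-1)
    if d.size and d.min() < OVERLAP_TOL:
        i, j = np.unravel_index(int(d.argmin()), d.shape)
        raise ValueError(
            f"overlapping atoms: {elems_a[i]}–{elems_b[j]} at {d[i, j]:.3f} Å"
        )
    rc = potential.cutoff
    mask = d < rc
    e = 0.0
    eps = np.empty(d.shape)
    rm = np.empty(d.shape)
    for i, ei in enumerate(elems_a):
        for j, ej in enumerate(elems_b):
            eps[i, j], rm[i, j] = potential.mixed(ei, ej)
    with np.errstate(divide="ignore"):
        x6 = np.where(mask, (rm / np.where(mask, d, 1.0)) ** 6, 0.0)
    xc6 = (rm / rc) ** 6
    elj = eps * ((x6 * x6 - 2 * x6) - (xc6 * xc6 - 2 * xc6))
    e += float(elj[mask].sum())
    if potential.coulomb:
        qq = np.outer(q_a, q_b)
        if np.any(qq != 0):
            ec = COULOMB_KCAL * qq / potential.dielectric * (1.0 / np.where(mask, d, 1.0) - 1.0 / rc)
            e += float(ec[mask].sum())
    return e


def _independent_unit_indices(units: list[MolecularUnit], sites) -> list[int]:
    """One representative unit per symmetry-independent molecule.

    Units are grouped by the multiset of asymmetric-unit atom indices they
    contain; with Z′ independent molecules this yields Z′ groups.
    """
    groups: dict[frozenset, int] = {}
    for ui, u in enumerate(units):
        key = frozenset(sites[i].asym_index for i in u.indices)
        groups.setdefault(key, ui)
    return sorted(groups.values())


def _image_shifts(structure: CrystalStructure, potential: PotentialParams,
                  extent: float) -> np.ndarray:
    """Lattice translations guaranteed to cover the cutoff sphere."""
    cell = structure.cell
    rec = cell.reciprocal_vectors
    widths = 1.0 / np.linalg.norm(rec, axis=1)  # perpendicular cell widths
    nmax = np.ceil((potential.cutoff + extent) / widths).astype(int)
    ranges = [np.arange(-n, n + 1) for n in nmax]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid


class LatticeSums:
    """Cached cell expansion used by both the cohesive and the face sums."""

    def __init__(self, structure: CrystalStructure, potential: PotentialParams):
        self.structure = structure
        self.potential = potential
        self.sites = expand_symmetry(structure)
        self.units = identify_molecules(self.sites, structure.cell)
        if not self.units:
            raise ValueError("no molecular units found")
        self.ref_indices = _independent_unit_indices(self.units, self.sites)
        extent = max(
            float(np.linalg.norm(u.cart - u.centroid, axis=1).max()) for u in self.units
        )
        self.shifts = _image_shifts(structure, potential, 2 * extent)
        self.M = structure.cell.frac_to_cart

    def interactions(self, unit_index: int) -> list[tuple[np.ndarray, float]]:
        """Cached (Δcentroid, pair energy) over all partner images of one unit."""
        if not hasattr(self, "_cache"):
            self._cache: dict[int, list[tuple[np.ndarray, float]]] = {}
        if unit_index in self._cache:
            return self._cache[unit_index]
        pot = self.potential
        ref = self.units[unit_index]
        reach = pot.cutoff + 2 * max(
            float(np.linalg.norm(u.cart - u.centroid, axis=1).max() + 1e-9) for u in self.units
        )
        out: list[tuple[np.ndarray, float]] = []
        for unit in self.units:
            base_delta = unit.centroid - ref.centroid
            for s in self.shifts:
                if unit is ref and not s.any():
                    continue
                t = self.M @ s.astype(float)
                dc = base_delta + t
                if np.linalg.norm(dc) > reach:
                    continue
                e = _pair_energy_matrix(
                    ref.elements, ref.charges, ref.cart,
                    unit.elements, unit.charges, unit.cart + t, pot,
                )
                if e != 0.0:
                    out.append((dc, e))
        self._cache[unit_index] = out
        return out

    def _unit_interaction(self, ref_index: int, partition=None):
        """Σ over partner images; ``partition(Δcentroid)`` buckets each term."""
        buckets: dict = {}
        for dc, e in self.interactions(ref_index):
            key = partition(dc) if partition else "total"
            buckets[key] = buckets.get(key, 0.0) + e
        return buckets


def cohesive_energy(structure: CrystalStructure, potential: PotentialParams,
                    sums: LatticeSums | None = None) -> float:
    """E_cr per growth unit: half the reference–environment pair-energy sum,
    averaged over the symmetry-independent molecules."""
    sums = sums or LatticeSums(structure, potential)
    vals = []
    for ui in sums.ref_indices:
        total = sums._unit_interaction(ui).get("total", 0.0)
        vals.append(0.5 * total)
    return float(np.mean(vals))


def slice_and_attachment_energy(structure: CrystalStructure, potential: PotentialParams,
                                form: FaceForm, sums: LatticeSums | None = None
                                ) -> FaceEnergyRecord:
    """Partition E_cr into slice and attachment parts for one face form.

    A partner molecule belongs to the reference slab when the fractional
    projection of its centroid offset on the face normal is within half a
    d-spacing (the d_hkl-thick slab centered on the reference molecule).
    """
    if form.d_hkl < 0.8:
        raise ValueError(f"form {form.hkl} has d_hkl {form.d_hkl:.3f} Å below the 0.8 Å resolution")
    sums = sums or LatticeSums(structure, potential)
    g = reciprocal_vector(structure.cell, form.hkl)  # |g| = 1/d

    def partition(dc: np.ndarray) -> str:
        return "slice" if abs(float(g @ dc)) < 0.5 else "att"

    e_slice_vals, e_att_vals = [], []
    for ui in sums.ref_indices:
        buckets = sums._unit_interaction(ui, partition)
        e_slice_vals.append(0.5 * buckets.get("slice", 0.0))
        e_att_vals.append(0.5 * buckets.get("att", 0.0))
    e_slice = float(np.mean(e_slice_vals))
    e_att = float(np.mean(e_att_vals))
    return FaceEnergyRecord(form=form, e_slice=e_slice, e_att=e_att, e_cr=e_slice + e_att)
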