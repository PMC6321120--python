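"""Grid-based packing coefficient and solvent-accessible void search.

The Kitaigorodskii-style packing index is the fraction of unit-cell volume
covered by the atoms' van der Waals spheres (periodic images included),
estimated on a regular fractional grid.  The void search marks the grid
points farther than r_vdW + probe from every atom and clusters them into
periodic connected components; with the conventional 1.2 Å probe a dense
molecular crystal reports no voids.

Both numbers are grid estimates: quoted with the grid spacing, converging
as the grid is refined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .elements import VDW_RADII
from .structure_io import CrystalStructure, expand_symmetry


@dataclass
class PackingConfig:
    """Grid spacing and probe radius (Å), both per the conventional settings."""

    grid: float = 0.20
    probe: float = 1.20
    radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))

    def __post_init__(self) -> None:
        if self.grid <= 0:
            raise ValueError("grid spacing must be positive")
        if self.probe < 0:
            raise ValueError("probe radius must be non-negative")


@dataclass
class Void:
    volume: float
    centroid_frac: tuple[float, float, float]
    n_points: int


@dataclass
class PackingResult:
    packing_coefficient: float
    cell_volume: float
    occupied_volume: float
    grid_shape: tuple[int, int, int]
    grid: float
    void_volume: float = 0.0
    voids: list[Void] = field(default_factory=list)

    @property
    def void_count(self) -> int:
        return len(self.voids)


def _occupancy_mask(structure: CrystalStructure, config: PackingConfig,
                    inflate: float = 0.0) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Boolean grid over the cell: True where inside an (inflated) vdW sphere."""
    cell = structure.cell
    M = cell.frac_to_cart
    rec = cell.reciprocal_vectors
    widths = 1.0 / np.linalg.norm(rec, axis=1)          # perpendicular cell widths
    shape = tuple(max(2, int(round(w / config.grid))) for w in widths)
    sites = expand_symmetry(structure)
    for s in sites:
        if s.element not in config.radii:
            raise KeyError(f"no van der Waals radius configured for element {s.element!r}")
    mask = np.zeros(shape, dtype=bool)
    axes = [np.arange(n) / n for n in shape]
    for s in sites:
        r = config.radii[s.element] + inflate
        frac = np.array(s.frac)
        # fractional half-extents of the sphere's bounding box along each axis
        ext = [r / w for w in widths]
        idx_ranges = []
        for ax in range(3):
            n = shape[ax]
            lo = int(np.floor((frac[ax] - ext[ax]) * n)) - 1
            hi = int(np.ceil((frac[ax] + ext[ax]) * n)) + 1
            idx_ranges.append(np.arange(lo, hi + 1))
        ii, jj, kk = np.meshgrid(*idx_ranges, indexing="ij")
        pts = np.stack([ii / shape[0], jj / shape[1], kk / shape[2]], axis=-1)
        delta = pts - frac
        cart = delta @ M.T
        inside = (cart**2).sum(axis=-1) <= r * r
        wi, wj, wk = ii[inside] % shape[0], jj[inside] % shape[1], kk[inside] % shape[2]
        mask[wi, wj, wk] = True
    return mask, shape


def packing_coefficient(structure: CrystalStructure, config: PackingConfig | None = None
                        ) -> PackingResult:
    """Fraction of cell volume inside the raw van der Waals envelope."""
    config = config or PackingConfig()
    mask, shape = _occupancy_mask(structure, config, inflate=0.0)
    vol = structure.cell.volume
    frac_occ = float(mask.sum()) / mask.size
    return PackingResult(
        packing_coefficient=frac_occ,
        cell_volume=vol,
        occupied_volume=frac_occ * vol,
        grid_shape=shape,
        grid=config.grid,
    )


def _periodic_label(free: np.ndarray) -> np.ndarray:
    """6-connected component labels with periodic wrap on all three axes."""
    labels, n = ndimage.label(free)
    if n == 0:
        return labels
    # merge labels touching across each periodic boundary
    parent = list(range(n + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for ax in range(3):
        lo = np.take(labels, 0, axis=ax)
        hi = np.take(labels, -1, axis=ax)
        both = (lo > 0) & (hi > 0)
        for a, b in zip(lo[both].ravel(), hi[both].ravel()):
            union(int(a), int(b))
    remap = np.array([find(x) for x in range(n + 1)])
    return remap[labels]


def find_voids(structure: CrystalStructure, config: PackingConfig | None = None
               ) -> PackingResult:
    """Probe-accessible void clusters: grid points outside every inflated sphere."""
    config = config or PackingConfig()
    blocked, shape = _occupancy_mask(structure, config, inflate=config.probe)
    vol = structure.cell.volume
    free = ~blocked
    point_vol = vol / free.size
    labels = _periodic_label(free)
    voids: list[Void] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = labels == lab
        npts = int(sel.sum())
        idx = np.argwhere(sel)
        centroid = tuple(float(c) for c in (idx.mean(axis=0) + 0.5) / np.array(shape))
        voids.append(Void(volume=npts * point_vol, centroid_frac=centroid, n_points=npts))
    voids.sort(key=lambda v: -v.volume)
    occ_mask, _ = _occupancy_mask(structure, config, inflate=0.0)
    frac_occ = float(occ_mask.sum()) / occ_mask.size
    return PackingResult(
        packing_coefficient=frac_occ,
        cell_volume=vol,
        occupied_volume=frac_occ * vol,
        grid_shape=shape,
        grid=config.grid,
        void_volume=sum(v.volume for v in voids),
        voids=voids,
    )
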