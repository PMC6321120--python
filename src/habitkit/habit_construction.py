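"""Growth-morphology construction.

The attachment-energy model of crystal habit: a face's linear growth rate is
taken proportional to the magnitude of its attachment energy, so in the
steady-state shape the center-to-face distance of each form scales with
|E_att|.  The habit is then the intersection of the half-spaces
{x : n̂_f · x ≤ h_f} over all symmetry-equivalent faces of every form,
with plane normals along the reciprocal-lattice vectors h·a* + k·b* + l·c*.
The geometric BFDH variant replaces |E_att| by 1/d_hkl.

Facet areas are reported per form as a percentage of the total surface
(the TFA table); shapes are scale-free, normalized to unit maximum distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, HalfspaceIntersection

from .lattice_geometry import FaceForm, MillerIndex, reciprocal_vector
from .structure_io import CellParameters

#: Relative tolerance for vertex deduplication and facet-plane matching.
PLANE_TOL = 1e-8


@dataclass
class GrowthInput:
    """Per-form growth driver: attachment energies or custom distances."""

    forms: list[FaceForm]
    e_att: list[float]
    source: str = "computed"  # or "user-supplied"

    def __post_init__(self) -> None:
        if len(self.forms) != len(self.e_att):
            raise ValueError("one energy per form required")
        signs = {e > 0 for e in self.e_att if e != 0}
        if 0.0 in self.e_att or len(signs) > 1:
            raise ValueError("attachment energies must be nonzero and share one sign")


@dataclass
class FacetSet:
    """Expanded half-space set: one entry per symmetry-equivalent face."""

    normals: np.ndarray            # (n, 3) unit outward normals
    distances: np.ndarray          # (n,) center-to-plane distances, max = 1
    face_hkl: list[MillerIndex]    # per half-space
    form_index: np.ndarray         # per half-space, into the source form list
    forms: list[FaceForm]


@dataclass
class HabitPolyhedron:
    """Closed convex growth polyhedron with per-form facet areas."""

    vertices: np.ndarray                       # (m, 3) Cartesian, unit max distance
    facets: list[dict] = field(default_factory=list)
    forms: list[FaceForm] = field(default_factory=list)
    form_areas: np.ndarray | None = None       # absolute areas per form

    @property
    def total_area(self) -> float:
        return float(self.form_areas.sum())

    @property
    def area_percent(self) -> np.ndarray:
        return 100.0 * self.form_areas / self.total_area

    @property
    def volume(self) -> float:
        return float(ConvexHull(self.vertices).volume)


def growth_distances(cell: CellParameters, growth: GrowthInput) -> FacetSet:
    """Center-to-face distances ∝ |E_att|, expanded over form equivalents.

    Distances are normalized so the fastest-growing face (largest |E_att|)
    sits at 1; the habit is scale-free so only ratios matter.
    """
    emax = max(abs(e) for e in growth.e_att)
    normals, dists, face_hkl, form_idx = [], [], [], []
    for fi, (form, e) in enumerate(zip(growth.forms, growth.e_att)):
        equivalents = form.equivalents or [form.hkl]
        for eq in equivalents:
            g = reciprocal_vector(cell, eq)
            normals.append(g / np.linalg.norm(g))
            dists.append(abs(e) / emax)
            face_hkl.append(eq)
            form_idx.append(fi)
    return FacetSet(
        normals=np.array(normals),
        distances=np.array(dists),
        face_hkl=face_hkl,
        form_index=np.array(form_idx),
        forms=list(growth.forms),
    )


def bfdh_distances(cell: CellParameters, forms: list[FaceForm]) -> FacetSet:
    """Geometric fallback: distance ∝ 1/d_hkl (large-spacing faces dominate)."""
    inv_d = [1.0 / f.d_hkl for f in forms]
    scale = max(inv_d)
    normals, dists, face_hkl, form_idx = [], [], [], []
    for fi, (form, dd) in enumerate(zip(forms, inv_d)):
        for eq in form.equivalents or [form.hkl]:
            g = reciprocal_vector(cell, eq)
            normals.append(g / np.linalg.norm(g))
            dists.append(dd / scale)
            face_hkl.append(eq)
            form_idx.append(fi)
    return FacetSet(
        normals=np.array(normals),
        distances=np.array(dists),
        face_hkl=face_hkl,
        form_index=np.array(form_idx),
        forms=list(forms),
    )


def _order_polygon(points: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Order coplanar points counterclockwise about the outward normal."""
    center = points.mean(axis=0)
    ref = points[0] - center
    ref /= np.linalg.norm(ref)
    perp = np.cross(normal, ref)
    ang = np.arctan2((points - center) @ perp, (points - center) @ ref)
    return points[np.argsort(ang)]


def _polygon_area(points: np.ndarray, normal: np.ndarray) -> float:
    ordered = _order_polygon(points, normal)
    s = np.zeros(3)
    for i in range(len(ordered)):
        s += np.cross(ordered[i], ordered[(i + 1) % len(ordered)])
    return abs(0.5 * float(s @ normal))


def wulff_polyhedron(facet_set: FacetSet) -> HabitPolyhedron:
    """Intersect the half-spaces into the closed growth polyhedron.

    Every input form stays in the report; forms whose planes never touch the
    hull get zero area (fully occluded).  Raises if the set is unbounded,
    naming an uncovered direction.
    """
    n = facet_set.normals
    d = facet_set.distances
    if len(n) < 4:
        raise ValueError("need at least 4 half-spaces for a bounded polyhedron")
    # bounded iff the normals positively span R³, i.e. the origin lies strictly
    # inside their convex hull
    try:
        hull_n = ConvexHull(n)
    except Exception:
        raise ValueError("half-space set unbounded: normals are coplanar or degenerate") from None
    worst = int(np.argmax(hull_n.equations[:, 3]))
    if hull_n.equations[worst, 3] > -1e-9:
        u = hull_n.equations[worst, :3]
        raise ValueError(
            f"half-space set unbounded: no face covers direction {np.round(u, 4)}"
        )
    hs = HalfspaceIntersection(np.hstack([n, -d[:, None]]), np.zeros(3))

    pts = hs.intersections
    # deduplicate vertices
    scale = np.max(np.abs(pts)) or 1.0
    keep: list[np.ndarray] = []
    for p in pts:
        if not any(np.linalg.norm(p - q) < 1e-8 * max(scale, 1.0) * 10 for q in keep):
            keep.append(p)
    vertices = np.array(keep)

    facets: list[dict] = []
    form_areas = np.zeros(len(facet_set.forms))
    for i in range(len(n)):
        on_plane = vertices[np.abs(vertices @ n[i] - d[i]) < 1e-7]
        area = 0.0
        poly = None
        if len(on_plane) >= 3:
            poly = _order_polygon(on_plane, n[i])
            area = _polygon_area(on_plane, n[i])
        facets.append(
            {
                "hkl": facet_set.face_hkl[i],
                "form": facet_set.forms[facet_set.form_index[i]],
                "normal": n[i],
                "distance": d[i],
                "area": area,
                "polygon": poly,
            }
        )
        form_areas[facet_set.form_index[i]] += area
    poly = HabitPolyhedron(
        vertices=vertices,
        facets=facets,
        forms=list(facet_set.forms),
        form_areas=form_areas,
    )
    if poly.total_area <= 0:
        raise ValueError("degenerate polyhedron: zero surface area")
    return poly


def facet_area_table(poly: HabitPolyhedron, e_att: list[float] | None = None) -> pd.DataFrame:
    """Per-form report (hkl, multiplicity, d_hkl, E_att, TFA %), TFA-sorted."""
    rows = []
    pct = poly.area_percent
    for i, form in enumerate(poly.forms):
        rows.append(
            {
                "hkl": str(form.hkl),
                "multiplicity": form.multiplicity,
                "d_hkl": form.d_hkl,
                "E_att": e_att[i] if e_att is not None else float("nan"),
                "tfa_percent": float(pct[i]),
            }
        )
    df = pd.DataFrame(rows).sort_values("tfa_percent", ascending=False, kind="stable")
    return df.reset_index(drop=True)


def export_off(poly: HabitPolyhedron) -> str:
    """OFF mesh text of the polyhedron (one polygon per visible facet)."""
    verts = [tuple(v) for v in poly.vertices]
    faces = []
    for f in poly.facets:
        if f["polygon"] is None:
            continue
        idx = []
        for p in f["polygon"]:
            for vi, v in enumerate(verts):
                if np.linalg.norm(np.array(v) - p) < 1e-9:
                    idx.append(vi)
                    break
        faces.append(idx)
    lines = ["OFF", f"{len(verts)} {len(faces)} 0"]
    lines += [f"{v[0]:.8f} {v[1]:.8f} {v[2]:.8f}" for v in verts]
    lines += [" ".join([str(len(f))] + [str(i) for i in f]) for f in faces]
    return "\n".join(lines) + "\n"
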