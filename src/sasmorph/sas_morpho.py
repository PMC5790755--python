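"""Apposition-surface extraction and per-synapse morphometry.

The synaptic apposition surface (SAS) is the single open surface standing in
for the presynaptic density / PSD pair.  It is extracted from a segmented
junction as a triangle mesh and measured: surface area, outer-perimeter
length, projected area on the best-fit plane, the curvature statistic
``1 - projected_area / area`` (0 for a flat surface), the Feret diameter
(minimal enclosing sphere), and shrinkage-corrected versions of all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from . import meshing
from .errors import (DegenerateGeometryError, TruncatedSegmentError,
                     ValidationError)
from .segment import JunctionSegment
from .stack import VoxelStack


@dataclass
class SASMesh:
    """Triangle mesh with boundary representing one apposition surface."""

    vertices: np.ndarray          # (N, 3) nm
    triangles: np.ndarray         # (M, 3) vertex indices
    boundary_loops: list[np.ndarray] = field(default_factory=list)
    source_segment: int | str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.intp)
        if not self.boundary_loops:
            self.boundary_loops = meshing.boundary_loops(self.triangles)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.triangles,
                               process=False)

    def to_ply(self, path) -> None:
        self.as_trimesh().export(str(path), encoding="ascii")

    @classmethod
    def from_ply(cls, path, source_segment="") -> "SASMesh":
        tm = trimesh.load_mesh(str(path), process=False)
        return cls(vertices=np.asarray(tm.vertices),
                   triangles=np.asarray(tm.faces),
                   source_segment=source_segment)


@dataclass
class MorphoRecord:
    """Per-synapse measurements."""

    area_nm2: float
    perimeter_nm: float
    projected_area_nm2: float
    curvature: float
    feret_nm: float
    n_perforations: int = 0
    perforation_rim_nm: float = 0.0
    shape_class: str | None = None
    synapse_type: str | None = None
    layer_label: str = ""
    target_label: str = ""
    volume_nm3: float = float("nan")
    corrected: bool = False


@dataclass(frozen=True)
class ShrinkageFactors:
    """Tissue-shrinkage correction factors (volume, surface, linear).

    Processing for EM shrinks the tissue; measured quantities are divided by
    the corresponding factor to recover pre-shrinkage values.  The defaults
    are mutually consistent: surface = linear^2 and volume = linear^3 up to
    rounding.
    """

    volume: float = 0.73
    surface: float = 0.81
    linear: float = 0.90


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _interface_points(segment: JunctionSegment) -> tuple[np.ndarray, np.ndarray]:
    """Centers of voxel faces separating post-side and pre-side sublabels.

    Returns (points, weights): a face center is quantized to half the voxel
    step along its axis, so faces across the coarse sectioning axis carry
    proportionally less weight in the height estimate.
    """
    v = segment.voxels
    sub = segment.sublabels
    zmin, ymin, xmin = v.min(axis=0)
    zmax, ymax, xmax = v.max(axis=0)
    shape = (zmax - zmin + 1, ymax - ymin + 1, xmax - xmin + 1)
    code = np.zeros(shape, dtype=np.uint8)
    code[v[:, 0] - zmin, v[:, 1] - ymin, v[:, 2] - xmin] = sub
    vx, vy, vz = segment.voxel_size_nm
    steps = (vz, vy, vx)   # physical step along axes (z, y, x)
    pts = []
    wts = []
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        a, b = code[tuple(lo)], code[tuple(hi)]
        pair = ((a == 1) & (b == 2)) | ((a == 2) & (b == 1))
        if not pair.any():
            continue
        zz, yy, xx = np.nonzero(pair)
        center = np.column_stack([
            (xx + xmin) + (0.5 if axis == 2 else 0.0),
            (yy + ymin) + (0.5 if axis == 1 else 0.0),
            (zz + zmin) + (0.5 if axis == 0 else 0.0),
        ]).astype(float)
        center[:, 0] *= vx
        center[:, 1] *= vy
        center[:, 2] *= vz
        pts.append(center)
        wts.append(np.full(len(center), 1.0 / steps[axis] ** 2))
    if not pts:
        return np.zeros((0, 3)), np.zeros(0)
    return np.concatenate(pts, axis=0), np.concatenate(wts)


def extract_sas(
    segment: JunctionSegment,
    stack: VoxelStack,
    *,
    grid_nm: float | None = None,
    fill_hole_area_nm2: float = 1000.0,
) -> SASMesh:
    """Extract the apposition surface of a non-truncated junction segment.

    When per-voxel pre/post sublabels are available the mesh follows the
    dual surface of the voxel faces separating the two sides (this is exact
    up to half a voxel).  Otherwise the segment is collapsed to its medial
    sheet along the minor principal axis.  Either way the resulting point
    cloud is meshed as a smoothed height field.
    """
    if segment.truncated:
        raise TruncatedSegmentError(
            f"segment {segment.segment_id} touches the stack border; "
            "its apposition surface cannot be extracted")
    if segment.n_voxels < 4:
        raise DegenerateGeometryError("segment too small for a surface")

    have_sub = (segment.sublabels is not None
                and (segment.sublabels == 1).any()
                and (segment.sublabels == 2).any())
    section_step = max(stack.voxel_size_nm)
    if have_sub:
        pts, weights = _interface_points(segment)
        if grid_nm is None:
            grid_nm = 6.0
        mode = "mean"
    else:
        pts = segment.physical_coords()
        weights = None
        if grid_nm is None:
            grid_nm = min(stack.voxel_size_nm) * 2.2
        mode = "midrange"
    if len(pts) < 6:
        raise DegenerateGeometryError(
            "segment thinner than one voxel everywhere; no interface found")
    verts, faces = meshing.heightfield_mesh(
        pts, grid_nm=grid_nm, weights=weights, section_step_nm=section_step,
        mid_mode=mode, fill_hole_area_nm2=fill_hole_area_nm2)
    return SASMesh(vertices=verts, triangles=faces,
                   source_segment=segment.segment_id)


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def mesh_area(mesh: SASMesh) -> float:
    """Total triangle area in nm^2."""
    if len(mesh.triangles) == 0:
        raise ValidationError("empty mesh")
    v = mesh.vertices
    t = mesh.triangles
    cr = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    return float(0.5 * np.linalg.norm(cr, axis=1).sum())


def boundary_lengths(mesh: SASMesh, simplify_tol_nm: float = 5.0) -> list[float]:
    """Lengths of all boundary loops, longest first, after staircase removal."""
    if not mesh.boundary_loops:
        raise ValidationError("mesh has no boundary; an apposition surface "
                              "is an open surface")
    lengths = []
    for loop in mesh.boundary_loops:
        p = meshing.clean_loop(mesh.vertices[loop], simplify_tol_nm)
        lengths.append(meshing.polyline_length(p, closed=True))
    lengths.sort(reverse=True)
    return lengths


def mesh_perimeter(mesh: SASMesh, simplify_tol_nm: float = 5.0) -> float:
    """Length of the longest boundary loop (the outer outline) in nm.

    Perforation rims are reported separately via :func:`boundary_lengths`.
    """
    return boundary_lengths(mesh, simplify_tol_nm)[0]


def _plane_fit(mesh: SASMesh):
    """Area-weighted least-squares plane through triangle centroids.

    Returns (point_on_plane, normal, triangle_areas, centroids).
    """
    v, t = mesh.vertices, mesh.triangles
    if len(t) == 0:
        raise ValidationError("empty mesh")
    cent = v[t].mean(axis=1)
    cr = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    areas = 0.5 * np.linalg.norm(cr, axis=1)
    wsum = areas.sum()
    if wsum <= 0:
        raise ValidationError("zero-area mesh")
    c0 = (cent * areas[:, None]).sum(axis=0) / wsum
    d = cent - c0
    cov = (d * areas[:, None]).T @ d
    w_, v_ = np.linalg.eigh(cov)
    normal = v_[:, 0]
    return c0, normal, areas, cr


def projected_area(mesh: SASMesh) -> tuple[float, np.ndarray, np.ndarray]:
    """Unsigned area of the mesh projected on its best-fit plane.

    Returns (projected_area, plane_point, plane_normal).
    """
    c0, normal, _, cr = _plane_fit(mesh)
    proj = float(0.5 * np.abs(cr @ normal).sum())
    return proj, c0, normal


def curvature(mesh: SASMesh) -> float:
    """Curvature statistic: one minus projected area over surface area.

    0 for a perfectly flat surface, growing toward 1 as the surface bends
    away from its best-fit plane.  The projection plane is the area-weighted
    least-squares plane, which makes the statistic orientation-invariant.
    """
    area = mesh_area(mesh)
    proj, _, _ = projected_area(mesh)
    return float(np.clip(1.0 - proj / area, 0.0, 1.0 - 1e-12))


def feret_diameter(mesh: SASMesh) -> float:
    """Diameter of the smallest sphere circumscribing the mesh.

    The minimal enclosing sphere is governed entirely by extreme points, so
    single jittery rim vertices would bias it outward; the boundary loops
    are therefore denoised before the sphere is computed, while interior
    vertices enter as they are.
    """
    if mesh.n_vertices == 0:
        raise ValidationError("empty mesh")
    if mesh.n_vertices == 1:
        return 0.0
    if mesh.boundary_loops:
        on_boundary = np.zeros(mesh.n_vertices, dtype=bool)
        parts = []
        for loop in mesh.boundary_loops:
            on_boundary[loop] = True
            parts.append(meshing.clean_loop(mesh.vertices[loop], 0.0))
        parts.append(mesh.vertices[~on_boundary])
        pts = np.concatenate([p for p in parts if len(p)], axis=0)
    else:
        pts = mesh.vertices
    _, r = meshing.min_enclosing_sphere(pts)
    return 2.0 * r


def measure(
    mesh: SASMesh,
    *,
    synapse_type: str | None = None,
    layer_label: str = "",
    target_label: str = "",
    volume_nm3: float = float("nan"),
    simplify_tol_nm: float = 5.0,
) -> MorphoRecord:
    """Full uncorrected morphometry of one apposition surface."""
    area = mesh_area(mesh)
    proj, _, _ = projected_area(mesh)
    lengths = boundary_lengths(mesh, simplify_tol_nm)
    return MorphoRecord(
        area_nm2=area,
        perimeter_nm=lengths[0],
        projected_area_nm2=proj,
        curvature=float(np.clip(1.0 - proj / area, 0.0, 1.0 - 1e-12)),
        feret_nm=feret_diameter(mesh),
        n_perforations=max(0, len(lengths) - 1),
        perforation_rim_nm=float(sum(lengths[1:])),
        synapse_type=synapse_type,
        layer_label=layer_label,
        target_label=target_label,
        volume_nm3=volume_nm3,
    )


def shrinkage_correct(
    record: MorphoRecord,
    factors: ShrinkageFactors = ShrinkageFactors(),
) -> MorphoRecord:
    """Correct a record for tissue shrinkage.

    Areas are divided by the surface factor, lengths by the linear factor and
    volumes by the volume factor; the curvature is a ratio of areas and is
    unchanged.  Correcting twice is refused.
    """
    if record.corrected:
        raise ValidationError("record is already shrinkage-corrected")
    return replace(
        record,
        area_nm2=record.area_nm2 / factors.surface,
        projected_area_nm2=record.projected_area_nm2 / factors.surface,
        perimeter_nm=record.perimeter_nm / factors.linear,
        perforation_rim_nm=record.perforation_rim_nm / factors.linear,
        feret_nm=record.feret_nm / factors.linear,
        volume_nm3=record.volume_nm3 / factors.volume,
        corrected=True,
    )
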