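"""Macular / perforated / horseshoe classification of apposition surfaces.

The three classes are separated by mesh topology and outline geometry:
perforated surfaces carry one or more holes (Euler characteristic below 1),
horseshoe surfaces have a deep indentation of their outer outline, and
everything else is macular (a plain disc).  Perforation takes precedence
over indentation, matching the field's convention that the classes are
mutually exclusive with perforation defined by holes in the PSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint, Point

from . import meshing
from .errors import ValidationError
from .sas_morpho import SASMesh, mesh_area, projected_area

DEFAULT_HORSESHOE_THRESHOLD = 0.5


@dataclass
class ShapeReport:
    shape_class: str
    n_holes: int
    euler_characteristic: int
    indentation_depth_frac: float
    tortuosity: float


def count_perforations(mesh: SASMesh) -> tuple[int, int]:
    """Number of holes and Euler characteristic of a single-component mesh.

    chi = V - E + F; a genus-0 surface with b boundary loops has
    chi = 2 - 2*0 - b, so holes = 1 - chi (a disc has chi = 1, an annulus 0).
    """
    faces = mesh.triangles
    if len(faces) == 0:
        raise ValidationError("empty mesh")
    _assert_single_component(mesh)
    vset = np.unique(faces)
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    n_edges = len(np.unique(e, axis=0))
    chi = len(vset) - n_edges + len(faces)
    return max(0, 1 - chi), chi


def _assert_single_component(mesh: SASMesh) -> None:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    nf = len(mesh.triangles)
    rows = np.repeat(np.arange(nf), 3)
    cols = mesh.triangles.ravel()
    m = coo_matrix((np.ones(3 * nf), (rows, cols)),
                   shape=(nf, mesh.n_vertices)).tocsr()
    ncomp, _ = connected_components(m @ m.T, directed=False)
    if ncomp > 1:
        raise ValidationError(
            "multi-component mesh: fragmented surfaces are outside the "
            "macular/perforated/horseshoe taxonomy")


def indentation_depth(mesh: SASMesh, simplify_tol_nm: float = 5.0) -> float:
    """Depth of the deepest outline indentation, as a fraction of the
    equivalent radius of the projected surface.

    The outer boundary loop is projected on the best-fit plane; the depth is
    the maximum distance from the outline to its 2D convex hull, divided by
    sqrt(projected_area / pi).  Convex outlines score 0.
    """
    if not mesh.boundary_loops:
        raise ValidationError("mesh has no boundary loop")
    proj, c0, normal = projected_area(mesh)
    if proj <= 0:
        raise ValidationError("zero projected area")
    r_eq = float(np.sqrt(proj / np.pi))
    # 2D coordinates of the (simplified) outer loop in the plane
    loop = mesh.vertices[mesh.boundary_loops[0]]
    loop = meshing.clean_loop(loop, simplify_tol_nm)
    b = np.array([1.0, 0.0, 0.0])
    if abs(normal[0]) > 0.9:
        b = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, b)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    d = loop - c0
    pts2 = np.column_stack([d @ e1, d @ e2])
    hull = MultiPoint([tuple(p) for p in pts2]).convex_hull
    if hull.geom_type != "Polygon":
        return 0.0
    ring = hull.exterior
    depth = max(ring.distance(Point(tuple(p))) for p in pts2)
    return float(depth / r_eq)


def classify_shape(
    mesh: SASMesh,
    *,
    horseshoe_threshold: float = DEFAULT_HORSESHOE_THRESHOLD,
) -> ShapeReport:
    """Classify an apposition surface as macular, perforated or horseshoe.

    Perforated if the mesh has >= 1 hole; otherwise horseshoe if the outline
    indentation depth reaches ``horseshoe_threshold`` of the equivalent
    radius; otherwise macular.  Any mesh with a hole is never horseshoe,
    regardless of indentation.
    """
    n_holes, chi = count_perforations(mesh)
    area = mesh_area(mesh)
    from .sas_morpho import mesh_perimeter
    perim = mesh_perimeter(mesh)
    tort = float(perim / (2 * np.sqrt(np.pi * area)))
    depth = indentation_depth(mesh)
    if n_holes >= 1:
        cls = "perforated"
    elif depth >= horseshoe_threshold:
        cls = "horseshoe"
    else:
        cls = "macular"
    return ShapeReport(
        shape_class=cls,
        n_holes=n_holes,
        euler_characteristic=chi,
        indentation_depth_frac=depth,
        tortuosity=tort,
    )
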