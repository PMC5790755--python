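"""Low-level mesh machinery for apposition-surface extraction.

The extraction problem is always the same: a cloud of points known to lie on
(or close to) a gently curved, open sheet embedded in 3D, from which we need
a clean triangle mesh whose area, outline and topology (holes) are faithful.
The approach is a *height field*: project the points onto the sheet's
principal plane, bin them on a regular 2D grid, average the height per cell
with a masked smoothing filter, and triangulate occupied cells.  Because the
mesh is a piecewise-linear graph over the plane, its area and projection are
unbiased, holes in the sheet appear as unoccupied grid regions, and the open
boundary follows the data at grid resolution.

Also here: boundary-loop extraction, Douglas-Peucker polyline simplification
(used to measure outline length without staircase inflation), analytic
spherical-cap meshes for oracles, and an exact minimal enclosing sphere
(Welzl's randomized incremental algorithm) for the Feret diameter.
"""

from __future__ import annotations

import sys

import numpy as np
from scipy import ndimage

from .errors import DegenerateGeometryError


# ---------------------------------------------------------------------------
# principal frame
# ---------------------------------------------------------------------------

def principal_frame(points: np.ndarray):
    """Centroid and orthonormal axes (e1, e2, n) of a point cloud.

    ``n`` is the minor axis (sheet normal).  The in-plane axes are rotated so
    that ``e1`` is horizontal (no z component): sampling along e1 is then set
    by the fine in-plane pixel size while ``e2`` absorbs the coarse section
    step, letting the binning grid adapt to the anisotropy.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points for a frame")
    c = pts.mean(axis=0)
    # SVD of the centered cloud; right singular vectors ordered by variance
    _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
    n = vt[2]
    zhat = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(n, zhat)
    nrm = np.linalg.norm(e1)
    if nrm < 1e-8:           # normal along z: any horizontal pair will do
        e1 = np.array([1.0, 0.0, 0.0])
    else:
        e1 = e1 / nrm
    e2 = np.cross(n, e1)
    return c, e1, e2, n


# ---------------------------------------------------------------------------
# height-field meshing
# ---------------------------------------------------------------------------

def _masked_smooth(h: np.ndarray, mask: np.ndarray, cell_weight: np.ndarray,
                   size: int, passes: int) -> np.ndarray:
    """Local-quadratic (Savitzky-Golay) smoothing restricted to ``mask``.

    For each cell, the surface a + b*di + c*dj + d*di^2 + e*di*dj + f*dj^2
    is fitted (weighted by ``cell_weight``) over the masked cells of the
    surrounding window and evaluated at the cell itself.  A quadratic fit is
    unbiased on gently curved sheets even where the window is one-sided (at
    the rim), so neither steep edges nor dome curvature are flattened.
    Ill-conditioned windows fall back to the weighted windowed mean.
    """
    out = np.where(mask, h, 0.0)
    m = np.where(mask, cell_weight, 0.0)
    mmean = m[mask].mean() if mask.any() else 1.0
    m = m / max(mmean, 1e-12)

    half = size // 2
    scale = max(half, 1)
    off = (np.arange(size) - half) / scale      # normalized window offsets
    powers = [off ** p for p in range(5)]

    def moment(arr, p, q):
        t = ndimage.correlate1d(arr, powers[p], axis=0, mode="constant")
        return ndimage.correlate1d(t, powers[q], axis=1, mode="constant")

    # quadratic basis exponents: 1, i, j, i^2, i*j, j^2
    basis = [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)]
    nb = len(basis)
    for _ in range(passes):
        mh = m * out
        A = np.empty(h.shape + (nb, nb))
        rhs = np.empty(h.shape + (nb,))
        for r, (pr, qr) in enumerate(basis):
            rhs[..., r] = moment(mh, pr, qr)
            for s_, (ps, qs) in enumerate(basis):
                if s_ < r:
                    A[..., r, s_] = A[..., s_, r]
                else:
                    A[..., r, s_] = moment(m, pr + ps, qr + qs)
        # regularize ill-conditioned windows toward the windowed mean
        w0 = A[..., 0, 0]
        eps = 1e-8 * np.maximum(w0, 1e-12)[..., None]
        A[..., np.arange(nb), np.arange(nb)] += eps
        try:
            coef = np.linalg.solve(A, rhs[..., None])[..., 0, 0]
        except np.linalg.LinAlgError:
            coef = np.full(h.shape, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            meanfit = rhs[..., 0] / np.maximum(w0, 1e-12)
        bad = ~np.isfinite(coef)
        sm = np.where(bad, meanfit, coef)
        out = np.where(mask, sm, 0.0)
    try:
        sol = np.linalg.solve(A, rhs[..., None])[..., 0]
        dhdi = np.where(bad, 0.0, sol[..., 1] / scale)
        dhdj = np.where(bad, 0.0, sol[..., 2] / scale)
    except np.linalg.LinAlgError:
        dhdi = np.zeros_like(out)
        dhdj = np.zeros_like(out)
    return out, dhdi, dhdj


def _fill_small_holes(occ: np.ndarray, cell_area: float, max_hole_area: float):
    """Mark as occupied any interior hole smaller than ``max_hole_area``.

    Returns the updated occupancy and a mask of the filled cells.
    """
    filled = ndimage.binary_fill_holes(occ)
    holes = filled & ~occ
    if not holes.any():
        return occ, np.zeros_like(occ)
    lab, nlab = ndimage.label(holes)
    keep = np.zeros_like(occ)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
    for i, sz in enumerate(sizes, start=1):
        if sz * cell_area < max_hole_area:
            keep |= lab == i
    return occ | keep, keep


def heightfield_mesh(
    points: np.ndarray,
    grid_nm: float,
    *,
    weights: np.ndarray | None = None,
    section_step_nm: float | None = None,
    mid_mode: str = "mean",
    smooth_size: int = 7,
    smooth_passes: int = 3,
    fill_hole_area_nm2: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate a sheet-like point cloud.  Returns (vertices, faces).

    Parameters
    ----------
    grid_nm : base cell size of the 2D binning grid in nm (along e1, which
        is horizontal and therefore sampled at the in-plane pixel pitch).
    weights : optional per-point precision weights for the height estimate
        (points quantized by the coarse section step should weigh less).
    section_step_nm : physical section thickness; the cell size along e2 is
        widened to cover the projected section step so that tilted sheets do
        not fragment into stripes.
    mid_mode : how the per-cell height is estimated. ``"mean"`` for clouds
        already concentrated on the surface (interface face centers);
        ``"midrange"`` ((min+max)/2) for a full slab of voxel centers whose
        medial sheet is wanted.
    fill_hole_area_nm2 : interior holes smaller than this are treated as
        sampling dropouts and closed; larger ones survive as perforations.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 6:
        raise DegenerateGeometryError("too few points to mesh")
    c, e1, e2, n = principal_frame(pts)
    d = pts - c
    u, v, h = d @ e1, d @ e2, d @ n
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.mean()

    s1 = float(grid_nm)
    s2 = float(grid_nm)
    if section_step_nm is not None:
        s2 = max(s2, 1.1 * float(section_step_nm) * abs(float(e2[2])))
    iu = np.floor((u - u.min()) / s1).astype(np.intp)
    iv = np.floor((v - v.min()) / s2).astype(np.intp)
    nu, nv = iu.max() + 1, iv.max() + 1
    if nu * nv > 50_000_000:
        raise DegenerateGeometryError("grid too large; point cloud not sheet-like")

    cnt = np.zeros((nu, nv))
    su = np.zeros((nu, nv))
    sv = np.zeros((nu, nv))
    sw = np.zeros((nu, nv))
    np.add.at(cnt, (iu, iv), 1.0)
    np.add.at(su, (iu, iv), u)
    np.add.at(sv, (iu, iv), v)
    np.add.at(sw, (iu, iv), w)
    occ = cnt > 0

    if mid_mode == "midrange":
        hmin = np.full((nu, nv), np.inf)
        hmax = np.full((nu, nv), -np.inf)
        np.minimum.at(hmin, (iu, iv), h)
        np.maximum.at(hmax, (iu, iv), h)
        with np.errstate(invalid="ignore"):
            hcell = np.where(occ, 0.5 * (hmin + hmax), 0.0)
    else:
        sh = np.zeros((nu, nv))
        np.add.at(sh, (iu, iv), w * h)
        with np.errstate(invalid="ignore"):
            hcell = np.where(occ, sh / np.maximum(sw, 1e-12), 0.0)

    # keep the largest 8-connected patch of occupied cells
    lab, nlab = ndimage.label(occ, structure=np.ones((3, 3)))
    if nlab == 0:
        raise DegenerateGeometryError("empty occupancy grid")
    if nlab > 1:
        sizes = ndimage.sum_labels(occ, lab, index=np.arange(1, nlab + 1))
        occ = lab == (1 + int(np.argmax(sizes)))

    occ, filled = _fill_small_holes(occ, s1 * s2, fill_hole_area_nm2)

    # heights for filled cells: iterative neighbour averaging from known cells
    known = occ & (cnt > 0)
    hgrid = np.where(known, hcell, 0.0)
    todo = occ & ~known
    for _ in range(64):
        if not todo.any():
            break
        num = ndimage.uniform_filter(hgrid * known, size=3, mode="constant")
        den = ndimage.uniform_filter(known.astype(float), size=3, mode="constant")
        reach = todo & (den > 1e-12)
        with np.errstate(invalid="ignore", divide="ignore"):
            hgrid = np.where(reach, num / den, hgrid)
        known = known | reach
        todo = todo & ~reach

    cell_w = np.where(occ, np.where(cnt > 0, sw, np.median(w)), 0.0)
    hgrid, dhdi, dhdj = _masked_smooth(hgrid, occ, cell_w, smooth_size,
                                       smooth_passes)

    # vertex positions: centroid of the member points in-plane (cell center
    # for synthesised hole-fill cells), smoothed height out-of-plane
    gi, gj = np.nonzero(occ)
    vid = -np.ones((nu, nv), dtype=np.intp)
    vid[gi, gj] = np.arange(gi.size)
    has_pts = cnt[gi, gj] > 0
    cu = np.where(has_pts, su[gi, gj] / np.maximum(cnt[gi, gj], 1),
                  u.min() + (gi + 0.5) * s1)
    cv = np.where(has_pts, sv[gi, gj] / np.maximum(cnt[gi, gj], 1),
                  v.min() + (gj + 0.5) * s2)
    ch = hgrid[gi, gj]

    # triangulate 2x2 cell blocks
    a = vid[:-1, :-1]
    b = vid[1:, :-1]
    cc = vid[:-1, 1:]
    dd = vid[1:, 1:]
    npresent = (a >= 0).astype(int) + (b >= 0).astype(int) \
        + (cc >= 0).astype(int) + (dd >= 0).astype(int)
    faces = []
    full = npresent == 4
    if full.any():
        A, B, C, D = a[full], b[full], cc[full], dd[full]
        faces.append(np.column_stack([A, B, D]))
        faces.append(np.column_stack([A, D, C]))
    tri = npresent == 3
    if tri.any():
        A, B, C, D = a[tri], b[tri], cc[tri], dd[tri]
        quads = np.stack([A, B, D, C], axis=1)   # cyclic order around the block
        miss = np.argmin(quads, axis=1)          # index of the -1 entry
        out = np.empty((quads.shape[0], 3), dtype=np.intp)
        for k in range(4):
            sel = miss == k
            if sel.any():
                out[sel] = quads[sel][:, [(k + 1) % 4, (k + 2) % 4, (k + 3) % 4]]
        faces.append(out)
    if not faces:
        raise DegenerateGeometryError("no triangles; sheet thinner than the grid")
    faces = np.concatenate(faces, axis=0)

    # extend boundary vertices outward to the supporting extreme of the data
    # in the surrounding 3x3 cell neighbourhood: cell centroids stop half a
    # cell short of the data rim (a full cell where the outermost sparse
    # cells did not triangulate), which on a small surface loses several
    # percent of area; the height is carried along the local gradient
    uv = np.column_stack([cu, cv])
    flat_pts = iu * nv + iv
    order = np.argsort(flat_pts, kind="stable")
    sorted_cells = flat_pts[order]
    step_cap = 2.2 * max(s1, s2)
    for loop in boundary_loops(faces):
        p = uv[loop]
        tang = np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)
        outward = np.column_stack([tang[:, 1], -tang[:, 0]])
        norms = np.linalg.norm(outward, axis=1)
        outward /= np.maximum(norms, 1e-12)[:, None]
        for k, vtx in enumerate(loop):
            ci, cj = gi[vtx], gj[vtx]
            cand = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if not (0 <= ci + di < nu and 0 <= cj + dj < nv):
                        continue
                    cell = (ci + di) * nv + (cj + dj)
                    a = np.searchsorted(sorted_cells, cell, side="left")
                    b = np.searchsorted(sorted_cells, cell, side="right")
                    if b > a:
                        cand.append(order[a:b])
            if not cand:
                continue   # synthesized hole-fill cell region, no data points
            idx = np.concatenate(cand)
            rel_u = u[idx] - uv[vtx, 0]
            rel_v = v[idx] - uv[vtx, 1]
            d = rel_u * outward[k, 0] + rel_v * outward[k, 1]
            perp = rel_u * outward[k, 1] - rel_v * outward[k, 0]
            band = np.abs(perp) <= 0.75 * max(s1, s2)
            if not band.any():
                continue
            db = d[band]
            # the outermost sample sits on average half a sample spacing
            # inside the true rim; add that allowance, estimated from the
            # local point density along the outward direction
            if len(db) > 3:
                allowance = (db.max() - db.min()) / (len(db) - 1)
            else:
                allowance = 0.5 * s1
            step = float(np.clip(db.max() + allowance, 0.0, step_cap))
            uv[vtx] += step * outward[k]
            ch[vtx] += (dhdi[ci, cj] * step * outward[k, 0] / s1
                        + dhdj[ci, cj] * step * outward[k, 1] / s2)
    verts = c + np.outer(uv[:, 0], e1) + np.outer(uv[:, 1], e2) + np.outer(ch, n)

    verts, faces = largest_face_component(verts, faces)
    return verts, faces


def largest_face_component(verts: np.ndarray, faces: np.ndarray):
    """Keep the largest edge/vertex-connected set of faces; drop unused vertices."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    nf = len(faces)
    if nf == 0:
        raise DegenerateGeometryError("empty mesh")
    nv = len(verts)
    rows = np.repeat(np.arange(nf), 3)
    cols = faces.ravel()
    m = coo_matrix((np.ones(3 * nf), (rows, cols)), shape=(nf, nv)).tocsr()
    g = m @ m.T  # faces sharing at least one vertex
    ncomp, labels = connected_components(g, directed=False)
    if ncomp > 1:
        counts = np.bincount(labels)
        faces = faces[labels == np.argmax(counts)]
    used = np.unique(faces)
    remap = -np.ones(nv, dtype=np.intp)
    remap[used] = np.arange(used.size)
    return verts[used], remap[faces]


# ---------------------------------------------------------------------------
# boundary loops
# ---------------------------------------------------------------------------

def boundary_loops(faces: np.ndarray) -> list[np.ndarray]:
    """Ordered vertex-index cycles of the mesh boundary.

    A boundary edge is a directed edge whose reverse never occurs.  Loops are
    walked edge-to-edge; pinch vertices (several boundary fans meeting at one
    vertex) are resolved by consuming any unused outgoing edge.
    """
    f = np.asarray(faces)
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=0)
    eset = set(map(tuple, e.tolist()))
    boundary = [ed for ed in eset if (ed[1], ed[0]) not in eset]
    out: dict[int, list[int]] = {}
    for a, b in boundary:
        out.setdefault(a, []).append(b)
    loops = []
    unused = set(boundary)
    while unused:
        a0, b0 = next(iter(unused))
        loop = [a0]
        a, b = a0, b0
        unused.discard((a, b))
        while b != a0:
            loop.append(b)
            nxts = [c for c in out.get(b, []) if (b, c) in unused]
            if not nxts:
                break  # non-manifold dead end; emit what we have
            c = nxts[0]
            unused.discard((b, c))
            a, b = b, c
        loops.append(np.asarray(loop, dtype=np.intp))
    loops.sort(key=len, reverse=True)
    return loops


def polyline_length(points: np.ndarray, closed: bool = True) -> float:
    p = np.asarray(points, dtype=float)
    q = np.roll(p, -1, axis=0) if closed else p[1:]
    r = p if closed else p[:-1]
    return float(np.linalg.norm(q - r, axis=1).sum())


def _dp_open(points: np.ndarray, tol: float) -> np.ndarray:
    """Douglas-Peucker on an open 3D polyline; returns kept indices."""
    n = len(points)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        seg = points[j] - points[i]
        L2 = seg @ seg
        rel = points[i + 1:j] - points[i]
        if L2 < 1e-30:
            d = np.linalg.norm(rel, axis=1)
        else:
            t = np.clip(rel @ seg / L2, 0.0, 1.0)
            d = np.linalg.norm(rel - np.outer(t, seg), axis=1)
        k = int(np.argmax(d))
        if d[k] > tol:
            m = i + 1 + k
            keep[m] = True
            stack.append((i, m))
            stack.append((m, j))
    return np.nonzero(keep)[0]


def clean_loop(points: np.ndarray, tol_nm: float) -> np.ndarray:
    """Denoise a closed outline: light moving average, then simplification.

    The moving average removes the +/- one-cell jitter of boundary vertices
    (which would otherwise inflate the measured length), and is kept short
    relative to the loop so that real outline features survive; the
    Douglas-Peucker pass then removes the remaining staircase.
    """
    p = np.asarray(points, dtype=float)
    n = len(p)
    win = 5 if n > 60 else (3 if n > 24 else 0)
    if win:
        kernel = np.ones(win) / win
        ext = np.concatenate([p[-(win // 2):], p, p[: win // 2]], axis=0)
        p = np.column_stack([
            np.convolve(ext[:, k], kernel, mode="valid") for k in range(3)])
    return simplify_loop(p, tol_nm)


def simplify_loop(points: np.ndarray, tol_nm: float) -> np.ndarray:
    """Simplify a closed 3D polyline, removing voxel-scale staircase jitter."""
    p = np.asarray(points, dtype=float)
    if len(p) <= 4 or tol_nm <= 0:
        return p
    # anchor at two mutually distant vertices, simplify each half
    i0 = 0
    i1 = int(np.argmax(np.linalg.norm(p - p[i0], axis=1)))
    if i1 == 0:
        return p
    half1 = p[i0:i1 + 1]
    half2 = np.concatenate([p[i1:], p[:i0 + 1]], axis=0)
    k1 = _dp_open(half1, tol_nm)
    k2 = _dp_open(half2, tol_nm)
    out = np.concatenate([half1[k1][:-1], half2[k2][:-1]], axis=0)
    return out


# ---------------------------------------------------------------------------
# analytic cap meshes (oracles and direct mesh-op inputs)
# ---------------------------------------------------------------------------

def cap_surface_mesh(radius: float, theta: float, n_rings: int = 60):
    """Triangulated spherical cap of half-angle ``theta`` about +z.

    Apex at (0, 0, R); an open surface with a single rim at polar angle theta.
    """
    verts = [np.array([0.0, 0.0, radius])]
    rings = []
    for i in range(1, n_rings + 1):
        psi = theta * i / n_rings
        m = max(8, int(round(2 * np.pi * np.sin(psi) / (theta / n_rings))))
        phi = 2 * np.pi * np.arange(m) / m
        ring = np.arange(len(verts), len(verts) + m)
        verts.extend(
            np.column_stack([
                radius * np.sin(psi) * np.cos(phi),
                radius * np.sin(psi) * np.sin(phi),
                np.full(m, radius * np.cos(psi)),
            ])
        )
        rings.append(ring)
    faces = []
    first = rings[0]
    for k in range(len(first)):
        faces.append([0, first[k], first[(k + 1) % len(first)]])
    for r0, r1 in zip(rings[:-1], rings[1:]):
        faces.extend(_stitch_rings(r0, r1))
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=np.intp)


def _stitch_rings(r0: np.ndarray, r1: np.ndarray) -> list[list[int]]:
    """Triangles between two concentric vertex rings of possibly unequal size."""
    n0, n1 = len(r0), len(r1)
    faces = []
    i = j = 0
    while i < n0 or j < n1:
        a0 = (i + 0.5) / n0
        a1 = (j + 0.5) / n1
        if j >= n1 or (i < n0 and a0 <= a1):
            faces.append([r0[i % n0], r1[j % n1], r0[(i + 1) % n0]])
            i += 1
        else:
            faces.append([r1[j % n1], r1[(j + 1) % n1], r0[i % n0]])
            j += 1
    return faces


def disc_mesh(radius: float, n_rings: int = 40):
    """Flat triangulated disc of given radius in the z=0 plane."""
    v, f = cap_surface_mesh(1.0, 1e-6, n_rings)
    # flatten: project onto z=0 and rescale the in-plane radius
    r_in = np.linalg.norm(v[:, :2], axis=1)
    scale = radius / r_in.max()
    v2 = np.column_stack([v[:, 0] * scale, v[:, 1] * scale, np.zeros(len(v))])
    return v2, f


def annulus_mesh(r_inner: float, r_outer: float, n_seg: int = 64, n_rings: int = 8):
    """Flat annulus in the z=0 plane (one perforation)."""
    verts = []
    rings = []
    for i in range(n_rings + 1):
        r = r_inner + (r_outer - r_inner) * i / n_rings
        phi = 2 * np.pi * np.arange(n_seg) / n_seg
        ring = np.arange(len(verts), len(verts) + n_seg)
        verts.extend(np.column_stack(
            [r * np.cos(phi), r * np.sin(phi), np.zeros(n_seg)]))
        rings.append(ring)
    faces = []
    for r0, r1 in zip(rings[:-1], rings[1:]):
        for k in range(n_seg):
            a, b = r0[k], r0[(k + 1) % n_seg]
            c, d = r1[k], r1[(k + 1) % n_seg]
            faces.append([a, c, b])
            faces.append([b, c, d])
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=np.intp)


# ---------------------------------------------------------------------------
# minimal enclosing sphere (Welzl)
# ---------------------------------------------------------------------------

def _circumsphere(support: list[np.ndarray]):
    """Smallest sphere with all support points on its surface; None if degenerate."""
    k = len(support)
    if k == 0:
        return np.zeros(3), 0.0
    if k == 1:
        return support[0].copy(), 0.0
    p0 = support[0]
    a = np.asarray(support[1:]) - p0
    rhs = 0.5 * np.sum(a * a, axis=1)
    try:
        sol, res, rank, _ = np.linalg.lstsq(a, rhs, rcond=None)
    except np.linalg.LinAlgError:
        return None
    if rank < len(a):
        return None
    c = p0 + sol
    r = float(np.linalg.norm(c - p0))
    return c, r


def _in_sphere(p: np.ndarray, c: np.ndarray, r: float) -> bool:
    return float(np.linalg.norm(p - c)) <= r * (1 + 1e-10) + 1e-9


def min_enclosing_sphere(points: np.ndarray, seed: int = 0):
    """Exact minimal enclosing sphere via Welzl's randomized incremental method.

    Returns (center, radius).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None]
    pts = np.unique(pts, axis=0)
    if len(pts) == 1:
        return pts[0].copy(), 0.0
    if len(pts) > 64:
        # reduce to hull vertices; the minimal sphere depends only on them
        try:
            from scipy.spatial import ConvexHull
            hull = ConvexHull(pts, qhull_options="QJ")
            pts = pts[np.unique(hull.vertices)]
        except Exception:
            pass
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pts))
    pts = [pts[i] for i in order]

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * len(pts) + 100))

    def welzl(i: int, support: list[np.ndarray]):
        if i == len(pts) or len(support) == 4:
            s = _circumsphere(support)
            if s is None:
                s = _circumsphere(support[:-1])
            return s if s is not None else (np.zeros(3), 0.0)
        c, r = welzl(i + 1, support)
        if _in_sphere(pts[i], c, r):
            return c, r
        return welzl(i + 1, support + [pts[i]])

    try:
        c, r = welzl(0, [])
    finally:
        sys.setrecursionlimit(old)
    return c, r
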