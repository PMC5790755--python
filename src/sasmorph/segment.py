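"""Junction segmentation from serial-section stacks.

Pre- and postsynaptic densities image dark; segmentation is a Gaussian blur
(specified in physical nm so it is anisotropy-aware), a gray-level threshold
keeping dark voxels, 26-connected components, a physical minimum-volume
filter, and the edge-truncation exclusion: any component touching a stack
face cannot have its apposition surface extracted and is discarded from the
analysis, exactly as junctions cut by the field of view are discarded in
real stacks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import IndeterminateClassification, ValidationError
from .stack import LabelVolume, VoxelStack

log = logging.getLogger(__name__)

DEFAULT_MIN_VOLUME_NM3 = 20_000.0
DEFAULT_AS_SS_SPLIT_NM = 25.0


@dataclass
class JunctionSegment:
    """A 26-connected set of voxels covering one synaptic junction.

    The component merges the presynaptic density, cleft and PSD.  ``voxels``
    is an (N, 3) integer array of (z, y, x) indices into the source stack.
    """

    segment_id: int
    voxels: np.ndarray
    voxel_size_nm: tuple[float, float, float]
    stack_shape: tuple[int, int, int]        # (nz, ny, nx)
    truncated: bool
    gray_mean: float
    gray_min: float
    sublabels: np.ndarray | None = None      # per-voxel: 1 post, 2 pre, 0 unknown
    synapse_type: str | None = None
    phantom_id: int | None = None
    stack_ref: str = ""

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def volume_nm3(self) -> float:
        vx, vy, vz = self.voxel_size_nm
        return self.n_voxels * vx * vy * vz

    def physical_coords(self) -> np.ndarray:
        vx, vy, vz = self.voxel_size_nm
        v = self.voxels
        return np.column_stack([v[:, 2] * vx, v[:, 1] * vy, v[:, 0] * vz]).astype(float)


def gaussian_blur(stack: VoxelStack, sigma_nm) -> VoxelStack:
    """Gaussian smoothing with per-axis sigmas given in nm, (x, y, z) order.

    Sigmas are converted to voxel units per axis, so the same physical
    smoothing is applied despite the anisotropic sectioning. Sigma 0 is the
    identity.
    """
    sig = tuple(float(s) for s in np.broadcast_to(sigma_nm, (3,)))
    if any(s < 0 or not np.isfinite(s) for s in sig):
        raise ValidationError(f"blur sigmas must be >= 0, got {sig}")
    vx, vy, vz = stack.voxel_size_nm
    sigma_vox = (sig[2] / vz, sig[1] / vy, sig[0] / vx)   # (z, y, x)
    data = ndimage.gaussian_filter(stack.data.astype(np.float32), sigma=sigma_vox)
    return VoxelStack(data=data, voxel_size_nm=stack.voxel_size_nm)


def threshold_components(
    stack: VoxelStack,
    gray_threshold: float | None = None,
    min_volume_nm3: float = DEFAULT_MIN_VOLUME_NM3,
) -> list[JunctionSegment]:
    """Extract dark 26-connected components as junction segments.

    Voxels with intensity <= threshold are kept (densities are dark).  When
    no threshold is given, a per-stack bimodal (Otsu) threshold is derived.
    Components smaller than ``min_volume_nm3`` of physical volume are
    dropped; components touching any of the six stack faces are flagged
    truncated.
    """
    data = stack.data
    if data.size == 0:
        raise ValidationError("empty stack")
    if gray_threshold is None:
        gray_threshold = float(threshold_otsu(np.asarray(data)))
    mask = data <= gray_threshold
    if not mask.any():
        return []
    lab, nlab = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    nz, ny, nx = data.shape
    vox_vol = stack.voxel_volume_nm3
    min_voxels = int(np.ceil(min_volume_nm3 / vox_vol))
    segments: list[JunctionSegment] = []
    slices = ndimage.find_objects(lab)
    sid = 0
    for comp_idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        local = lab[sl] == comp_idx
        n = int(local.sum())
        if n < min_voxels:
            continue
        zz, yy, xx = np.nonzero(local)
        zz = zz + sl[0].start
        yy = yy + sl[1].start
        xx = xx + sl[2].start
        truncated = bool(
            zz.min() == 0 or zz.max() == nz - 1
            or yy.min() == 0 or yy.max() == ny - 1
            or xx.min() == 0 or xx.max() == nx - 1
        )
        vals = data[zz, yy, xx]
        sid += 1
        segments.append(JunctionSegment(
            segment_id=sid,
            voxels=np.column_stack([zz, yy, xx]).astype(np.int32),
            voxel_size_nm=stack.voxel_size_nm,
            stack_shape=data.shape,
            truncated=truncated,
            gray_mean=float(np.mean(vals)),
            gray_min=float(np.min(vals)),
        ))
    return segments


def exclude_truncated(
    segments: list[JunctionSegment],
) -> tuple[list[JunctionSegment], list[JunctionSegment]]:
    """Partition segments into (kept, discarded-by-truncation)."""
    kept = [s for s in segments if not s.truncated]
    discarded = [s for s in segments if s.truncated]
    total = len(segments)
    if total:
        log.info("truncation exclusion: %d/%d discarded (%.2f%%), %d kept",
                 len(discarded), total, 100.0 * len(discarded) / total, len(kept))
    return kept, discarded


def attach_ground_truth(
    segments: list[JunctionSegment],
    labels: LabelVolume,
) -> None:
    """Attach phantom ids and post/pre sublabels from a rendered label volume.

    The phantom id is the majority non-background id among member voxels;
    halo voxels picked up by the threshold keep sublabel 0 and are ignored by
    the dual-surface extraction.
    """
    for seg in segments:
        zz, yy, xx = seg.voxels[:, 0], seg.voxels[:, 1], seg.voxels[:, 2]
        ids = labels.ids[zz, yy, xx]
        nz = ids[ids > 0]
        seg.phantom_id = int(np.bincount(nz).argmax()) if nz.size else None
        sub = labels.side[zz, yy, xx].astype(np.uint8)
        if seg.phantom_id is not None:
            sub = np.where(ids == seg.phantom_id, sub, 0).astype(np.uint8)
        seg.sublabels = sub


def classify_as_ss(
    segment: JunctionSegment,
    stack: VoxelStack,
    *,
    split_nm: float = DEFAULT_AS_SS_SPLIT_NM,
    cleft_width_nm: float = 20.0,
    pre_thickness_nm: float = 20.0,
    sas_area_nm2: float | None = None,
) -> str:
    """Classify a junction as excitatory (AS) or inhibitory (SS) by PSD thickness.

    The mean total slab thickness along the surface normal is estimated as
    component volume / apposition-surface area; subtracting the nominal
    cleft and presynaptic-density thicknesses leaves the PSD thickness,
    which is thick for AS and thin for SS.  ``split_nm`` is the decision
    threshold on the PSD thickness.
    """
    if segment.n_voxels < 2:
        raise IndeterminateClassification(
            "single-voxel segment: thickness undefined")
    if sas_area_nm2 is None:
        from .meshing import heightfield_mesh
        from .sas_morpho import mesh_area
        from .sas_morpho import SASMesh
        pts = segment.physical_coords()
        grid = min(stack.voxel_size_nm) * 2.2
        try:
            verts, faces = heightfield_mesh(
                pts, grid_nm=grid, mid_mode="midrange",
                section_step_nm=max(stack.voxel_size_nm))
        except Exception as exc:
            raise IndeterminateClassification(
                f"cannot estimate a medial surface: {exc}") from exc
        sas_area_nm2 = mesh_area(SASMesh(vertices=verts, triangles=faces))
    if sas_area_nm2 <= 0:
        raise IndeterminateClassification("zero apposition-surface area")
    total_thickness = segment.volume_nm3 / sas_area_nm2
    psd_thickness = total_thickness - cleft_width_nm - pre_thickness_nm
    label = "AS" if psd_thickness >= split_nm else "SS"
    segment.synapse_type = label
    return label
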