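"""Synthetic synaptic-junction phantoms with analytically known geometry.

No EM stacks are deposited with the study this pipeline reimplements, so
every downstream stage is exercised on phantoms whose apposition-surface
geometry is closed-form.  The target surface is a spherical cap of radius R
and half-angle theta:

    area        = 2 pi R^2 (1 - cos theta)
    perimeter   = 2 pi R sin theta
    curvature   = (1 - cos theta) / 2      (the 1 - projected/area statistic)
    Feret       = 2 R sin theta            (minimal enclosing sphere diameter)

A phantom is the cap thickened into a postsynaptic-density slab, a synaptic
cleft and a presynaptic-density slab; all three render dark against the
neuropil background, exactly as the electron-dense pre/postsynaptic
specializations appear in FIB/SEM stacks.  Excitatory (AS) phantoms carry a
thick PSD, inhibitory (SS) phantoms a thin one — the classical morphologic
criterion separating the two types.

Shape classes: *macular* caps are plain; *perforated* caps have circular
holes fully interior to the cap; *horseshoe* caps have a deep radial notch
cut into the rim.  Population sampling draws target areas from a log-normal
distribution, the class from a 3-way mixture, and the AS/SS type from a
Bernoulli fraction; cap angle and radius are then solved exactly so the
analytic cap area equals the drawn area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .stack import LabelVolume, VoxelStack

HORSESHOE_DEPTH_THRESHOLD = 0.5

# curvature statistic (1-cos theta)/2 drawn per shape class; means follow the
# per-class curvature ordering reported for cortical synapses
_CURVATURE_MEAN = {"macular": 0.07, "perforated": 0.10, "horseshoe": 0.11}
_CURVATURE_SD = 0.03
_CURVATURE_RANGE = (0.02, 0.30)

# size tilt of the class assignment: perforated and horseshoe junctions sit
# in the right tail of the size distribution; the exponents reproduce the
# reported per-class mean-area ratios (perforated ~2.7x, horseshoe ~2.3x the
# overall mean) under a log-normal size marginal
_CLASS_SIZE_TILT = {"macular": 0.0, "perforated": 2.0, "horseshoe": 1.55}

# postsynaptic-target mixtures (spine head / spine neck / shaft) by type
_TARGET_P = {
    "AS": {"spine_head": 0.81, "spine_neck": 0.04, "shaft": 0.15},
    "SS": {"spine_head": 0.20, "spine_neck": 0.07, "shaft": 0.73},
}

AS_PSD_THICKNESS_NM = 40.0
SS_PSD_THICKNESS_NM = 15.0


@dataclass
class PhantomSpec:
    """One synthetic synaptic junction with closed-form SAS geometry.

    ``cap_angle_rad == 0`` denotes the flat-disc limit, in which case
    ``sphere_radius_nm`` is the disc radius.
    """

    synapse_type: str = "AS"                  # {AS, SS}
    shape_class: str = "macular"              # {macular, perforated, horseshoe}
    sphere_radius_nm: float = 300.0
    cap_angle_rad: float = math.pi / 6
    n_perforations: int = 0
    perforation_radius_nm: float = 0.0
    indentation_depth_frac: float = 0.0
    notch_halfwidth_rad: float = 0.35
    center_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    psd_thickness_nm: float = AS_PSD_THICKNESS_NM
    pre_thickness_nm: float = 20.0
    cleft_width_nm: float = 20.0
    target_label: str = "spine_head"

    def __post_init__(self) -> None:
        if self.synapse_type not in ("AS", "SS"):
            raise ValidationError(f"unknown synapse type {self.synapse_type!r}")
        if self.shape_class not in ("macular", "perforated", "horseshoe"):
            raise ValidationError(f"unknown shape class {self.shape_class!r}")
        for name in ("sphere_radius_nm", "psd_thickness_nm", "pre_thickness_nm",
                     "cleft_width_nm"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be positive and finite, got {v}")
        if not (0 <= self.cap_angle_rad <= math.pi / 2):
            raise ValidationError("cap angle must lie in [0, pi/2]")
        if not (0 <= self.indentation_depth_frac < 1):
            raise ValidationError("indentation depth fraction must lie in [0, 1)")
        if self.n_perforations < 0:
            raise ValidationError("n_perforations must be non-negative")
        if self.shape_class == "macular":
            if self.n_perforations != 0:
                raise ValidationError("macular phantoms cannot carry perforations")
            if self.indentation_depth_frac >= HORSESHOE_DEPTH_THRESHOLD:
                raise ValidationError("macular indentation at/above horseshoe depth")
        if self.shape_class == "perforated" and self.n_perforations < 1:
            raise ValidationError("perforated phantoms need at least one hole")
        if self.shape_class == "horseshoe" and \
                self.indentation_depth_frac < HORSESHOE_DEPTH_THRESHOLD:
            raise ValidationError("horseshoe indentation below the class threshold")
        axis = np.asarray(self.orientation, dtype=float)
        nrm = np.linalg.norm(axis)
        if not np.isfinite(nrm) or nrm == 0:
            raise ValidationError("orientation must be a non-zero vector")
        self.orientation = tuple(axis / nrm)

    # -- derived geometry ------------------------------------------------
    @property
    def is_flat(self) -> bool:
        return self.cap_angle_rad == 0.0

    @property
    def cap_area_nm2(self) -> float:
        """Area of the un-perforated, un-notched cap."""
        R, th = self.sphere_radius_nm, self.cap_angle_rad
        if self.is_flat:
            return math.pi * R * R
        return 2 * math.pi * R * R * (1 - math.cos(th))

    @property
    def equivalent_radius_nm(self) -> float:
        return math.sqrt(self.cap_area_nm2 / math.pi)

    @property
    def slab_inner_nm(self) -> float:
        """Slab extent on the postsynaptic side of the apposition surface."""
        return self.cleft_width_nm / 2 + self.psd_thickness_nm

    @property
    def slab_outer_nm(self) -> float:
        """Slab extent on the presynaptic side."""
        return self.cleft_width_nm / 2 + self.pre_thickness_nm

    def local_frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (e1, e2, axis) with a deterministic in-plane basis."""
        w = np.asarray(self.orientation, dtype=float)
        a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(w, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(w, e1)
        return e1, e2, w

    def perforation_directions(self) -> np.ndarray:
        """Unit directions (in world frame) of the perforation centers."""
        if self.n_perforations == 0:
            return np.zeros((0, 3))
        e1, e2, w = self.local_frame()
        psi = 0.45 * self.cap_angle_rad
        k = self.n_perforations
        phis = 2 * np.pi * np.arange(k) / k + 0.3
        return (np.sin(psi) * (np.cos(phis)[:, None] * e1 + np.sin(phis)[:, None] * e2)
                + np.cos(psi) * w)


@dataclass
class StackSpec:
    """Rendering parameters for a synthetic FIB/SEM-like stack."""

    shape_voxels: tuple[int, int, int] = (256, 256, 64)      # (nx, ny, nz)
    voxel_size_nm: tuple[float, float, float] = (3.7, 3.7, 20.0)
    background_gray: float = 180.0
    density_gray: float = 60.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) < 1 for s in self.shape_voxels):
            raise ValidationError("stack shape must be positive")
        if any(not (np.isfinite(v) and v > 0) for v in self.voxel_size_nm):
            raise ValidationError("voxel sizes must be positive")
        if not self.density_gray < self.background_gray:
            raise ValidationError("densities must be darker than the background")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass
class PopulationParams:
    """Population-level generation parameters.

    Defaults are the study conditions of the pooled cortical population:
    log-normal SAS areas with location 10.84 and scale 0.79 (log nm^2),
    a 93 / 4.5 / 2.5 % macular / perforated / horseshoe mixture, and a
    90.83 % excitatory (AS) fraction.
    """

    lognormal_mu: float = 10.84
    lognormal_sigma: float = 0.79
    shape_mix: tuple[float, float, float] = (0.93, 0.045, 0.025)
    as_fraction: float = 0.9083
    n_synapses: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.lognormal_mu):
            raise ValidationError("lognormal_mu must be finite")
        if not (np.isfinite(self.lognormal_sigma) and self.lognormal_sigma >= 0):
            raise ValidationError("lognormal_sigma must be finite and >= 0")
        mix = np.asarray(self.shape_mix, dtype=float)
        if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-12:
            raise ValidationError("shape_mix must be non-negative and sum to 1")
        if not (0 <= self.as_fraction <= 1):
            raise ValidationError("as_fraction must lie in [0, 1]")
        if self.n_synapses < 1:
            raise ValidationError("n_synapses must be >= 1")


@dataclass
class TruthRecord:
    """Closed-form morphometry of one phantom."""

    area_nm2: float
    perimeter_nm: float
    curvature: float
    feret_nm: float


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _random_unit_vector(rng: np.random.Generator) -> tuple[float, float, float]:
    v = rng.normal(size=3)
    return tuple(v / np.linalg.norm(v))


def _assign_classes(areas: np.ndarray, mix: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Size-tilted shape-class assignment with exact marginal class shares.

    Perforated and horseshoe junctions are preferentially the large ones
    (probability tilted by area^gamma per class), while iterative
    proportional fitting rescales the per-class weights so the expected
    class frequencies still equal ``mix``.  The size marginal is untouched:
    classes are assigned to already-drawn areas.
    """
    names = np.array(["macular", "perforated", "horseshoe"])
    n = len(areas)
    if n == 1 or mix.max() == 1.0:
        return rng.choice(names, size=n, p=mix)
    rel = areas / np.exp(np.mean(np.log(areas)))
    w = np.column_stack([rel ** _CLASS_SIZE_TILT[c] for c in names])
    alpha = np.ones(3)
    for _ in range(200):
        p = w * alpha
        p /= p.sum(axis=1, keepdims=True)
        shares = p.mean(axis=0)
        if np.abs(shares - mix).max() < 1e-10:
            break
        alpha *= np.where(shares > 0, mix / np.maximum(shares, 1e-300), 1.0)
    idx = np.array([rng.choice(3, p=pi) for pi in p])
    return names[idx]


def sample_population(params: PopulationParams) -> list[PhantomSpec]:
    """Draw a list of phantom specs from the population model.

    Target SAS areas come from the log-normal; the cap angle is set by a
    per-class curvature draw and the sphere radius solved exactly so the
    analytic cap area equals the drawn area (``A = 4 pi c R^2`` with
    curvature ``c = (1 - cos theta)/2``).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_synapses
    areas = np.exp(rng.normal(params.lognormal_mu, params.lognormal_sigma, size=n))
    classes = _assign_classes(areas, np.asarray(params.shape_mix, dtype=float), rng)
    types = np.where(rng.random(n) < params.as_fraction, "AS", "SS")

    specs: list[PhantomSpec] = []
    for i in range(n):
        cls = str(classes[i])
        typ = str(types[i])
        c = float(np.clip(rng.normal(_CURVATURE_MEAN[cls], _CURVATURE_SD),
                          *_CURVATURE_RANGE))
        theta = math.acos(1 - 2 * c)
        R = math.sqrt(areas[i] / (4 * math.pi * c))
        n_perf, r_perf, depth = 0, 0.0, 0.0
        if cls == "perforated":
            n_perf = 1 if rng.random() < 0.8 else 2
            # holes sized relative to the cap so they stay fully interior
            r_perf = 0.25 * R * theta / math.sqrt(n_perf)
        elif cls == "horseshoe":
            depth = float(rng.uniform(0.65, 0.85))
        tp = _TARGET_P[typ]
        target = str(rng.choice(list(tp.keys()), p=list(tp.values())))
        specs.append(PhantomSpec(
            synapse_type=typ,
            shape_class=cls,
            sphere_radius_nm=R,
            cap_angle_rad=theta,
            n_perforations=n_perf,
            perforation_radius_nm=r_perf,
            indentation_depth_frac=depth,
            orientation=_random_unit_vector(rng),
            psd_thickness_nm=(AS_PSD_THICKNESS_NM if typ == "AS"
                              else SS_PSD_THICKNESS_NM),
            target_label=target,
        ))
    return specs


# ---------------------------------------------------------------------------
# analytic truth
# ---------------------------------------------------------------------------

def analytic_truth(spec: PhantomSpec) -> TruthRecord:
    """Closed-form area, perimeter, curvature and Feret diameter of a phantom.

    The area subtracts perforation caps and the horseshoe notch; perimeter,
    curvature and Feret refer to the un-perforated outer cap.
    """
    R, th = spec.sphere_radius_nm, spec.cap_angle_rad
    if spec.is_flat:
        area = math.pi * R * R - spec.n_perforations * math.pi * spec.perforation_radius_nm ** 2
        return TruthRecord(area, 2 * math.pi * R, 0.0, 2 * R)
    area = 2 * math.pi * R * R * (1 - math.cos(th))
    if spec.n_perforations:
        phi_h = spec.perforation_radius_nm / R
        area -= spec.n_perforations * 2 * math.pi * R * R * (1 - math.cos(phi_h))
    if spec.indentation_depth_frac > 0:
        delta = _notch_polar_extent(spec)
        area -= 2 * spec.notch_halfwidth_rad * R * R * (
            math.cos(th - delta) - math.cos(th))
    perim = 2 * math.pi * R * math.sin(th)
    curv = (1 - math.cos(th)) / 2
    return TruthRecord(area, perim, curv, 2 * R * math.sin(th))


def _notch_polar_extent(spec: PhantomSpec) -> float:
    """Polar-angle extent of the horseshoe notch.

    Chosen so the notch depth *in the projection plane* equals
    ``indentation_depth_frac`` times the projected equivalent radius
    (R sin theta): the rim sits at in-plane radius R sin(theta) and the notch
    bottom at R sin(theta - delta), hence
    sin(theta - delta) = (1 - frac) sin(theta).
    This makes the generated fraction directly comparable with the
    hull-based indentation measurement, which operates in projection.
    """
    th = spec.cap_angle_rad
    frac = spec.indentation_depth_frac
    return th - math.asin((1.0 - frac) * math.sin(th))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _phantom_local_bbox(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounds of the slab in the phantom's local frame (nm)."""
    a, b = spec.slab_inner_nm, spec.slab_outer_nm
    if spec.is_flat:
        r = spec.sphere_radius_nm
        lo = np.array([-r, -r, -a])
        hi = np.array([r, r, b])
    else:
        R, th = spec.sphere_radius_nm, spec.cap_angle_rad
        s = (R + b) * math.sin(th)
        lo = np.array([-s, -s, (R - a) * math.cos(th)])
        hi = np.array([s, s, R + b])
    return lo, hi


def phantom_world_bbox(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """World-frame bounding box (x, y, z nm) of the phantom slab."""
    lo, hi = _phantom_local_bbox(spec)
    e1, e2, w = spec.local_frame()
    M = np.column_stack([e1, e2, w])          # local -> world
    center_local = (lo + hi) / 2
    half = (hi - lo) / 2
    c_world = np.asarray(spec.center_nm) + M @ center_local
    half_world = np.abs(M) @ half
    return c_world - half_world, c_world + half_world


def _membership(spec: PhantomSpec, px, py, pz):
    """Boolean slab mask and post/pre side codes at physical points.

    Returns (member, side) where side is 1 on the postsynaptic side of the
    apposition surface and 2 on the presynaptic side.
    """
    c = np.asarray(spec.center_nm)
    dx, dy, dz = px - c[0], py - c[1], pz - c[2]
    e1, e2, w = spec.local_frame()
    lz = dx * w[0] + dy * w[1] + dz * w[2]
    lx = dx * e1[0] + dy * e1[1] + dz * e1[2]
    ly = dx * e2[0] + dy * e2[1] + dz * e2[2]
    a_in, b_out = spec.slab_inner_nm, spec.slab_outer_nm
    if spec.is_flat:
        lat2 = lx * lx + ly * ly
        member = (lat2 <= spec.sphere_radius_nm ** 2) & (lz >= -a_in) & (lz <= b_out)
        if spec.n_perforations:
            for hd in _flat_hole_centers(spec):
                member &= ((lx - hd[0]) ** 2 + (ly - hd[1]) ** 2
                           >= spec.perforation_radius_nm ** 2)
        side = np.where(lz < 0, 1, 2)
        return member, side
    R, th = spec.sphere_radius_nm, spec.cap_angle_rad
    rho = np.sqrt(dx * dx + dy * dy + dz * dz)
    rho_safe = np.maximum(rho, 1e-9)
    cos_psi = lz / rho_safe
    member = (rho >= R - a_in) & (rho <= R + b_out) & (cos_psi >= math.cos(th))
    if spec.n_perforations:
        dirs = spec.perforation_directions()
        phi_h = spec.perforation_radius_nm / R
        for hd in dirs:
            cos_d = (dx * hd[0] + dy * hd[1] + dz * hd[2]) / rho_safe
            member &= cos_d <= math.cos(phi_h)
    if spec.indentation_depth_frac > 0:
        delta = _notch_polar_extent(spec)
        psi = np.arccos(np.clip(cos_psi, -1, 1))
        phi = np.arctan2(ly, lx)
        in_notch = (np.abs(phi) <= spec.notch_halfwidth_rad) & (psi >= th - delta)
        member &= ~in_notch
    side = np.where(rho < R, 1, 2)
    return member, side


def _flat_hole_centers(spec: PhantomSpec) -> np.ndarray:
    if spec.n_perforations == 0:
        return np.zeros((0, 2))
    k = spec.n_perforations
    phis = 2 * np.pi * np.arange(k) / k + 0.3
    rr = 0.5 * spec.sphere_radius_nm
    return np.column_stack([rr * np.cos(phis), rr * np.sin(phis)])


def render_stack(
    specs: list[PhantomSpec],
    stack: StackSpec,
) -> tuple[VoxelStack, LabelVolume, list[str]]:
    """Render phantoms into a noisy grayscale stack with ground-truth labels.

    Voxels whose centers fall inside any phantom slab take ``density_gray``,
    everything else ``background_gray``; Gaussian noise of ``noise_sd`` is
    added and the result clipped to 8 bits.  The label volume carries the
    phantom id (1-based) and the post/pre side code.  Returns
    ``(stack, labels, warnings)`` where warnings lists phantoms whose slab is
    thinner than one section along z (aliasing risk), and phantoms that
    overlap previously placed ones.
    """
    nx, ny, nz = (int(s) for s in stack.shape_voxels)
    vx, vy, vz = stack.voxel_size_nm
    gray = np.full((nz, ny, nx), float(stack.background_gray), dtype=np.float32)
    ids = np.zeros((nz, ny, nx), dtype=np.uint16)
    side = np.zeros((nz, ny, nx), dtype=np.uint8)
    notes: list[str] = []

    for i, spec in enumerate(specs, start=1):
        lo, hi = phantom_world_bbox(spec)
        i0 = np.maximum(np.floor(lo / [vx, vy, vz]).astype(int) - 1, 0)
        i1 = np.minimum(np.ceil(hi / [vx, vy, vz]).astype(int) + 2, [nx, ny, nz])
        if np.any(i0 >= i1):
            continue  # entirely outside the stack
        xs = (np.arange(i0[0], i1[0]) * vx)[None, None, :]
        ys = (np.arange(i0[1], i1[1]) * vy)[None, :, None]
        zs = (np.arange(i0[2], i1[2]) * vz)[:, None, None]
        member, side_code = _membership(spec, xs, ys, zs)
        if not member.any():
            continue
        slab_total = spec.slab_inner_nm + spec.slab_outer_nm
        axis_z = abs(spec.orientation[2])
        if axis_z > 0 and min(spec.psd_thickness_nm, spec.pre_thickness_nm) < vz * axis_z:
            notes.append(
                f"phantom {i}: density slab thinner than one section along z")
        sub = (slice(i0[2], i1[2]), slice(i0[1], i1[1]), slice(i0[0], i1[0]))
        if (ids[sub][member] != 0).any():
            notes.append(f"phantom {i}: overlaps a previously rendered phantom")
        gray[sub][member] = stack.density_gray
        ids[sub][member] = i
        side[sub][member] = np.broadcast_to(side_code, member.shape)[member]
        del member, side_code, slab_total

    rng = np.random.default_rng(stack.seed)
    if stack.noise_sd > 0:
        gray += rng.normal(0.0, stack.noise_sd, size=gray.shape).astype(np.float32)
    data = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    vs = VoxelStack(data=data, voxel_size_nm=stack.voxel_size_nm)
    labels = LabelVolume(ids=ids, side=side, voxel_size_nm=stack.voxel_size_nm)
    return vs, labels, notes


def tight_stack_spec(
    spec: PhantomSpec,
    *,
    voxel_size_nm: tuple[float, float, float] = (3.7, 3.7, 20.0),
    margin_nm: tuple[float, float, float] = (40.0, 40.0, 80.0),
    noise_sd: float = 10.0,
    seed: int = 0,
    background_gray: float = 180.0,
    density_gray: float = 60.0,
) -> tuple[PhantomSpec, StackSpec]:
    """Re-center one phantom inside a minimal stack that fully contains it.

    Returns the recentered spec and the matching StackSpec.  The margin must
    cover the blur support so that the segmented component never touches a
    stack face.
    """
    lo, hi = phantom_world_bbox(spec)
    vsz = np.asarray(voxel_size_nm)
    mar = np.asarray(margin_nm)
    extent = (hi - lo) + 2 * mar
    shape = np.maximum(np.ceil(extent / vsz).astype(int) + 1, 4)
    shift = mar - lo
    moved = replace(spec, center_nm=tuple(np.asarray(spec.center_nm) + shift))
    sspec = StackSpec(shape_voxels=tuple(int(s) for s in shape),
                      voxel_size_nm=tuple(voxel_size_nm),
                      background_gray=background_gray,
                      density_gray=density_gray,
                      noise_sd=noise_sd, seed=seed)
    return moved, sspec


def place_phantoms(
    specs: list[PhantomSpec],
    stack: StackSpec,
    *,
    clearance_nm: float = 30.0,
    seed: int = 0,
    max_tries: int = 2000,
) -> list[PhantomSpec]:
    """Assign random non-overlapping centers inside the stack.

    Rejection sampling on bounding spheres with a minimum clearance (one blur
    kernel width by default) so segmentation cannot merge phantoms.
    """
    rng = np.random.default_rng(seed)
    vx, vy, vz = stack.voxel_size_nm
    extent = np.array([stack.shape_voxels[0] * vx,
                       stack.shape_voxels[1] * vy,
                       stack.shape_voxels[2] * vz])
    placed: list[PhantomSpec] = []
    radii: list[float] = []
    centers: list[np.ndarray] = []
    for spec in specs:
        lo, hi = phantom_world_bbox(spec)
        rad = float(np.linalg.norm(hi - lo) / 2)
        if np.any(2 * rad + 2 * clearance_nm > extent):
            raise ValidationError("phantom too large for the stack")
        ok = False
        for _ in range(max_tries):
            c = rng.uniform(rad + clearance_nm, extent - rad - clearance_nm)
            if all(np.linalg.norm(c - cj) >= rad + rj + clearance_nm
                   for cj, rj in zip(centers, radii)):
                ok = True
                break
        if not ok:
            warnings.warn("could not place all phantoms without overlap; "
                          "stack too crowded", stacklevel=2)
            break
        bc = (lo + hi) / 2 - np.asarray(spec.center_nm)   # bbox center offset
        placed.append(replace(spec, center_nm=tuple(c - bc)))
        centers.append(c)
        radii.append(rad)
    return placed
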