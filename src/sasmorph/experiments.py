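"""End-to-end experiment helpers on synthetic phantom populations.

Each helper runs the full chain — sample phantoms, render them into noisy
anisotropic stacks, blur + threshold + connected components, apposition
surface extraction, morphometry, shape and type classification — and
aggregates the results against the analytic ground truth.  They back both
the test suite and the reproduction script, so the numbers they return are
always recomputed from scratch.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import popstats, sas_morpho, segment as seg, shape_class, synthgen
from .errors import SasmorphError

log = logging.getLogger(__name__)

DEFAULT_BLUR_SIGMA_NM = (7.4, 7.4, 20.0)


@dataclass
class PhantomResult:
    spec: synthgen.PhantomSpec
    truth: synthgen.TruthRecord
    record: sas_morpho.MorphoRecord | None
    report: shape_class.ShapeReport | None
    error: str | None = None


def measure_phantom(
    spec: synthgen.PhantomSpec,
    *,
    seed: int = 0,
    noise_sd: float = 10.0,
    voxel_size_nm=(3.7, 3.7, 20.0),
    blur_sigma_nm=DEFAULT_BLUR_SIGMA_NM,
    gray_threshold: float | None = None,
    use_sublabels: bool = True,
    classify_type: bool = True,
) -> PhantomResult:
    """Render one phantom in a tight stack and run the full pipeline on it."""
    truth = synthgen.analytic_truth(spec)
    moved, sspec = synthgen.tight_stack_spec(
        spec, voxel_size_nm=voxel_size_nm, noise_sd=noise_sd, seed=seed)
    stack, labels, _ = synthgen.render_stack([moved], sspec)
    try:
        blurred = seg.gaussian_blur(stack, blur_sigma_nm)
        segments = seg.threshold_components(blurred, gray_threshold)
        kept, _ = seg.exclude_truncated(segments)
        if not kept:
            raise SasmorphError("no non-truncated component found")
        target = max(kept, key=lambda s: s.n_voxels)
        if use_sublabels:
            seg.attach_ground_truth([target], labels)
        mesh = sas_morpho.extract_sas(target, blurred)
        syn_type = None
        if classify_type:
            syn_type = seg.classify_as_ss(
                target, blurred, sas_area_nm2=sas_morpho.mesh_area(mesh))
        record = sas_morpho.measure(
            mesh, synapse_type=syn_type, target_label=spec.target_label,
            volume_nm3=target.volume_nm3)
        report = shape_class.classify_shape(mesh)
        record.shape_class = report.shape_class
        record.n_perforations = report.n_holes
        return PhantomResult(spec, truth, record, report)
    except SasmorphError as exc:
        return PhantomResult(spec, truth, None, None, error=str(exc))


def results_to_frame(results: list[PhantomResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "true_shape": r.spec.shape_class,
            "true_type": r.spec.synapse_type,
            "true_area_nm2": r.truth.area_nm2,
            "true_perimeter_nm": r.truth.perimeter_nm,
            "true_curvature": r.truth.curvature,
            "true_feret_nm": r.truth.feret_nm,
            "target_label": r.spec.target_label,
            "error": r.error or "",
        }
        if r.record is not None:
            row.update({k: v for k, v in dataclasses.asdict(r.record).items()})
            row["layer_label"] = row.get("layer_label") or "all"
            row["shape_class"] = r.report.shape_class
            row["indentation_depth_frac"] = r.report.indentation_depth_frac
        rows.append(row)
    return pd.DataFrame(rows)


def run_population(
    params: synthgen.PopulationParams,
    *,
    noise_sd: float = 10.0,
    classify_type: bool = True,
) -> pd.DataFrame:
    """Sample a population, pipeline every phantom, return a tidy frame."""
    specs = synthgen.sample_population(params)
    rng = np.random.default_rng(params.seed + 1)
    results = []
    for i, spec in enumerate(specs):
        res = measure_phantom(
            spec, seed=int(rng.integers(0, 2**31 - 1)), noise_sd=noise_sd,
            classify_type=classify_type)
        results.append(res)
        if (i + 1) % 200 == 0:
            log.info("pipelined %d/%d phantoms", i + 1, len(specs))
    return results_to_frame(results)


def shape_mixture_experiment(
    n: int = 2000,
    seed: int = 0,
    shape_mix=(0.93, 0.045, 0.025),
) -> dict:
    """End-to-end shape-mixture recovery.

    Generates ``n`` phantoms at the given macular/perforated/horseshoe
    mixture, renders, segments, extracts and classifies each, and returns
    the recovered class percentages together with the generated ones.
    """
    params = synthgen.PopulationParams(shape_mix=tuple(shape_mix),
                                       n_synapses=n, seed=seed)
    df = run_population(params, classify_type=False)
    ok = df[df["error"] == ""]
    n_eff = len(ok)
    out = {"n": n, "n_measured": n_eff}
    for cls in ("macular", "perforated", "horseshoe"):
        out[f"percent_{cls}"] = 100.0 * float((ok["shape_class"] == cls).mean())
        out[f"generated_percent_{cls}"] = 100.0 * float(
            (df["true_shape"] == cls).mean())
    return out


def geometry_oracle_experiment(n: int = 200, seed: int = 0) -> dict:
    """Noise-free macular caps: relative error of mesh vs closed-form values.

    Returns the median relative errors of area, perimeter and Feret diameter
    and the median absolute curvature error.
    """
    rng = np.random.default_rng(seed)
    rel_area, rel_perim, rel_feret, abs_curv = [], [], [], []
    for _ in range(n):
        area = float(np.exp(rng.normal(10.84, 0.79)))
        c = float(rng.uniform(0.03, 0.30))
        theta = math.acos(1 - 2 * c)
        R = math.sqrt(area / (4 * math.pi * c))
        spec = synthgen.PhantomSpec(
            sphere_radius_nm=R, cap_angle_rad=theta,
            orientation=tuple(rng.normal(size=3)))
        res = measure_phantom(spec, seed=int(rng.integers(0, 2**31 - 1)),
                              noise_sd=0.0, classify_type=False)
        if res.record is None:
            continue
        rel_area.append(abs(res.record.area_nm2 - res.truth.area_nm2)
                        / res.truth.area_nm2)
        rel_perim.append(abs(res.record.perimeter_nm - res.truth.perimeter_nm)
                         / res.truth.perimeter_nm)
        rel_feret.append(abs(res.record.feret_nm - res.truth.feret_nm)
                         / res.truth.feret_nm)
        abs_curv.append(abs(res.record.curvature - res.truth.curvature))
    return {
        "n": len(rel_area),
        "median_rel_area": float(np.median(rel_area)),
        "median_rel_perimeter": float(np.median(rel_perim)),
        "median_rel_feret": float(np.median(rel_feret)),
        "median_abs_curvature": float(np.median(abs_curv)),
    }


def flat_disc_curvature(
    seed: int = 0,
    *,
    area_nm2: float = 65_299.31,
    tilt_deg: float = 25.0,
) -> float:
    """Curvature measured on a noise-free flat disc rendered at a tilt.

    A perfectly flat apposition surface must score ~0.
    """
    r = math.sqrt(area_nm2 / math.pi)
    t = math.radians(tilt_deg)
    rng = np.random.default_rng(seed)
    phi = float(rng.uniform(0, 2 * math.pi))
    axis = (math.sin(t) * math.cos(phi), math.sin(t) * math.sin(phi), math.cos(t))
    spec = synthgen.PhantomSpec(sphere_radius_nm=r, cap_angle_rad=0.0,
                                orientation=axis)
    res = measure_phantom(spec, seed=seed, noise_sd=0.0, classify_type=False)
    if res.record is None:
        raise SasmorphError(f"flat-disc pipeline failed: {res.error}")
    return float(res.record.curvature)


def lognormal_recovery(
    seed: int = 0,
    *,
    mu: float = 10.84,
    sigma: float = 0.79,
    n: int = 6259,
) -> popstats.FitResult:
    """Draw a seeded log-normal sample of SAS areas and refit it by MLE."""
    rng = np.random.default_rng(seed)
    values = np.exp(rng.normal(mu, sigma, size=n))
    return popstats.fit_lognormal(values)


def exclusion_arithmetic(n_total: int = 7569, n_truncated: int = 678,
                         n_as: int = 6259) -> dict:
    """Bookkeeping percentages of the truncation exclusion and AS fraction.

    Builds the segment population explicitly and runs the partition, so the
    percentages are computed by the pipeline's own exclusion step.
    """
    dummy = []
    for i in range(n_total):
        dummy.append(seg.JunctionSegment(
            segment_id=i + 1,
            voxels=np.array([[1, 1, 1]], dtype=np.int32),
            voxel_size_nm=(3.7, 3.7, 20.0),
            stack_shape=(4, 4, 4),
            truncated=i < n_truncated,
            gray_mean=60.0, gray_min=50.0))
    kept, discarded = seg.exclude_truncated(dummy)
    pct_discarded = 100.0 * len(discarded) / len(dummy)
    pct_as = 100.0 * n_as / len(kept)
    return {
        "n_found": len(dummy),
        "n_discarded": len(discarded),
        "n_kept": len(kept),
        "percent_discarded": pct_discarded,
        "percent_as": pct_as,
    }
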