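"""Population statistics for synapse morphometry.

Covers the analyses run on the measured population: log-normal fitting of
size distributions with goodness-of-fit ranking across candidate families,
per-layer/per-type summary tables (mean +/- SEM with fitted log-normal
location and scale), pairwise Mann-Whitney tests (exact by enumeration for
small tie-free samples, tie-corrected normal approximation otherwise),
Pearson chi-squared contingency tests, and the area-perimeter regression
with the circle reference curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, ValidationError


@dataclass
class FitResult:
    family: str
    location: float       # mu for lognormal/normal
    scale: float          # sigma for lognormal/normal
    shape: float | None   # extra shape parameter (gamma, weibull)
    ks_statistic: float
    aic: float
    n: int


@dataclass
class GroupComparison:
    test: str             # {mann_whitney, chi2, linear_regression}
    statistic: float
    p_value: float
    effect_summary: dict = field(default_factory=dict)
    groups: tuple = ()
    n_per_group: tuple = ()


# ---------------------------------------------------------------------------
# distribution fitting
# ---------------------------------------------------------------------------

def _check_positive(values: np.ndarray, min_n: int) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    if v.size < min_n:
        raise ValidationError(f"need at least {min_n} values, got {v.size}")
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise ValidationError("all values must be positive and finite")
    return v


def fit_lognormal(values) -> FitResult:
    """Maximum-likelihood log-normal fit.

    mu is the mean of the log-values and sigma their ML standard deviation
    (1/n denominator).  The KS statistic is computed against the fitted
    distribution.
    """
    v = _check_positive(values, 3)
    logs = np.log(v)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs))       # MLE: ddof=0
    if sigma == 0:
        raise DegenerateFitError("constant sample: log-normal scale is zero")
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    ks = float(stats.ks_1samp(v, dist.cdf).statistic)
    loglik = float(np.sum(dist.logpdf(v)))
    return FitResult("lognormal", mu, sigma, None, ks, 2 * 2 - 2 * loglik, v.size)


def _fit_family(family: str, v: np.ndarray) -> FitResult:
    if family == "lognormal":
        return fit_lognormal(v)
    if family == "normal":
        mu, sigma = float(np.mean(v)), float(np.std(v))
        if sigma == 0:
            raise DegenerateFitError("constant sample")
        dist = stats.norm(mu, sigma)
        k = 2
        shape = None
        loc, scale = mu, sigma
    elif family == "gamma":
        a, _, scale_ = stats.gamma.fit(v, floc=0)
        dist = stats.gamma(a, loc=0, scale=scale_)
        k = 2
        shape, loc, scale = float(a), 0.0, float(scale_)
    elif family == "weibull":
        c, _, scale_ = stats.weibull_min.fit(v, floc=0)
        dist = stats.weibull_min(c, loc=0, scale=scale_)
        k = 2
        shape, loc, scale = float(c), 0.0, float(scale_)
    else:
        raise ValidationError(f"unknown family {family!r}")
    ks = float(stats.ks_1samp(v, dist.cdf).statistic)
    loglik = float(np.sum(dist.logpdf(v)))
    return FitResult(family, loc, scale, shape, ks, 2 * k - 2 * loglik, v.size)


DEFAULT_FAMILIES = ("lognormal", "normal", "gamma", "weibull")


def rank_families(values, candidates=DEFAULT_FAMILIES) -> list[FitResult]:
    """Fit candidate families by maximum likelihood, rank by KS statistic."""
    v = _check_positive(values, 20)
    fits = [_fit_family(f, v) for f in candidates]
    fits.sort(key=lambda r: r.ks_statistic)
    return fits


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a against b, with the midrank tie convention."""
    allv = np.concatenate([a, b])
    ranks = stats.rankdata(allv)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2)


def _exact_u_counts(n: int, m: int) -> np.ndarray:
    """Number of rank assignments with each U value under the tie-free null.

    Standard counting recurrence N_{n,m}(u) = N_{n-1,m}(u-m) + N_{n,m-1}(u):
    the largest observation is either from sample a (contributing m to U) or
    from sample b (contributing nothing).
    """
    prev = [np.array([1.0]) for _ in range(m + 1)]   # n'=0: U always 0
    for np_ in range(1, n + 1):
        cur: list[np.ndarray] = []
        for m_ in range(0, m + 1):
            arr = np.zeros(np_ * m_ + 1)
            a1 = prev[m_]                 # largest value from sample a
            arr[m_: m_ + len(a1)] += a1
            if m_ > 0:                    # largest value from sample b
                a2 = cur[m_ - 1]
                arr[: len(a2)] += a2
            cur.append(arr)
        prev = cur
    return prev[m]


def mann_whitney(a, b, *, method: str = "auto") -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    ``method``: "exact" enumerates the tie-free null distribution of U with
    the standard counting recurrence; "approx" uses the tie-corrected normal
    approximation with continuity correction; "auto" picks exact when
    min(n) <= 8 and there are no ties.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    n, m = len(a), len(b)
    allv = np.concatenate([a, b])
    has_ties = len(np.unique(allv)) < len(allv)
    u = _u_statistic(a, b)
    if method == "auto":
        method = "exact" if (min(n, m) <= 8 and not has_ties) else "approx"
    if method == "exact":
        if has_ties:
            raise ValidationError("exact Mann-Whitney requires tie-free data")
        counts = _exact_u_counts(n, m)
        probs = counts / counts.sum()
        u_min = min(u, n * m - u)
        p = float(min(1.0, 2.0 * probs[: int(round(u_min)) + 1].sum()))
    else:
        mean = n * m / 2.0
        nn = n + m
        _, t_counts = np.unique(allv, return_counts=True)
        tie_term = ((t_counts ** 3 - t_counts).sum()) / (nn * (nn - 1))
        var = n * m / 12.0 * ((nn + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u - mean) - 0.5) / np.sqrt(var)
            z = max(z, 0.0)
            p = float(2 * stats.norm.sf(z))
            p = min(1.0, p)
    return GroupComparison(
        test="mann_whitney", statistic=u, p_value=p,
        effect_summary={"method": method},
        groups=("a", "b"), n_per_group=(n, m))


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def chi2_contingency(table) -> GroupComparison:
    """Pearson chi-squared test on a contingency table (no Yates correction)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.min() < 0:
        raise ValidationError("table must be a 2D non-negative count matrix")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("zero-margin row or column in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(t, correction=False)
    if (expected < 5).any():
        warnings.warn("some expected counts are below 5; the chi-squared "
                      "approximation may be poor", stacklevel=2)
    return GroupComparison(
        test="chi2", statistic=float(chi2), p_value=float(p),
        effect_summary={"dof": int(dof)},
        n_per_group=tuple(int(x) for x in t.sum(axis=1)))


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def area_perimeter_regression(areas, perimeters) -> GroupComparison:
    """OLS of perimeter on sqrt(area), plus log-log, with circle reference.

    The primary model regresses perimeter on sqrt(area), the natural scale
    on which similar shapes are exactly linear; a circle satisfies
    P = 2 sqrt(pi A).  The log-log fit is reported alongside.
    """
    a = np.asarray(areas, dtype=float).ravel()
    p = np.asarray(perimeters, dtype=float).ravel()
    if a.size != p.size:
        raise ValidationError("areas and perimeters must have equal length")
    if a.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.any(a <= 0) or np.any(p <= 0):
        raise ValidationError("areas and perimeters must be positive")
    x = np.sqrt(a)
    if np.std(x) == 0:
        raise ValidationError("constant predictor")
    res = stats.linregress(x, p)
    res_log = stats.linregress(np.log(a), np.log(p))
    return GroupComparison(
        test="linear_regression",
        statistic=float(res.slope),
        p_value=float(res.pvalue),
        effect_summary={
            "r2": float(res.rvalue ** 2),
            "intercept": float(res.intercept),
            "loglog_slope": float(res_log.slope),
            "loglog_r2": float(res_log.rvalue ** 2),
            "circle_reference": "perimeter = 2*sqrt(pi*area)",
        },
        n_per_group=(a.size,))


def circle_reference_curve(areas) -> np.ndarray:
    """Perimeter of a circle of each given area (plot reference)."""
    return 2.0 * np.sqrt(np.pi * np.asarray(areas, dtype=float))


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def _stratum_row(values: np.ndarray) -> dict:
    out = {"mean": float("nan"), "sem": float("nan"), "n": int(values.size),
           "mu": float("nan"), "sigma": float("nan")}
    if values.size:
        out["mean"] = float(np.mean(values))
        out["sem"] = _sem(values)
        if values.size >= 3 and np.all(values > 0) and np.std(values) > 0:
            fit = fit_lognormal(values)
            out["mu"], out["sigma"] = fit.location, fit.scale
    return out


def build_summary_tables(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-layer x per-type and per-shape summary tables.

    ``records`` needs columns area_nm2, perimeter_nm, curvature,
    synapse_type, shape_class, layer_label.  Returns tables keyed
    ``areas`` / ``perimeters`` / ``curvatures`` (layer x type, mean +/- SEM,
    n, and the fitted log-normal mu/sigma for sizes) and ``shapes``
    (shape x type).  Each layered table ends with an unweighted pooled row
    covering all layers.
    """
    df = records
    required = {"area_nm2", "perimeter_nm", "curvature", "synapse_type",
                "shape_class", "layer_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"records missing columns: {sorted(missing)}")
    layers = sorted(df["layer_label"].astype(str).unique())
    types = ["AS", "SS"]
    tables: dict[str, pd.DataFrame] = {}
    for key, col, with_fit in (("areas", "area_nm2", True),
                               ("perimeters", "perimeter_nm", True),
                               ("curvatures", "curvature", False)):
        rows = []
        for layer in layers + ["all"]:
            sub = df if layer == "all" else df[df["layer_label"].astype(str) == layer]
            row: dict = {"layer": layer}
            for t in types:
                vals = sub.loc[sub["synapse_type"] == t, col].to_numpy(dtype=float)
                st = _stratum_row(vals)
                row[f"{t}_mean"] = st["mean"]
                row[f"{t}_sem"] = st["sem"]
                row[f"{t}_n"] = st["n"]
                if with_fit:
                    row[f"{t}_mu"] = st["mu"]
                    row[f"{t}_sigma"] = st["sigma"]
            rows.append(row)
        tables[key] = pd.DataFrame(rows)
    shape_rows = []
    for shape in ("macular", "perforated", "horseshoe"):
        for t in types + ["AS + SS"]:
            sub = df[df["shape_class"] == shape]
            if t != "AS + SS":
                sub = sub[sub["synapse_type"] == t]
            row = {"shape": shape, "type": t, "n": int(len(sub))}
            for col, name in (("area_nm2", "area"), ("perimeter_nm", "perimeter"),
                              ("curvature", "curvature")):
                vals = sub[col].to_numpy(dtype=float)
                row[f"{name}_mean"] = float(np.mean(vals)) if vals.size else float("nan")
                row[f"{name}_sem"] = _sem(vals)
            shape_rows.append(row)
    tables["shapes"] = pd.DataFrame(shape_rows)
    return tables
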