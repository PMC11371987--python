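"""Iso-gravitational layer profiles and profile statistics.

Any voxel map over a lung mask is summarized along the gravity axis by
partitioning the masked extent into ``n_layers`` (default 100)
equal-thickness iso-gravitational layers and averaging the masked voxel
values per layer. Layer 1 is nondependent (ventral, in supine position);
layer ``n_layers`` is dependent (dorsal).

The gravitational course of a profile is characterized by an ordinary
least-squares line fitted to its progressively leaning central part — the
two central quartiles, layers 25 to 75 inclusive. Profiles from two
conditions are compared by:

* an extra-sum-of-squares F test of a common line against separate lines
  (joint slope + intercept comparison);
* a Z test on the angular coefficients, Z = (b1-b2)/sqrt(se1^2+se2^2),
  for slope-only comparisons;
* Wilcoxon tests (rank-sum for independent groups, signed-rank for
  paired data) for location comparisons of whole-image statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GravProfile",
    "RegressionFit",
    "RegressionComparison",
    "WilcoxonResult",
    "layer_profile",
    "group_profile",
    "fit_central_quartiles",
    "compare_regressions_F",
    "slope_z_test",
    "suvr_vs_nongaseous_regression",
    "wilcoxon_compare",
    "DEFAULT_N_LAYERS",
    "DEFAULT_FIT_RANGE",
]

DEFAULT_N_LAYERS = 100
DEFAULT_FIT_RANGE = (25, 75)  # inclusive layer indices, the two central quartiles


@dataclass
class GravProfile:
    """Per-layer summary of a voxel map along the gravity axis.

    ``layer_mean`` is NaN for empty layers (possible with irregular
    masks); ``layer_n`` carries the voxel (or subject) count per layer and
    ``layer_se`` the standard error of the layer mean.
    """

    layer_mean: np.ndarray
    layer_se: np.ndarray
    layer_n: np.ndarray
    source: str = ""

    @property
    def n_layers(self) -> int:
        return self.layer_mean.size

    @property
    def layer_index(self) -> np.ndarray:
        """1-based layer indices; 1 = nondependent."""
        return np.arange(1, self.n_layers + 1)

    @property
    def empty_layers(self) -> np.ndarray:
        return self.layer_index[self.layer_n == 0]

    @property
    def gravitational_max(self) -> float:
        """Maximum layer mean (the dependent-region peak of the profile)."""
        return float(np.nanmax(self.layer_mean))


@dataclass
class RegressionFit:
    """OLS line fit of layer means against layer index (or another x)."""

    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    n: int
    fit_range: tuple[int, int] = DEFAULT_FIT_RANGE
    # populated only by suvr_vs_nongaseous_regression
    slope_through_origin: float | None = None
    slope_through_origin_se: float | None = None


@dataclass
class RegressionComparison:
    """Result of an F test (joint) or Z test (slopes) between two lines."""

    statistic: float
    p_value: float
    df: tuple[int, int] | None = None
    kind: str = "F"


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Closed-form simple OLS: slope, intercept, slope SE, R^2, SSR.

    For a constant y (zero total variance) the convention is slope 0,
    R^2 = 0.
    """
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points for a line fit, got {n}")
    xm = x.mean()
    ym = y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("degenerate x-range: all abscissae identical")
    sxy = float(np.sum((x - xm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    slope = sxy / sxx
    intercept = ym - slope * xm
    ssr = max(syy - slope * sxy, 0.0)
    sigma2 = ssr / (n - 2)
    slope_se = float(np.sqrt(sigma2 / sxx))
    r_squared = 0.0 if syy == 0 else max(1.0 - ssr / syy, 0.0)
    return slope, intercept, slope_se, r_squared, ssr


def layer_profile(
    values: np.ndarray,
    mask: np.ndarray,
    gravity_axis: int,
    n_layers: int = DEFAULT_N_LAYERS,
    source: str = "",
) -> GravProfile:
    """Average a voxel map over ``n_layers`` iso-gravitational layers.

    The masked extent along the gravity axis (first to last plane holding
    any masked voxel) is split into ``n_layers`` equal-thickness bins;
    each masked voxel is assigned to the bin containing its plane center.
    Works on 2-D slices as well as 3-D volumes.

    Parameters
    ----------
    values, mask : ndarray
        Same shape; mask must be nonempty.
    gravity_axis : int
        Axis aligned with gravity, dependent side at the high-index end.
    n_layers : int
        Number of layers, at least 2 (1 gives the whole-mask mean).
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError(f"mask shape {mask.shape} != values shape {values.shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    if n_layers < 1:
        raise ValueError(f"n_layers must be >= 1, got {n_layers}")

    axis_len = values.shape[gravity_axis]
    planes = np.any(mask, axis=tuple(a for a in range(values.ndim) if a != gravity_axis))
    lo = int(np.argmax(planes))
    hi = axis_len - 1 - int(np.argmax(planes[::-1]))
    extent = hi - lo + 1

    idx = np.nonzero(mask)
    g = idx[gravity_axis]
    # normalized depth of each voxel's plane center within the masked extent
    depth = (g - lo + 0.5) / extent
    layer = np.minimum((depth * n_layers).astype(int), n_layers - 1)
    v = values[idx]

    counts = np.bincount(layer, minlength=n_layers)
    sums = np.bincount(layer, weights=v, minlength=n_layers)
    sq = np.bincount(layer, weights=v * v, minlength=n_layers)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(counts > 1, (sq - counts * mean**2) / np.maximum(counts - 1, 1), 0.0)
        se = np.where(counts > 0, np.sqrt(np.maximum(var, 0.0) / np.maximum(counts, 1)), np.nan)
    if (counts == 0).any():
        warnings.warn(
            f"layer_profile: {int((counts == 0).sum())} of {n_layers} layers are empty",
            stacklevel=2,
        )
    return GravProfile(layer_mean=mean, layer_se=se, layer_n=counts, source=source)


def group_profile(profiles: Sequence[GravProfile], source: str = "") -> GravProfile:
    """Average layer profiles across subjects; SE is the between-subject
    SD divided by sqrt(k).

    A single profile passes through with SE 0 and a warning. Layers empty
    in some subjects use the subjects that populate them.
    """
    if not profiles:
        raise ValueError("no profiles given")
    n_layers = profiles[0].n_layers
    if any(p.n_layers != n_layers for p in profiles):
        raise ValueError("profiles have mismatched layer counts")
    stack = np.stack([p.layer_mean for p in profiles])  # (k, n_layers)
    k_per_layer = np.sum(~np.isnan(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    if len(profiles) == 1:
        warnings.warn("group_profile of a single subject: SE set to 0", stacklevel=2)
        se = np.zeros(n_layers)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(stack, axis=0, ddof=1)
        se = np.where(k_per_layer > 1, sd / np.sqrt(np.maximum(k_per_layer, 1)), 0.0)
    src = source or (profiles[0].source if profiles else "")
    return GravProfile(layer_mean=mean, layer_se=se, layer_n=k_per_layer, source=src)


def _fit_points(
    profile: GravProfile, fit_range: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = fit_range
    sel = (profile.layer_index >= lo) & (profile.layer_index <= hi)
    x = profile.layer_index[sel].astype(float)
    y = profile.layer_mean[sel]
    ok = ~np.isnan(y)
    if ok.sum() < sel.sum():
        warnings.warn(
            f"fit range {fit_range}: {int(sel.sum() - ok.sum())} empty layers excluded",
            stacklevel=3,
        )
    return x[ok], y[ok]


def fit_central_quartiles(
    profile: GravProfile, fit_range: tuple[int, int] = DEFAULT_FIT_RANGE
) -> RegressionFit:
    """OLS of layer mean on layer index over the central quartiles.

    Restricted to layer indices ``fit_range`` (inclusive; default 25-75,
    51 points); empty layers are excluded with a warning.
    """
    x, y = _fit_points(profile, fit_range)
    slope, intercept, slope_se, r2, _ = _ols_line(x, y)
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        r_squared=r2,
        n=x.size,
        fit_range=fit_range,
    )


def compare_regressions_F(
    x_a: np.ndarray, y_a: np.ndarray, x_b: np.ndarray, y_b: np.ndarray
) -> RegressionComparison:
    """Extra-sum-of-squares F test: one common line vs. separate lines.

    The reduced model fits a single slope and intercept to the pooled
    points; the full model fits each group its own line. The statistic

        F = [(SSR_pooled - SSR_separate)/2] / [SSR_separate/(nA+nB-4)]

    tests slope and intercept jointly (numerator df 2).
    """
    x_a = np.asarray(x_a, dtype=float).ravel()
    y_a = np.asarray(y_a, dtype=float).ravel()
    x_b = np.asarray(x_b, dtype=float).ravel()
    y_b = np.asarray(y_b, dtype=float).ravel()
    if x_a.size != y_a.size or x_b.size != y_b.size:
        raise ValueError("x and y lengths differ within a group")
    if x_a.size < 3 or x_b.size < 3:
        raise ValueError("each group needs at least 3 points")
    *_, ssr_a = _ols_line(x_a, y_a)
    *_, ssr_b = _ols_line(x_b, y_b)
    *_, ssr_pooled = _ols_line(np.concatenate([x_a, x_b]), np.concatenate([y_a, y_b]))
    ssr_sep = ssr_a + ssr_b
    df2 = x_a.size + x_b.size - 4
    if ssr_sep <= 0:
        # both groups exactly linear: identical lines -> F=0, else infinite
        f_stat = 0.0 if ssr_pooled <= 1e-30 else float("inf")
    else:
        f_stat = max((ssr_pooled - ssr_sep) / 2.0, 0.0) / (ssr_sep / df2)
    p = float(stats.f.sf(f_stat, 2, df2))
    return RegressionComparison(statistic=float(f_stat), p_value=p, df=(2, df2), kind="F")


def slope_z_test(b1: float, se1: float, b2: float, se2: float) -> RegressionComparison:
    """Z test for the equality of two regression slopes.

    Z = (b1 - b2) / sqrt(se1^2 + se2^2), two-sided p from the standard
    normal.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("slope standard errors must be positive")
    z = (b1 - b2) / float(np.hypot(se1, se2))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return RegressionComparison(statistic=float(z), p_value=p, df=None, kind="Z")


def suvr_vs_nongaseous_regression(
    suvr_profile: GravProfile,
    nongaseous_profile: GravProfile,
    fit_range: tuple[int, int] = DEFAULT_FIT_RANGE,
) -> RegressionFit:
    """Regress SUVR layer means (y) on nongaseous-content layer means (x).

    Uses the leaning part of both profiles (default layers 25-75) and
    requires the two profiles to share the layer grid. Besides the
    ordinary fit, the zero-intercept slope sum(xy)/sum(x^2) and its SE are
    reported, which eases comparing angular coefficients across
    conditions.
    """
    if suvr_profile.n_layers != nongaseous_profile.n_layers:
        raise ValueError("profiles have mismatched layer counts")
    lo, hi = fit_range
    sel = (suvr_profile.layer_index >= lo) & (suvr_profile.layer_index <= hi)
    x = nongaseous_profile.layer_mean[sel]
    y = suvr_profile.layer_mean[sel]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    slope, intercept, slope_se, r2, _ = _ols_line(x, y)
    # zero-intercept variant
    sxx0 = float(np.sum(x * x))
    b0 = float(np.sum(x * y)) / sxx0
    ssr0 = float(np.sum((y - b0 * x) ** 2))
    se0 = float(np.sqrt(ssr0 / (x.size - 1) / sxx0))
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        r_squared=r2,
        n=x.size,
        fit_range=fit_range,
        slope_through_origin=b0,
        slope_through_origin_se=se0,
    )


def wilcoxon_compare(
    group_a: Sequence[float], group_b: Sequence[float], paired: bool = False
) -> WilcoxonResult:
    """Nonparametric location comparison of two groups.

    Unpaired data use the Wilcoxon rank-sum (Mann-Whitney U) test; paired
    data the Wilcoxon signed-rank test. Paired samples with all-zero
    differences are degenerate: the result is flagged and carries p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired groups must have equal lengths")
        if np.all(a == b):
            warnings.warn("all paired differences are zero; signed-rank test degenerate", stacklevel=2)
            return WilcoxonResult(statistic=0.0, p_value=1.0, method="signed-rank", degenerate=True)
        res = stats.wilcoxon(a, b)
        return WilcoxonResult(float(res.statistic), float(res.pvalue), "signed-rank")
    # exact null distribution for the small tie-free samples typical of
    # animal cohorts; normal approximation for larger or tied data
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (no_ties and max(a.size, b.size) <= 25) else "auto"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return WilcoxonResult(float(res.statistic), float(res.pvalue), "rank-sum")
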