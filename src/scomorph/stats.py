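"""Group statistics, co-expression regression and 2D transcript density maps.

Group comparisons follow a normality-gated decision tree common in
biomedical practice: per-group normality is screened with a
Kolmogorov–Smirnov-type test (Lilliefors correction, since mean and SD
are estimated from the sample — the plain KS null would be
anti-conservative); two Gaussian groups are compared with Welch's t-test,
more than two with one-way ANOVA plus Dunnett's comparisons against a
control; non-Gaussian data fall to Mann–Whitney U (two groups) or
Kruskal–Wallis with Dunn's pairwise post-hoc (more groups).  The
rank-based branch uses Dunn's test, the standard partner of
Kruskal–Wallis; Dunnett's procedure applies to the parametric branch.

Density maps are Gaussian-kernel intensity surfaces in the spatial
point-pattern convention: the surface integrates to (approximately) the
number of points, i.e. units are transcripts per µm².
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

NORMALITY_ALPHA = 0.05


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    normality_p: list[float]
    #: one row per pairwise comparison: group_a, group_b, statistic,
    #: p_unadjusted, p_adjusted (adjusted == unadjusted for 2 groups)
    comparisons: pd.DataFrame
    alpha: float = 0.05


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float              # slope t-test
    x_band: np.ndarray          # sorted x at which the band is evaluated
    band_lower: np.ndarray      # pointwise 95% CI of the mean response
    band_upper: np.ndarray
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x)


@dataclass
class DensitySurface:
    grid: np.ndarray            # (ny, nx) intensity, points per µm²
    extent_um: tuple[float, float]   # (width, height)
    bandwidth_um: float
    cell_area_um2: float

    def total_mass(self) -> float:
        return float(self.grid.sum() * self.cell_area_um2)


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

def _normality_p(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=np.float64)
    if np.ptp(values) == 0:  # degenerate: constant sample is not Gaussian
        return 0.0
    if len(values) < 4:
        # Lilliefors tables need n >= 4; fall back to the plain KS statistic
        # with estimated moments (essentially powerless at n = 3, so tiny
        # groups route to the parametric branch)
        res = sps.kstest(values, "norm", args=(values.mean(), values.std(ddof=1)))
        return float(res.pvalue)
    _, p = lilliefors(values, dist="norm")
    return float(p)


def _dunn_posthoc(groups: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests with Bonferroni adjustment."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (N - 1))
    var_base = N * (N + 1) / 12 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        rows.append({"group_a": names[i], "group_b": names[j],
                     "statistic": z, "p_unadjusted": p,
                     "p_adjusted": min(p * m, 1.0)})
    return pd.DataFrame(rows)


def compare_groups(groups: list[np.ndarray], group_names: list[str] | None = None,
                   control: int | str = 0, method: str = "auto",
                   alpha: float = 0.05) -> GroupComparison:
    """Compare >= 2 numeric groups via the normality-gated decision tree.

    ``method`` may force a branch (``"welch"``, ``"mannwhitney"``,
    ``"anova"``, ``"kruskal"``); ``"auto"`` applies the gate at
    alpha = 0.05 per group.  The parametric >2-group branch runs
    Dunnett's comparisons against ``control`` (index or name); the
    rank-based branch runs Dunn's all-pairwise test.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 3 for g in groups):
        raise ValueError("every group needs at least 3 values")
    names = group_names or [f"g{i}" for i in range(len(groups))]
    ctrl_idx = names.index(control) if isinstance(control, str) else int(control)

    normality_p = [_normality_p(g) for g in groups]
    if method == "auto":
        all_normal = all(p > NORMALITY_ALPHA for p in normality_p)
        if len(groups) == 2:
            method = "welch" if all_normal else "mannwhitney"
        else:
            method = "anova" if all_normal else "kruskal"

    if method == "welch":
        res = sps.ttest_ind(groups[0], groups[1], equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        comp = pd.DataFrame([{"group_a": names[0], "group_b": names[1],
                              "statistic": stat, "p_unadjusted": p,
                              "p_adjusted": p}])
        name = "welch_t"
    elif method == "mannwhitney":
        res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        comp = pd.DataFrame([{"group_a": names[0], "group_b": names[1],
                              "statistic": stat, "p_unadjusted": p,
                              "p_adjusted": p}])
        name = "mann_whitney_u"
    elif method == "anova":
        res = sps.f_oneway(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
        treat_idx = [i for i in range(len(groups)) if i != ctrl_idx]
        dres = sps.dunnett(*[groups[i] for i in treat_idx],
                           control=groups[ctrl_idx])
        # unadjusted reference: pooled-variance t against the control,
        # same df as Dunnett's marginal comparisons
        nobs = np.array([len(g) for g in groups])
        df = nobs.sum() - len(groups)
        s2 = sum(((len(g) - 1) * g.var(ddof=1)) for g in groups) / df
        rows = []
        for k, i in enumerate(treat_idx):
            se = np.sqrt(s2 * (1 / nobs[i] + 1 / nobs[ctrl_idx]))
            t = (groups[i].mean() - groups[ctrl_idx].mean()) / se
            rows.append({"group_a": names[i], "group_b": names[ctrl_idx],
                         "statistic": float(dres.statistic[k]),
                         "p_unadjusted": float(2 * sps.t.sf(abs(t), df)),
                         "p_adjusted": float(dres.pvalue[k])})
        comp = pd.DataFrame(rows)
        name = "anova_dunnett"
    elif method == "kruskal":
        res = sps.kruskal(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
        comp = _dunn_posthoc(groups, names)
        name = "kruskal_dunn"
    else:
        raise ValueError(f"unknown method {method!r}")

    return GroupComparison(test_name=name, statistic=stat, p_value=p,
                           normality_p=normality_p, comparisons=comp,
                           alpha=alpha)


# ---------------------------------------------------------------------------
# Co-expression regression
# ---------------------------------------------------------------------------

def linear_coexpression(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Ordinary least squares y ~ x with a pointwise 95% band of the mean.

    The band (evaluated at the sorted observed x) is the confidence
    region of the fitted line, narrowest at the mean of x.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    xs = np.sort(x)
    pred = fit.get_prediction(sm.add_constant(xs))
    ci = pred.conf_int(alpha=0.05)
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        x_band=xs,
        band_lower=ci[:, 0],
        band_upper=ci[:, 1],
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------

def _silverman_bandwidth(points_um: np.ndarray) -> float:
    """Normal-reference bandwidth, averaged over the two coordinates."""
    n = len(points_um)
    if n < 2:
        return 1.0
    sd = points_um.std(axis=0, ddof=1).mean()
    return float(max(sd * n ** (-1 / 6), 1e-6))


def density_map(points_xy_px: np.ndarray, pixel_size_um: float,
                bandwidth_um: float | None = None,
                grid_shape: tuple[int, int] = (256, 256),
                extent_um: tuple[float, float] | None = None) -> DensitySurface:
    """Gaussian-kernel intensity surface of a transcript point pattern.

    ``points_xy_px`` is (n, 2) of (x, y) pixel coordinates; the surface
    is evaluated on a regular ``grid_shape = (ny, nx)`` grid over
    ``extent_um`` (defaults to the point bounding box padded by 3
    bandwidths).  Kernel mass outside the extent is truncated, so the
    integral over the grid slightly undershoots n for edge points.  An
    empty point set yields a zero surface with a warning.
    """
    points = np.asarray(points_xy_px, dtype=np.float64).reshape(-1, 2) * pixel_size_um
    ny, nx = grid_shape
    if len(points) == 0:
        warnings.warn("empty spot table: returning zero density surface",
                      stacklevel=2)
        extent = extent_um or (1.0, 1.0)
        cell = (extent[0] / nx) * (extent[1] / ny)
        return DensitySurface(np.zeros(grid_shape), extent, bandwidth_um or 1.0, cell)
    h = bandwidth_um if bandwidth_um is not None else _silverman_bandwidth(points)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if extent_um is None:
        pad = 3 * h
        extent_um = (points[:, 0].max() + pad, points[:, 1].max() + pad)
    wx, wy = extent_um
    xs = (np.arange(nx) + 0.5) * (wx / nx)
    ys = (np.arange(ny) + 0.5) * (wy / ny)
    # separable Gaussian: accumulate outer products per point (chunked)
    grid = np.zeros((ny, nx))
    norm = 1.0 / (2 * np.pi * h * h)
    chunk = 256
    for start in range(0, len(points), chunk):
        pts = points[start:start + chunk]
        kx = np.exp(-((xs[None, :] - pts[:, 0:1]) ** 2) / (2 * h * h))
        ky = np.exp(-((ys[None, :] - pts[:, 1:2]) ** 2) / (2 * h * h))
        grid += norm * np.einsum("py,px->yx", ky, kx)
    cell = (wx / nx) * (wy / ny)
    return DensitySurface(grid, (wx, wy), h, cell)
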