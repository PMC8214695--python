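"""Rate-paleoclimate correlation: Pearson and DCCA per posterior draw.

For every retained posterior draw of the diversification analysis, the
speciation-rate trajectory is correlated against a paleotemperature series
on the same age grid, with both the plain product-moment coefficient and
the detrended cross-correlation coefficient rho_DCCA, which is robust to
the nonstationarity and autocorrelation both series carry.  A one-sample
Student's t test then asks whether the mean coefficient across draws
differs from zero.

rho_DCCA(n): integrate both demeaned series into profiles, slide
overlapping boxes of length n (step 1), remove a least-squares linear
trend from each profile inside each box, and form the ratio of the summed
residual cross-products to the geometric mean of the summed residual
squares.  It equals 1 for y = a*x + b with a > 0 and -1 for a < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .datatypes import ClimateSeries, ValidationError
from .paleoclimate import resample_to_grid


def pearson(x, y) -> float:
    """Product-moment correlation; raises on zero variance or length < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("pearson needs equal-length series, len >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in series")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def _box_residual_maker(n: int) -> np.ndarray:
    """(I - H) for a linear fit on indices 0..n-1: maps a box to residuals."""
    idx = np.arange(n, dtype=float)
    M = np.column_stack([np.ones(n), idx])
    H = M @ np.linalg.solve(M.T @ M, M.T)
    return np.eye(n) - H


def dcca_coefficient(x, y, n: int) -> float:
    """Detrended cross-correlation coefficient at box length ``n``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    N = x.size
    if y.size != N or N < n + 1:
        raise ValidationError("series too short for the requested box length")
    if not (4 <= n <= N // 2):
        raise ValidationError("box length must satisfy 4 <= n <= len/2")
    X = np.cumsum(x - x.mean())
    Y = np.cumsum(y - y.mean())
    R = _box_residual_maker(n)
    wx = sliding_window_view(X, n) @ R.T
    wy = sliding_window_view(Y, n) @ R.T
    f2x = float(np.sum(wx * wx))
    f2y = float(np.sum(wy * wy))
    if f2x <= 0 or f2y <= 0:
        raise ValidationError("degenerate (constant) profile in DCCA")
    num = float(np.sum(wx * wy))
    if num == f2x and num == f2y:  # identical residuals: exactly coherent
        return 1.0
    rho = num / math.sqrt(f2x * f2y)
    return max(-1.0, min(1.0, rho))


def default_windows(length: int, k: int = 6) -> list:
    """Geometric grid of ``k`` box lengths from 4 up to length/4."""
    hi = max(length // 4, 4)
    sizes = np.unique(np.round(np.geomspace(4, hi, k)).astype(int))
    return [int(s) for s in sizes if 4 <= s <= length // 2]


def t_test_mean_zero(coeffs) -> tuple:
    """Two-sided one-sample t test of the mean against zero.

    Degenerate inputs: identical values give t = +/-inf (p = 0) unless the
    common value is zero, in which case t = 0, p = 1.
    """
    c = np.asarray(coeffs, dtype=float)
    c = c[np.isfinite(c)]
    if c.size < 2:
        raise ValidationError("t test needs at least two finite values")
    if np.ptp(c) == 0:
        if c[0] == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, c[0]), 0.0
    res = stats.ttest_1samp(c, 0.0)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationResult:
    """Per-draw coefficients plus the t tests of their means."""

    per_draw_pearson: np.ndarray
    per_draw_dcca: np.ndarray          # median over windows, per draw
    per_window_dcca: dict              # n -> array over draws
    window_sizes: list
    pearson_t: float
    pearson_p: float
    dcca_t: float
    dcca_p: float
    n_excluded: int
    climate_window: str
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "mean_pearson": float(np.nanmean(self.per_draw_pearson)),
            "mean_dcca": float(np.nanmean(self.per_draw_dcca)),
            "pearson_t": self.pearson_t, "pearson_p": self.pearson_p,
            "dcca_t": self.dcca_t, "dcca_p": self.dcca_p,
            "n_draws": int(self.per_draw_pearson.size),
            "n_excluded": self.n_excluded,
            "windows": list(self.window_sizes),
        }


def correlate_draws(draws, climate: ClimateSeries, windows=None,
                    use: str = "speciation") -> CorrelationResult:
    """Correlate each draw's rate trajectory with paleotemperature.

    ``use`` selects the speciation rate (default, matching the analysis
    this stage supports) or the net diversification rate.  Both series are
    oriented past->present before the DCCA profiling.  Draws with a flat
    trajectory have no defined coefficient; they are excluded and counted.
    """
    if not draws:
        raise ValidationError("no draws supplied")
    full_grid = draws[0].grid
    # restrict to the ages the climate record actually covers (bin-mean
    # smoothing trims half a window from each end of the record)
    keep = (full_grid >= climate.age[0] - 1e-12) & \
        (full_grid <= climate.age[-1] + 1e-12)
    if keep.sum() < 8:
        raise ValidationError("climate record barely overlaps the rate grid")
    grid = full_grid[keep]
    clim = resample_to_grid(climate, grid)
    temp = clim.value
    if np.ptp(temp) == 0:
        raise ValidationError("temperature series is constant on the grid")
    if windows is None:
        windows = default_windows(grid.size)
    if not windows:
        raise ValidationError("no admissible DCCA windows for this grid")
    # orient past -> present (descending age)
    temp_o = temp[::-1]

    rs, rhos = [], []
    per_window = {n: [] for n in windows}
    n_excluded = 0
    for d in draws:
        if d.grid.shape != full_grid.shape or \
                not np.allclose(d.grid, full_grid):
            raise ValidationError("draws carry inconsistent age grids")
        traj = d.rate_trajectory if use == "speciation" else d.net_trajectory
        traj = traj[keep]
        if np.ptp(traj) == 0:
            n_excluded += 1
            continue
        x = traj[::-1]
        rs.append(pearson(x, temp_o))
        vals = [dcca_coefficient(x, temp_o, n) for n in windows]
        for n, v in zip(windows, vals):
            per_window[n].append(v)
        rhos.append(float(np.median(vals)))
    if len(rs) < 2:
        raise ValidationError(
            f"fewer than two draws with defined coefficients "
            f"({n_excluded} excluded)")
    rs = np.array(rs)
    rhos = np.array(rhos)
    t_r, p_r = t_test_mean_zero(rs)
    t_d, p_d = t_test_mean_zero(rhos)
    return CorrelationResult(
        per_draw_pearson=rs, per_draw_dcca=rhos,
        per_window_dcca={n: np.array(v) for n, v in per_window.items()},
        window_sizes=list(windows),
        pearson_t=t_r, pearson_p=p_r, dcca_t=t_d, dcca_p=p_d,
        n_excluded=n_excluded, climate_window=climate.window)
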