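"""Group statistics and kernel-density maps.

The statistical unit throughout is the scene (tomogram or image), not the
pooled segment, so n is the number of scenes per condition. Dispersion is
reported as mean +/- SEM. Multi-group comparisons use one-way ANOVA with
Tukey HSD pairwise adjustment; two-group comparisons use an F-test of
variance equality followed by Student's t (equal variances retained) or
Welch's t (rejected at alpha = 0.05).

2D density maps use a product-Gaussian kernel estimate with per-axis
Scott's-rule bandwidths (h_i = sigma_i * n^(-1/6) for 2D data), evaluated
on a regular grid spanning the data range padded by two bandwidths and
normalized to unit integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class GroupSummary:
    """Per-condition summary over scenes: mean +/- SEM with n."""

    condition: str
    values: np.ndarray
    mean: float
    sem: float
    n: int

    @classmethod
    def from_values(cls, condition: str, values) -> "GroupSummary":
        v = np.asarray(values, float)
        if v.size == 0:
            raise ValidationError(f"condition {condition!r}: no values")
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size >= 2 else np.nan
        return cls(condition=condition, values=v, mean=float(v.mean()),
                   sem=sem, n=int(v.size))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    tukey: pd.DataFrame  # group_a, group_b, mean_diff, p_adj


def anova_tukey(
    groups: list[np.ndarray], labels: list[str] | None = None
) -> AnovaResult:
    """One-way ANOVA across >= 2 groups plus Tukey HSD pairwise p-values."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every group needs n >= 2")
    pooled = np.concatenate(arrays)
    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if within == 0 and np.allclose(pooled, pooled[0]):
        raise DegenerateInputError("all values identical: ANOVA undefined")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    # zero within-variance with distinct means legitimately yields F = inf
    with np.errstate(divide="ignore", invalid="ignore"):
        F, p = sps.f_oneway(*arrays)
        hsd = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append((
                labels[i], labels[j],
                float(arrays[i].mean() - arrays[j].mean()),
                float(hsd.pvalue[i, j]),
            ))
    tukey = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p_adj"])
    return AnovaResult(F=float(F), p=float(p), tukey=tukey)


@dataclass(frozen=True)
class FThenTResult:
    F: float
    F_p: float
    t: float
    t_p: float
    variant: str  # "student" | "welch"


def f_then_t(a, b, alpha: float = 0.05) -> FThenTResult:
    """F-test of variance equality, then the matching two-sample t-test.

    The two-sided variance-ratio F-test (F = s_a^2 / s_b^2) selects the
    t variant: Student's pooled t when equality is retained (F p >= alpha),
    Welch's t otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both samples need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        raise DegenerateInputError("constant identical inputs")
    if vb == 0:
        F, F_p = np.inf, 0.0
    else:
        F = va / vb
        cdf = sps.f.cdf(F, a.size - 1, b.size - 1)
        F_p = float(2 * min(cdf, 1 - cdf))
    equal_var = F_p >= alpha
    t, t_p = sps.ttest_ind(a, b, equal_var=equal_var)
    return FThenTResult(F=float(F), F_p=float(F_p), t=float(t), t_p=float(t_p),
                        variant="student" if equal_var else "welch")


@dataclass(frozen=True)
class DensityMap:
    """A normalized 2D kernel-density grid with axis metadata."""

    x_label: str
    y_label: str
    grid: np.ndarray  # (ny, nx), >= 0
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    bandwidth: tuple[float, float]

    @property
    def x_centers(self) -> np.ndarray:
        return np.linspace(*self.x_range, self.grid.shape[1])

    @property
    def y_centers(self) -> np.ndarray:
        return np.linspace(*self.y_range, self.grid.shape[0])

    def mode(
        self,
        x_bounds: tuple[float, float] | None = None,
        y_bounds: tuple[float, float] | None = None,
    ) -> tuple[float, float]:
        """(x, y) location of the density maximum.

        Optional bounds restrict the search to the variable's physical
        support (the padded grid extends beyond the data range, where the
        kernel tails can place a spurious argmax for boundary-concentrated
        data, e.g. axial angles near 0).
        """
        gx, gy = self.x_centers, self.y_centers
        mx = (np.ones_like(gx, bool) if x_bounds is None
              else (gx >= x_bounds[0]) & (gx <= x_bounds[1]))
        my = (np.ones_like(gy, bool) if y_bounds is None
              else (gy >= y_bounds[0]) & (gy <= y_bounds[1]))
        sub = self.grid[np.ix_(my, mx)]
        iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
        return float(gx[mx][ix]), float(gy[my][iy])


def kde_map(
    samples: np.ndarray,
    grid_shape: tuple[int, int] = (128, 128),
    bandwidth: tuple[float, float] | None = None,
    x_label: str = "x",
    y_label: str = "y",
) -> DensityMap:
    """Product-Gaussian KDE of (x, y) samples on a regular grid.

    Bandwidths default to per-axis Scott's rule; the grid spans the data
    range padded by two bandwidths and the returned density integrates
    to ~1 over the grid domain.
    """
    samples = np.asarray(samples, float)
    if samples.ndim != 2 or samples.shape[1] != 2 or samples.shape[0] < 2:
        raise ValidationError("kde_map needs >= 2 (x, y) samples")
    x, y = samples[:, 0], samples[:, 1]
    n = samples.shape[0]
    if bandwidth is None:
        hx = float(x.std(ddof=1)) * n ** (-1.0 / 6.0)
        hy = float(y.std(ddof=1)) * n ** (-1.0 / 6.0)
    else:
        hx, hy = float(bandwidth[0]), float(bandwidth[1])
    if hx <= 0 or hy <= 0:
        raise DegenerateInputError(
            "zero bandwidth (all samples identical on one axis); "
            "pass an explicit bandwidth"
        )
    ny, nx = grid_shape
    gx = np.linspace(x.min() - 2 * hx, x.max() + 2 * hx, nx)
    gy = np.linspace(y.min() - 2 * hy, y.max() + 2 * hy, ny)
    # separable kernels: (grid, sample) weight matrices per axis
    wx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2)
    wy = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2)
    grid = (wy @ wx.T) / (n * 2 * np.pi * hx * hy)
    # renormalize over the finite grid domain
    dx = gx[1] - gx[0]
    dy = gy[1] - gy[0]
    total = grid.sum() * dx * dy
    if total > 0:
        grid = grid / total
    return DensityMap(
        x_label=x_label, y_label=y_label, grid=grid,
        x_range=(float(gx[0]), float(gx[-1])),
        y_range=(float(gy[0]), float(gy[-1])),
        bandwidth=(hx, hy),
    )
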