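"""Grade-based (partial credit) DOOR analysis.

A grading key assigns each DOOR category an academic-style grade: 100 for
the most desirable category, 0 for the least desirable (death), and partial
credit in between.  The treatment contrast is the difference in mean grades
(experimental − control) on the 0–100 scale, compared with a large-sample
unpooled-variance normal test.

Because the mean grade is linear in the grades, the contrast is an affine
function of each free grade — sweeping two interior grades over [0,100]²
yields the contour plots used for robustness analysis, and the tipping
boundary is the locus in grading-key space separating keys that favor one
therapy from keys favoring the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import DoorTable, EffectEstimate, GradingKey

__all__ = [
    "GradeGridResult",
    "apply_grading",
    "partial_credit_diff",
    "grade_grid",
    "tipping_boundary",
    "grid_long_frame",
]

FAVOR_EXPERIMENTAL = 1
FAVOR_INDETERMINATE = 0
FAVOR_CONTROL = -1


def apply_grading(table: DoorTable, key: GradingKey) -> dict[str, float]:
    """Per-arm mean grade Σ_k count_k·grade_k / n_arm on the 0–100 scale."""
    if key.K != table.K:
        raise ValueError(f"grading key has {key.K} grades but the table has {table.K} categories")
    g = key.as_array()
    out = {}
    for arm_idx, arm in enumerate(table.arms):
        c = table.counts[arm_idx].astype(float)
        out[arm] = float(np.dot(c, g) / c.sum())
    return out


def _mean_var(counts: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """Mean grade, (Bessel-corrected) sample variance and n for one arm."""
    c = counts.astype(float)
    n = c.sum()
    mu = float(np.dot(c, g) / n)
    ss = float(np.dot(c, (g - mu) ** 2))
    var = ss / (n - 1.0) if n > 1 else 0.0
    return mu, var, n


def partial_credit_diff(
    table: DoorTable, key: GradingKey, level: float = 0.95
) -> EffectEstimate:
    """Between-arm difference in mean grades with CI and two-sided p-value.

    Large-sample normal comparison of means with unpooled variances.  When
    both arms are degenerate (zero variance) the CI collapses to the point
    and p = 1.
    """
    if key.K != table.K:
        raise ValueError(f"grading key has {key.K} grades but the table has {table.K} categories")
    if table.n1 < 2 or table.n2 < 2:
        raise ValueError("need at least 2 participants per arm")
    g = key.as_array()
    mu1, v1, n1 = _mean_var(table.counts[0], g)
    mu2, v2, n2 = _mean_var(table.counts[1], g)
    diff = mu1 - mu2
    se = float(np.sqrt(v1 / n1 + v2 / n2))
    z = norm.ppf(0.5 + level / 2.0)
    if se == 0.0:
        import warnings

        warnings.warn("zero grade variance in both arms: degenerate contrast", UserWarning,
                      stacklevel=2)
        return EffectEstimate(diff, diff, diff, level, 1.0,
                              "normal-unpooled (degenerate)", "grade-points", int(n1), int(n2))
    p = float(2.0 * norm.sf(abs(diff) / se))
    return EffectEstimate(
        diff, diff - z * se, diff + z * se, level, p,
        "normal-unpooled", "grade-points", int(n1), int(n2),
        extras={"mean_experimental": mu1, "mean_control": mu2, "se": se},
    )


@dataclass(frozen=True)
class GradeGridResult:
    """Partial-credit contrast over a grid of grades for two free categories.

    ``diff[i, j]`` and ``p[i, j]`` correspond to grade ``grid1[i]`` for
    ``free_levels[0]`` and ``grid2[j]`` for ``free_levels[1]``.  ``favored``
    is +1 where the experimental arm is significantly favored (diff > 0,
    p < alpha), −1 for control, 0 where indeterminate.  ``monotone`` marks
    cells whose implied full key is monotone nonincreasing.
    """

    free_levels: tuple[int, int]
    grid1: np.ndarray
    grid2: np.ndarray
    diff: np.ndarray
    p: np.ndarray
    favored: np.ndarray
    monotone: np.ndarray
    alpha: float
    fixed_grades: dict[int, float]

    def __post_init__(self) -> None:
        shape = (len(self.grid1), len(self.grid2))
        for name in ("diff", "p", "favored", "monotone"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} matrix does not match the grid shape {shape}")


def _full_key_grades(
    K: int, free_levels: tuple[int, int], g_free: tuple[float, float],
    fixed_grades: dict[int, float],
) -> np.ndarray:
    g = np.empty(K)
    g[0], g[-1] = 100.0, 0.0
    g[free_levels[0] - 1], g[free_levels[1] - 1] = g_free
    for k, v in fixed_grades.items():
        g[k - 1] = v
    return g


def grade_grid(
    table: DoorTable,
    free_levels: tuple[int, int] = (2, 3),
    fixed_grades: dict[int, float] | None = None,
    step: float = 1.0,
    alpha: float = 0.05,
    level: float = 0.95,
) -> GradeGridResult:
    """Sweep the grades of two interior categories over [0, 100]².

    ``fixed_grades`` supplies grades for the remaining interior categories
    (1-based indices); the first and last categories stay pinned at 100 and
    0.  The default 1-point step gives a 101×101 grid.  Cells where the
    implied key is non-monotone are evaluated anyway and flagged.
    """
    K = table.K
    lo, hi = free_levels
    if lo in (1, K) or hi in (1, K):
        raise ValueError("free levels must be interior categories (grades 100/0 are pinned)")
    if lo == hi or not (1 < lo <= K - 1 and 1 < hi <= K - 1):
        raise ValueError(f"free levels must be two distinct interior categories of 1..{K}")
    fixed_grades = dict(fixed_grades or {})
    interior = set(range(2, K)) - {lo, hi}
    missing = interior - set(fixed_grades)
    if missing:
        raise ValueError(f"fixed grades required for interior categories {sorted(missing)}")
    bad = set(fixed_grades) - interior
    if bad:
        raise ValueError(f"fixed grades given for non-free/non-interior categories {sorted(bad)}")

    grid1 = np.arange(0.0, 100.0 + step / 2.0, step)
    grid2 = grid1.copy()

    # diff is affine in each free grade: diff = base + s_lo·g_lo + s_hi·g_hi
    a = table.counts[0].astype(float) / table.n1
    b = table.counts[1].astype(float) / table.n2
    slope = a - b                                    # per category, grade-points per grade-point
    g0 = _full_key_grades(K, free_levels, (0.0, 0.0), fixed_grades)
    base = float(np.dot(slope, g0))
    diff = base + slope[lo - 1] * grid1[:, None] + slope[hi - 1] * grid2[None, :]

    # per-cell standard errors need the full second moment; vectorized over the grid
    G = g0[None, None, :] * np.ones((len(grid1), len(grid2), 1))
    G[:, :, lo - 1] = grid1[:, None]
    G[:, :, hi - 1] = grid2[None, :]
    n1, n2 = table.n1, table.n2
    mu1 = G @ a
    mu2 = G @ b
    v1 = ((G - mu1[..., None]) ** 2 @ a) * n1 / (n1 - 1)
    v2 = ((G - mu2[..., None]) ** 2 @ b) * n2 / (n2 - 1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, diff / se, 0.0)
    p = 2.0 * norm.sf(np.abs(zstat))
    p[se == 0] = 1.0

    favored = np.zeros_like(diff, dtype=np.int8)
    favored[(p < alpha) & (diff > 0)] = FAVOR_EXPERIMENTAL
    favored[(p < alpha) & (diff < 0)] = FAVOR_CONTROL

    sorted_levels = sorted([1, lo, hi, K] + sorted(interior))
    grades_by_level = {1: 100.0, K: 0.0, **fixed_grades}
    # monotone iff grades are nonincreasing along category order
    seq_fixed = [grades_by_level.get(k) for k in sorted_levels]
    pos_lo = sorted_levels.index(lo)
    pos_hi = sorted_levels.index(hi)
    seq = np.array([v if v is not None else np.nan for v in seq_fixed])
    M = np.tile(seq, (len(grid1), len(grid2), 1))
    M[:, :, pos_lo] = grid1[:, None]
    M[:, :, pos_hi] = grid2[None, :]
    monotone = np.all(np.diff(M, axis=2) <= 1e-12, axis=2)

    return GradeGridResult(
        free_levels=(lo, hi), grid1=grid1, grid2=grid2, diff=diff, p=p,
        favored=favored, monotone=monotone, alpha=alpha, fixed_grades=fixed_grades,
    )


def tipping_boundary(grid: GradeGridResult) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Cell-edge segments separating regions of different favored status.

    Marching-squares-style: for every pair of adjacent grid cells whose
    favored status differs, the shared edge (at the midpoint between the two
    grade values, spanning one grid step in the other coordinate) is
    emitted, in (g_free1, g_free2) coordinates.  Empty when one status
    covers the whole grid.
    """
    fav = grid.favored
    x, y = grid.grid1, grid.grid2
    segments: list[tuple[tuple[float, float], tuple[float, float]]] = []
    hx = np.diff(x).mean() / 2.0 if len(x) > 1 else 0.5
    hy = np.diff(y).mean() / 2.0 if len(y) > 1 else 0.5
    # vertical edges between horizontally adjacent cells (differ along axis 0 = g1)
    d0 = fav[1:, :] != fav[:-1, :]
    for i, j in zip(*np.nonzero(d0)):
        xm = (x[i] + x[i + 1]) / 2.0
        segments.append(((xm, y[j] - hy), (xm, y[j] + hy)))
    d1 = fav[:, 1:] != fav[:, :-1]
    for i, j in zip(*np.nonzero(d1)):
        ym = (y[j] + y[j + 1]) / 2.0
        segments.append(((x[i] - hx, ym), (x[i] + hx, ym)))
    segments.sort()
    return segments


def grid_long_frame(grid: GradeGridResult) -> pd.DataFrame:
    """Long-format (g1, g2, diff, p, favored, monotone) frame for export."""
    i, j = np.meshgrid(np.arange(len(grid.grid1)), np.arange(len(grid.grid2)), indexing="ij")
    name = {FAVOR_EXPERIMENTAL: "experimental", FAVOR_CONTROL: "control",
            FAVOR_INDETERMINATE: "indeterminate"}
    return pd.DataFrame(
        {
            f"grade_level_{grid.free_levels[0]}": grid.grid1[i.ravel()],
            f"grade_level_{grid.free_levels[1]}": grid.grid2[j.ravel()],
            "diff": grid.diff.ravel(),
            "p": grid.p.ravel(),
            "favored": [name[v] for v in grid.favored.ravel()],
            "monotone": grid.monotone.ravel(),
        }
    )
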