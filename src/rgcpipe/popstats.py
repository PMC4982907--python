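"""Population-level comparisons: χ² tests on 2x2 class-count tables,
Wilcoxon-Mann-Whitney rank tests on metric distributions, labelling
fractions with confidence intervals, and density-masked co-label counts.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .synth import LabeledCellMap
from .types import ContingencyTable


def chi2_2x2(
    table: ContingencyTable | np.ndarray,
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Pearson χ² test (1 df) of a 2x2 contingency table.

    The continuity (Yates) correction is off by default; it only shrinks
    the statistic. Zero row or column margins are an error.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else \
        np.asarray(table, dtype=int)
    if counts.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero margin: test undefined")
    res = stats.chi2_contingency(counts, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Uses the exact null distribution when min(n, m) ≤ 8 and the pooled data
    are tie-free, otherwise the normal approximation with tie correction.
    Returns (U of sample_a, p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if not np.isfinite(p):  # fully tied data: no evidence against the null
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def fraction_with_ci(k: int, n: int) -> tuple[float, tuple[float, float]]:
    """Proportion k/n with its Wilson 95% confidence interval."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return k / n, (float(lo), float(hi))


def replicate_mean_se(fractions: Sequence[float]) -> tuple[float, float]:
    """Mean ± standard error across replicate retinas."""
    f = np.asarray(fractions, dtype=float)
    if f.size == 0:
        raise ValueError("need at least one replicate")
    se = float(f.std(ddof=1) / np.sqrt(f.size)) if f.size > 1 else 0.0
    return float(f.mean()), se


class DensityMask:
    """Spatial mask of grid cells whose labelled-cell density is at least
    ``min_density`` times the peak density of the map."""

    def __init__(self, x_edges: np.ndarray, y_edges: np.ndarray,
                 grid: np.ndarray):
        self.x_edges = x_edges
        self.y_edges = y_edges
        self.grid = grid.astype(bool)

    @property
    def n_cells_masked(self) -> int:
        return int(self.grid.sum())

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of (n, 2) points in the mask."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        ix = np.searchsorted(self.x_edges, pts[:, 0], side="right") - 1
        iy = np.searchsorted(self.y_edges, pts[:, 1], side="right") - 1
        ok = (
            (ix >= 0) & (ix < self.grid.shape[0])
            & (iy >= 0) & (iy < self.grid.shape[1])
        )
        out = np.zeros(pts.shape[0], dtype=bool)
        out[ok] = self.grid[ix[ok], iy[ok]]
        return out


def density_mask(
    cell_map: LabeledCellMap,
    channel: str,
    grid_um: float = 100.0,
    min_density: float = 0.25,
) -> DensityMask:
    """Grid cells densely labelled in ``channel`` (≥ min_density x peak).

    An empty channel yields an empty mask.
    """
    if grid_um <= 0:
        raise ValueError("grid spacing must be > 0")
    pts = cell_map.points(channel)
    if pts.shape[0] == 0:
        edges = np.array([0.0, grid_um])
        return DensityMask(edges, edges, np.zeros((1, 1), dtype=bool))
    x0, x1 = pts[:, 0].min(), pts[:, 0].max()
    y0, y1 = pts[:, 1].min(), pts[:, 1].max()
    x_edges = np.arange(np.floor(x0 / grid_um) * grid_um,
                        np.ceil(x1 / grid_um) * grid_um + grid_um, grid_um)
    y_edges = np.arange(np.floor(y0 / grid_um) * grid_um,
                        np.ceil(y1 / grid_um) * grid_um + grid_um, grid_um)
    hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1],
                                bins=[x_edges, y_edges])
    return DensityMask(x_edges, y_edges, hist >= min_density * hist.max())


def colabel_fraction(
    cell_map: LabeledCellMap,
    ref_channel: str,
    test_channel: str,
    mask: Optional[DensityMask] = None,
) -> Optional[float]:
    """Fraction of reference-labelled cells (inside the mask) that also
    carry the test label; ``None`` when no reference cells fall in the mask.
    """
    cells = cell_map.cells
    ref = cells[f"label_{ref_channel}"].to_numpy(dtype=bool)
    test = cells[f"label_{test_channel}"].to_numpy(dtype=bool)
    if mask is not None:
        inside = mask.contains(cells[["x_um", "y_um"]].to_numpy(dtype=float))
        ref = ref & inside
    n_ref = int(ref.sum())
    if n_ref == 0:
        return None
    return float((ref & test).sum() / n_ref)
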