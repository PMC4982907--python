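"""Spatial analysis of retrogradely labelled cell maps: 2D Gaussian fits,
centroid vectors from the optic nerve head, angular separations,
inter-centroid distances and two-standard-deviation overlap counts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .synth import LabeledCellMap
from .types import Gaussian2DFit


def fit_gaussian2d(points: np.ndarray | Sequence) -> Gaussian2DFit:
    """Moment-based 2D Gaussian fit of a point cloud.

    Centre = sample mean; sd_major/sd_minor = square roots of the sample
    covariance eigenvalues; orientation = angle of the major axis (deg CCW
    from +x). Fewer than 3 points (or collinear points) yield a degenerate
    but well-defined fit with zero minor SD.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("cannot fit a Gaussian to zero points")
    center = pts.mean(axis=0)
    if pts.shape[0] < 2:
        cov = np.zeros((2, 2))
    else:
        cov = np.cov(pts.T, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    major, minor = np.sqrt(vals[1]), np.sqrt(vals[0])
    orient = float(np.degrees(np.arctan2(vecs[1, 1], vecs[0, 1])) % 180.0)
    return Gaussian2DFit(center=center, sd_major=float(major),
                         sd_minor=float(minor), orientation=orient,
                         n_points=pts.shape[0], cov=cov)


def centroid_vector(
    fit: Gaussian2DFit, onh: Sequence[float] = (0.0, 0.0)
) -> tuple[float, float]:
    """Polar angle (deg in [0, 360), CCW from +x) and length (μm) of the
    vector from the optic nerve head to the fitted centre.

    A centre coincident with the optic nerve head has distance 0 and an
    undefined angle, returned as nan.
    """
    d = fit.center - np.asarray(onh, dtype=float)
    dist = float(np.hypot(*d))
    if dist == 0:
        return float("nan"), 0.0
    ang = float(np.degrees(np.arctan2(d[1], d[0])) % 360.0)
    return ang, dist


def angular_separation(angle1: float, angle2: float) -> float:
    """Unsigned separation of two direction angles, deg in [0, 180]."""
    d = abs(angle1 - angle2) % 360.0
    return float(min(d, 360.0 - d))


def centroid_distance(fit1: Gaussian2DFit, fit2: Gaussian2DFit) -> float:
    """Euclidean distance between two fitted centres, μm."""
    return float(np.hypot(*(fit1.center - fit2.center)))


def two_sd_overlap(fit: Gaussian2DFit, points: np.ndarray | Sequence) -> int:
    """Number of points within Mahalanobis distance 2 of the fitted centre
    (boundary inclusive). Zero replicates full spatial separation of the
    two labelled populations.
    """
    if fit.sd_minor <= 0 or fit.cov is None:
        raise ValueError("degenerate fit: standard deviations must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        return 0
    d = pts - fit.center
    icov = np.linalg.inv(fit.cov)
    md2 = np.einsum("ni,ij,nj->n", d, icov, d)
    return int(np.count_nonzero(md2 <= 4.0 + 1e-12))


def retinomap_report(
    cell_map: LabeledCellMap, channels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-channel fit summary plus pairwise separations for one retina."""
    channels = list(channels) if channels is not None else cell_map.channels
    fits = {}
    rows = []
    for ch in channels:
        pts = cell_map.points(ch)
        fit = fit_gaussian2d(pts)
        fits[ch] = fit
        ang, dist = centroid_vector(fit, cell_map.optic_nerve_head)
        rows.append(dict(
            retina_id=cell_map.retina_id, kind="fit", channel=ch,
            center_x_um=fit.center[0], center_y_um=fit.center[1],
            sd_major_um=fit.sd_major, sd_minor_um=fit.sd_minor,
            orientation_deg=fit.orientation, n_points=fit.n_points,
            vector_angle_deg=ang, vector_length_um=dist,
        ))
    for i, a in enumerate(channels):
        for b in channels[i + 1:]:
            ang_a, _ = centroid_vector(fits[a], cell_map.optic_nerve_head)
            ang_b, _ = centroid_vector(fits[b], cell_map.optic_nerve_head)
            rows.append(dict(
                retina_id=cell_map.retina_id, kind="pair", channel=f"{a}|{b}",
                separation_deg=angular_separation(ang_a, ang_b),
                centroid_distance_um=centroid_distance(fits[a], fits[b]),
                overlap_2sd=(
                    two_sd_overlap(fits[a], cell_map.points(b))
                    if fits[a].sd_minor > 0 else None
                ),
            ))
    return pd.DataFrame(rows)
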