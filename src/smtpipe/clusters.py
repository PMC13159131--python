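"""Spatial cluster analysis of localization point patterns.

Density-based clustering (DBSCAN: a core point has ≥ min_pts neighbors
within eps; clusters are connected components of core points plus their
border points) applied to super-resolution localization maps.  Cluster
size is reported as the radius of gyration about the cluster centroid,
with the convex-hull area alongside; size distributions of two
conditions are compared with a two-sided Mann–Whitney rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import mannwhitneyu
from sklearn.cluster import DBSCAN

EPS_DEFAULT = 0.05  # µm
MIN_PTS_DEFAULT = 10


@dataclass
class ClusterResult:
    """Clusters found in one point pattern.  Radii/areas in µm / µm²."""

    n_clusters: int
    point_counts: list[int]
    radii_gyration: list[float]
    hull_areas: list[float]
    noise_fraction: float
    labels: np.ndarray  # per-point cluster label, -1 = noise


def radius_of_gyration(points: np.ndarray) -> float:
    """RMS distance of points from their centroid."""
    p = np.asarray(points, dtype=float)
    c = p.mean(axis=0)
    return float(np.sqrt(((p - c) ** 2).sum(axis=1).mean()))


def _hull_area(points: np.ndarray) -> float:
    try:
        return float(ConvexHull(points).volume)  # 2-D: volume == area
    except QhullError:
        return 0.0  # degenerate (collinear) cluster


def cluster_points(
    points: np.ndarray,
    eps: float = EPS_DEFAULT,
    min_pts: int = MIN_PTS_DEFAULT,
) -> ClusterResult:
    """DBSCAN-cluster a 2-D point pattern (µm) and measure cluster sizes."""
    if not eps > 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError(f"expected (n, 2) points, got shape {points.shape}")
    if len(points) < min_pts:
        raise ValueError(f"need >= min_pts={min_pts} points, got {len(points)}")
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(points).labels_
    ids = sorted(set(labels) - {-1})
    counts, radii, areas = [], [], []
    for cid in ids:
        cp = points[labels == cid]
        counts.append(len(cp))
        radii.append(radius_of_gyration(cp))
        areas.append(_hull_area(cp))
    return ClusterResult(
        n_clusters=len(ids),
        point_counts=counts,
        radii_gyration=radii,
        hull_areas=areas,
        noise_fraction=float((labels == -1).mean()),
        labels=labels,
    )


def compare_cluster_sizes(result_a: ClusterResult, result_b: ClusterResult) -> dict:
    """Two-sided Mann–Whitney test on radius-of-gyration distributions.

    Returns the statistic, p-value, per-condition median radii and a
    direction label ("A > B" / "B > A" / "A ~ B" by median).
    """
    if result_a.n_clusters < 3 or result_b.n_clusters < 3:
        raise ValueError(
            f"need >= 3 clusters per condition, got "
            f"{result_a.n_clusters} and {result_b.n_clusters}"
        )
    ra, rb = result_a.radii_gyration, result_b.radii_gyration
    stat, p = mannwhitneyu(ra, rb, alternative="two-sided")
    med_a, med_b = float(np.median(ra)), float(np.median(rb))
    direction = "A > B" if med_a > med_b else ("B > A" if med_b > med_a else "A ~ B")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "median_radius_a": med_a,
        "median_radius_b": med_b,
        "direction": direction,
    }
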