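"""Label-to-membrane distances and synaptic cleft-width statistics.

Membranes enter as already-segmented geometry: either an infinite plane
(point + unit normal) or a triangulated surface. Shortest distances are
exact (plane projection, or the closed-form point-to-triangle minimum over
all faces via trimesh). Cleft width is the shortest distance from sample
points on the postsynaptic membrane to the presynaptic membrane, and
labeled-vs-unlabeled conditions are compared with a Welch two-sample test
reported with its effect size, never thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh.triangles
from scipy import stats


@dataclass(frozen=True)
class MembraneModel:
    """Plane (point + unit normal) or triangulated surface, in Angstrom."""

    kind: str  # "plane" | "mesh"
    point: np.ndarray | None = None
    normal: np.ndarray | None = None
    vertices: np.ndarray | None = None
    faces: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "plane":
            if self.point is None or self.normal is None:
                raise ValueError("plane membranes need point and normal")
            n = np.asarray(self.normal, float)
            if abs(np.linalg.norm(n) - 1.0) > 1e-6:
                raise ValueError("plane normal must have unit norm")
            object.__setattr__(self, "point", np.asarray(self.point, float))
            object.__setattr__(self, "normal", n)
        elif self.kind == "mesh":
            v = np.asarray(self.vertices, float)
            f = np.asarray(self.faces, int)
            if len(f) == 0:
                raise ValueError("empty mesh")
            if f.min() < 0 or f.max() >= len(v):
                raise ValueError("mesh faces index invalid vertices")
            object.__setattr__(self, "vertices", v)
            object.__setattr__(self, "faces", f)
        else:
            raise ValueError(f"unknown membrane kind {self.kind!r}")


@dataclass(frozen=True)
class DistanceStats:
    distances: np.ndarray
    mean: float
    sd: float
    n: int
    fraction_in_range: float | None = None


@dataclass(frozen=True)
class CleftWidthStats:
    widths: np.ndarray
    mean: float
    sd: float


@dataclass(frozen=True)
class ConditionComparison:
    statistic: float
    dof: float
    p_value: float
    mean_difference: float


def shortest_distance(point: np.ndarray, membrane: MembraneModel) -> float:
    """Exact shortest distance from one point to the membrane surface."""
    return float(shortest_distances(np.asarray(point, float)[None, :], membrane)[0])


def shortest_distances(points: np.ndarray, membrane: MembraneModel) -> np.ndarray:
    """Vectorized shortest distances for (N, 3) points."""
    points = np.atleast_2d(np.asarray(points, float))
    if membrane.kind == "plane":
        return np.abs((points - membrane.point) @ membrane.normal)
    tris = membrane.vertices[membrane.faces]  # (M, 3, 3)
    n_pts, n_tri = len(points), len(tris)
    tri_tiled = np.repeat(tris[None, :, :, :], n_pts, axis=0).reshape(-1, 3, 3)
    pts_tiled = np.repeat(points, n_tri, axis=0)
    closest = trimesh.triangles.closest_point(tri_tiled, pts_tiled)
    d = np.linalg.norm(closest - pts_tiled, axis=1).reshape(n_pts, n_tri)
    return d.min(axis=1)


def distance_stats(
    centers: np.ndarray,
    membrane: MembraneModel,
    in_range: tuple[float, float] | None = None,
) -> DistanceStats:
    """Per-particle shortest distances with mean, SD (n-1), and optionally
    the fraction falling inside a supplied reach interval."""
    centers = np.atleast_2d(np.asarray(centers, float))
    if len(centers) < 1:
        raise ValueError("need at least one center")
    d = shortest_distances(centers, membrane)
    frac = None
    if in_range is not None:
        lo, hi = in_range
        frac = float(np.mean((d >= lo) & (d <= hi)))
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return DistanceStats(
        distances=d, mean=float(np.mean(d)), sd=sd, n=len(d), fraction_in_range=frac
    )


def plane_patch_grid(
    membrane: MembraneModel, extent: float, spacing: float = 10.0
) -> np.ndarray:
    """Regular grid of points on a plane membrane patch (extent x extent A)."""
    if membrane.kind != "plane":
        raise ValueError("plane_patch_grid needs a plane membrane")
    n = membrane.normal
    # any vector not parallel to n seeds an in-plane basis
    seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, seed)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    ticks = np.arange(-extent / 2, extent / 2 + spacing / 2, spacing)
    uu, vv = np.meshgrid(ticks, ticks)
    return membrane.point + uu.ravel()[:, None] * u + vv.ravel()[:, None] * v


def cleft_width(
    pre_membrane: MembraneModel,
    post_membrane: MembraneModel,
    sample_grid: np.ndarray,
) -> CleftWidthStats:
    """Shortest distance to the presynaptic membrane at each sample point
    on (or near) the postsynaptic membrane."""
    pts = np.atleast_2d(np.asarray(sample_grid, float))
    # project samples onto the postsynaptic surface so widths are surface-to-surface
    if post_membrane.kind == "plane":
        offs = (pts - post_membrane.point) @ post_membrane.normal
        pts = pts - offs[:, None] * post_membrane.normal
    widths = shortest_distances(pts, pre_membrane)
    sd = float(np.std(widths, ddof=1)) if len(widths) > 1 else 0.0
    return CleftWidthStats(widths=widths, mean=float(np.mean(widths)), sd=sd)


def compare_conditions(
    stats_a: CleftWidthStats, stats_b: CleftWidthStats
) -> ConditionComparison:
    """Welch unequal-variance comparison of two width samples.

    Returns statistic, Welch-Satterthwaite degrees of freedom, p-value and
    the mean difference (effect size); no significance threshold is applied.
    """
    a, b = stats_a.widths, stats_b.widths
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    if np.array_equal(a, b) or (np.std(a) == 0 and np.std(b) == 0 and a[0] == b[0]):
        return ConditionComparison(
            statistic=0.0, dof=float(len(a) + len(b) - 2), p_value=1.0, mean_difference=0.0
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return ConditionComparison(
        statistic=float(res.statistic),
        dof=float(dof),
        p_value=float(res.pvalue),
        mean_difference=float(np.mean(a) - np.mean(b)),
    )
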