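"""Line-fitting and distance primitives.

Three geometric operations underpin the topology pipeline:

* :func:`pca_axis` turns a segmented helix density region (a point cloud)
  into an α-trace — the first principal axis through the centroid, clipped
  to the cloud's extent.
* :func:`segment_distance` is the exact shortest Euclidean distance between
  two closed 3D line segments, used to decide whether two traces are close
  enough to satisfy a predicted contact.
* :func:`skeleton_distance` measures the through-density distance between
  two points by routing along the map skeleton, which is how loop lengths
  are compared with inter-trace distances.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .model import InputError, Skeleton, SSEType, Trace

__all__ = [
    "DegenerateCloudError",
    "pca_axis",
    "segment_distance",
    "SkeletonGraph",
    "skeleton_distance",
]


class DegenerateCloudError(ValueError):
    """All points of a cloud coincide; no axis can be fitted."""


_EIGEN_TIE_RTOL = 1e-9


def pca_axis(
    points: np.ndarray,
    *,
    trace_id: str = "L0",
    sse_type: SSEType = SSEType.HELIX,
) -> Trace:
    """Fit a line segment to a 3D point cloud by principal component analysis.

    The returned trace lies along the first principal axis through the
    centroid and is clipped to the minimum/maximum projection of the cloud
    onto that axis.  ``p_start → p_end`` follows increasing projection
    coordinate; which end is the N-side is resolved later by the topology
    (each trace carries two candidate directions).

    Raises
    ------
    DegenerateCloudError
        If all points coincide.

    Warns
    -----
    UserWarning
        If the top two eigenvalues tie; the reported axis is then chosen
        deterministically (direction vector lexicographically largest in
        (x, y, z)).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise InputError("axis fitting needs an (n>=2, 3) point array")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if not np.any(np.abs(centered) > 1e-12):
        raise DegenerateCloudError("all points coincide")
    cov = centered.T @ centered / len(pts)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    top = eigvals[-1]
    tied = np.nonzero(eigvals >= top * (1.0 - _EIGEN_TIE_RTOL))[0]
    if len(tied) > 1:
        warnings.warn(
            "ambiguous principal axis: top eigenvalues tie; "
            "using deterministic lexicographic tie-break",
            UserWarning,
            stacklevel=2,
        )
    # Among tied eigenvectors pick the lexicographically largest of ±v.
    candidates = []
    for k in tied:
        v = eigvecs[:, k]
        candidates.append(max(tuple(v), tuple(-v)))
    axis = np.array(max(candidates))
    proj = centered @ axis
    t_min, t_max = proj.min(), proj.max()
    return Trace(
        trace_id,
        sse_type,
        centroid + t_min * axis,
        centroid + t_max * axis,
    )


def _segment_points(t: Trace) -> Tuple[np.ndarray, np.ndarray]:
    return np.asarray(t.p_start, float), np.asarray(t.p_end, float)


def segment_distance(a: Trace, b: Trace) -> float:
    """Exact shortest distance between two closed 3D line segments (Å).

    Closed-form clamped solution: minimize ``|(P0 + s·u) − (Q0 + t·v)|`` over
    s, t ∈ [0, 1], handling the parallel (degenerate normal-equation) case
    explicitly.  Symmetric and non-negative.
    """
    p0, p1 = _segment_points(a)
    q0, q1 = _segment_points(b)
    u = p1 - p0
    v = q1 - q0
    w0 = p0 - q0
    A = float(u @ u)
    B = float(u @ v)
    C = float(v @ v)
    D = float(u @ w0)
    E = float(v @ w0)
    if A <= 0.0 or C <= 0.0:
        raise InputError("degenerate (zero-length) trace")

    denom = A * C - B * B
    if denom > 1e-12 * A * C:
        s = (B * E - C * D) / denom
        t = (A * E - B * D) / denom
    else:
        # (near-)parallel: fix s = 0 and let the clamping passes refine
        s = 0.0
        t = E / C
    s = min(1.0, max(0.0, s))
    # re-optimize t for clamped s, then s for clamped t (standard two-pass)
    t = (B * s + E) / C
    t = min(1.0, max(0.0, t))
    s = (B * t - D) / A
    s = min(1.0, max(0.0, s))
    diff = (p0 + s * u) - (q0 + t * v)
    return float(np.linalg.norm(diff))


class SkeletonGraph:
    """A reusable shortest-path structure over a skeleton point set.

    Skeleton points within ``link_radius`` of each other are joined by edges
    weighted with their Euclidean length.  Query points are snapped to their
    nearest skeleton point; the reported distance is snap-in + geodesic +
    snap-out.  If the two snapped points fall in disconnected components the
    straight-line distance is returned instead (the weakest consistent lower
    bound for a broken skeleton).
    """

    def __init__(self, skeleton: Skeleton):
        if len(skeleton) == 0:
            raise InputError("empty skeleton")
        self.skeleton = skeleton
        self._tree = cKDTree(skeleton.points)
        pairs = self._tree.query_pairs(r=skeleton.link_radius, output_type="ndarray")
        n = len(skeleton)
        if len(pairs):
            weights = np.linalg.norm(
                skeleton.points[pairs[:, 0]] - skeleton.points[pairs[:, 1]], axis=1
            )
            rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
            cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
            data = np.concatenate([weights, weights])
            self._graph = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
        else:
            self._graph = sparse.csr_matrix((n, n))

    def snap(self, p: np.ndarray) -> Tuple[float, int]:
        """Distance to, and index of, the nearest skeleton point."""
        d, idx = self._tree.query(np.asarray(p, float))
        return float(d), int(idx)

    def distance(self, p: np.ndarray, q: np.ndarray) -> float:
        dp, ip = self.snap(p)
        dq, iq = self.snap(q)
        geo = dijkstra(self._graph, indices=ip, min_only=False)[iq]
        if not np.isfinite(geo):
            return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))
        return dp + float(geo) + dq

    def distance_matrix(self, points: np.ndarray) -> np.ndarray:
        """All-pairs skeleton distance between query points (vectorized).

        Disconnected pairs fall back to their Euclidean distance.
        """
        pts = np.asarray(points, float)
        snap_d, snap_i = self._tree.query(pts)
        uniq, inverse = np.unique(snap_i, return_inverse=True)
        geo = dijkstra(self._graph, indices=uniq)
        geo_pairs = geo[:, uniq][inverse][:, inverse]
        total = geo_pairs + snap_d[:, None] + snap_d[None, :]
        eucl = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        out = np.where(np.isfinite(total), total, eucl)
        np.fill_diagonal(out, 0.0)
        return out


def skeleton_distance(skeleton: Skeleton, p: np.ndarray, q: np.ndarray) -> float:
    """Through-density distance between two points along the map skeleton.

    Convenience wrapper over :class:`SkeletonGraph` for one-off queries; use
    the class directly when measuring many pairs on the same skeleton.
    """
    return SkeletonGraph(skeleton).distance(p, q)
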