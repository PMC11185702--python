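"""Geometry operations on neuron skeletons.

Covers edge-wise resampling, point-cloud-with-tangents (dotprops)
construction, simplification to the longest neurite from an entry point,
mirroring about an axis-aligned plane, and thin-plate-spline landmark
registration between datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import ROOT_PARENT, TreeSkeleton
from .errors import ConditioningError

AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class DotProps:
    """Points with local tangent directions, the representation NBLAST scores.

    ``tangents`` are unit vectors; ``alpha`` in [0, 1] measures how colinear
    each point's neighbourhood is (1 = perfectly colinear).
    """

    points: np.ndarray
    tangents: np.ndarray
    alpha: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.tangents = np.atleast_2d(np.asarray(self.tangents, dtype=float))
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if self.points.shape[0] < 1:
            raise ValueError("DotProps needs at least one point")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("tangents must be unit vectors")
        if np.any((self.alpha < -1e-12) | (self.alpha > 1 + 1e-12)):
            raise ValueError("alpha must lie in [0, 1]")
        self.alpha = np.clip(self.alpha, 0.0, 1.0)

    def __len__(self) -> int:
        return self.points.shape[0]


def resample(skel: TreeSkeleton, spacing: float) -> TreeSkeleton:
    """Subdivide edges so no parent-child edge exceeds ``spacing`` (nm).

    Original nodes (hence all branch and end points) are preserved exactly;
    edges longer than ``spacing`` get evenly spaced intermediate nodes.
    Total cable length and topology are unchanged.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    nodes = skel.nodes
    by_id = {int(r.node_id): r for r in nodes.itertuples()}
    next_id = int(nodes["node_id"].max()) + 1
    rows = [
        (int(r.node_id), int(r.parent_id), r.x, r.y, r.z, r.radius, int(r.label))
        for r in nodes.itertuples()
    ]
    out = []
    for nid, pid, x, y, z, rad, lab in rows:
        if pid == ROOT_PARENT:
            out.append((nid, pid, x, y, z, rad, lab))
            continue
        p = by_id[pid]
        a = np.array([p.x, p.y, p.z])
        b = np.array([x, y, z])
        length = float(np.linalg.norm(b - a))
        n_seg = max(1, int(np.ceil(length / spacing - 1e-12)))
        prev = pid
        for i in range(1, n_seg):
            t = i / n_seg
            q = a + t * (b - a)
            out.append((next_id, prev, q[0], q[1], q[2], rad, lab))
            prev = next_id
            next_id += 1
        out.append((nid, prev, x, y, z, rad, lab))
    df = pd.DataFrame(
        out, columns=["node_id", "parent_id", "x", "y", "z", "radius", "label"]
    )
    return TreeSkeleton(neuron_id=skel.neuron_id, nodes=df)


def _principal_direction(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal axis of a centred point set and its variance fraction."""
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred
    evals, evecs = np.linalg.eigh(cov)
    lead = evecs[:, -1]
    total = float(evals.sum())
    frac = float(evals[-1] / total) if total > 0 else 1.0 / 3.0
    return lead, frac


def _orient(t: np.ndarray) -> np.ndarray:
    """Store the lexicographically larger of the two tangent orientations."""
    return t if tuple(t) >= tuple(-t) else -t


def to_dotprops(skel: TreeSkeleton, k: int = 5, spacing: float = 1000.0) -> DotProps:
    """Build dotprops: resample, then fit a tangent per node from k neighbours.

    The tangent at a point is the first principal direction of its k nearest
    resampled points (the point itself included); alpha rescales that
    direction's variance fraction from [1/3, 1] to [0, 1]. ``k`` is clipped
    to the number of available points. Single-point skeletons get the
    degenerate fallback tangent (1, 0, 0) with alpha 0.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rs = resample(skel, spacing)
    pts = rs.coords()
    n = pts.shape[0]
    if n == 1:
        return DotProps(
            points=pts,
            tangents=np.array([[1.0, 0.0, 0.0]]),
            alpha=np.array([0.0]),
            source_id=skel.neuron_id,
        )
    kk = min(k, n)
    tree = cKDTree(pts)
    _, nn = tree.query(pts, k=kk)
    tangents = np.empty((n, 3))
    alpha = np.empty(n)
    for i in range(n):
        lead, frac = _principal_direction(pts[nn[i]])
        tangents[i] = _orient(lead / np.linalg.norm(lead))
        alpha[i] = (frac - 1.0 / 3.0) / (2.0 / 3.0)
    return DotProps(points=pts, tangents=tangents, alpha=np.clip(alpha, 0, 1),
                    source_id=skel.neuron_id)


def longest_neurite_from_point(
    skel: TreeSkeleton, entry: np.ndarray, snap_tolerance: float | None = None
) -> TreeSkeleton:
    """Longest unbranched path from the node nearest ``entry`` to a leaf.

    The skeleton is treated as an undirected tree; the returned path is the
    entry-node-to-leaf walk of maximal cable length, re-rooted at the entry
    node. Ties between equally long paths go to the smaller leaf node_id.
    """
    entry = np.asarray(entry, dtype=float)
    pts = skel.coords()
    ids = skel.nodes["node_id"].to_numpy().astype(int)
    d = np.linalg.norm(pts - entry, axis=1)
    start = int(ids[int(np.argmin(d))])
    if snap_tolerance is not None and d.min() > snap_tolerance:
        raise ValueError(
            f"entry point {entry} is {d.min():.0f} nm from the nearest node, "
            f"beyond tolerance {snap_tolerance:.0f} nm"
        )

    # undirected adjacency with edge lengths
    idx = {int(n): i for i, n in enumerate(ids)}
    adj: dict[int, list[tuple[int, float]]] = {int(n): [] for n in ids}
    for r in skel.nodes.itertuples():
        p = int(r.parent_id)
        if p == ROOT_PARENT:
            continue
        nid = int(r.node_id)
        w = float(np.linalg.norm(pts[idx[nid]] - pts[idx[p]]))
        adj[nid].append((p, w))
        adj[p].append((nid, w))

    # DFS from start recording distance and predecessor
    dist = {start: 0.0}
    pred: dict[int, int] = {}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                pred[v] = u
                stack.append(v)

    terminals = [n for n in dist if n != start and len(adj[n]) == 1]
    if not terminals:
        terminals = [n for n in dist if n != start] or [start]
    best = min(terminals, key=lambda n: (-dist[n], n))

    path = [best]
    while path[-1] != start:
        path.append(pred[path[-1]])
    path.reverse()

    by_id = {int(r.node_id): r for r in skel.nodes.itertuples()}
    rows = []
    prev = ROOT_PARENT
    for nid in path:
        r = by_id[nid]
        rows.append((nid, prev, r.x, r.y, r.z, r.radius, int(r.label)))
        prev = nid
    df = pd.DataFrame(
        rows, columns=["node_id", "parent_id", "x", "y", "z", "radius", "label"]
    )
    return TreeSkeleton(neuron_id=skel.neuron_id, nodes=df)


def mirror(points: np.ndarray, plane_axis: str = "x", plane_position: float = 0.0) -> np.ndarray:
    """Reflect points about the plane ``axis == plane_position``; involution."""
    pts = np.array(points, dtype=float, copy=True)
    ax = AXES[plane_axis]
    pts[..., ax] = 2.0 * plane_position - pts[..., ax]
    return pts


def mirror_skeleton(
    skel: TreeSkeleton, plane_axis: str = "x", plane_position: float = 0.0
) -> TreeSkeleton:
    """Mirror a whole skeleton about an axis-aligned plane."""
    nodes = skel.nodes.copy()
    nodes[["x", "y", "z"]] = mirror(
        nodes[["x", "y", "z"]].to_numpy(dtype=float), plane_axis, plane_position
    )
    return TreeSkeleton(neuron_id=skel.neuron_id, nodes=nodes)


@dataclass
class LandmarkTransform:
    """Thin-plate-spline transform fitted to paired 3-D landmarks.

    Exact interpolation (zero regularization): every source landmark maps
    onto its destination landmark. The mapping is
    ``f(x) = A [x; 1] + sum_i w_i * phi(|x - src_i|)`` with the 3-D
    biharmonic kernel ``phi(r) = r``.
    """

    src_landmarks: np.ndarray
    dst_landmarks: np.ndarray
    affine_part: np.ndarray  # 3x4, acts on [x, y, z, 1]
    kernel_weights: np.ndarray  # m x 3

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_transform(self, points)


def fit_landmark_transform(src: np.ndarray, dst: np.ndarray) -> LandmarkTransform:
    """Fit an exact-interpolation 3-D TPS from src landmarks to dst landmarks.

    Requires m >= 4 non-coplanar source points; raises
    :class:`ConditioningError` otherwise.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (m, 3) arrays")
    m = src.shape[0]
    if m < 4:
        raise ConditioningError("need at least 4 landmark pairs")
    centred = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max())) < 3:
        raise ConditioningError("source landmarks are coplanar or degenerate")

    d = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    P = np.hstack([src, np.ones((m, 1))])
    L = np.zeros((m + 4, m + 4))
    L[:m, :m] = d
    L[:m, m:] = P
    L[m:, :m] = P.T
    rhs = np.zeros((m + 4, 3))
    rhs[:m] = dst
    sol = np.linalg.solve(L, rhs)
    w = sol[:m]
    a = sol[m:]  # 4x3; rows: x, y, z, 1 coefficients
    affine = a.T  # 3x4
    return LandmarkTransform(
        src_landmarks=src, dst_landmarks=dst, affine_part=affine, kernel_weights=w
    )


def apply_transform(t: LandmarkTransform, points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted TPS at arbitrary points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.linalg.norm(pts[:, None, :] - t.src_landmarks[None, :, :], axis=2)
    out = d @ t.kernel_weights + np.hstack([pts, np.ones((pts.shape[0], 1))]) @ t.affine_part.T
    return out.reshape(np.shape(points))


def transform_skeleton(t: LandmarkTransform, skel: TreeSkeleton) -> TreeSkeleton:
    """Apply a landmark transform to all node coordinates of a skeleton."""
    nodes = skel.nodes.copy()
    nodes[["x", "y", "z"]] = apply_transform(
        t, nodes[["x", "y", "z"]].to_numpy(dtype=float)
    )
    return TreeSkeleton(neuron_id=skel.neuron_id, nodes=nodes)


def read_landmarks(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a landmark-pair CSV with columns x_src..z_src, x_dst..z_dst."""
    df = pd.read_csv(path)
    src = df[["x_src", "y_src", "z_src"]].to_numpy(dtype=float)
    dst = df[["x_dst", "y_dst", "z_dst"]].to_numpy(dtype=float)
    return src, dst
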