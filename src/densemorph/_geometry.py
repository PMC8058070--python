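"""Exact closest-point queries on triangle meshes.

The workhorse is a vectorized point-to-triangle kernel (Ericson's region
decomposition) combined with a KD-tree over face centroids. The prefilter only
discards faces that provably cannot contain the global minimum (centroid
distance minus the largest face circumradius), so the result is identical to
exhaustive search over all faces; uncertified queries fall back to an exact
radius search. Ties between faces are broken by the lowest face index.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

# point-pair budget per vectorized block
_CHUNK = 4_000_000


def closest_on_triangles(p, a, b, c):
    """Closest point on each triangle (a, b, c) to each paired query point.

    All arguments are (n, 3) arrays; triangle i is tested against point i.
    Returns (closest_points (n, 3), barycentric (n, 3)).
    """
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    n = p.shape[0]
    u = np.empty(n)
    v = np.empty(n)
    w = np.empty(n)
    done = np.zeros(n, dtype=bool)

    def settle(mask, uu, vv, ww):
        m = mask & ~done
        if np.any(m):
            for arr, val in ((u, uu), (v, vv), (w, ww)):
                arr[m] = val if np.isscalar(val) else val[m]
            done[m] = True

    # vertex regions
    settle((d1 <= 0.0) & (d2 <= 0.0), 1.0, 0.0, 0.0)
    settle((d3 >= 0.0) & (d4 <= d3), 0.0, 1.0, 0.0)
    settle((d6 >= 0.0) & (d5 <= d6), 0.0, 0.0, 1.0)
    # edge regions
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = d1 / (d1 - d3)
        t_ac = d2 / (d2 - d6)
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    settle((vc <= 0.0) & (d1 >= 0.0) & (d3 <= 0.0), 1.0 - t_ab, t_ab, 0.0)
    settle((vb <= 0.0) & (d2 >= 0.0) & (d6 <= 0.0), 1.0 - t_ac, 0.0, t_ac)
    settle((va <= 0.0) & (d4 - d3 >= 0.0) & (d5 - d6 >= 0.0), 0.0, 1.0 - t_bc, t_bc)
    # interior
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = va + vb + vc
        vi = vb / denom
        wi = vc / denom
    settle(np.ones(n, dtype=bool), 1.0 - vi - wi, vi, wi)

    bary = np.stack([u, v, w], axis=1)
    pts = bary[:, :1] * a + bary[:, 1:2] * b + bary[:, 2:3] * c
    return pts, bary


def vertex_normals(vertices, faces):
    """Area-weighted outward vertex normals (unnormalized faces assumed consistent)."""
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64)
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    normals = np.zeros_like(v)
    for k in range(3):
        np.add.at(normals, f[:, k], fn)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm < 1e-300] = 1.0
    return normals / norm


def face_normals(vertices, faces):
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64)
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    norm = np.linalg.norm(fn, axis=1, keepdims=True)
    norm[norm < 1e-300] = 1.0
    return fn / norm


class SurfaceQuery:
    """Exact closest-point structure over one triangle soup."""

    def __init__(self, vertices, faces):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.tri = self.vertices[self.faces]  # (F, 3, 3)
        self.centroids = self.tri.mean(axis=1)
        # largest vertex-to-centroid distance over all faces
        self.radius = float(
            np.sqrt(((self.tri - self.centroids[:, None, :]) ** 2).sum(axis=2).max())
        )
        self.n_faces = len(self.faces)
        self.tree = cKDTree(self.centroids) if self.n_faces > 128 else None

    def _best_among(self, points, cand):
        """Exact minimum over per-row candidate faces (rows sorted ascending)."""
        n, m = cand.shape
        tri = self.tri[cand]  # (n, m, 3, 3)
        P = np.repeat(points, m, axis=0)
        pts, bary = closest_on_triangles(
            P, tri[:, :, 0].reshape(-1, 3), tri[:, :, 1].reshape(-1, 3), tri[:, :, 2].reshape(-1, 3)
        )
        d2 = ((pts - P) ** 2).sum(axis=1).reshape(n, m)
        j = np.argmin(d2, axis=1)  # first occurrence -> lowest face index
        rows = np.arange(n)
        flat = rows * m + j
        return (
            pts[flat],
            cand[rows, j],
            bary[flat],
            np.sqrt(d2[rows, j]),
        )

    def _brute(self, points):
        n = len(points)
        out_p = np.empty((n, 3))
        out_f = np.empty(n, dtype=np.int64)
        out_b = np.empty((n, 3))
        out_d = np.empty(n)
        step = max(1, _CHUNK // max(self.n_faces, 1))
        allf = np.arange(self.n_faces)
        for s in range(0, n, step):
            e = min(s + step, n)
            cand = np.broadcast_to(allf, (e - s, self.n_faces))
            p, f, bb, d = self._best_among(points[s:e], cand)
            out_p[s:e], out_f[s:e], out_b[s:e], out_d[s:e] = p, f, bb, d
        return out_p, out_f, out_b, out_d

    def closest(self, points, k=32):
        """Globally closest surface points: (points, face_index, barycentric, distance)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.tree is None:
            return self._brute(points)
        k = min(k, self.n_faces)
        dc, ci = self.tree.query(points, k=k)
        cand = np.sort(ci, axis=1)
        pts, fi, bary, dist = self._best_among(points, cand)
        # faces outside the candidate set have centroid distance >= dc[:, -1];
        # their surface cannot be nearer than dc[:, -1] - radius
        uncertified = dist > dc[:, -1] - self.radius - 1e-9
        for i in np.nonzero(uncertified)[0]:
            idx = self.tree.query_ball_point(points[i], dist[i] + self.radius + 1e-9)
            idx = np.sort(np.asarray(idx, dtype=np.int64))
            p, f, bb, d = self._best_among(points[i : i + 1], idx[None, :])
            pts[i], fi[i], bary[i], dist[i] = p[0], f[0], bb[0], d[0]
        return pts, fi, bary, dist
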