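"""The dense mapping chain and Procrustes machinery.

A template mesh is brought into dense correspondence with a target surface in
three stages: (1) a closed-form least-squares similarity transform estimated
from five crudely indicated positioning landmarks, (2) rigid ICP refinement
(scale frozen after stage 1), and (3) non-rigid ICP that deforms the template
onto the target while preserving its topology, so that every template vertex
becomes a quasi-landmark on the target.

The non-rigid step follows the visco-elastic dense-mapping family: a global
affine ICP warmup, then per iteration symmetric weighted closest-point
correspondences (a push field from template vertices onto the target surface
and a pull field from target vertices onto the floating surface, spread
barycentrically over face vertices), inlier weighting by robust distance
scale and normal agreement, and a displacement field regularized by
confidence-weighted linear moving-least-squares fits over Gaussian
neighborhoods whose physical bandwidth (mm) anneals from broad (stiff,
near-affine behaviour) to narrow (fine detail). The linear fits — rather
than weighted means — are what propagate stretch and rotation from curvature
features across featureless regions, recovering tangential correspondence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import SurfaceQuery, vertex_normals
from .errors import (
    DegenerateGeometryError,
    RegistrationDivergenceError,
    TopologyMismatchError,
)
from .meshkit import LandmarkConfiguration, SurfaceMesh


@dataclass(frozen=True)
class SimilarityTransform:
    """x -> scale * rotation @ x + translation, with det(rotation) = +1."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self):
        R = np.array(self.rotation, dtype=float, copy=True)
        t = np.array(self.translation, dtype=float, copy=True)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length-3")
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-9:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) <= 0:
            raise ValueError("rotation must have determinant +1 (no reflection)")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "scale", float(self.scale))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), 1.0, np.zeros(3))

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return self.scale * (p @ self.rotation.T) + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self o other (apply ``other`` first)."""
        cls = SimilarityTransform
        return cls(
            self.rotation @ other.rotation,
            self.scale * other.scale,
            self.scale * (self.rotation @ other.translation) + self.translation,
        )

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        return SimilarityTransform(Rinv, 1.0 / self.scale, -(Rinv @ self.translation) / self.scale)


@dataclass(frozen=True)
class RigidTransform(SimilarityTransform):
    """A similarity transform with scale fixed to exactly 1."""

    def __post_init__(self):
        if self.scale != 1.0:
            raise ValueError("RigidTransform requires scale == 1")
        super().__post_init__()

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), 1.0, np.zeros(3))


@dataclass(frozen=True)
class NonRigidParams:
    """Tuning knobs of the non-rigid registration.

    ``elasticity_start``/``elasticity_end`` are the Gaussian bandwidths (mm)
    of the displacement-field smoother at the first and last annealing
    iteration; the schedule is geometric over the first ``anneal_fraction`` of
    the iterations and then holds the final bandwidth, so late iterations
    refine detail at a fixed, resolution-independent physical scale.
    ``smoothing_neighbors`` bounds the k-nearest-neighbor stencil realizing
    the kernel. ``correspondence_k`` is the barycentric vote spread of the
    symmetric (pull) channel — each target vertex votes to the vertices of
    its closest floating face. ``affine_warmup`` iterations of global affine
    ICP absorb smooth global stretch/shear before local refinement.
    """

    n_iterations: int = 200
    correspondence_k: int = 3
    inlier_kappa: float = 3.0
    smoothing_neighbors: int = 96
    elasticity_start: float = 8.0
    elasticity_end: float = 2.5
    symmetric_correspondence: bool = True
    affine_warmup: int = 30
    anneal_fraction: float = 0.5

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (self.elasticity_start >= self.elasticity_end >= 0):
            raise ValueError("need elasticity_start >= elasticity_end >= 0")
        if self.smoothing_neighbors < 1:
            raise ValueError("smoothing_neighbors must be >= 1")
        if self.affine_warmup < 0:
            raise ValueError("affine_warmup must be >= 0")
        if not 0.0 < self.anneal_fraction <= 1.0:
            raise ValueError("anneal_fraction must be in (0, 1]")


@dataclass(frozen=True)
class CorrespondenceMap:
    """Template-topology mesh whose vertices lie on (near) a target surface."""

    faces: np.ndarray
    mapped_vertices: np.ndarray
    target_id: str
    mean_surface_distance: float

    def __post_init__(self):
        f = np.array(self.faces, dtype=np.int64, copy=True)
        v = np.array(self.mapped_vertices, dtype=float, copy=True)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("mapped_vertices must be (n, 3)")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite mapped vertices")
        if not np.isfinite(self.mean_surface_distance):
            raise ValueError("mean surface distance must be finite")
        f.setflags(write=False)
        v.setflags(write=False)
        object.__setattr__(self, "faces", f)
        object.__setattr__(self, "mapped_vertices", v)
        object.__setattr__(self, "mean_surface_distance", float(self.mean_surface_distance))

    @property
    def vertices(self) -> np.ndarray:
        # lets a CorrespondenceMap act as a mesh-like for barycentric evaluation
        return self.mapped_vertices

    def as_mesh(self, validate: bool = False) -> SurfaceMesh:
        return SurfaceMesh(self.mapped_vertices, self.faces, validate=validate)

    def same_topology(self, other) -> bool:
        return self.faces.shape == np.asarray(other.faces).shape and np.array_equal(
            self.faces, np.asarray(other.faces)
        )


# ---------------------------------------------------------------------------
# closed-form similarity / rigid fits


def _fit_similarity(src: np.ndarray, dst: np.ndarray, with_scale: bool, weights=None):
    """Least-squares similarity (Kabsch–Umeyama), reflections excluded."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if len(src) < 3:
        raise DegenerateGeometryError("need at least 3 points to fit a transform")
    if weights is None:
        w = np.full(len(src), 1.0 / len(src))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    mu_s = w @ src
    mu_d = w @ dst
    X = src - mu_s
    Y = dst - mu_d
    cov = (Y * w[:, None]).T @ X
    U, S, Vt = np.linalg.svd(cov)
    if S[1] <= 1e-12 * max(S[0], 1e-30):
        raise DegenerateGeometryError("degenerate (collinear or coincident) configuration")
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.array([1.0, 1.0, d])
    R = (U * D) @ Vt
    if with_scale:
        var = float((w[:, None] * X**2).sum())
        s = float((S * D).sum() / var)
        T = SimilarityTransform(R, s, mu_d - s * (R @ mu_s))
    else:
        T = RigidTransform(R, 1.0, mu_d - R @ mu_s)
    return T


def similarity_from_landmarks(
    source: LandmarkConfiguration, target: LandmarkConfiguration
):
    """Least-squares similarity transform mapping source landmarks onto target.

    Landmark names and order must agree. Returns ``(transform, rms_residual)``.
    """
    if source.names != target.names:
        raise ValueError(
            f"landmark name mismatch: {source.names} vs {target.names}"
        )
    T = _fit_similarity(source.points, target.points, with_scale=True)
    res = float(np.sqrt(((T.apply(source.points) - target.points) ** 2).sum(axis=1).mean()))
    return T, res


def rigid_icp(
    moving: SurfaceMesh,
    target: SurfaceMesh,
    init: SimilarityTransform | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
):
    """Rigid ICP of ``moving`` onto ``target`` starting from ``init``.

    Alternates exact closest-point correspondence with a closed-form rigid
    update until the RMS correspondence distance improves by less than ``tol``
    mm. Returns the composed transform (scale inherited from ``init``) and the
    objective trace, which is non-increasing.
    """
    T = init if init is not None else SimilarityTransform.identity()
    pts = T.apply(moving.vertices)
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        cp, _, _, dist = target.query.closest(pts)
        obj = float(np.sqrt((dist**2).mean()))
        if not np.isfinite(obj):
            raise RegistrationDivergenceError("non-finite ICP objective", trace)
        trace.append(obj)
        if prev - obj < tol:
            break
        prev = obj
        Tu = _fit_similarity(pts, cp, with_scale=False)
        pts = Tu.apply(pts)
        T = Tu.compose(T)
    return T, trace


# ---------------------------------------------------------------------------
# non-rigid registration


def _robust_inlier_weights(dist: np.ndarray, kappa: float) -> np.ndarray:
    # correspondences within kappa robust scales keep full weight; beyond that
    # a Gaussian taper rejects outliers. The scale is floored at mean + std so
    # legitimately large displacements (local deformation still to be
    # recovered) are not mistaken for outliers once most of the mesh has
    # converged onto the surface.
    scale = float(dist.mean() + dist.std())
    if scale < 1e-12:
        return np.ones_like(dist)
    z = dist / scale
    return np.where(z <= kappa, 1.0, np.exp(-0.5 * (z - kappa) ** 2))


def _affine_icp(f, target_query, n_iterations):
    """Global affine ICP refinement (exact fixed point when already on target)."""
    for _ in range(n_iterations):
        cp, _, _, _ = target_query.closest(f)
        X = np.concatenate([f, np.ones((len(f), 1))], axis=1)
        beta, *_ = np.linalg.lstsq(X, cp, rcond=None)
        f = X @ beta
    return f


def _mls_smooth(positions0, desired, conf, nb_i, nb_d, h):
    """Weighted linear moving-least-squares smoothing of desired positions.

    Per vertex, fits an affine map from the undeformed neighborhood
    coordinates to the desired positions (Gaussian weights of bandwidth ``h``
    times correspondence confidence) and evaluates it at the vertex. Unlike a
    weighted mean, the linear fit propagates stretch and rotation, which is
    what recovers tangential correspondence away from curvature features.
    """
    W = np.exp(-0.5 * (nb_d / h) ** 2) * np.maximum(conf, 1e-6)[nb_i]
    local = positions0[nb_i] - positions0[:, None, :]  # centered basis per vertex
    Xn = np.concatenate([local, np.ones(local.shape[:2] + (1,))], axis=2)
    Yn = desired[nb_i]
    A = np.einsum("vk,vki,vkj->vij", W, Xn, Xn)
    B = np.einsum("vk,vki,vkj->vij", W, Xn, Yn)
    A += 1e-9 * np.trace(A, axis1=1, axis2=2)[:, None, None] * np.eye(4)
    # the constant term of the centered fit is the smoothed position
    return np.linalg.solve(A, B)[:, 3, :]


def nonrigid_register(
    template: SurfaceMesh,
    target: SurfaceMesh,
    params: NonRigidParams | None = None,
    target_id: str = "target",
    divergence_patience: int = 10,
) -> CorrespondenceMap:
    """Deform a (rigidly pre-aligned) template onto a target surface.

    Returns a :class:`CorrespondenceMap` carrying the template topology; raises
    :class:`RegistrationDivergenceError` if the mean vertex-to-target distance
    worsens for more than ``divergence_patience`` consecutive iterations.
    """
    params = params or NonRigidParams()
    f0 = np.array(template.vertices, dtype=float)
    faces = template.faces
    tq = target.query
    t_vnormals = target.vertex_normals
    t_fnormals = target.face_normals

    f = _affine_icp(f0.copy(), tq, params.affine_warmup)

    k = int(min(params.smoothing_neighbors + 1, len(f0)))  # stencil includes self
    nb_d, nb_i = cKDTree(f0).query(f0, k=k)

    trace = []
    best = np.inf
    worse = 0
    n_it = params.n_iterations
    n_anneal = max(int(np.ceil(params.anneal_fraction * n_it)), 1)
    h0 = max(params.elasticity_start, 1e-6)
    h1 = max(params.elasticity_end, 1e-6)
    for it in range(n_it):
        frac = min(it / max(n_anneal - 1, 1), 1.0)
        h = h0 * (h1 / h0) ** frac

        f_normals = vertex_normals(f, faces)
        cp, fi, _, dist = tq.closest(f)
        mean_dist = float(dist.mean())
        trace.append(mean_dist)
        if mean_dist > best * 1.05 + 1e-4:
            worse += 1
            if worse > divergence_patience:
                raise RegistrationDivergenceError(
                    f"mean surface distance worsened for {worse} consecutive iterations",
                    trace,
                )
        else:
            worse = 0
            best = min(best, mean_dist)

        # push: template vertices toward their closest target surface points
        wf = _robust_inlier_weights(dist, params.inlier_kappa)
        wf *= np.clip(np.einsum("ij,ij->i", f_normals, t_fnormals[fi]), 0.0, 1.0)
        num = wf[:, None] * (cp - f)
        den = wf.copy()

        if params.symmetric_correspondence:
            # pull: target vertices project onto the floating surface and vote
            # barycentrically to the floating face vertices
            fq = SurfaceQuery(f, faces)
            cp2, fi2, bary2, dist2 = fq.closest(target.vertices)
            f_fnormals_now = np.cross(
                f[faces[:, 1]] - f[faces[:, 0]], f[faces[:, 2]] - f[faces[:, 0]]
            )
            nrm = np.linalg.norm(f_fnormals_now, axis=1, keepdims=True)
            nrm[nrm < 1e-300] = 1.0
            f_fnormals_now /= nrm
            wb = _robust_inlier_weights(dist2, params.inlier_kappa)
            wb *= np.clip(
                np.einsum("ij,ij->i", t_vnormals, f_fnormals_now[fi2]), 0.0, 1.0
            )
            disp2 = target.vertices - cp2
            votes = bary2 * wb[:, None]  # (n_target, 3)
            vidx = faces[fi2]  # (n_target, 3)
            for kk in range(3):
                np.add.at(num, vidx[:, kk], votes[:, kk, None] * disp2)
                np.add.at(den, vidx[:, kk], votes[:, kk])

        D = np.zeros_like(f)
        ok = den > 1e-12
        D[ok] = num[ok] / den[ok, None]

        # visco-elastic update: MLS-smoothed desired positions
        f = _mls_smooth(f0, f + D, den, nb_i, nb_d, h)

    _, _, _, dist = tq.closest(f)
    cmap = CorrespondenceMap(
        faces=faces,
        mapped_vertices=f,
        target_id=target_id,
        mean_surface_distance=float(dist.mean()),
    )
    object.__setattr__(cmap, "trace", trace)  # diagnostic, not part of identity
    return cmap


def map_mandible(
    template: SurfaceMesh,
    template_init_lms: LandmarkConfiguration,
    target: SurfaceMesh,
    target_init_lms: LandmarkConfiguration,
    params: NonRigidParams | None = None,
    target_id: str = "target",
):
    """Full mapping chain: landmark similarity -> rigid ICP -> non-rigid.

    Returns ``(CorrespondenceMap, diagnostics)`` where diagnostics carries the
    per-stage residuals and iteration traces.
    """
    sim, sim_residual = similarity_from_landmarks(template_init_lms, target_init_lms)
    T, icp_trace = rigid_icp(template, target, init=sim)
    pre = template.with_vertices(T.apply(template.vertices))
    cmap = nonrigid_register(pre, target, params, target_id=target_id)
    diagnostics = {
        "similarity_residual": sim_residual,
        "icp_iterations": len(icp_trace),
        "icp_trace": icp_trace,
        "nonrigid_trace": list(getattr(cmap, "trace", [])),
        "mean_surface_distance": cmap.mean_surface_distance,
    }
    return cmap, diagnostics


# ---------------------------------------------------------------------------
# generalized Procrustes analysis


@dataclass(frozen=True)
class GPAResult:
    aligned: list
    consensus: np.ndarray
    scales: np.ndarray
    objective_trace: list
    n_iterations: int


def _as_point_array(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return np.asarray(config.points, dtype=float)
    if isinstance(config, SurfaceMesh):
        return np.asarray(config.vertices, dtype=float)
    if isinstance(config, CorrespondenceMap):
        return np.asarray(config.mapped_vertices, dtype=float)
    return np.asarray(config, dtype=float)


def generalized_procrustes(configs, tol: float = 1e-9, max_iter: int = 200) -> GPAResult:
    """Iterative similarity alignment of point sets in correspondence.

    The consensus is normalized to unit centroid size; the fitted per-config
    scales are returned so original sizes stay recoverable. Raises on
    degenerate (coincident-point) configurations.
    """
    X = [_as_point_array(c) for c in configs]
    if len(X) < 2:
        raise ValueError("generalized Procrustes needs at least 2 configurations")
    shape = X[0].shape
    if any(x.shape != shape for x in X):
        raise ValueError("all configurations must have the same point count")
    for i, x in enumerate(X):
        if np.linalg.norm(x - x.mean(axis=0)) < 1e-12:
            raise DegenerateGeometryError(f"configuration {i} has coincident points")

    def _normalize(c):
        c = c - c.mean(axis=0)
        size = np.linalg.norm(c)
        if size < 1e-300:
            raise DegenerateGeometryError("degenerate consensus")
        return c / size

    # seed the consensus with the centered mean so that GPA is a no-op on its
    # own aligned output (gauge-consistent); fall back to the first config when
    # the raw mean is degenerate (e.g. mutually rotated copies cancelling out)
    centred = [x - x.mean(axis=0) for x in X]
    seed = np.mean(centred, axis=0)
    sizes = [np.linalg.norm(c) for c in centred]
    if np.linalg.norm(seed) > 1e-6 * np.mean(sizes):
        consensus = _normalize(seed)
    else:
        consensus = _normalize(X[0])
    aligned = list(X)
    scales = np.ones(len(X))
    objective_trace = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        transforms = [_fit_similarity(x, consensus, with_scale=True) for x in X]
        aligned = [T.apply(x) for T, x in zip(transforms, X)]
        scales = np.array([T.scale for T in transforms])
        new_consensus = _normalize(np.mean(aligned, axis=0))
        objective_trace.append(
            float(sum(((a - new_consensus) ** 2).sum() for a in aligned))
        )
        delta = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if delta < tol:
            break
    return GPAResult(aligned, consensus, scales, objective_trace, n_iter)


def build_template(mapped) -> SurfaceMesh:
    """Average GPA-aligned correspondence maps into a template mesh.

    The consensus is rescaled to the mean centroid size of the inputs so the
    template stays in millimetres (the consensus itself is unit-size by the
    GPA convention).
    """
    mapped = list(mapped)
    if len(mapped) == 0:
        raise ValueError("no correspondence maps given")
    faces = np.asarray(mapped[0].faces)
    for m in mapped[1:]:
        if not np.array_equal(np.asarray(m.faces), faces):
            raise TopologyMismatchError("correspondence maps do not share one template topology")
    arrs = [_as_point_array(m) for m in mapped]
    sizes = [float(np.linalg.norm(a - a.mean(axis=0))) for a in arrs]
    mean_size = float(np.mean(sizes))
    if len(arrs) == 1:
        centred = arrs[0] - arrs[0].mean(axis=0)
        return SurfaceMesh(centred, faces, validate=False)
    gpa = generalized_procrustes(arrs)
    return SurfaceMesh(gpa.consensus * mean_size, faces, validate=False)
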