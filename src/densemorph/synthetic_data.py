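"""Synthetic mandible-like mesh populations with known ground truth.

Real CBCT-derived mandible surfaces are not publicly shareable, so this module
generates everything the study design needs with exact bookkeeping:

* a smooth closed bilaterally symmetric base shape built by radially
  perturbing a subdivided icosahedron — a horseshoe-ish body with condylar,
  coronoid, gonial and chin prominences — carrying the canonical 26 anatomical
  landmarks and the 5 positioning landmarks at labeled geometric features;
* populations of members deformed by smooth random radial-basis displacement
  fields, in exact vertexwise correspondence with the base (correspondence is
  vertex identity), true landmarks carried along as fixed barycentric
  addresses;
* an "operated" variant in which an anterior tooth-bearing region is rigidly
  displaced inside a smoothstep transition band with added high-frequency
  band perturbation (healed-bone-cut irregularity);
* simulated repeated manual indications by multiple observers (per-observer
  bias + per-repetition noise, re-projected onto the surface) and jittered
  positioning landmarks driving repeated automatic mapping rounds.

Axes: +x right, +y anterior, +z superior; units mm. All generators are
deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .errors import DegenerateGeometryError
from .meshkit import (
    CANONICAL_INIT_5,
    CANONICAL_LANDMARKS_26,
    BarycentricPoint,
    LandmarkConfiguration,
    SurfaceMesh,
    closest_points_on_surface,
)

BASE_RADIUS_MM = 45.0


# ---------------------------------------------------------------------------
# icosphere (own subdivision: deterministic and exactly mirror-symmetric in x)

_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    verts = list(map(np.asarray, verts))
    midpoint: dict = {}
    new_faces = []

    def mid(i, j):
        key = (i, j) if i < j else (j, i)
        if key not in midpoint:
            m = (verts[i] + verts[j]) / 2.0
            m = m / np.linalg.norm(m)
            midpoint[key] = len(verts)
            verts.append(m)
        return midpoint[key]

    for a, b, c in faces:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.array(verts), np.array(new_faces, dtype=np.int64)


def unit_icosphere(subdivisions: int):
    """Unit sphere by recursive icosahedron subdivision (642 vertices at level 3)."""
    v = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    f = _ICO_FACES
    for _ in range(subdivisions):
        v, f = _subdivide(v, f)
    return v, f


def random_sphere_mesh(n_vertices: int, seed: int = 0, radius: float = 1.0) -> SurfaceMesh:
    """Convex triangulation of exactly ``n_vertices`` random points on a sphere.

    Handy for I/O and counting tests at arbitrary vertex counts.
    """
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_vertices, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= radius
    hull = ConvexHull(pts)
    faces = hull.simplices.copy()
    # orient all faces outward
    tri = pts[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flip = np.einsum("ij,ij->i", n, tri.mean(axis=1)) < 0
    faces[flip] = faces[flip][:, ::-1]
    return SurfaceMesh(pts, faces)


# ---------------------------------------------------------------------------
# the base shape

# feature bumps of the radial field: (direction, amplitude, angular width)
_SHAPE_BUMPS = [
    # condyles (posterior-superior-lateral prominences)
    ((0.62, -0.45, 0.62), 0.42, 0.055),
    ((-0.62, -0.45, 0.62), 0.42, 0.055),
    # coronoid processes
    ((0.55, 0.02, 0.62), 0.28, 0.035),
    ((-0.55, 0.02, 0.62), 0.28, 0.035),
    # gonial angles
    ((0.66, -0.46, -0.44), 0.30, 0.065),
    ((-0.66, -0.46, -0.44), 0.30, 0.065),
    # chin (protuberance of the mental region)
    ((0.0, 0.86, -0.48), 0.34, 0.085),
    # broad mandibular body arch
    ((0.45, 0.72, -0.40), 0.16, 0.11),
    ((-0.45, 0.72, -0.40), 0.16, 0.11),
]

# landmark feature directions (right side + midline; left side is mirrored)
_LANDMARK_DIRS_RIGHT_MID = {
    "right condylar superior pole": (0.60, -0.43, 0.68),
    "right condylar medial pole": (0.48, -0.45, 0.58),
    "right condylar lateral pole": (0.74, -0.44, 0.50),
    "right condylar posterior point": (0.60, -0.62, 0.50),
    "right fovea pterygoidea": (0.55, -0.27, 0.52),
    "right incisura lowest point": (0.59, -0.20, 0.58),
    "right coronoid process tip": (0.55, 0.02, 0.64),
    "right lingula": (0.46, -0.28, 0.22),
    "right gonion": (0.66, -0.46, -0.44),
    "right antegonial notch": (0.56, -0.05, -0.58),
    "right mental foramen": (0.40, 0.62, -0.28),
    "right tuberculum mentale": (0.24, 0.80, -0.44),
    "protuberans mentale": (0.0, 0.88, -0.46),
    "spina mentalis": (0.0, 0.80, -0.60),
}


def _all_landmark_dirs() -> dict:
    dirs = dict(_LANDMARK_DIRS_RIGHT_MID)
    for name, d in _LANDMARK_DIRS_RIGHT_MID.items():
        if name.startswith("right "):
            dirs["left " + name[len("right "):]] = (-d[0], d[1], d[2])
    return {n: np.asarray(dirs[n], dtype=float) / np.linalg.norm(dirs[n]) for n in CANONICAL_LANDMARKS_26}


def _radius_field(dirs: np.ndarray, seed: int) -> np.ndarray:
    """Radial distance of the base surface along unit directions."""
    u = np.atleast_2d(dirs)
    r = np.ones(len(u))
    # squash vertically for a jaw-like aspect
    r -= 0.18 * u[:, 2] ** 2
    for center, amp, width in _SHAPE_BUMPS:
        c = np.asarray(center) / np.linalg.norm(center)
        r += amp * np.exp((u @ c - 1.0) / width)
    # seeded individual character, symmetrized so the base stays bilateral
    rng = np.random.default_rng(seed)
    for _ in range(4):
        c = rng.normal(size=3)
        c /= np.linalg.norm(c)
        amp = 0.03 * rng.standard_normal()
        width = 0.2 + 0.2 * rng.random()
        for cc in (c, c * np.array([-1.0, 1.0, 1.0])):
            r += amp * np.exp((u @ cc - 1.0) / width)
    return BASE_RADIUS_MM * r


def make_base_shape(resolution: int = 3, seed: int = 0):
    """Deterministic mandible-like closed surface with named landmarks.

    ``resolution`` is the icosphere subdivision level; level 3 gives 642
    vertices, level 4 gives 2562. Returns ``(mesh, landmarks_26, init_5)``
    with all landmark points lying exactly on the triangulated surface.
    """
    u, faces = unit_icosphere(resolution)
    if len(u) < 500:
        raise ValueError(
            f"resolution {resolution} yields only {len(u)} vertices (< 500); use >= 3"
        )
    verts = _radius_field(u, seed)[:, None] * u
    mesh = SurfaceMesh(verts, faces)

    dirs = _all_landmark_dirs()
    names = list(dirs)
    d = np.stack([dirs[n] for n in names])
    analytic = _radius_field(d, seed)[:, None] * d
    on_surface, _, _, _ = closest_points_on_surface(analytic, mesh)
    lm26 = LandmarkConfiguration(tuple(names), on_surface)
    lm5 = lm26.subset(CANONICAL_INIT_5)
    return mesh, lm26, lm5


# ---------------------------------------------------------------------------
# population with known dense correspondence


def _surface_addresses(config: LandmarkConfiguration, mesh: SurfaceMesh):
    _, fi, bary, _ = closest_points_on_surface(config.points, mesh)
    return [BarycentricPoint(int(f), b) for f, b in zip(fi, bary)]


def _evaluate_addresses(addresses, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    out = np.empty((len(addresses), 3))
    for i, bc in enumerate(addresses):
        out[i] = bc.weights @ vertices[faces[bc.face_index]]
    return out


@dataclass(frozen=True)
class PopulationTruth:
    """A synthetic shape population with exact correspondence bookkeeping."""

    base: SurfaceMesh
    members: list
    true_landmarks: list  # per member, 26-name LandmarkConfiguration
    init_landmarks: list  # per member, 5-name LandmarkConfiguration
    deformation_fields: np.ndarray  # (n_members, n_vertices, 3)
    landmark_addresses: list = field(default_factory=list)
    init_addresses: list = field(default_factory=list)
    seed: int = 0
    label: str = "unaltered"

    def __post_init__(self):
        for member, lms in zip(self.members, self.true_landmarks):
            if member.faces.shape != self.base.faces.shape or not np.array_equal(
                member.faces, self.base.faces
            ):
                raise ValueError("population members must share the base topology")
            if self.landmark_addresses:
                pts = _evaluate_addresses(
                    self.landmark_addresses, member.vertices, member.faces
                )
                if np.abs(pts - lms.points).max() > 1e-9:
                    raise AssertionError(
                        "true landmarks inconsistent with member geometry"
                    )

    @property
    def n_members(self) -> int:
        return len(self.members)


def deform_population(
    base: SurfaceMesh,
    n_members: int,
    amplitude: float = 2.5,
    smoothness: float = 45.0,
    seed: int = 0,
    n_bumps: int = 10,
    base_landmarks: LandmarkConfiguration | None = None,
    base_init_landmarks: LandmarkConfiguration | None = None,
    label: str = "unaltered",
) -> PopulationTruth:
    """Smooth random deformations of the base with exact vertex correspondence.

    Each member is ``base + field`` where the field is a sum of Gaussian
    radial-basis bumps of length scale ``smoothness`` (mm), rescaled so the
    mean per-vertex displacement norm equals ``amplitude`` (mm).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    v0 = base.vertices
    scale = float(np.linalg.norm(v0 - v0.mean(axis=0), axis=1).mean())
    lm_addr = _surface_addresses(base_landmarks, base) if base_landmarks is not None else []
    init_addr = (
        _surface_addresses(base_init_landmarks, base) if base_init_landmarks is not None else []
    )

    members, fields, true_lms, init_lms = [], [], [], []
    for _ in range(n_members):
        centers = rng.normal(size=(n_bumps, 3))
        centers = centers / np.linalg.norm(centers, axis=1, keepdims=True) * (1.1 * scale)
        coeffs = rng.normal(size=(n_bumps, 3))
        d2 = ((v0[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        kern = np.exp(-d2 / (2.0 * smoothness**2))
        disp = kern @ coeffs
        norm = np.linalg.norm(disp, axis=1).mean()
        disp = disp * (amplitude / norm) if (amplitude > 0 and norm > 1e-12) else np.zeros_like(disp)
        member = base.with_vertices(v0 + disp)
        members.append(member)
        fields.append(disp)
        if lm_addr:
            true_lms.append(
                LandmarkConfiguration(
                    base_landmarks.names,
                    _evaluate_addresses(lm_addr, member.vertices, member.faces),
                )
            )
        if init_addr:
            init_lms.append(
                LandmarkConfiguration(
                    base_init_landmarks.names,
                    _evaluate_addresses(init_addr, member.vertices, member.faces),
                )
            )
    return PopulationTruth(
        base=base,
        members=members,
        true_landmarks=true_lms,
        init_landmarks=init_lms,
        deformation_fields=np.stack(fields) if fields else np.zeros((0, len(v0), 3)),
        landmark_addresses=lm_addr,
        init_addresses=init_addr,
        seed=seed,
        label=label,
    )


# ---------------------------------------------------------------------------
# the operated variant


@dataclass(frozen=True)
class OperatedRegion:
    """Landmark-anchored spherical region with a smoothstep transition band."""

    anchor_names: tuple = ("protuberans mentale", "right tuberculum mentale", "left tuberculum mentale")
    inner_radius: float = 14.0
    outer_radius: float = 30.0
    band_perturbation: float = 0.35  # mm, high-frequency irregularity in the band
    band_scale: float = 4.0  # mm, length scale of that irregularity


def simulate_operated(
    member: SurfaceMesh,
    landmarks: LandmarkConfiguration,
    displacement,
    seed: int = 0,
    region: OperatedRegion | None = None,
) -> SurfaceMesh:
    """Rigidly displace the tooth-bearing region inside a smooth falloff band.

    Vertices within ``inner_radius`` of the anchor centroid move by the full
    ``displacement`` vector; a smoothstep transition to ``outer_radius``
    preserves continuity, and a seeded short-length-scale perturbation inside
    the band mimics healed bone cuts.
    """
    region = region or OperatedRegion()
    displacement = np.asarray(displacement, dtype=float)
    if displacement.shape != (3,) or not np.isfinite(displacement).all():
        raise ValueError("displacement must be a finite 3-vector")
    anchors = np.stack([landmarks[n] for n in region.anchor_names])
    center = anchors.mean(axis=0)
    v = member.vertices
    d = np.linalg.norm(v - center, axis=1)
    if not (d <= region.outer_radius).any():
        raise DegenerateGeometryError("operated region contains no vertices")
    t = np.clip((d - region.inner_radius) / (region.outer_radius - region.inner_radius), 0.0, 1.0)
    w = 1.0 - (3.0 * t**2 - 2.0 * t**3)  # 1 inside, 0 outside
    new_v = v + w[:, None] * displacement
    if region.band_perturbation > 0:
        rng = np.random.default_rng(seed)
        band = w * (1.0 - w) * 4.0  # peaks mid-band, vanishes at both ends
        centers = v[rng.choice(len(v), size=8, replace=False)]
        d2 = ((v[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        noise = np.exp(-d2 / (2.0 * region.band_scale**2)) @ rng.normal(size=(8, 3))
        nmax = np.linalg.norm(noise, axis=1).max()
        if nmax > 1e-12:
            new_v = new_v + (region.band_perturbation / nmax) * band[:, None] * noise
    return member.with_vertices(new_v, validate=True)


def operated_population(
    truth: PopulationTruth,
    displacement=(0.0, 4.0, -1.5),
    seed: int = 0,
    region: OperatedRegion | None = None,
) -> PopulationTruth:
    """Apply the operated-shape transform to every member, rebuilding truth."""
    rng = np.random.default_rng(seed)
    members = [
        simulate_operated(m, lms, displacement, seed=int(rng.integers(2**31)), region=region)
        for m, lms in zip(truth.members, truth.true_landmarks)
    ]
    faces = truth.base.faces
    true_lms = [
        LandmarkConfiguration(
            truth.true_landmarks[i].names,
            _evaluate_addresses(truth.landmark_addresses, m.vertices, faces),
        )
        for i, m in enumerate(members)
    ]
    init_lms = [
        LandmarkConfiguration(
            truth.init_landmarks[i].names,
            _evaluate_addresses(truth.init_addresses, m.vertices, faces),
        )
        for i, m in enumerate(members)
    ]
    fields = np.stack([m.vertices - truth.base.vertices for m in members])
    return PopulationTruth(
        base=truth.base,
        members=members,
        true_landmarks=true_lms,
        init_landmarks=init_lms,
        deformation_fields=fields,
        landmark_addresses=truth.landmark_addresses,
        init_addresses=truth.init_addresses,
        seed=truth.seed,
        label="operated",
    )


# ---------------------------------------------------------------------------
# observers and initialization jitter


@dataclass(frozen=True)
class ObserverSim:
    """Manual-landmarking noise model.

    ``intra_sd`` is the per-coordinate repetition noise and
    ``observer_bias_sd`` the per-coordinate systematic observer offset (fixed
    per observer x landmark); indications are re-projected onto the surface,
    which suppresses the normal noise component. The default ``intra_sd`` is
    calibrated so the mean intra-observer RMS-to-centroid lands in the
    0.75-1.2 mm range reported for trained observers.
    """

    n_observers: int = 7
    n_repetitions: int = 3
    intra_sd: float = 0.8
    observer_bias_sd: float = 0.7
    seed: int = 0
    project_to_surface: bool = True

    def __post_init__(self):
        if self.n_observers < 1 or self.n_repetitions < 1:
            raise ValueError("need at least 1 observer and 1 repetition")
        if self.intra_sd < 0 or self.observer_bias_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def simulate_observers(truth: PopulationTruth, sim: ObserverSim):
    """Repeated manual indications per member.

    Returns one :class:`~densemorph.morphostats.RepeatedIndications` per
    member, with coordinates ordered like the member's true-landmark
    configuration.
    """
    from .morphostats import RepeatedIndications

    rng = np.random.default_rng(sim.seed)
    L = len(truth.true_landmarks[0]) if truth.true_landmarks else 0
    bias = rng.normal(scale=sim.observer_bias_sd or 1e-300, size=(sim.n_observers, L, 3))
    if sim.observer_bias_sd == 0:
        bias = np.zeros_like(bias)
    out = []
    for member, lms in zip(truth.members, truth.true_landmarks):
        noise = rng.normal(scale=sim.intra_sd or 1e-300, size=(L, sim.n_observers, sim.n_repetitions, 3))
        if sim.intra_sd == 0:
            noise = np.zeros_like(noise)
        pts = lms.points[:, None, None, :] + bias.transpose(1, 0, 2)[:, :, None, :] + noise
        if sim.project_to_surface:
            flat = pts.reshape(-1, 3)
            proj, _, _, _ = closest_points_on_surface(flat, member)
            pts = proj.reshape(pts.shape)
        out.append(
            RepeatedIndications(
                landmarks=lms.names, coords=pts, sample_label=truth.label
            )
        )
    return out


def jitter_init_landmarks(
    lms: LandmarkConfiguration, surface: SurfaceMesh, sd: float = 2.0, seed: int = 0
) -> LandmarkConfiguration:
    """Crude re-indication of the positioning landmarks: Gaussian jitter,
    re-projected onto the surface."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    pts = lms.points + (rng.normal(scale=sd, size=lms.points.shape) if sd > 0 else 0.0)
    proj, _, _, _ = closest_points_on_surface(pts, surface)
    return LandmarkConfiguration(lms.names, proj)
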