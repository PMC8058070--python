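"""Transfer of sparse manual landmarks into dense template space.

A manually indicated landmark (ML) on a target surface is embedded as the
barycentric address of its closest point on the mapped (template-topology)
surface. Because the mapped surface shares the template's topology, the same
address names a location on the template itself. Averaging the template-space
positions of one landmark over a training set — followed by closest-point
projection back onto the template surface — yields a template landmark whose
evaluation on any mapped target is the corresponding automatic landmark (CAL).

The leave-one-out protocol trains each target's template landmarks on all
*other* sample members, which is enforced structurally on the records.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingLandmarkError, TopologyMismatchError
from .meshkit import (
    BarycentricPoint,
    LandmarkConfiguration,
    SurfaceMesh,
    barycentric_to_cartesian,
    closest_point_on_surface,
)
from .registration import CorrespondenceMap


@dataclass(frozen=True)
class TemplateLandmark:
    """A named landmark pinned to a barycentric address on the template."""

    name: str
    bc: BarycentricPoint


@dataclass(frozen=True)
class TransferRecord:
    """One ML/CAL pair for one landmark on one target."""

    target_id: str
    landmark: str
    ml: np.ndarray
    cal: np.ndarray
    training_ids: tuple

    def __post_init__(self):
        ml = np.array(self.ml, dtype=float, copy=True)
        cal = np.array(self.cal, dtype=float, copy=True)
        if ml.shape != (3,) or cal.shape != (3,):
            raise ValueError("ml and cal must be 3D points")
        if not (np.all(np.isfinite(ml)) and np.all(np.isfinite(cal))):
            raise ValueError("non-finite ML/CAL coordinates")
        tids = tuple(self.training_ids)
        if self.target_id in tids:
            raise ValueError(
                f"leave-one-out violation: target {self.target_id!r} in its own training set"
            )
        ml.setflags(write=False)
        cal.setflags(write=False)
        object.__setattr__(self, "ml", ml)
        object.__setattr__(self, "cal", cal)
        object.__setattr__(self, "training_ids", tids)


def _mapped_mesh(mapped) -> SurfaceMesh:
    if isinstance(mapped, CorrespondenceMap):
        cached = getattr(mapped, "_mesh_cache", None)
        if cached is None:
            cached = mapped.as_mesh()
            object.__setattr__(mapped, "_mesh_cache", cached)
        return cached
    return mapped


def embed_landmark(ml, mapped) -> BarycentricPoint:
    """Barycentric address of the closest point to ``ml`` on a mapped surface."""
    mesh = _mapped_mesh(mapped)
    _, bc, _ = closest_point_on_surface(np.asarray(ml, dtype=float), mesh)
    return bc


def evaluate_cal(tl: TemplateLandmark, mapped) -> np.ndarray:
    """Evaluate a template landmark's address on a mapped surface (the CAL)."""
    faces = np.asarray(mapped.faces)
    if not 0 <= tl.bc.face_index < len(faces):
        raise TopologyMismatchError(
            f"template landmark face {tl.bc.face_index} invalid for map with {len(faces)} faces"
        )
    return barycentric_to_cartesian(tl.bc, mapped)


def _check_names(configs, names=None):
    if names is None:
        names = configs[0].names
    for i, cfg in enumerate(configs):
        missing = [n for n in names if n not in cfg.names]
        if missing:
            raise MissingLandmarkError(
                f"training configuration {i} is missing landmarks: {missing}"
            )
    return names


def train_template_landmarks(training, template: SurfaceMesh, names=None):
    """Derive template landmarks from ``(CorrespondenceMap, LandmarkConfiguration)`` pairs.

    Per landmark: embed each training ML on its mapped surface, evaluate the
    address on the template geometry, average the template-space points, and
    project the average back onto the template surface by closest point.
    """
    training = list(training)
    if not training:
        raise ValueError("empty training set")
    maps = [t[0] for t in training]
    configs = [t[1] for t in training]
    names = _check_names(configs, names)
    template_faces = np.asarray(template.faces)
    for i, m in enumerate(maps):
        if not np.array_equal(np.asarray(m.faces), template_faces):
            raise TopologyMismatchError(f"map {i} does not share the template topology")
    out = []
    for name in names:
        pts = np.empty((len(training), 3))
        for i, (cmap, cfg) in enumerate(zip(maps, configs)):
            bc = embed_landmark(cfg[name], cmap)
            pts[i] = barycentric_to_cartesian(bc, template)
        _, bc, _ = closest_point_on_surface(pts.mean(axis=0), template)
        out.append(TemplateLandmark(name, bc))
    return out


def train_template_landmarks_full(sample, template: SurfaceMesh, names=None):
    """Train on the entire sample (no leave-one-out); used for the
    repeated-measures reliability experiment, independently per sample."""
    return train_template_landmarks(list(sample), template, names=names)


def leave_one_out_cals(sample, template: SurfaceMesh, target_ids=None, names=None):
    """Leave-one-out CAL derivation across a sample.

    ``sample`` is a list of ``(CorrespondenceMap, LandmarkConfiguration)``;
    returns exactly ``len(sample) * n_landmarks`` :class:`TransferRecord`.
    """
    sample = list(sample)
    if len(sample) < 3:
        raise ValueError("leave-one-out needs a sample of at least 3")
    if target_ids is None:
        target_ids = [getattr(m, "target_id", None) or f"target_{i}" for i, (m, _) in enumerate(sample)]
    target_ids = [str(t) for t in target_ids]
    if len(set(target_ids)) != len(target_ids):
        raise ValueError("target ids must be unique")
    names = _check_names([c for _, c in sample], names)
    records = []
    for i, (cmap, cfg) in enumerate(sample):
        training = [s for j, s in enumerate(sample) if j != i]
        tids = tuple(t for j, t in enumerate(target_ids) if j != i)
        tls = train_template_landmarks(training, template, names=names)
        for tl in tls:
            records.append(
                TransferRecord(
                    target_id=target_ids[i],
                    landmark=tl.name,
                    ml=cfg[tl.name],
                    cal=evaluate_cal(tl, cmap),
                    training_ids=tids,
                )
            )
    return records
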