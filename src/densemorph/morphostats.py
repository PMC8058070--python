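"""Repeated-measures reliability and accuracy statistics.

The validation battery for dense phenotyping against manual landmarking:

* RMS distance of repeated indications to their centroid (reliability),
* principal axes of indication scatter,
* per-landmark ML-CAL Euclidean-distance descriptives,
* Bland-Altman limits of agreement,
* balanced-design variance components (jaw / observer / method-error) for
  centroid size, with the derived agreement statistics ICC, SEM and RC,
* the trace-based multivariate ICC on interlandmark-distance vectors.

Conventions fixed here: the ICC excludes the observer component from its
denominator (``sigma2_jaw / (sigma2_jaw + sigma2_error)``), the convention
that reproduces the study's printed table from its printed variance
components; the alternative (observer included) is exposed as an option. The
reproducibility coefficient uses the literal constant 2.77 x SEM.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist

from .errors import MissingLandmarkError, UnbalancedDesignError
from .meshkit import LandmarkConfiguration

RC_FACTOR = 2.77  # the stated multiple of SEM bounding 95% of method differences


# ---------------------------------------------------------------------------
# repeated indications


@dataclass(frozen=True)
class RepeatedIndications:
    """Landmark x observer x repetition coordinate tensor for one mandible."""

    landmarks: tuple
    coords: np.ndarray  # (n_landmarks, n_observers, n_repetitions, 3)
    sample_label: str = "unaltered"

    def __post_init__(self):
        names = tuple(str(n) for n in self.landmarks)
        c = np.array(self.coords, dtype=float, copy=True)
        if c.ndim != 4 or c.shape[3] != 3:
            raise ValueError(f"coords must be (L, O, R, 3), got {c.shape}")
        if c.shape[0] != len(names):
            raise ValueError("landmark name count does not match coords")
        if c.shape[2] < 2:
            raise UnbalancedDesignError("need at least 2 repetitions")
        bad = ~np.isfinite(c).all(axis=3)
        if bad.any():
            l, o, r = (int(i[0]) for i in np.nonzero(bad))
            raise UnbalancedDesignError(
                f"missing cell: landmark {names[l]!r}, observer {o}, repetition {r}"
            )
        c.setflags(write=False)
        object.__setattr__(self, "landmarks", names)
        object.__setattr__(self, "coords", c)

    @property
    def shape(self):
        return self.coords.shape

    def observer_means(self) -> np.ndarray:
        """Per-observer mean indication, shape (L, O, 3)."""
        return self.coords.mean(axis=2)


def rms_to_centroid(points) -> float:
    """Root mean square distance of a set of points to their centroid."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need at least 2 three-dimensional points")
    centroid = pts.mean(axis=0)
    return float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))


def _rms_along(coords: np.ndarray) -> np.ndarray:
    """RMS-to-centroid over the second-to-last axis of (..., r, 3) stacks."""
    centred = coords - coords.mean(axis=-2, keepdims=True)
    return np.sqrt((centred**2).sum(axis=-1).mean(axis=-1))


def _summary_row(values: np.ndarray, ci_level: float) -> dict:
    values = np.asarray(values, dtype=float)
    n = len(values)
    mean = float(values.mean())
    std = float(values.std(ddof=1)) if n > 1 else 0.0
    if n > 1 and std > 0:
        half = float(sps.t.ppf(0.5 + ci_level / 2, n - 1) * std / np.sqrt(n))
    else:
        half = 0.0
    return {
        "mean": mean,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "std": std,
        "min": float(values.min()),
        "max": float(values.max()),
    }


def reliability_report(
    manual,
    automatic=None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Repeated-measures reliability table (one row per error source).

    ``manual`` is a sequence of :class:`RepeatedIndications` (one per
    mandible, identical layout); ``automatic`` optionally gives per-mandible
    ``(L, n_rounds, 3)`` arrays of repeated automatic landmarks. Per-landmark
    RMS values are averaged over mandibles; the row summaries (mean, t-based
    CI of the mean, std, min, max) are taken over the landmarks.

    Rows: ``automated`` (if given), ``inter_observer``, then one
    ``intra_observer_<k>`` row per observer.
    """
    manual = list(manual)
    if not manual:
        raise ValueError("no manual indication data")
    names = manual[0].landmarks
    shape = manual[0].shape
    for i, m in enumerate(manual):
        if m.landmarks != names or m.shape != shape:
            raise UnbalancedDesignError(f"mandible {i} has a different design layout")
    L, O, R, _ = shape
    stack = np.stack([m.coords for m in manual])  # (M, L, O, R, 3)

    rows = {}
    if automatic is not None:
        auto = np.stack([np.asarray(a, dtype=float) for a in automatic])  # (M, L, rounds, 3)
        if auto.shape[1] != L or auto.shape[2] < 2:
            raise UnbalancedDesignError("automatic repeats must be (L, rounds>=2, 3) per mandible")
        if not np.isfinite(auto).all():
            raise UnbalancedDesignError("missing cells in automatic repeats")
        rows["automated"] = _rms_along(auto).mean(axis=0)  # (L,)

    obs_means = stack.mean(axis=3)  # (M, L, O, 3)
    rows["inter_observer"] = _rms_along(obs_means).mean(axis=0)
    intra = _rms_along(stack)  # (M, L, O)
    for o in range(O):
        rows[f"intra_observer_{o + 1}"] = intra[:, :, o].mean(axis=0)

    return pd.DataFrame(
        {name: _summary_row(vals, ci_level) for name, vals in rows.items()}
    ).T[["mean", "ci_low", "ci_high", "std", "min", "max"]]


# ---------------------------------------------------------------------------
# principal variation axes


@dataclass(frozen=True)
class PrincipalAxes:
    axes: np.ndarray  # rows are orthonormal axes, descending variance
    variances: np.ndarray
    degenerate: bool


def principal_variation_axes(deviations) -> PrincipalAxes:
    """Eigen-decomposition of the (uncentered) second moment of deviation vectors.

    The variances sum to the mean squared deviation norm.
    """
    d = np.asarray(deviations, dtype=float)
    if d.ndim != 2 or d.shape[1] != 3 or len(d) < 3:
        raise ValueError("need at least 3 three-dimensional deviation vectors")
    M = d.T @ d / len(d)
    if np.trace(M) < 1e-300:
        return PrincipalAxes(np.eye(3), np.zeros(3), True)
    w, V = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    return PrincipalAxes(V[:, order].T, np.clip(w[order], 0.0, None), False)


# ---------------------------------------------------------------------------
# ML-CAL accuracy


def euclidean_accuracy(records, landmark_order=None) -> pd.DataFrame:
    """Per-landmark descriptives of the ML-CAL Euclidean distance.

    Rows follow ``landmark_order`` (default: first-appearance order) plus a
    final ``average`` row holding the arithmetic mean of the per-landmark
    columns.
    """
    records = list(records)
    if not records:
        raise ValueError("no transfer records")
    by_landmark: dict = {}
    per_target: dict = {}
    for r in records:
        d = float(np.linalg.norm(np.asarray(r.ml, float) - np.asarray(r.cal, float)))
        by_landmark.setdefault(r.landmark, []).append(d)
        per_target.setdefault(r.target_id, set()).add(r.landmark)
    names = list(by_landmark) if landmark_order is None else list(landmark_order)
    full = set(names)
    for tid, present in per_target.items():
        missing = sorted(full - present)
        if missing:
            raise MissingLandmarkError(f"target {tid!r} is missing landmarks: {missing}")
    table = {}
    for name in names:
        vals = np.asarray(by_landmark[name], dtype=float)
        table[name] = {
            "mean": float(vals.mean()),
            "std": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    df = pd.DataFrame(table).T[["mean", "std", "min", "max"]]
    df.loc["average"] = df.mean(axis=0)
    return df


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    loa_low: float
    loa_high: float
    pair_means: np.ndarray
    pair_differences: np.ndarray


def bland_altman(a, b) -> BlandAltman:
    """Agreement between paired measurements: d = a - b, limits mean(d) +/- 1.96 sd(d)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1D sequences")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(md, md - 1.96 * sd, md + 1.96 * sd, (a + b) / 2.0, d)


# ---------------------------------------------------------------------------
# variance components and agreement statistics


@dataclass(frozen=True)
class VarianceComponents:
    """sigma^2 of jaw (subject), observer, and error (the method contribution), mm^2."""

    sigma2_jaw: float
    sigma2_observer: float
    sigma2_error: float
    truncated: tuple = ()

    def __post_init__(self):
        for name in ("sigma2_jaw", "sigma2_observer", "sigma2_error"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative number")
            object.__setattr__(self, name, v)
        object.__setattr__(self, "truncated", tuple(self.truncated))


def variance_components(values) -> VarianceComponents:
    """Balanced-design ANOVA variance components for a jaw x observer x method layout.

    ``values`` has shape ``(n_jaw, n_observer, n_method)`` with one observation
    per cell; jaw and observer are random, method is the fixed factor whose
    contribution lands in the error component. Expected-mean-squares estimates
    equal restricted-likelihood estimates for balanced data; negative estimates
    are truncated to zero and flagged.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3:
        raise UnbalancedDesignError(f"values must be (n_jaw, n_observer, n_method), got {y.shape}")
    if not np.isfinite(y).all():
        raise UnbalancedDesignError("unbalanced input: missing (non-finite) cells")
    a, b, m = y.shape
    if a < 2 or b < 2 or m < 2:
        raise UnbalancedDesignError("need at least 2 levels of each factor")
    grand = y.mean()
    ms_jaw = b * m * ((y.mean(axis=(1, 2)) - grand) ** 2).sum() / (a - 1)
    ms_obs = a * m * ((y.mean(axis=(0, 2)) - grand) ** 2).sum() / (b - 1)
    ss_method = a * b * ((y.mean(axis=(0, 1)) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    df_resid = a * b * m - a - b - m + 2
    ss_resid = ss_total - (a - 1) * ms_jaw - (b - 1) * ms_obs - ss_method
    ms_resid = ss_resid / df_resid

    sigma2_error = ms_resid
    sigma2_jaw = (ms_jaw - ms_resid) / (b * m)
    sigma2_obs = (ms_obs - ms_resid) / (a * m)
    truncated = []
    if sigma2_jaw < 0:
        sigma2_jaw, truncated = 0.0, truncated + ["sigma2_jaw"]
    if sigma2_obs < 0:
        sigma2_obs, truncated = 0.0, truncated + ["sigma2_observer"]
    if sigma2_error < 0:
        sigma2_error, truncated = 0.0, truncated + ["sigma2_error"]
    return VarianceComponents(sigma2_jaw, sigma2_obs, sigma2_error, tuple(truncated))


@dataclass(frozen=True)
class AgreementStats:
    """ICC, standard error of measurement (mm) and reproducibility coefficient (mm)."""

    icc: float
    sem: float
    rc: float

    def __post_init__(self):
        if not 0.0 <= self.icc <= 1.0:
            raise ValueError(f"ICC {self.icc} outside [0, 1]")
        if abs(self.rc - RC_FACTOR * self.sem) > 1e-12 * max(1.0, self.rc):
            raise ValueError("RC must equal 2.77 x SEM")


def agreement_stats(vc: VarianceComponents, include_observer: bool = False) -> AgreementStats:
    """Derive ICC, SEM and RC from variance components.

    ``SEM = sqrt(sigma2_error)``; ``RC = 2.77 * SEM``; the default ICC is
    ``sigma2_jaw / (sigma2_jaw + sigma2_error)`` (the convention that
    reproduces the study's worked examples); set ``include_observer`` to add
    the observer component to the denominator.
    """
    denom = vc.sigma2_jaw + vc.sigma2_error + (vc.sigma2_observer if include_observer else 0.0)
    if denom <= 0:
        raise ValueError("ICC undefined: all variance components are zero")
    sem = float(np.sqrt(vc.sigma2_error))
    return AgreementStats(icc=vc.sigma2_jaw / denom, sem=sem, rc=RC_FACTOR * sem)


# ---------------------------------------------------------------------------
# interlandmark distances and the multivariate ICC


def interlandmark_distances(config) -> np.ndarray:
    """All n(n-1)/2 unique pairwise distances in lexicographic pair order (mm)."""
    if isinstance(config, LandmarkConfiguration):
        pts = config.points  # name uniqueness enforced by the type
    else:
        pts = np.asarray(config, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need at least 2 three-dimensional landmarks")
    return pdist(pts)


def multivariate_icc(X, Y) -> float:
    """Trace-based agreement ICC between two methods on multivariate responses.

    ``X`` and ``Y`` are ``(n_subjects, n_dimensions)`` matrices of the same
    quantity measured by two methods. Per dimension, a two-way subject x
    method decomposition estimates subject, method and error variance; the
    statistic is ``trace(subject) / trace(subject + method + error)``. It
    reduces to the univariate absolute-agreement ICC at dimension 1 and equals
    1 when Y == X.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape != Y.shape:
        raise ValueError(f"dimension mismatch: {X.shape} vs {Y.shape}")
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    data = np.stack([X, Y], axis=1)  # (n, 2, p)
    grand = data.mean(axis=(0, 1))
    subj = data.mean(axis=1) - grand  # (n, p)
    meth = data.mean(axis=0) - grand  # (2, p)
    resid = data - subj[:, None, :] - meth[None, :, :] - grand
    msr = 2.0 * (subj**2).sum(axis=0) / (n - 1)
    msc = n * (meth**2).sum(axis=0)  # df = 1
    mse = (resid**2).sum(axis=(0, 1)) / (n - 1)
    sigma_subj = (msr - mse) / 2.0
    sigma_meth = (msc - mse) / n
    denom = (sigma_subj + sigma_meth + mse).sum()
    if denom <= 0:
        raise ValueError("multivariate ICC undefined: zero total variance")
    return float(sigma_subj.sum() / denom)
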