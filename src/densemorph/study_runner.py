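"""End-to-end study replica: simulate -> map -> transfer -> validate.

``run_study`` generates the two synthetic samples (unaltered and operated),
maps the template onto every member in several rounds that differ only in the
jitter of the five positioning landmarks, derives corresponding automatic
landmarks (full-sample training for the reliability comparison, leave-one-out
training for the accuracy assessment), and runs the complete statistics
battery. The report carries a provenance block (config hash, seeds, version)
and every reported number is recomputable from the raw-data manifest, which
``validate_report`` checks cell by cell.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .landmark_transfer import TransferRecord, evaluate_cal
from .meshkit import (
    BarycentricPoint,
    barycentric_to_cartesian,
    centroid_size,
    closest_point_on_surface,
)
from .morphostats import (
    RepeatedIndications,
    agreement_stats,
    bland_altman,
    euclidean_accuracy,
    interlandmark_distances,
    multivariate_icc,
    reliability_report,
    variance_components,
)
from .registration import NonRigidParams, map_mandible
from .synthetic_data import (
    ObserverSim,
    deform_population,
    jitter_init_landmarks,
    make_base_shape,
    operated_population,
    simulate_observers,
)


@dataclass(frozen=True)
class StudyConfig:
    """Fully explicit configuration of a study replica (no implicit entropy)."""

    n_unaltered: int = 30
    n_operated: int = 20
    n_observers: int = 7
    n_repetitions: int = 3
    n_rounds: int = 3
    resolution: int = 3
    deform_amplitude: float = 2.5
    deform_smoothness: float = 45.0
    operated_displacement: tuple = (0.0, 4.0, -1.5)
    intra_sd: float = 0.8
    observer_bias_sd: float = 0.7
    init_jitter_sd: float = 2.0
    nonrigid: NonRigidParams = field(
        default_factory=lambda: NonRigidParams(n_iterations=100)
    )
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class StudyReport:
    """Per-sample report tables plus provenance."""

    tables: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {"tables": self.tables, "provenance": self.provenance}, sort_keys=True
        )

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        for sample, tabs in self.tables.items():
            for name in ("reliability", "accuracy", "multivariate_icc"):
                pd.DataFrame(tabs[name]).to_csv(out / f"{sample}_{name}.csv")
            ba = tabs["agreement"]["bland_altman"]
            pd.DataFrame(
                {"pair_mean": ba["pair_means"], "difference": ba["pair_differences"]}
            ).to_csv(out / f"{sample}_bland_altman.csv", index=False)


def _spawn_seeds(seed: int, n: int):
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _df_to_dict(df: pd.DataFrame) -> dict:
    return {str(c): {str(i): float(v) for i, v in df[c].items()} for c in df.columns}


def _map_rounds(template, template_init5, truth, params, jitter_sd, seeds):
    """All mapping rounds for one sample; rounds differ only in init jitter."""
    maps = []
    for i, member in enumerate(truth.members):
        rounds = []
        for r, seed in enumerate(seeds[i]):
            jlms = jitter_init_landmarks(
                truth.init_landmarks[i], member, sd=jitter_sd, seed=seed
            )
            cmap, _ = map_mandible(
                template,
                template_init5,
                member,
                jlms,
                params=params,
                target_id=f"{truth.label}_{i}_round{r}",
            )
            rounds.append(cmap)
        maps.append(rounds)
    return maps


def _template_points(template, maps_round0, ml_obs_mean, names):
    """Template-space embedding of every (member, observer) mean ML.

    Returns an (n_members, n_observers, L, 3) tensor: each manual landmark
    embedded barycentrically on its member's mapped surface and evaluated on
    the template geometry.
    """
    n_mem, n_obs, L, _ = ml_obs_mean.shape
    out = np.empty((n_mem, n_obs, L, 3))
    for m in range(n_mem):
        cmap = maps_round0[m]
        mesh = cmap.as_mesh()
        flat = ml_obs_mean[m].reshape(-1, 3)
        _, fi, bary, _ = mesh.query.closest(flat)
        for j, (f, b) in enumerate(zip(fi, bary)):
            bc = BarycentricPoint(int(f), b)
            out[m, j // L, j % L] = barycentric_to_cartesian(bc, template)
    return out


def _project_to_template_landmarks(template, points, names):
    """Closest-point projection of averaged template-space points -> addresses."""
    from .landmark_transfer import TemplateLandmark

    tls = []
    for name, p in zip(names, points):
        _, bc, _ = closest_point_on_surface(p, template)
        tls.append(TemplateLandmark(name, bc))
    return tls


def _analyze_sample(template, truth, indications, maps, config, label):
    names = truth.true_landmarks[0].names
    L = len(names)
    n_mem = truth.n_members
    n_obs = config.n_observers
    n_rounds = config.n_rounds

    # per-observer mean manual landmarks, (n_mem, n_obs, L, 3)
    ml_obs_mean = np.stack([ind.observer_means().transpose(1, 0, 2) for ind in indications])
    maps_round0 = [rounds[0] for rounds in maps]
    tp = _template_points(template, maps_round0, ml_obs_mean, names)

    # --- reliability: full-sample training, CAL per mapping round
    tls_full = _project_to_template_landmarks(template, tp.mean(axis=(0, 1)), names)
    cal_rounds = np.empty((n_mem, L, n_rounds, 3))
    for m in range(n_mem):
        for r in range(n_rounds):
            for l, tl in enumerate(tls_full):
                cal_rounds[m, l, r] = evaluate_cal(tl, maps[m][r])
    reliability = reliability_report(indications, automatic=list(cal_rounds))

    # --- accuracy: leave-one-out training, CAL averaged over rounds
    tp_sum = tp.sum(axis=(0, 1))  # (L, 3)
    cal_mean = np.empty((n_mem, L, 3))
    records = []
    member_ids = [f"{label}_{m}" for m in range(n_mem)]
    for m in range(n_mem):
        loo_avg = (tp_sum - tp[m].sum(axis=0)) / ((n_mem - 1) * n_obs)
        tls = _project_to_template_landmarks(template, loo_avg, names)
        for l, tl in enumerate(tls):
            cal_mean[m, l] = np.mean(
                [evaluate_cal(tl, maps[m][r]) for r in range(n_rounds)], axis=0
            )
        training = tuple(t for t in member_ids if t != member_ids[m])
        for o in range(n_obs):
            for l, name in enumerate(names):
                records.append(
                    TransferRecord(
                        target_id=f"{member_ids[m]}_obs{o + 1}",
                        landmark=name,
                        ml=ml_obs_mean[m, o, l],
                        cal=cal_mean[m, l],
                        training_ids=training,
                    )
                )
    accuracy = euclidean_accuracy(records, landmark_order=names)

    # --- centroid-size agreement
    manual_cs = np.array(
        [[centroid_size(ml_obs_mean[m, o]) for o in range(n_obs)] for m in range(n_mem)]
    )
    auto_cs = np.array([centroid_size(cal_mean[m]) for m in range(n_mem)])
    values = np.stack([manual_cs, np.repeat(auto_cs[:, None], n_obs, axis=1)], axis=2)
    vc = variance_components(values)
    ag = agreement_stats(vc)
    ba = bland_altman(manual_cs.mean(axis=1), auto_cs)

    # --- multivariate ICC on interlandmark distances, per observer
    Y = np.stack([interlandmark_distances(cal_mean[m]) for m in range(n_mem)])
    micc = {}
    for o in range(n_obs):
        X = np.stack([interlandmark_distances(ml_obs_mean[m, o]) for m in range(n_mem)])
        micc[f"observer_{o + 1}"] = multivariate_icc(X, Y)
    micc["mean"] = float(np.mean(list(micc.values())))
    micc_df = pd.DataFrame({"icc": micc})

    tables = {
        "reliability": _df_to_dict(reliability),
        "accuracy": _df_to_dict(accuracy),
        "agreement": {
            "variance_components": {
                "jaw": vc.sigma2_jaw,
                "observer": vc.sigma2_observer,
                "error": vc.sigma2_error,
            },
            "icc": ag.icc,
            "sem": ag.sem,
            "rc": ag.rc,
            "bland_altman": {
                "mean_difference": ba.mean_difference,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "pair_means": ba.pair_means.tolist(),
                "pair_differences": ba.pair_differences.tolist(),
            },
        },
        "multivariate_icc": _df_to_dict(micc_df),
    }
    manifest = {
        "landmark_names": list(names),
        "indications": np.stack([ind.coords for ind in indications]).tolist(),
        "cal_rounds": cal_rounds.tolist(),
        "ml_observer_mean": ml_obs_mean.tolist(),
        "cal_mean": cal_mean.tolist(),
    }
    return tables, manifest


def run_study(config: StudyConfig):
    """Execute the full replica; returns ``(StudyReport, manifest)``."""
    seeds = _spawn_seeds(config.seed, 8)
    base, lm26, lm5 = make_base_shape(config.resolution, seed=seeds[0])
    template = base  # the synthetic stand-in for the population-average template

    tables, manifest = {}, {}
    sample_specs = [
        ("unaltered", config.n_unaltered, seeds[1], seeds[3], seeds[5], None),
        ("operated", config.n_operated, seeds[2], seeds[4], seeds[6], seeds[7]),
    ]
    for label, n, pop_seed, obs_seed, round_seed, op_seed in sample_specs:
        if n == 0:
            continue
        truth = deform_population(
            base,
            n,
            amplitude=config.deform_amplitude,
            smoothness=config.deform_smoothness,
            seed=pop_seed,
            base_landmarks=lm26,
            base_init_landmarks=lm5,
            label=label,
        )
        if op_seed is not None:
            truth = operated_population(
                truth, displacement=config.operated_displacement, seed=op_seed
            )
        indications = simulate_observers(
            truth,
            ObserverSim(
                n_observers=config.n_observers,
                n_repetitions=config.n_repetitions,
                intra_sd=config.intra_sd,
                observer_bias_sd=config.observer_bias_sd,
                seed=obs_seed,
            ),
        )
        jitter_seeds = np.array(
            _spawn_seeds(round_seed, n * config.n_rounds)
        ).reshape(n, config.n_rounds)
        maps = _map_rounds(
            template, lm5, truth, config.nonrigid, config.init_jitter_sd, jitter_seeds
        )
        tables[label], manifest[label] = _analyze_sample(
            template, truth, indications, maps, config, label
        )

    report = StudyReport(
        tables=tables,
        provenance={
            "config": json.loads(json.dumps(asdict(config), default=str)),
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": __version__,
        },
    )
    manifest["config"] = json.loads(json.dumps(asdict(config), default=str))
    return report, manifest


# ---------------------------------------------------------------------------
# report validation


@dataclass(frozen=True)
class ValidationResult:
    passed: bool
    failures: tuple

    def __bool__(self):  # pragma: no cover
        return self.passed


def _compare(failures, path, reported, recomputed, tol=1e-9):
    if abs(float(reported) - float(recomputed)) > tol:
        failures.append(f"{path}: reported {reported!r} != recomputed {recomputed!r}")


def validate_report(report: StudyReport, manifest: dict) -> ValidationResult:
    """Recompute every reported statistic from the raw manifest data."""
    failures: list = []
    for label, tabs in report.tables.items():
        raw = manifest.get(label)
        if raw is None:
            failures.append(f"{label}: missing from manifest")
            continue
        names = tuple(raw["landmark_names"])
        ind = np.asarray(raw["indications"])
        cal_rounds = np.asarray(raw["cal_rounds"])
        ml = np.asarray(raw["ml_observer_mean"])
        cal = np.asarray(raw["cal_mean"])
        n_mem, n_obs = ml.shape[:2]

        indications = [
            RepeatedIndications(landmarks=names, coords=c, sample_label=label) for c in ind
        ]
        rel = reliability_report(indications, automatic=list(cal_rounds))
        for col, cells in tabs["reliability"].items():
            for row, val in cells.items():
                _compare(failures, f"{label}/reliability/{row}/{col}", val, rel.loc[row, col])

        records = [
            TransferRecord(
                target_id=f"{label}_{m}_obs{o + 1}",
                landmark=name,
                ml=ml[m, o, l],
                cal=cal[m, l],
                training_ids=(),
            )
            for m in range(n_mem)
            for o in range(n_obs)
            for l, name in enumerate(names)
        ]
        acc = euclidean_accuracy(records, landmark_order=names)
        for col, cells in tabs["accuracy"].items():
            for row, val in cells.items():
                _compare(failures, f"{label}/accuracy/{row}/{col}", val, acc.loc[row, col])

        manual_cs = np.array(
            [[centroid_size(ml[m, o]) for o in range(n_obs)] for m in range(n_mem)]
        )
        auto_cs = np.array([centroid_size(cal[m]) for m in range(n_mem)])
        vc = variance_components(
            np.stack([manual_cs, np.repeat(auto_cs[:, None], n_obs, axis=1)], axis=2)
        )
        ag = agreement_stats(vc)
        agr = tabs["agreement"]
        _compare(failures, f"{label}/agreement/jaw", agr["variance_components"]["jaw"], vc.sigma2_jaw)
        _compare(
            failures,
            f"{label}/agreement/observer",
            agr["variance_components"]["observer"],
            vc.sigma2_observer,
        )
        _compare(failures, f"{label}/agreement/error", agr["variance_components"]["error"], vc.sigma2_error)
        _compare(failures, f"{label}/agreement/icc", agr["icc"], ag.icc)
        _compare(failures, f"{label}/agreement/sem", agr["sem"], ag.sem)
        _compare(failures, f"{label}/agreement/rc", agr["rc"], ag.rc)
        ba = bland_altman(manual_cs.mean(axis=1), auto_cs)
        _compare(
            failures,
            f"{label}/agreement/bland_altman/mean_difference",
            agr["bland_altman"]["mean_difference"],
            ba.mean_difference,
        )

        Y = np.stack([interlandmark_distances(cal[m]) for m in range(n_mem)])
        for o in range(n_obs):
            X = np.stack([interlandmark_distances(ml[m, o]) for m in range(n_mem)])
            _compare(
                failures,
                f"{label}/multivariate_icc/observer_{o + 1}",
                tabs["multivariate_icc"]["icc"][f"observer_{o + 1}"],
                multivariate_icc(X, Y),
            )
    return ValidationResult(passed=not failures, failures=tuple(failures))
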