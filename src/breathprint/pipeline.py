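"""End-to-end study orchestration: simulate -> blind split -> preprocess ->
cross-validate -> blind-validate -> report.

Blinded participants (excluded by the block-size rule) never influence
model building: the preprocessor's Tucker factors and [-1, 1] rescaling
map are fitted on the training cohort only and applied frozen to the
blinded cohort; the final network is trained on the training cohort only.
A single integer seed fans out to per-stage seeds through
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .ann import RpropNetClassifier
from .evaluation import (
    DEFAULT_BLOCK_SIZE,
    DEFAULT_THRESHOLD,
    DiagnosticReport,
    assign_blind_set,
    covariates_design,
    diagnostic_report,
    leave_10pct_out_cv,
    logistic_stepwise,
)
from .io import SensorTensor, write_cohort_csv, write_feature_csv, FeatureVector
from .preprocess import BreathprintPreprocessor
from .synthetic import GeneratorConfig, generate_cohort, labels_array


@dataclass
class StudyConfig:
    """One reproducible run: generator + preprocess + training + evaluation."""

    generator: GeneratorConfig = field(default_factory=lambda: GeneratorConfig(arrangement="blocked"))
    preprocessor: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    threshold: float = DEFAULT_THRESHOLD
    block_size: int = DEFAULT_BLOCK_SIZE
    cv_fraction: float = 0.1
    seed: int = 0


@dataclass
class StudyResult:
    manifest: dict
    training_report: DiagnosticReport
    blinded_report: DiagnosticReport | None
    cv_values: "object"  # DataFrame: participant_id, label, value, fold
    blinded_values: np.ndarray
    stepwise_auc: float | None
    stepwise_selected: list[str] | None


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("generator", "cv", "final_model")
    states = ss.generate_state(len(names)) % (2**31)
    return dict(zip(names, (int(s) for s in states)))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_study(
    config: StudyConfig,
    out_dir: str | Path | None = None,
    cohort: Sequence[SensorTensor] | None = None,
) -> StudyResult:
    """Execute the full chain and return reports plus a run manifest.

    ``cohort`` overrides the generator (e.g. measurements read from CSV);
    otherwise a synthetic cohort is generated under the config's
    conditions.  With ``out_dir`` set, the cohort, features, per-
    participant values, and reports are written and their SHA-256 digests
    recorded in the manifest.
    """
    timings: dict[str, float] = {}
    seeds = _stage_seeds(config.seed)

    t0 = time.perf_counter()
    if cohort is None:
        gen_cfg = GeneratorConfig(**{**asdict(config.generator), "seed": seeds["generator"]})
        cohort = generate_cohort(gen_cfg)
    else:
        gen_cfg = None
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    training, blinded = assign_blind_set(cohort, block_size=config.block_size)
    if len(training) < 10:
        raise ValueError("fewer than 10 training participants after the block-size rule")
    prep = BreathprintPreprocessor(**config.preprocessor).fit(training)
    X_train = prep.transform(training)
    y_train = labels_array(training)
    X_blind = prep.transform(blinded) if blinded else np.empty((0, X_train.shape[1]))
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    est = RpropNetClassifier(**config.classifier)
    cv = leave_10pct_out_cv(
        X_train,
        y_train,
        estimator=est,
        seed=seeds["cv"],
        ids=[t.participant_id for t in training],
        fraction=config.cv_fraction,
    )
    training_report = diagnostic_report(
        cv["value"].to_numpy(), y_train == 1, threshold=config.threshold
    )
    timings["cross_validate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    final = RpropNetClassifier(**{**config.classifier, "random_state": seeds["final_model"]})
    final.fit(X_train, y_train)
    blinded_values = (
        final.decision_function(X_blind) if len(X_blind) else np.empty(0)
    )
    blinded_report = None
    if blinded:
        y_blind = labels_array(blinded)
        blinded_report = diagnostic_report(
            blinded_values, y_blind == 1, threshold=config.threshold
        )
    timings["blind_validate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stepwise_auc = None
    stepwise_selected = None
    cov, keep = covariates_design(training)
    if keep.sum() >= 20 and min((y_train[keep] == 1).sum(), (y_train[keep] == 0).sum()) >= 10:
        sw = logistic_stepwise(
            cv["value"].to_numpy()[keep], cov, (y_train == 1)[keep].astype(int)
        )
        stepwise_auc = sw.auc
        stepwise_selected = sw.selected
    timings["stepwise"] = time.perf_counter() - t0

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": {
            "generator": None if gen_cfg is None else asdict(gen_cfg),
            "preprocessor": prep.get_params(),
            "classifier": est.get_params(),
            "threshold": config.threshold,
            "block_size": config.block_size,
            "cv_fraction": config.cv_fraction,
        },
        "cohort": {
            "n_total": len(cohort),
            "n_training": len(training),
            "n_blinded": len(blinded),
        },
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "outputs": {},
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(out / "cohort.csv", cohort)
        feats = [
            FeatureVector(t.participant_id, x, t.label)
            for t, x in zip(training, X_train)
        ]
        write_feature_csv(out / "features.csv", feats)
        cv.to_csv(out / "cv_values.csv", index=False)
        reports = {
            "training": training_report.to_dict(),
            "blinded": None if blinded_report is None else blinded_report.to_dict(),
            "stepwise": {"auc": stepwise_auc, "selected": stepwise_selected},
        }
        (out / "report.json").write_text(json.dumps(reports, indent=2))
        for name in ("cohort.csv", "features.csv", "cv_values.csv", "report.json"):
            manifest["outputs"][name] = _digest(out / name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return StudyResult(
        manifest=manifest,
        training_report=training_report,
        blinded_report=blinded_report,
        cv_values=cv,
        blinded_values=blinded_values,
        stepwise_auc=stepwise_auc,
        stepwise_selected=stepwise_selected,
    )
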