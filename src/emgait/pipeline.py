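"""End-to-end orchestration: simulate -> preprocess -> features ->
severity -> fit -> explain, with a run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import io as eio
from . import model as mdl
from . import prom as prm
from . import shapley as shp
from .config import RunConfig
from .core import LimbRecord
from .preprocess import NoUsableCyclesError, process_limb
from .synthetic import SyntheticSubject, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "features", "severity", "fit", "explain")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def cohort_to_limb_records(
    subjects: list[SyntheticSubject], snr_threshold_db: float = 18.0
) -> tuple[list[LimbRecord], list[dict]]:
    """Preprocess every limb of a synthetic cohort into analysis rows."""
    records: list[LimbRecord] = []
    skipped: list[dict] = []
    for subject in subjects:
        for limb_name, limb in subject.limbs.items():
            try:
                envelopes, exclusions = process_limb(limb.trials, snr_threshold_db)
            except NoUsableCyclesError as exc:
                skipped.append(
                    {"subject_id": subject.subject_id, "limb": limb_name, "reason": str(exc)}
                )
                continue
            records.append(
                LimbRecord(
                    subject_id=subject.subject_id,
                    limb=limb_name,
                    envelopes=envelopes,
                    temporospatial=limb.temporospatial,
                    prom=subject.prom,
                    latent_severity=subject.latent_severity,
                    excluded_epochs=exclusions,
                )
            )
    return records, skipped


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages, writing artifacts and a run manifest under
    ``out_dir``. Deterministic given the config (including its seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_fingerprint": config.fingerprint(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            eio.write_json(out / "manifest.json", manifest)
            raise StageError(name, exc) from exc
        manifest["stages"][name] = {
            "status": "completed",
            "seconds": round(time.perf_counter() - t0, 3),
        }
        return result

    spec = config.cohort_spec()
    subjects = run_stage("simulate", lambda: generate_cohort(spec))

    prom_rows = [(s.subject_id, s.prom) for s in subjects]
    eio.write_prom_csv(out / "prom.csv", prom_rows)
    ts_rows = [
        (s.subject_id, ln, limb.temporospatial)
        for s in subjects
        for ln, limb in s.limbs.items()
    ]
    eio.write_temporospatial_csv(out / "temporospatial.csv", ts_rows)

    def _preprocess():
        records, skipped = cohort_to_limb_records(
            subjects, config.preprocess.snr_threshold_db
        )
        if not records:
            raise NoUsableCyclesError("no usable cycles in any limb")
        exclusions = [e for r in records for e in r.excluded_epochs]
        with open(out / "exclusions.jsonl", "w") as fh:
            import json

            for entry in exclusions + [{"skipped_limb": s} for s in skipped]:
                fh.write(json.dumps(entry) + "\n")
        return records

    records = run_stage("preprocess", _preprocess)

    table = run_stage(
        "features",
        lambda: feat.build_feature_table(records, divisor=config.features.cci_divisor),
    )
    eio.write_feature_table(
        out / "features.csv",
        table,
        sidecar={"columns": list(table.columns), "cci_divisor": config.features.cci_divisor},
    )

    def _severity():
        labelled = prm.label_table(table)
        labelled.to_csv(out / "labels.csv", index=False)
        summary = prm.group_summary(labelled, feat.emg_feature_columns(table))
        summary.to_csv(out / "group_summary.csv", index=False)
        return labelled

    run_stage("severity", _severity)

    model_config = mdl.ModelConfig(
        k_features=config.model.k_features,
        test_fraction=config.model.test_fraction,
        cv_folds=config.model.cv_folds,
        depth_grid=tuple(config.model.depth_grid),
        n_trees=config.model.n_trees,
        seed=config.seed,
        targets=tuple(config.model.targets),
        family=config.model.family,
        group_by_subject=config.model.group_by_subject,
        include_temporospatial=config.model.include_temporospatial,
    )
    reports = run_stage("fit", lambda: mdl.run_all_targets(table, model_config))
    eio.write_json(out / "report.json", mdl.report_to_dict(reports))
    for target, rep in reports.items():
        rep.predictions.to_csv(out / f"predictions_{target}.csv", index=False)

    def _explain():
        results = {}
        rng = np.random.default_rng(config.seed)
        for target, rep in reports.items():
            X = table[rep.selected_features]
            train_X = X.iloc[rep.train_index].to_numpy(dtype=float)
            size = min(config.shap.background_size, train_X.shape[0])
            bg = train_X[rng.choice(train_X.shape[0], size=size, replace=False)]
            explain_idx = rep.test_index[: config.shap.n_explain]
            attrs = shp.attribute_dataset(rep.model, X.iloc[explain_idx], bg)
            summary = shp.summary_table(attrs, X.iloc[explain_idx])
            summary.to_csv(out / f"shap_summary_{target}.csv", index=False)
            matrix = pd.DataFrame(
                [a.phi for a in attrs], index=[a.instance_id for a in attrs]
            )
            matrix.to_csv(out / f"shap_values_{target}.csv")
            results[target] = summary
        return results

    run_stage("explain", _explain)

    for p in sorted(out.glob("*.csv")):
        manifest["outputs"][p.name] = _sha256(p)
    eio.write_json(out / "manifest.json", manifest)
    return manifest
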