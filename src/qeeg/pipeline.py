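"""End-to-end pipeline: simulate/ingest -> reject -> spectra -> features
-> combination sweep -> survival -> permutation -> report.

A run is driven by a single serializable :class:`RunConfig`; outputs land
in a run directory together with the config hash so that reruns with an
unchanged config can reuse cached upstream artifacts (the permutation
stage dominates cost, so re-sweeping from cached feature records is the
common path).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import QeegError
from .evaluation import (
    PermutationResult,
    combination_sweep,
    extract_survival,
    permutation_test,
    select_best,
)
from .features import build_feature_matrix, extract_subject_features
from .models import ModelSpec, cross_validate
from .recording import Recording, load_recording, reject_artifact_windows, resample_to_rate
from .simulate import (
    COVARIATE_PRESETS,
    EFFECT_PRESETS,
    CohortConfig,
    EffectSpec,
    generate_cohort,
)
from .spectral import sliding_cross_spectrum

log = logging.getLogger("qeeg")


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    out_dir: str = "qeeg_run"
    input_manifest: str | None = None  # CSV manifest of recordings; None -> simulate
    preset: str = "alpha_power"  # effect preset name when simulating
    n_cases: int = 60
    n_controls: int = 60
    duration_s: float = 60.0
    amplitude_limit: float = 100.0
    transform: str = "log10"
    adjust_iq: bool = False
    method: str = "EN"
    inner_cv_folds: int = 10
    en_mixing: float = 0.5
    en_n_lambdas: int = 30
    n_perm: int = 200
    survival_threshold: int = 7
    survival_lambda_rule: str = "1se"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise QeegError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            method=self.method,
            en_mixing=self.en_mixing,
            en_n_lambdas=self.en_n_lambdas,
            inner_cv_folds=self.inner_cv_folds,
            seed=self.seed,
        )


# ---------------------------------------------------------------- stages


def preprocess_recording(
    rec: Recording, amplitude_limit: float = 100.0, target_rate: float = 128.0
):
    """Resample to the analysis rate and reject artifact epochs."""
    if rec.rate > target_rate:
        rec = resample_to_rate(rec, target_rate)
    clean, mask = reject_artifact_windows(rec, amplitude_limit)
    return clean, mask


def extract_records(
    recs: list[Recording],
    amplitude_limit: float = 100.0,
    transform: str = "log10",
    reject: bool = True,
) -> pd.DataFrame:
    """Per-subject full QEEG records (rows) from recordings."""
    rows = []
    for rec in recs:
        if reject:
            rec, _ = preprocess_recording(rec, amplitude_limit)
        cs = sliding_cross_spectrum(rec)
        rows.append(extract_subject_features(cs, transform=transform).rename(rec.subject_id))
    out = pd.DataFrame(rows)
    out.index.name = "subject_id"
    return out


def load_manifest(manifest_path) -> tuple[list[Recording], pd.DataFrame]:
    """Load a cohort from a manifest CSV (subject_id, label, covariates, path)."""
    manifest_path = Path(manifest_path)
    covs = pd.read_csv(manifest_path, index_col="subject_id")
    recs = []
    for sid in covs.index:
        path = covs.loc[sid, "path"] if "path" in covs.columns else f"{sid}.csv"
        recs.append(load_recording(manifest_path.parent / path))
    return recs, covs


def _stage_cached(out: Path, name: str, cfg_hash: str, files: list[str]) -> bool:
    marker = out / f".{name}.hash"
    return (
        marker.exists()
        and marker.read_text().strip() == cfg_hash
        and all((out / f).exists() for f in files)
    )


def _mark_stage(out: Path, name: str, cfg_hash: str) -> None:
    (out / f".{name}.hash").write_text(cfg_hash + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the paths of the five artifacts.

    Stage order: ingest/simulate -> reject -> cross-spectrum -> features
    -> sweep -> survival -> permutation -> report. Stages whose inputs
    and config are unchanged are reloaded from the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    config.to_yaml(out / "config.yaml")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t_start = time.time()
    try:
        # -- features (ingest/simulate + reject + spectra + extraction)
        feat_hash = cfg_hash
        if _stage_cached(out, "features", feat_hash, ["records.csv", "manifest.csv"]):
            log.info("features: reusing cached records.csv")
            records = pd.read_csv(out / "records.csv", index_col="subject_id")
            covs = pd.read_csv(out / "manifest.csv", index_col="subject_id")
        else:
            t0 = time.time()
            if config.input_manifest:
                recs, covs = load_manifest(config.input_manifest)
                log.info("ingest: %d recordings from %s", len(recs), config.input_manifest)
            else:
                effects = EFFECT_PRESETS.get(config.preset)
                if effects is None:
                    raise QeegError(
                        f"unknown preset {config.preset!r}; known: {sorted(EFFECT_PRESETS)}"
                    )
                cc = CohortConfig(
                    n_cases=config.n_cases,
                    n_controls=config.n_controls,
                    duration_s=config.duration_s,
                    seed=config.seed,
                )
                recs, covs = generate_cohort(cc, effects)
                log.info("simulate: preset=%s n=%d", config.preset, len(recs))
            records = extract_records(recs, config.amplitude_limit, config.transform)
            records.to_csv(out / "records.csv")
            covs.to_csv(out / "manifest.csv")
            _mark_stage(out, "features", feat_hash)
            log.info("features: %.1f s", time.time() - t0)
        labels = covs["label"].to_numpy()

        # -- sweep
        spec = config.model_spec()
        t0 = time.time()
        sweep = combination_sweep(records, covs, labels, spec, config.adjust_iq)
        sweep.table.to_csv(out / "sweep.csv", index=False)
        log.info("sweep: best=%s auc=%.1f (%.1f s)", sweep.best.label(),
                 sweep.best_cv.mean_auc, time.time() - t0)

        # -- best-model CV + survival
        sweep.best_cv.fold_metrics.to_csv(out / "best_cv.csv", index=False)
        if spec.method == "EN":
            # performance is reported at the deviance-minimum penalty;
            # feature survival uses a one-SE-rule refit (parsimony), the
            # glmnet convention for interpretation after CV
            from dataclasses import replace as dc_replace

            fm_best = build_feature_matrix(records, covs, sweep.best, labels)
            cv_surv = cross_validate(fm_best, dc_replace(spec, en_lambda_rule=config.survival_lambda_rule))
            survival = extract_survival(cv_surv, config.survival_threshold)
            survival.table.to_csv(out / "survival.csv")
            log.info("survival: %d features survived", len(survival.survived))
        else:
            pd.DataFrame().to_csv(out / "survival.csv")
            log.info("survival: skipped (method %s has no EN coefficients)", spec.method)

        # -- permutation
        if config.n_perm > 0:
            t0 = time.time()
            fm = build_feature_matrix(records, covs, sweep.best, labels)
            perm = permutation_test(fm, spec, n_perm=config.n_perm, seed=config.seed,
                                    observed=sweep.best_cv)
            with open(out / "permutation.json", "w") as fh:
                json.dump(
                    {
                        "observed_auc": perm.observed_auc,
                        "p_value": perm.p_value,
                        "p_display": perm.p_display,
                        "n_perm": perm.n_perm,
                        "null_auc_mean": float(perm.null_aucs.mean()),
                    },
                    fh,
                    indent=2,
                )
            log.info("permutation: p=%s (%.1f s)", perm.p_display, time.time() - t0)
        else:
            log.info("permutation: skipped (n_perm=0)")

        # -- report
        best_row = sweep.table.iloc[select_best(sweep.table)]
        report = {
            "config_hash": cfg_hash,
            "best_combination": f"{best_row['parameter']}/{best_row['bands']}",
            "auc_mean": float(best_row["auc_mean"]),
            "auc_sd": float(best_row["auc_sd"]),
            "sens_mean": float(best_row["sens_mean"]),
            "spec_mean": float(best_row["spec_mean"]),
            "elapsed_s": time.time() - t_start,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        log.info("done in %.1f s", report["elapsed_s"])
        return {
            "sweep": out / "sweep.csv",
            "best_cv": out / "best_cv.csv",
            "survival": out / "survival.csv",
            "permutation": out / "permutation.json" if config.n_perm > 0 else None,
            "report": out / "report.json",
        }
    finally:
        log.removeHandler(handler)
        handler.close()
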