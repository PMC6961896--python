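"""End-to-end study replica: extract → filter → fit → score → evaluate.

`run_pipeline` drives the full analysis from a cohort manifest on disk
and writes every stage's artifact (feature table, signature JSON,
rad-score CSV, ROC results, summary tables, log) to a run directory.
`run_synthetic_study` is the in-memory equivalent on generated cohorts,
used by the examples and the acceptance machinery.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .features import extract_all_features
from .imaging import extract_roi, load_manifest, normalize_patch, read_image, read_mask
from .registry import DEFAULT_REGISTRY, FeatureRegistry
from .signature import (
    CohortTable,
    RadiomicsSignature,
    build_signature,
    drop_degenerate_features,
    fit_lasso_cv,
    standardize,
)
from .synthetic import SyntheticConfig, SyntheticPatient, generate_cohort

log = logging.getLogger("usradiomics")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_synthetic_study",
           "extract_cohort_features", "patients_to_features"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; serialized into the run directory."""

    manifest: str = ""
    out_dir: str = "run"
    levels: int = 32
    clip: tuple[float, float] | None = (1.0, 99.0)
    distance: int = 1
    wavelet: str = "haar"
    n_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    cv_metric: str = "auc"
    cd_tol: float = 1e-7
    cd_max_irls: int = 50
    seed: int = 0


@dataclass
class PipelineResult:
    signature: RadiomicsSignature
    rad_scores: pd.DataFrame       # patient_id, score, label, cohort
    roc: dict[str, st.RocResult]   # cohort tag -> RocResult
    n_features_extracted: int
    n_features_kept: int
    n_selected: int
    lambda_min: float


def _extract_one(image, mask, registry, cfg: PipelineConfig, patient_id: str):
    patch = normalize_patch(extract_roi(image, mask))
    return extract_all_features(
        patch, registry, patient_id=patient_id, levels=cfg.levels,
        clip=cfg.clip, distance=cfg.distance, wavelet=cfg.wavelet,
    )


def extract_cohort_features(
    manifest: pd.DataFrame, cfg: PipelineConfig, registry: FeatureRegistry = DEFAULT_REGISTRY
) -> pd.DataFrame:
    """Feature table (patients x registry) from a manifest of image files."""
    rows = {}
    for rec in manifest.itertuples():
        for col in ("image", "mask"):
            p = Path(getattr(rec, col))
            if not p.exists():
                raise FileNotFoundError(
                    f"patient {rec.patient_id}: missing {col} file {p}"
                )
        fv = _extract_one(read_image(rec.image), read_mask(rec.mask), registry, cfg,
                          str(rec.patient_id))
        rows[rec.patient_id] = fv.values
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(registry.names))


def patients_to_features(
    patients: list[SyntheticPatient], cfg: PipelineConfig,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """Feature table straight from in-memory synthetic patients."""
    rows = {
        p.patient_id: _extract_one(p.image, p.mask, registry, cfg, p.patient_id).values
        for p in patients
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(registry.names))


def _analyze(
    train: CohortTable, valid: CohortTable | None, cfg: PipelineConfig
) -> PipelineResult:
    """Shared modelling/evaluation tail of both pipeline entry points."""
    n_extracted = train.features.shape[1]
    reduced, report = drop_degenerate_features(train)
    if valid is not None:
        valid = valid.with_features(valid.features[reduced.features.columns])
    z_train, z_valid, constants = standardize(reduced, valid)
    path = fit_lasso_cv(
        z_train, n_folds=cfg.n_folds, seed=cfg.seed, n_lambda=cfg.n_lambda,
        lambda_min_ratio=cfg.lambda_min_ratio, metric=cfg.cv_metric,
        tol=cfg.cd_tol, max_irls=cfg.cd_max_irls,
    )
    sig = build_signature(path, constants)
    if not sig.coefficients:
        log.warning("all coefficients shrunk to zero; intercept-only signature")

    frames = []
    roc = {}
    for cohort in (reduced, valid):
        if cohort is None:
            continue
        scores = sig.score_frame(cohort.features)
        frames.append(pd.DataFrame({
            "patient_id": cohort.features.index,
            "score": scores.to_numpy(),
            "label": cohort.labels.to_numpy(),
            "cohort": cohort.tag,
        }))
        if cohort.labels.nunique() == 2:
            # an intercept-only signature gives constant scores -> AUC 0.5
            roc[cohort.tag] = st.roc_auc(scores.to_numpy(), cohort.labels.to_numpy(),
                                         cohort=cohort.tag)
    return PipelineResult(
        signature=sig,
        rad_scores=pd.concat(frames, ignore_index=True),
        roc=roc,
        n_features_extracted=n_extracted,
        n_features_kept=reduced.features.shape[1],
        n_selected=len(sig.coefficients),
        lambda_min=path.lambda_min,
    )


def _cohort_from_manifest(manifest: pd.DataFrame, features: pd.DataFrame, tag: str) -> CohortTable:
    sub = manifest[manifest["cohort"] == tag].set_index("patient_id")
    cov_cols = [c for c in ("age", "sex", "tumor_size_mm", "central_lnm") if c in sub.columns]
    return CohortTable(
        features=features.loc[sub.index],
        labels=sub["label"].astype(int),
        covariates=sub[cov_cols] if cov_cols else None,
        tag=tag,
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full study replica from a manifest file, writing artifacts.

    The manifest must define `training` and `validation` cohorts with
    binary labels.  Deterministic given (config, seed): the run
    directory receives features.csv, removed_features.csv,
    signature.json, rad_scores.csv, roc_<cohort>.csv, summary tables
    and a JSON log of the key run facts.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(cfg.manifest)
    registry = DEFAULT_REGISTRY

    features = extract_cohort_features(manifest, cfg, registry)
    features.rename_axis("patient_id").to_csv(out / "features.csv")
    (out / "features_config.json").write_text(json.dumps({
        "levels": cfg.levels, "clip": cfg.clip, "distance": cfg.distance,
        "wavelet": cfg.wavelet, "registry_hash": registry.hash(),
    }, indent=2))

    tags = set(manifest["cohort"])
    if "training" not in tags:
        raise ValueError("manifest must contain a training cohort")
    train = _cohort_from_manifest(manifest, features, "training")
    valid = _cohort_from_manifest(manifest, features, "validation") if "validation" in tags else None

    result = _analyze(train, valid, cfg)

    _, report = drop_degenerate_features(train)
    report.to_csv(out / "removed_features.csv", index=False)
    result.signature.to_json(out / "signature.json")
    result.rad_scores.to_csv(out / "rad_scores.csv", index=False)
    roc_summary = {}
    for tag, r in result.roc.items():
        st.roc_curve_points(r.scores, r.labels).to_csv(out / f"roc_{tag}.csv", index=False)
        roc_summary[tag] = {"auc": r.auc, "ci": [r.ci_lower, r.ci_upper]}

    # Table-1/2 style cohort summaries when covariates are present
    cov_cols = {"age", "sex", "tumor_size_mm", "central_lnm"}
    if cov_cols <= set(manifest.columns):
        comp = st.cohort_summary(manifest, "cohort")
        st.summary_to_frame(comp).to_csv(out / "table_cohorts.csv", index=False)
        for tag in sorted(tags):
            sub = manifest[manifest["cohort"] == tag].copy()
            scores = result.rad_scores.set_index("patient_id")["score"]
            sub["rad_score"] = sub["patient_id"].map(scores)
            comp = st.cohort_summary(sub, "label",
                                     continuous=("age", "tumor_size_mm", "rad_score"),
                                     categorical=("sex", "central_lnm"))
            st.summary_to_frame(comp).to_csv(out / f"table_by_label_{tag}.csv", index=False)

    (out / "run_log.json").write_text(json.dumps({
        "config": dataclasses.asdict(cfg),
        "registry_hash": registry.hash(),
        "n_patients": int(len(manifest)),
        "n_features_extracted": result.n_features_extracted,
        "n_features_kept": result.n_features_kept,
        "lambda_min": result.lambda_min,
        "n_selected": result.n_selected,
        "auc": roc_summary,
        "elapsed_s": round(time.time() - t0, 2),
    }, indent=2))
    return result


def run_synthetic_study(
    seed: int = 0,
    n_train: int = 400,
    n_valid: int = 368,
    delta: float = 2.0,
    image_size: tuple[int, int] = (128, 128),
    cfg: PipelineConfig | None = None,
    couple_central_lnm: bool = False,
) -> tuple[PipelineResult, pd.DataFrame]:
    """Generate train/validation speckle cohorts and run the analysis.

    Cohort prevalences follow the study design (0.21 training, 0.27
    validation).  Returns the pipeline result and the combined manifest
    (with covariates) for table reproduction.  All randomness derives
    from ``seed``.
    """
    cfg = cfg or PipelineConfig(seed=seed)
    ss = np.random.SeedSequence(seed)
    s_train, s_valid = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    train_cfg = SyntheticConfig(n_patients=n_train, prevalence=0.21, delta=delta,
                                image_size=image_size, seed=s_train, tag="training",
                                couple_central_lnm=couple_central_lnm)
    valid_cfg = SyntheticConfig(n_patients=n_valid, prevalence=0.27, delta=delta,
                                image_size=image_size, seed=s_valid, tag="validation",
                                couple_central_lnm=couple_central_lnm)
    pat_t, man_t = generate_cohort(train_cfg)
    pat_v, man_v = generate_cohort(valid_cfg)
    feats_t = patients_to_features(pat_t, cfg)
    feats_v = patients_to_features(pat_v, cfg)
    train = CohortTable(feats_t, man_t.set_index("patient_id")["label"].astype(int), tag="training")
    valid = CohortTable(feats_v, man_v.set_index("patient_id")["label"].astype(int), tag="validation")
    result = _analyze(train, valid, cfg)
    manifest = pd.concat([man_t, man_v], ignore_index=True)
    return result, manifest
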