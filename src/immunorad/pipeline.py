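"""End-to-end orchestration: simulate → enrich → phenotype → extract →
select → model → survival, with a reproducible run manifest.

A run is fully described by a :class:`RunConfig` plus its seed; every
stage writes its artifact as an open text format (CSV/JSON) and the
manifest records the config hash, seed, and per-stage counts so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment, modeling, phenotype, selection, survival
from .expression import SUBSETS
from .radiomics import ExtractionConfig, extract_all, normalize_intensity
from .synthetic import SimulationConfig, SyntheticCohort, simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of a full training/inference run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    modalities: tuple = ("T1C",)
    n_permutations: int = 200
    weight_exponent: float = 1.0
    n_bins: int = 32
    wavelet: str = "haar"
    bands_enabled: bool = True
    stage1_threshold: float = 0.90
    stage2_min_abs: float = 0.2
    stage2_strategy: str = "per_set_median"
    cluster_method: str = "ward"
    prob_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.modalities:
            if m not in ("T1C", "ADC"):
                raise ValueError(f"unknown modality {m!r}")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")

    def extraction_config(self) -> ExtractionConfig:
        return ExtractionConfig(n_bins=self.n_bins, wavelet=self.wavelet,
                                bands_enabled=self.bands_enabled)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


@dataclass
class TrainingResult:
    config: RunConfig
    nes: pd.DataFrame
    levels: pd.DataFrame
    igs: pd.DataFrame
    labels: pd.DataFrame
    features: dict[str, pd.DataFrame]            # per modality
    filter_reports: dict[str, selection.FeatureFilterReport]
    models: dict[str, dict[str, modeling.SubsetModel]]   # modality -> subset
    loocv: dict[str, dict[str, modeling.LoocvResult]]
    survival_tests: dict
    km_curves: pd.DataFrame
    manifest: dict


@dataclass
class InferenceResult:
    labels: pd.DataFrame
    group_counts: dict[str, int]
    survival_tests: dict
    km_curves: pd.DataFrame
    n_skipped: int


def extract_cohort_features(cohort: SyntheticCohort, modality: str,
                            config: ExtractionConfig) -> pd.DataFrame:
    """Normalized per-sample feature table for one modality.

    Intensities are standardized against the non-ROI background (the
    image's normal-appearing surround), so the ROI's level and spread
    relative to its surround are preserved independently of ROI size;
    features are then computed within the ROI mask.
    """
    rows = {}
    full = None
    for sid, (vol, mask) in cohort.images[modality].items():
        if full is None or full.shape != vol.voxels.shape:
            full = np.ones_like(vol.voxels, dtype=bool)
        norm = normalize_intensity(vol, full)
        rows[sid] = extract_all(norm, mask, config).features
    return pd.DataFrame.from_dict(rows, orient="index")


def run_training(config: RunConfig,
                 cohort: SyntheticCohort | None = None,
                 out_dir=None) -> TrainingResult:
    """Train the full pipeline on a (simulated or provided) cohort."""
    if cohort is None:
        cohort = simulate_cohort(config.simulation)
    log.info("cohort: %d samples", len(cohort.truths))

    nes = enrichment.profile_cohort(
        cohort.expr_rnaseq, cohort.catalog,
        n_permutations=config.n_permutations, seed=config.seed,
        weight_exponent=config.weight_exponent)
    levels = enrichment.binarize_levels(nes)
    igs = enrichment.immunogram_scores(nes)

    clusters = phenotype.cluster_profiles(nes, k=5, seed=config.seed,
                                          method=config.cluster_method)
    labels = phenotype.labels_to_frame(
        phenotype.label_clusters(clusters, levels))

    ext_cfg = config.extraction_config()
    features: dict[str, pd.DataFrame] = {}
    reports: dict[str, selection.FeatureFilterReport] = {}
    models: dict[str, dict[str, modeling.SubsetModel]] = {}
    loocv_res: dict[str, dict[str, modeling.LoocvResult]] = {}
    for modality in config.modalities:
        if modality not in cohort.images:
            raise ValueError(f"stage extract: modality {modality} absent")
        feats = extract_cohort_features(cohort, modality, ext_cfg)
        features[modality] = feats
        report = selection.run_filter(
            feats, cohort.expr_rnaseq, cohort.expr_array, cohort.catalog,
            levels, seed=config.seed, stage1_threshold=config.stage1_threshold,
            min_abs=config.stage2_min_abs, strategy=config.stage2_strategy)
        reports[modality] = report
        models[modality] = {}
        loocv_res[modality] = {}
        for subset in SUBSETS:
            cols = report.selected_by_subset[subset]
            if not cols:
                log.warning("%s/%s: no features selected; skipping model",
                            modality, subset)
                continue
            x = feats[cols]
            models[modality][subset] = modeling.fit_subset_model(
                x, levels[subset], subset=subset, seed=config.seed)
            loocv_res[modality][subset] = modeling.loocv(
                x, levels[subset], subset=subset, seed=config.seed)

    clinical_wt = survival.idh_filter(cohort.clinical)
    records = survival.records_from_tables(clinical_wt, labels["group"])
    km_curves, tests = survival.group_survival_report(records)

    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_samples": len(cohort.truths),
        "stage_counts": {
            m: [(s, i, o) for s, i, o in reports[m].counts]
            for m in config.modalities
        },
        "n_models": {m: len(models[m]) for m in config.modalities},
        "group_counts": labels["group"].value_counts().sort_index().to_dict(),
    }

    result = TrainingResult(config, nes, levels, igs, labels, features,
                            reports, models, loocv_res, tests, km_curves,
                            manifest)
    if out_dir is not None:
        _write_training(result, cohort, Path(out_dir))
    return result


def predict_cohort(models: dict[str, modeling.SubsetModel],
                   features: pd.DataFrame, clinical: pd.DataFrame,
                   threshold: float = 0.5) -> InferenceResult:
    """Predict phenotype groups and compare their survival."""
    labels = modeling.predict_groups(models, features, threshold)
    frame = phenotype.labels_to_frame(labels)
    n_skipped = len(features) - len(frame)
    counts = frame["group"].value_counts().sort_index().to_dict()
    clinical_wt = survival.idh_filter(clinical)
    records = survival.records_from_tables(clinical_wt, frame["group"])
    km_curves, tests = survival.group_survival_report(records)
    return InferenceResult(frame, counts, tests, km_curves, n_skipped)


def run_inference(config: RunConfig,
                  models: dict[str, modeling.SubsetModel],
                  cohort: SyntheticCohort, modality: str = "T1C",
                  out_dir=None) -> InferenceResult:
    feats = extract_cohort_features(cohort, modality,
                                    config.extraction_config())
    result = predict_cohort(models, feats, cohort.clinical,
                            config.prob_threshold)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.labels.to_csv(out / "predicted_labels.csv")
        result.km_curves.to_csv(out / "predicted_km_curves.csv", index=False)
        (out / "predicted_survival_tests.json").write_text(
            json.dumps(result.survival_tests, indent=2, default=float))
    return result


def _write_training(result: TrainingResult, cohort: SyntheticCohort,
                    out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.nes.to_csv(out / "nes.csv", index_label="sample_id")
    enrichment.write_igs_table(result.nes, out / "igs.csv")
    result.labels.to_csv(out / "labels.csv")
    for modality in result.features:
        result.features[modality].to_csv(
            out / f"features_{modality}.csv", index_label="sample_id")
        result.filter_reports[modality].write(
            out / f"filter_ledger_{modality}.csv",
            out / f"filter_summary_{modality}.json")
        modeling.write_models(result.models[modality],
                              out / f"models_{modality}.json")
        loocv_summary = {
            s: {"accuracy": r.accuracy, "auc": r.auc,
                "skipped_folds": r.n_skipped_folds}
            for s, r in result.loocv[modality].items()
        }
        (out / f"loocv_{modality}.json").write_text(
            json.dumps(loocv_summary, indent=2))
    result.km_curves.to_csv(out / "km_curves.csv", index=False)
    (out / "survival_tests.json").write_text(
        json.dumps(result.survival_tests, indent=2, default=float))
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True, default=str))
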