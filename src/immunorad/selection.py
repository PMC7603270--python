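"""Three-stage radiomic feature filter with a full audit ledger.

Stage 1 drops features that are missing or zero in more than a fixed
fraction of patients. Stage 2 keeps features whose association with the
metagene-set genes is consistent across expression platforms (same sign
and a magnitude floor on both RNA-seq and microarray). Stage 3 ranks
the survivors per immune subset by two importance measures — random
forest mean decrease in Gini and entropy-based information gain — and
keeps the top-ranked features above a data-driven cutoff.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .enrichment import HIGH
from .expression import SUBSETS, ExpressionMatrix, MetageneCatalog


@dataclass
class FeatureFilterReport:
    """Per-stage kept/removed ledger plus per-subset selections."""

    stages: list[dict] = field(default_factory=list)
    selected_by_subset: dict[str, list[str]] = field(default_factory=dict)

    def add_stage(self, name: str, kept: list[str],
                  removed: dict[str, str]) -> None:
        self.stages.append({"stage": name, "features_in": len(kept) + len(removed),
                            "features_out": len(kept), "kept": list(kept),
                            "removed": dict(removed)})

    @property
    def counts(self) -> list[tuple[str, int, int]]:
        return [(s["stage"], s["features_in"], s["features_out"])
                for s in self.stages]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            rows.extend({"stage": s["stage"], "feature": f, "kept": True,
                         "reason": "passed"} for f in s["kept"])
            rows.extend({"stage": s["stage"], "feature": f, "kept": False,
                         "reason": r} for f, r in s["removed"].items())
        return pd.DataFrame(rows, columns=["stage", "feature", "kept", "reason"])

    def write(self, csv_path, json_path) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        summary = {
            "stages": [
                {"stage": n, "features_in": i, "features_out": o}
                for n, i, o in self.counts
            ],
            "selected_by_subset": self.selected_by_subset,
        }
        Path(json_path).write_text(json.dumps(summary, indent=2))


def stage1_missing_zero(features: pd.DataFrame,
                        threshold: float = 0.90) -> tuple[list[str], dict[str, str]]:
    """Drop a feature iff its missing-or-zero fraction strictly exceeds
    the threshold (the boundary fraction itself is kept)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if features.empty:
        raise ValueError("empty feature table")
    frac = (features.isna() | (features == 0)).mean(axis=0)
    kept, removed = [], {}
    for name in features.columns:
        if frac[name] > threshold:
            removed[name] = f"missing_or_zero_fraction={frac[name]:.3f}>{threshold}"
        else:
            kept.append(name)
    return kept, removed


def _spearman_matrix(features: pd.DataFrame, expr: pd.DataFrame) -> np.ndarray:
    """Spearman correlations, features x genes, over shared rows."""
    fr = np.apply_along_axis(rankdata, 0, features.to_numpy(float))
    gr = np.apply_along_axis(rankdata, 0, expr.to_numpy(float))
    fr_sd = fr.std(axis=0)
    fr = (fr - fr.mean(axis=0)) / np.where(fr_sd == 0, np.nan, fr_sd)
    gr = (gr - gr.mean(axis=0)) / np.where(gr.std(axis=0) == 0, np.nan,
                                           gr.std(axis=0))
    return fr.T @ gr / fr.shape[0]


def stage2_cross_platform_consistency(
        features: pd.DataFrame, expr_rnaseq: ExpressionMatrix,
        expr_array: ExpressionMatrix, catalog: MetageneCatalog,
        min_abs: float = 0.2,
        strategy: str = "per_set_median") -> tuple[list[str], dict[str, str]]:
    """Keep features whose metagene association replicates across platforms.

    For each feature and catalog gene present on both platforms, the
    feature–gene Spearman correlation is computed per platform over the
    shared samples. Under the default ``per_set_median`` strategy a
    feature survives iff for at least one gene set the per-gene median
    correlation has the same sign on both platforms with magnitude
    >= ``min_abs`` on both. ``per_gene_all`` requires every set gene to
    agree; ``overall`` pools all catalog genes into one median.
    """
    if strategy not in ("per_set_median", "per_gene_all", "overall"):
        raise ValueError(f"unknown strategy {strategy!r}")
    log_rna = expr_rnaseq.log_transform()
    log_arr = expr_array.log_transform()
    shared_rna = [s for s in features.index if s in log_rna.columns]
    shared_arr = [s for s in features.index if s in log_arr.columns]
    if len(shared_rna) < 5 or len(shared_arr) < 5:
        raise ValueError("need at least 5 shared samples with each platform")
    genes = sorted(
        catalog.all_genes() & set(log_rna.index) & set(log_arr.index))
    if not genes:
        raise ValueError("no catalog genes shared across platforms")
    corr_rna = _spearman_matrix(features.loc[shared_rna],
                                log_rna.loc[genes, shared_rna].T)
    corr_arr = _spearman_matrix(features.loc[shared_arr],
                                log_arr.loc[genes, shared_arr].T)
    gene_pos = {g: i for i, g in enumerate(genes)}

    def _consistent(r: np.ndarray, a: np.ndarray) -> bool:
        if strategy == "per_gene_all":
            return bool(np.all(np.sign(r) == np.sign(a))
                        and np.all(np.abs(r) >= min_abs)
                        and np.all(np.abs(a) >= min_abs))
        mr, ma = np.median(r), np.median(a)
        return bool(np.sign(mr) == np.sign(ma) != 0
                    and abs(mr) >= min_abs and abs(ma) >= min_abs)

    kept, removed = [], {}
    for fi, name in enumerate(features.columns):
        ok = False
        if strategy == "overall":
            ok = _consistent(corr_rna[fi], corr_arr[fi])
        else:
            for subset in SUBSETS:
                cols = [gene_pos[g] for g in catalog[subset] if g in gene_pos]
                if cols and _consistent(corr_rna[fi, cols], corr_arr[fi, cols]):
                    ok = True
                    break
        if ok:
            kept.append(name)
        else:
            removed[name] = "cross_platform_inconsistent"
    return kept, removed


def information_gain(values: np.ndarray, labels: np.ndarray,
                     n_bins: int = 10) -> float:
    """IG = H(Y) - H(Y|X), bits, with X in equal-width bins."""
    x = np.asarray(values, float)
    y = np.asarray(labels)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")

    def _entropy(arr) -> float:
        _, counts = np.unique(arr, return_counts=True)
        p = counts / counts.sum()
        return float(-(p * np.log2(p)).sum())

    hy = _entropy(y)
    if np.ptp(x) == 0:
        return 0.0
    bins = np.floor((x - x.min()) / np.ptp(x) * n_bins).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    h_cond = 0.0
    for b in np.unique(bins):
        sel = bins == b
        h_cond += sel.mean() * _entropy(y[sel])
    return max(hy - h_cond, 0.0)


def stage3_importance(features: pd.DataFrame, labels: pd.Series,
                      seed: int = 0, n_trees: int = 500,
                      ig_bins: int = 10) -> tuple[list[str], dict[str, str]]:
    """Per-subset selection by forest Gini importance and information gain.

    A feature survives iff its mean-decrease-in-Gini importance is > 0
    and its information gain is > 0 and >= the cutoff (mean of the
    positive gains; median fallback if the mean admits none). Survivors
    are returned ranked by descending gain.
    """
    y = labels.loc[features.index].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both label classes must be present")
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed)
    forest.fit(features.to_numpy(float), y)
    gini = pd.Series(forest.feature_importances_, index=features.columns)
    gain = pd.Series(
        {c: information_gain(features[c].to_numpy(float), y, n_bins=ig_bins)
         for c in features.columns})
    positive = gain[gain > 0]
    cutoff = positive.mean() if len(positive) else math.inf
    if not len(positive[positive >= cutoff]):
        cutoff = positive.median() if len(positive) else math.inf
    kept, removed = [], {}
    for name in features.columns:
        if gini[name] <= 0:
            removed[name] = "gini_importance<=0"
        elif gain[name] <= 0:
            removed[name] = "information_gain<=0"
        elif gain[name] < cutoff:
            removed[name] = f"information_gain<cutoff({cutoff:.4f})"
        else:
            kept.append(name)
    kept.sort(key=lambda nm: (-gain[nm], nm))
    return kept, removed


def run_filter(features: pd.DataFrame, expr_rnaseq: ExpressionMatrix,
               expr_array: ExpressionMatrix, catalog: MetageneCatalog,
               levels: pd.DataFrame, seed: int = 0,
               stage1_threshold: float = 0.90, min_abs: float = 0.2,
               strategy: str = "per_set_median") -> FeatureFilterReport:
    """Full three-stage cascade; per-subset stage-3 selections."""
    report = FeatureFilterReport()
    kept1, removed1 = stage1_missing_zero(features, stage1_threshold)
    report.add_stage("stage1_missing_zero", kept1, removed1)
    kept2, removed2 = stage2_cross_platform_consistency(
        features[kept1], expr_rnaseq, expr_array, catalog,
        min_abs=min_abs, strategy=strategy)
    report.add_stage("stage2_cross_platform", kept2, removed2)
    for subset in SUBSETS:
        y = (levels[subset] == HIGH).astype(int)
        kept3, removed3 = stage3_importance(
            features.loc[levels.index, kept2], y, seed=seed)
        report.add_stage(f"stage3_{subset}", kept3, removed3)
        report.selected_by_subset[subset] = kept3
    return report
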