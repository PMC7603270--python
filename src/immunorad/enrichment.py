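"""Per-sample gene-set enrichment: running-sum ES, permutation NES,
high/low levels and immunogram scores.

Enrichment of an immune subset in one sample is scored with the
weighted Kolmogorov–Smirnov-like running-sum statistic over genes
ranked by expression within that sample. The score is normalized to an
NES against a null of size-matched random gene sets drawn from the same
ranking (scoring is per sample, so gene-set — not phenotype —
permutation is the natural null). Cohort-level NES are binarized to
low/high by a per-subset median split and rescaled to immunogram scores
on [0, 5] for radar-chart style display.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import SUBSETS, ExpressionMatrix, MetageneCatalog

log = logging.getLogger(__name__)

LOW, HIGH = "low", "high"


@dataclass
class EnrichmentProfile:
    """Per-sample enrichment of the four immune subsets."""

    sample_id: str
    nes: dict[str, float]
    level: dict[str, str]
    igs: dict[str, float]

    def __post_init__(self) -> None:
        for subset in SUBSETS:
            if subset not in self.level:
                raise ValueError(f"level missing for subset {subset}")
        for v in self.igs.values():
            if not (0.0 <= v <= 5.0):
                raise ValueError("IGS must lie in [0, 5]")


def _rank_sample(values: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Descending expression order; ties broken by gene id for determinism."""
    order = np.lexsort((values.index.to_numpy(), -values.to_numpy()))
    return values.index.to_numpy()[order], values.to_numpy()[order]


def enrichment_score(ranked_genes: np.ndarray, ranked_values: np.ndarray,
                     gene_set, weight_exponent: float = 1.0) -> float:
    """Signed maximum deviation of the running-sum statistic.

    P_hit accumulates |value|^weight over set members (normalized by the
    members' total weight); P_miss accumulates 1/(N - N_hit) over
    non-members; ES is the running difference at its maximum magnitude.
    """
    genes = np.asarray(ranked_genes)
    if len(genes) != len(set(genes)):
        raise ValueError("duplicate genes in ranking")
    hit = np.isin(genes, list(gene_set))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranking")
    if n_hit == len(genes):
        # Degenerate all-genes set: the statistic climbs to +1 at the end.
        return 1.0
    return float(_es_from_hits(hit[None, :], np.asarray(ranked_values, float),
                               weight_exponent)[0])


def _es_from_hits(hits: np.ndarray, values: np.ndarray,
                  weight_exponent: float) -> np.ndarray:
    """Vectorized ES for a stack of hit-indicator rows over one ranking."""
    n = values.shape[0]
    w = np.abs(values) ** weight_exponent
    hw = hits * w  # (m, n)
    denom = hw.sum(axis=1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("zero total hit weight (all-constant expression?)")
    p_hit = np.cumsum(hw / denom, axis=1)
    n_miss = n - hits.sum(axis=1, keepdims=True)
    p_miss = np.cumsum((~hits) / n_miss, axis=1)
    dev = p_hit - p_miss
    idx = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(dev.shape[0]), idx]


def nes(es: float, ranked_genes: np.ndarray, ranked_values: np.ndarray,
        gene_set_size: int, n_permutations: int = 1000,
        seed: int | np.random.Generator = 0,
        weight_exponent: float = 1.0) -> float:
    """ES scaled by the mean |ES| of size-matched random gene sets."""
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    values = np.asarray(ranked_values, float)
    if np.ptp(values) == 0:
        raise ValueError("constant expression vector: NES undefined")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = len(values)
    hits = np.zeros((n_permutations, n), dtype=bool)
    for i in range(n_permutations):
        hits[i, rng.choice(n, size=gene_set_size, replace=False)] = True
    null = np.abs(_es_from_hits(hits, values, weight_exponent))
    mean_null = null.mean()
    if mean_null == 0:
        raise ValueError("degenerate permutation null")
    return float(es / mean_null)


def profile_cohort(matrix: ExpressionMatrix, catalog: MetageneCatalog,
                   n_permutations: int = 1000, seed: int = 0,
                   weight_exponent: float = 1.0) -> pd.DataFrame:
    """NES for every (sample, subset); one seeded RNG stream per cohort.

    Returns a samples x subsets DataFrame of NES values. Catalog genes
    absent from the platform are dropped (modified gene sets).
    """
    catalog = catalog.restrict_to(matrix.gene_ids)
    expr = matrix.log_transform()
    rng = np.random.default_rng(seed)
    rows = {}
    for sample in expr.columns:
        genes, values = _rank_sample(expr[sample])
        rows[sample] = {
            subset: nes(
                enrichment_score(genes, values, catalog[subset], weight_exponent),
                genes, values, len(catalog[subset]),
                n_permutations=n_permutations, seed=rng,
                weight_exponent=weight_exponent,
            )
            for subset in SUBSETS
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(SUBSETS)]


def binarize_levels(nes_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subset cohort-median split; strictly above median -> high."""
    if len(nes_table) < 2:
        raise ValueError("need a cohort of at least 2 samples")
    medians = nes_table.median(axis=0)
    return nes_table.gt(medians, axis=1).map(lambda b: HIGH if b else LOW)


def immunogram_scores(nes_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subset min–max rescaling of NES to immunogram scores in [0, 5]."""
    if len(nes_table) < 2:
        raise ValueError("need a cohort of at least 2 samples")
    lo, hi = nes_table.min(axis=0), nes_table.max(axis=0)
    span = hi - lo
    out = pd.DataFrame(index=nes_table.index, columns=nes_table.columns,
                       dtype=float)
    for subset in nes_table.columns:
        if span[subset] == 0:
            warnings.warn(f"zero NES range for {subset}; IGS set to 2.5")
            out[subset] = 2.5
        else:
            out[subset] = 5.0 * (nes_table[subset] - lo[subset]) / span[subset]
    return out


def profiles_from_tables(nes_table: pd.DataFrame) -> list[EnrichmentProfile]:
    levels = binarize_levels(nes_table)
    igs = immunogram_scores(nes_table)
    return [
        EnrichmentProfile(
            sample_id=str(s),
            nes=nes_table.loc[s].to_dict(),
            level=levels.loc[s].to_dict(),
            igs=igs.loc[s].to_dict(),
        )
        for s in nes_table.index
    ]


def write_igs_table(nes_table: pd.DataFrame, path) -> pd.DataFrame:
    """Radar-chart export: one row per sample, IGS + level per subset."""
    igs = immunogram_scores(nes_table)
    levels = binarize_levels(nes_table)
    out = pd.DataFrame(index=nes_table.index)
    for subset in SUBSETS:
        out[f"{subset.lower()}_igs"] = igs[subset]
    for subset in SUBSETS:
        out[f"{subset.lower()}_level"] = levels[subset]
    out.to_csv(path, index_label="sample_id")
    return out
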