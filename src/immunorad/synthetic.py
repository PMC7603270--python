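"""Fully synthetic cohorts with known immune ground truth.

The generator emulates the study's data situation end to end: paired
two-platform gene expression (RNA-seq FPKM + microarray intensities)
with planted metagene-set enrichment, co-registered ROI-masked MR-like
volumes whose texture statistics depend on the latent immune states,
and a clinical table with group-dependent exponential survival.

Each sample is assigned one of the five immunophenotype groups G1–G5
(default proportions follow the study cohort) and the group fixes a
canonical low/high state quadruple over (CTL, aDC, Treg, MDSC) that is
consistent with the labelling rule table:

* G1: all low            * G5: all high
* G2: CTL low,  aDC/Treg/MDSC high
* G3: CTL high, aDC/Treg/MDSC low
* G4: CTL high, Treg high, aDC/MDSC low

Image knobs (one per subset, all monotone in the planted state):
CTL raises the ROI mean intensity; MDSC coarsens the run-coherent
block field so run-length features respond; aDC raises the block-field
amplitude (ROI contrast); Treg adds an exponential bright tail (ROI
skewness). The first two mirror the feature directions the source
analysis reports; the last two make all four subset models learnable
without claiming biological realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .enrichment import HIGH, LOW
from .expression import (MICROARRAY, RNASEQ, SUBSETS, ExpressionMatrix,
                         MetageneCatalog, write_expression_tsv, write_gmt)
from .phenotype import GROUPS, map_levels_to_group
from .radiomics import ImageVolume

#: Canonical planted state quadruple (CTL, aDC, Treg, MDSC) per group.
GROUP_STATES: dict[str, tuple[str, str, str, str]] = {
    "G1": (LOW, LOW, LOW, LOW),
    "G2": (LOW, HIGH, HIGH, HIGH),
    "G3": (HIGH, LOW, LOW, LOW),
    "G4": (HIGH, LOW, HIGH, LOW),
    "G5": (HIGH, HIGH, HIGH, HIGH),
}

#: Study-cohort group proportions (unsupervised clustering, n = 154).
DEFAULT_PROPORTIONS = (0.377, 0.162, 0.065, 0.130, 0.266)

#: Reported median overall survival per group, in days (G1..G5).
DEFAULT_MEDIANS = (408.0, 266.0, 867.0, 330.0, 357.0)

#: Metagene-set sizes for CTL, aDC, Treg, MDSC.
DEFAULT_SET_SIZES = (5, 51, 26, 58)


@dataclass
class SimulationConfig:
    n_samples: int = 100
    group_proportions: tuple = DEFAULT_PROPORTIONS
    effect_size: float = 2.0
    image_shape: tuple = (24, 24, 12)
    voxel_spacing: tuple = (0.75, 0.75, 3.0)
    platform_noise_sd: float = 0.3
    median_survival_by_group: tuple = DEFAULT_MEDIANS
    seed: int = 0
    # secondary knobs
    set_sizes: tuple = DEFAULT_SET_SIZES
    n_background_genes: int = 200
    biological_sd: float = 0.5
    censor_rate: float = 0.2
    idh_mutant_fraction: float = 0.0
    modalities: tuple = ("T1C", "ADC")

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be at least 10 (LOOCV undefined below)")
        props = np.asarray(self.group_proportions, float)
        if props.shape != (5,) or (props < 0).any():
            raise ValueError("group_proportions must be 5 non-negative reals")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if len(self.image_shape) != 3 or any(s < 8 for s in self.image_shape):
            raise ValueError("image_shape entries must all be >= 8")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if self.platform_noise_sd < 0:
            raise ValueError("platform_noise_sd must be non-negative")
        if any(m <= 0 for m in self.median_survival_by_group):
            raise ValueError("median survivals must be positive")
        if any(s < 1 for s in self.set_sizes):
            raise ValueError("metagene sets must be non-empty")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")


@dataclass
class CohortTruth:
    sample_id: str
    group: str
    subset_state: dict[str, str]
    survival_days: float
    event: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group}")
        levels = tuple(self.subset_state[s] for s in SUBSETS)
        mapped, _ = map_levels_to_group(levels)
        if mapped != self.group:
            raise ValueError(
                f"{self.sample_id}: states {levels} map to {mapped}, not {self.group}"
            )
        if self.survival_days <= 0:
            raise ValueError("survival_days must be positive")


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    truths: list[CohortTruth]
    catalog: MetageneCatalog
    expr_rnaseq: ExpressionMatrix
    expr_array: ExpressionMatrix
    images: dict[str, dict[str, tuple[ImageVolume, np.ndarray]]]
    clinical: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return [t.sample_id for t in self.truths]

    def truth_levels(self) -> pd.DataFrame:
        """Planted state per (sample, subset) as a DataFrame."""
        return pd.DataFrame(
            {s: [t.subset_state[s] for t in self.truths] for s in SUBSETS},
            index=self.sample_ids,
        )

    def truth_groups(self) -> pd.Series:
        return pd.Series([t.group for t in self.truths], index=self.sample_ids,
                         name="group")


def _make_catalog(set_sizes) -> MetageneCatalog:
    return MetageneCatalog({
        name: frozenset(f"{name}_{i:03d}" for i in range(1, size + 1))
        for name, size in zip(SUBSETS, set_sizes)
    })


def _simulate_expression(config: SimulationConfig, catalog: MetageneCatalog,
                         states: pd.DataFrame, sample_ids,
                         rng: np.random.Generator):
    set_genes = [g for s in SUBSETS for g in sorted(catalog[s])]
    bg_genes = [f"BG_{i:04d}" for i in range(1, config.n_background_genes + 1)]
    genes = set_genes + bg_genes
    n_g, n_s = len(genes), len(sample_ids)
    mu = rng.uniform(3.0, 8.0, size=n_g)
    shift = np.zeros((n_g, n_s))
    for subset in SUBSETS:
        members = np.array([g in catalog[subset] for g in genes])
        high = (states[subset] == HIGH).to_numpy()
        shift[np.ix_(members, high)] = config.effect_size
    latent = mu[:, None] + shift + rng.normal(0, config.biological_sd, (n_g, n_s))
    rnaseq = np.exp2(latent + rng.normal(0, config.platform_noise_sd, (n_g, n_s)))
    sample_offset = rng.normal(0, 0.2, n_s)
    array = (latent + sample_offset[None, :]
             + rng.normal(0, config.platform_noise_sd, (n_g, n_s)))
    idx = pd.Index(genes, name="gene_id")
    expr_rnaseq = ExpressionMatrix(
        pd.DataFrame(rnaseq, index=idx, columns=sample_ids), RNASEQ)
    expr_array = ExpressionMatrix(
        pd.DataFrame(array, index=idx, columns=sample_ids), MICROARRAY)
    return expr_rnaseq, expr_array


def _ellipsoid_mask(shape, radii_frac, rng: np.random.Generator) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    center = [(s - 1) / 2 + rng.uniform(-0.5, 0.5) for s in shape]
    radii = [max(2.0, f * s) for f, s in zip(radii_frac, shape)]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d2 <= 1.0


def _block_field(shape, block_xy: int, block_z: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Blockwise-constant Gaussian field: larger blocks = coarser runs."""
    coarse_shape = tuple(
        math.ceil(s / b) for s, b in zip(shape, (block_xy, block_xy, block_z))
    )
    coarse = rng.normal(0.0, 1.0, coarse_shape)
    field_ = coarse.repeat(block_xy, 0).repeat(block_xy, 1).repeat(block_z, 2)
    return field_[: shape[0], : shape[1], : shape[2]]

# Image-model amplitudes (arbitrary units on the T1C scale). Chosen once
# to give a clearly supra-noise texture signal for each subset knob.
_CTL_SHIFT = 0.8
_BLOCK_AMP_LOW, _BLOCK_AMP_HIGH = 0.35, 0.70   # aDC knob
_BLOCK_XY = {LOW: 2, HIGH: 4}                  # MDSC knob
_BLOCK_Z = {LOW: 1, HIGH: 2}
_TREG_TAIL = 0.45                              # exponential-tail amplitude
_FINE_SD = 0.15
_BACKGROUND_MEAN, _BACKGROUND_SD = 0.2, 0.1


def _simulate_volume(config: SimulationConfig, state: dict[str, str],
                     modality: str, rng: np.random.Generator):
    shape = tuple(config.image_shape)
    radii = [rng.uniform(0.30, 0.42) for _ in range(3)]
    mask = _ellipsoid_mask(shape, radii, rng)
    vox = rng.normal(_BACKGROUND_MEAN, _BACKGROUND_SD, shape)
    roi = np.zeros(shape)
    roi += 1.0 + _CTL_SHIFT * (state["CTL"] == HIGH)
    amp = _BLOCK_AMP_HIGH if state["aDC"] == HIGH else _BLOCK_AMP_LOW
    roi += amp * _block_field(shape, _BLOCK_XY[state["MDSC"]],
                              _BLOCK_Z[state["MDSC"]], rng)
    if state["Treg"] == HIGH:
        roi += _TREG_TAIL * rng.exponential(1.0, shape)
    roi += rng.normal(0.0, _FINE_SD, shape)
    if modality == "ADC":
        # Same latent structure on a different intensity scale, noisier.
        roi = 2.4 - 0.8 * roi + rng.normal(0.0, 0.1, shape)
        vox = 2.4 - 0.8 * vox + rng.normal(0.0, 0.1, shape)
    vox[mask] = roi[mask]
    return ImageVolume(vox, tuple(config.voxel_spacing), modality), mask


@lru_cache(maxsize=64)
def _uniform_censor_window(median: float, rate: float) -> float:
    """Upper bound b of an independent U(0, b) censoring time such that
    P(C < T) = rate for exponential T with the given median.

    For x = lambda*b the censored fraction is (1 - e^-x)/x, which is
    solved by bisection. Independence of C and T keeps the
    Kaplan-Meier estimator unbiased, unlike censoring at a fraction of
    the subject's own death time.
    """
    lam = math.log(2) / median
    f = lambda x: (1.0 - math.exp(-x)) / x - rate
    return brentq(f, 1e-9, 1e9) / lam


def _simulate_survival(config: SimulationConfig, group: str,
                       rng: np.random.Generator) -> tuple[float, int]:
    median = config.median_survival_by_group[GROUPS.index(group)]
    t = rng.exponential(median / math.log(2))
    if config.censor_rate > 0:
        c = rng.uniform(0.0, _uniform_censor_window(median,
                                                    config.censor_rate))
        if c < t:
            return max(c, 1e-6), 0
    return t, 1


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    groups = [GROUPS[i] for i in
              rng.choice(5, size=n, p=np.asarray(config.group_proportions, float))]
    states = pd.DataFrame(
        [dict(zip(SUBSETS, GROUP_STATES[g])) for g in groups], index=sample_ids
    )
    catalog = _make_catalog(config.set_sizes)
    expr_rnaseq, expr_array = _simulate_expression(
        config, catalog, states, sample_ids, rng)

    images: dict[str, dict[str, tuple[ImageVolume, np.ndarray]]] = {
        m: {} for m in config.modalities
    }
    truths = []
    clin_rows = []
    for sid, group in zip(sample_ids, groups):
        state = states.loc[sid].to_dict()
        for modality in config.modalities:
            images[modality][sid] = _simulate_volume(config, state, modality, rng)
        days, event = _simulate_survival(config, group, rng)
        idh = "mutant" if rng.uniform() < config.idh_mutant_fraction else "wild-type"
        truths.append(CohortTruth(sid, group, state, days, event))
        clin_rows.append({"sample_id": sid, "survival_days": days,
                          "event": event, "idh_status": idh})
    clinical = pd.DataFrame(clin_rows).set_index("sample_id")
    return SyntheticCohort(config, truths, catalog, expr_rnaseq, expr_array,
                           images, clinical)


def write_fixtures(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write GMT, expression TSVs, NIfTI volume/mask pairs, clinical and
    truth CSVs; re-reading reproduces values to float32 precision."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gmt"] = out / "metagenes.gmt"
    write_gmt(cohort.catalog, paths["gmt"])
    paths["expr_rnaseq"] = out / "expression_rnaseq_fpkm.tsv"
    write_expression_tsv(cohort.expr_rnaseq, paths["expr_rnaseq"])
    paths["expr_array"] = out / "expression_microarray.tsv"
    write_expression_tsv(cohort.expr_array, paths["expr_array"])

    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    spacing = cohort.config.voxel_spacing
    affine = np.diag(list(spacing) + [1.0])
    for modality, samples in cohort.images.items():
        for sid, (vol, mask) in samples.items():
            vp = img_dir / f"{sid}_{modality}.nii"
            mp = img_dir / f"{sid}_{modality}_mask.nii"
            nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), vp)
            nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), mp)
    paths["images"] = img_dir

    paths["clinical"] = out / "clinical.csv"
    cohort.clinical.to_csv(paths["clinical"])
    truth = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "group": [t.group for t in cohort.truths],
            **{f"{s.lower()}_state": [t.subset_state[s] for t in cohort.truths]
               for s in SUBSETS},
            "survival_days": [t.survival_days for t in cohort.truths],
            "event": [t.event for t in cohort.truths],
        }
    ).set_index("sample_id")
    paths["truth"] = out / "truth.csv"
    truth.to_csv(paths["truth"])
    return paths


def read_volume(path, modality: str) -> tuple[ImageVolume, np.ndarray]:
    """Load a NIfTI volume and return it with its voxel spacing."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asarray(img.dataobj, float), spacing, modality), spacing
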