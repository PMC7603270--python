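"""Expression-matrix handling and the immune metagene catalog.

Two platforms are supported: RNA-seq expression in FPKM units and
two-colour microarray intensities. RNA-seq quantification upstream of
FPKM (read alignment, transcript assembly) is out of scope — fragment
counts plus library/transcript metadata go straight into :func:`fpkm`.
Microarray matrices are normalized against a per-gene cohort median
reference with a LOWESS fit of the intensity-dependent bias.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

log = logging.getLogger(__name__)

#: The four immune subsets whose intratumoral enrichment is modelled,
#: in canonical order: cytotoxic T lymphocytes, activated dendritic
#: cells, regulatory T cells, myeloid-derived suppressor cells.
SUBSETS = ("CTL", "aDC", "Treg", "MDSC")

RNASEQ = "rnaseq_fpkm"
MICROARRAY = "microarray"
PLATFORMS = (RNASEQ, MICROARRAY)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values for one platform.

    ``values`` is a DataFrame indexed by gene id with sample ids as
    columns. FPKM matrices must be non-negative.
    """

    values: pd.DataFrame
    platform: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.platform == RNASEQ and (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def log_transform(self) -> pd.DataFrame:
        """log2(x+1) for FPKM; microarray intensities pass through."""
        if self.platform == RNASEQ:
            return np.log2(self.values + 1.0)
        return self.values


@dataclass
class MetageneCatalog:
    """The four named metagene sets (CTL, aDC, Treg, MDSC)."""

    sets: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in SUBSETS if s not in self.sets]
        if missing:
            raise ValueError(f"missing metagene set(s): {', '.join(missing)}")
        extra = set(self.sets) - set(SUBSETS)
        if extra:
            raise ValueError(f"unknown metagene set(s): {sorted(extra)}")
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"metagene set {name} is empty")
        self.sets = {k: frozenset(self.sets[k]) for k in SUBSETS}

    def __getitem__(self, subset: str) -> frozenset[str]:
        return self.sets[subset]

    def all_genes(self) -> frozenset[str]:
        return frozenset().union(*self.sets.values())

    def restrict_to(self, gene_ids) -> "MetageneCatalog":
        """Drop catalog genes absent from a platform, with a warning.

        Mirrors the modified-gene-set situation where microarray probe
        sets do not cover every catalog gene.
        """
        avail = set(gene_ids)
        out = {}
        for name, genes in self.sets.items():
            kept = genes & avail
            if len(kept) < len(genes):
                log.warning(
                    "metagene set %s: %d of %d genes absent from platform; "
                    "using modified gene set",
                    name, len(genes) - len(kept), len(genes),
                )
            if not kept:
                raise ValueError(f"metagene set {name} has no genes on this platform")
            out[name] = kept
        return MetageneCatalog(out)


def fpkm(total_fragments: float, mapped_reads_millions: float,
         exon_length_kb: float) -> float:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM = total_fragments / (mapped reads [millions] x exon length [kb]).
    """
    if total_fragments < 0:
        raise ValueError("total_fragments must be non-negative")
    if mapped_reads_millions <= 0 or exon_length_kb <= 0:
        raise ValueError("mapped reads and exon length must be positive")
    return total_fragments / (mapped_reads_millions * exon_length_kb)


def normalize_array(matrix: ExpressionMatrix, frac: float = 0.3,
                    it: int = 3) -> ExpressionMatrix:
    """LOWESS normalization of a microarray matrix.

    For each sample, the deviation from a per-gene cohort-median
    reference is smoothed against mean intensity A = (sample + ref)/2
    and the fitted intensity-dependent bias is subtracted (one pass per
    sample, the usual MA-style correction). When a sample's deviation
    is pure intensity-dependent bias the correction removes it exactly,
    and a second application is then a no-op; on data whose deviations
    are not smooth in A the operation is only approximately idempotent,
    since the median reference moves with the correction.
    """
    if matrix.platform != MICROARRAY:
        raise ValueError("normalize_array requires a microarray matrix")
    vals = matrix.values
    if vals.shape[0] < 10:
        raise ValueError("need at least 10 genes for a LOWESS fit")
    ref = vals.median(axis=1).to_numpy()
    out = vals.copy()
    for sample in vals.columns:
        y = vals[sample].to_numpy(dtype=float)
        m = y - ref
        a = 0.5 * (y + ref)
        if np.ptp(a) == 0:
            out[sample] = y - m.mean()
            continue
        fit = lowess(m, a, frac=frac, it=it, return_sorted=False)
        out[sample] = y - fit
    return ExpressionMatrix(out, MICROARRAY)


def read_gmt(path) -> MetageneCatalog:
    """Parse a GMT file into the four-set metagene catalog."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: malformed GMT line")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set {name}")
        if not genes:
            raise ValueError(f"{path}:{lineno}: empty gene set {name}")
        if len(genes) != len(set(genes)):
            raise ValueError(f"{path}:{lineno}: duplicate gene ids in {name}")
        sets[name] = set(genes)
    return MetageneCatalog(sets)


def write_gmt(catalog: MetageneCatalog, path) -> None:
    lines = []
    for name in SUBSETS:
        genes = sorted(catalog[name])
        lines.append("\t".join([name, f"{name} metagene set"] + genes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_tsv(path, platform: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header row samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, platform)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
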