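"""Immunophenotype groups G1–G5: clustering, labelling and the
level-quadruple rule table.

Five groups are defined from the four binary enrichment levels
(CTL, aDC, Treg, MDSC):

* G1 — immune-cold: all four subsets lowly enriched;
* G2 — CTL low and MDSC high (worst prognosis);
* G3 — CTL high with Treg and MDSC low (best prognosis);
* G4 — residual mixed patterns;
* G5 — immune-hot: all four subsets highly enriched.

The rule table is applied in priority order (G1, G5, G3, G2, G4) and is
total over all 16 level combinations; G4 absorbs the fall-through
cases. Cohorts are first clustered on their 4-dimensional NES vectors
(Ward-linkage hierarchical clustering, K = 5) and each cluster is
labelled by its majority level pattern through the same rule table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .enrichment import HIGH, LOW
from .expression import SUBSETS

GROUPS = ("G1", "G2", "G3", "G4", "G5")

CLUSTERED = "clustered"
RULE_MAPPED = "rule_mapped"


@dataclass
class ImmunophenotypeLabel:
    sample_id: str
    group: str
    source: str
    rule_fired: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.source == RULE_MAPPED and not self.rule_fired:
            raise ValueError("rule_mapped labels must record the rule fired")


def map_levels_to_group(levels) -> tuple[str, str]:
    """Map a (CTL, aDC, Treg, MDSC) level quadruple to a group.

    Returns ``(group, rule_fired)``. Priority order makes the mapping a
    total function over the 16 combinations.
    """
    ctl, adc, treg, mdsc = levels
    for lv in (ctl, adc, treg, mdsc):
        if lv not in (LOW, HIGH):
            raise ValueError(f"undefined level {lv!r}")
    if all(lv == LOW for lv in (ctl, adc, treg, mdsc)):
        return "G1", "all_low"
    if all(lv == HIGH for lv in (ctl, adc, treg, mdsc)):
        return "G5", "all_high"
    if ctl == HIGH and treg == LOW and mdsc == LOW:
        return "G3", "ctl_high_treg_low_mdsc_low"
    if ctl == LOW and mdsc == HIGH:
        return "G2", "ctl_low_mdsc_high"
    return "G4", "residual"


def cluster_profiles(nes_table: pd.DataFrame, k: int = 5,
                     seed: int = 0, method: str = "ward") -> pd.Series:
    """Cluster samples on their 4-dim NES vectors into k clusters.

    Default is hierarchical agglomerative clustering with Ward linkage
    on Euclidean distances (deterministic); ``method="kmeans"`` uses a
    seeded k-means alternative.
    """
    x = nes_table.to_numpy(dtype=float)
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds cohort size {n}")
    if method == "ward":
        labels = fcluster(linkage(pdist(x), method="ward"), t=k,
                          criterion="maxclust")
    elif method == "kmeans":
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(x) + 1
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return pd.Series(labels, index=nes_table.index, name="cluster")


def _majority_pattern(levels: pd.DataFrame) -> tuple[str, ...]:
    """Majority level per subset within a cluster; ties resolve to low."""
    return tuple(
        HIGH if (levels[s] == HIGH).mean() > 0.5 else LOW for s in SUBSETS
    )


def label_clusters(clusters: pd.Series,
                   levels: pd.DataFrame) -> list[ImmunophenotypeLabel]:
    """Label every sample by its cluster's majority level pattern."""
    levels = levels.loc[clusters.index]
    out = []
    for cid in sorted(clusters.unique()):
        members = clusters.index[clusters == cid]
        group, rule = map_levels_to_group(_majority_pattern(levels.loc[members]))
        out.extend(
            ImmunophenotypeLabel(str(s), group, CLUSTERED, rule)
            for s in members
        )
    order = {s: i for i, s in enumerate(clusters.index)}
    out.sort(key=lambda lab: order[lab.sample_id])
    return out


def labels_to_frame(labels: list[ImmunophenotypeLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [l.sample_id for l in labels],
            "group": [l.group for l in labels],
            "source": [l.source for l in labels],
            "rule_fired": [l.rule_fired for l in labels],
        }
    ).set_index("sample_id")
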