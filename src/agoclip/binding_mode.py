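"""Per-miRNA binding-position frequency profiles and their clustering.

For each miRNA, the fraction of its heteroduplexes pairing each miRNA
position is summarized as a row of a miRNA x position matrix (row-max
normalized to [0, 1]) and clustered with agglomerative hierarchical
clustering (complete linkage, Euclidean distance) or seeded k-means.
Profiles require pairing masks, so only engine-computed duplexes enter;
imported predictor sites carry no structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from agoclip.duplex import Heteroduplex, MiRNA

logger = logging.getLogger(__name__)


@dataclass
class BindingPositionProfile:
    """miRNA x position matrix of normalized pairing frequencies."""

    mirna_names: list[str]
    matrix: np.ndarray
    n_sites: dict[str, int]

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.mirna_names):
            raise ValueError("matrix shape inconsistent with miRNA names")
        if self.matrix.size and (self.matrix.min() < 0 or self.matrix.max() > 1 + 1e-12):
            raise ValueError("profile entries must lie in [0, 1]")


def position_frequency_matrix(
    duplexes: Sequence[Heteroduplex],
    mirnas: Sequence[MiRNA],
    normalization: str = "row_max",
) -> BindingPositionProfile:
    """Count, per miRNA, how often each position is paired across duplexes.

    Rows are normalized by their maximum positional count (``row_max``,
    displayed range 0-1) or by their total (``row_sum``); miRNAs shorter
    than the longest are zero-padded on the right. miRNAs with no duplexes
    get a zero row (warning).
    """
    if normalization not in ("row_max", "row_sum"):
        raise ValueError("normalization must be 'row_max' or 'row_sum'")
    names = [m.name for m in mirnas]
    max_len = max(len(m.sequence) for m in mirnas)
    counts = np.zeros((len(names), max_len), dtype=float)
    n_sites = {name: 0 for name in names}
    row = {name: i for i, name in enumerate(names)}
    for d in duplexes:
        if d.pairing_mask is None:
            raise ValueError(
                f"duplex for {d.mirna_name} has no pairing mask; profiles "
                "require engine-computed duplexes"
            )
        if d.mirna_name not in row:
            continue
        i = row[d.mirna_name]
        counts[i, : len(d.pairing_mask)] += np.asarray(d.pairing_mask, dtype=float)
        n_sites[d.mirna_name] += 1

    matrix = counts.copy()
    for i, name in enumerate(names):
        if n_sites[name] == 0:
            logger.warning("miRNA %s has no duplexes; zero profile row", name)
            continue
        denom = counts[i].max() if normalization == "row_max" else counts[i].sum()
        if denom > 0:
            matrix[i] = counts[i] / denom
    return BindingPositionProfile(mirna_names=names, matrix=matrix, n_sites=n_sites)


def hierarchical_clusters(
    profile: BindingPositionProfile, n_groups: int
) -> tuple[np.ndarray, np.ndarray]:
    """Complete-linkage Euclidean hierarchical clustering of profile rows.

    Returns (labels, merge tree in scipy linkage format); the tree is cut
    into ``n_groups`` flat clusters.
    """
    n = profile.matrix.shape[0]
    if n < 2:
        raise ValueError("clustering requires >= 2 profiles")
    if n_groups > n:
        raise ValueError(f"n_groups {n_groups} exceeds {n} rows")
    tree = linkage(profile.matrix, method="complete", metric="euclidean")
    labels = fcluster(tree, t=n_groups, criterion="maxclust")
    return labels, tree


def kmeans_clusters(
    profile: BindingPositionProfile, k: int, seed: int, n_init: int = 10
) -> np.ndarray:
    """Seeded k-means (k-means++ init, best of n_init restarts) on rows."""
    n = profile.matrix.shape[0]
    if k > n:
        raise ValueError(f"k {k} exceeds {n} rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    return km.fit_predict(profile.matrix)
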