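"""Population-structure analysis: distances, Ward clustering, PCA, cluster ANOVA.

Subpopulation make-up drives which training-set strategy works: stratified
sampling needs cluster labels, and the fraction of phenotypic variance a
clustering explains indicates how strongly trait alleles follow the
structure.  Distances are Euclidean on marker calls, clustering is Ward's
minimum-variance criterion (the ward.D2 dialect on Euclidean input), and PCA
is the SVD of the centered marker matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .geno_io import MarkerMatrix, PhenotypeTable
from .kinship import CenteredMarkers


@dataclass
class ClusterModel:
    """Hierarchical clustering cut at K clusters."""

    labels: dict[str, int]
    k: int
    linkage: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        got = set(self.labels.values())
        if got != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k} with no empty cluster, got {sorted(got)}")

    def labels_for(self, ids) -> np.ndarray:
        return np.array([self.labels[str(i)] for i in ids], dtype=int)

    @property
    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for lab in self.labels.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes


@dataclass
class PCASummary:
    """Principal component scores of the panel and per-component variance shares."""

    ids: tuple[str, ...]
    scores: np.ndarray
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        ve = np.asarray(self.variance_explained, dtype=float)
        if (np.diff(ve) > 1e-12).any() or ve.sum() > 1.0 + 1e-9:
            raise ValueError("variance fractions must be non-increasing and sum to <= 1")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=list(self.ids), columns=cols)


def _marker_rows(markers) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(markers, CenteredMarkers):
        return markers.W, markers.individual_ids
    if isinstance(markers, MarkerMatrix):
        if np.isnan(markers.calls).any():
            raise ValueError("impute missing calls before distance/PCA computation")
        return markers.calls, markers.individual_ids
    raise TypeError("expected MarkerMatrix or CenteredMarkers")


def euclidean_distance(markers) -> pd.DataFrame:
    """Pairwise Euclidean distances between genotypes on their marker profiles.

    Column centering shifts every row identically, so raw and centered calls
    give the same distances.
    """
    X, ids = _marker_rows(markers)
    D = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(D, index=list(ids), columns=list(ids))


def ward_cluster(D: pd.DataFrame, k: int) -> ClusterModel:
    """Agglomerative Ward clustering of a Euclidean distance matrix, cut to k.

    At each step the merge minimizing the increase in within-cluster variance
    is applied (scipy's 'ward' on the condensed distances, i.e. ward.D2),
    which tends to produce clusters of comparable size.
    """
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"cluster count k={k} must be in [1, {n}]")
    ids = tuple(str(i) for i in D.index)
    condensed = squareform(D.to_numpy(), checks=False)
    Z = sch.linkage(condensed, method="ward")
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters 1..k by first appearance for a deterministic labeling
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for gid, lab in zip(ids, raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[gid] = remap[lab]
    return ClusterModel(labels=labels, k=k, linkage=Z)


def pca(cm: CenteredMarkers, d: int = 2) -> PCASummary:
    """PCA of the centered marker matrix via SVD; scores = U S, shares = s^2 / sum s^2."""
    n, m = cm.W.shape
    if not 1 <= d <= min(n, m):
        raise ValueError(f"component count d={d} must be in [1, {min(n, m)}]")
    W = cm.W - cm.W.mean(axis=0)  # exactly centered even under external frequencies
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    var = s**2
    total = var.sum()
    ve = var / total if total > 0 else np.zeros_like(var)
    return PCASummary(ids=cm.individual_ids, scores=U[:, :d] * s[:d], variance_explained=ve[:d])


def cluster_variance_explained(phenos: PhenotypeTable, model: ClusterModel) -> pd.DataFrame:
    """Per-trait share of phenotypic variance explained by cluster membership.

    One-way decomposition on per-individual trait means: R^2 = SSB / SST with
    K - 1 between-cluster degrees of freedom.  Clusters with no phenotyped
    member are excluded with a warning.
    """
    rows = []
    for trait in phenos.traits:
        means = phenos.line_means(trait)
        unlabeled = [i for i in means.index if i not in model.labels]
        if unlabeled:
            raise ValueError(f"phenotyped id(s) without cluster label: {unlabeled[:5]}")
        labs = model.labels_for(means.index)
        present = sorted(set(labs.tolist()))
        empty = set(range(1, model.k + 1)) - set(present)
        if empty:
            warnings.warn(f"cluster(s) {sorted(empty)} have no phenotyped members for {trait!r}",
                          stacklevel=2)
        y = means.to_numpy()
        grand = y.mean()
        sst = float(((y - grand) ** 2).sum())
        ssb = sum(
            (labs == lab).sum() * (y[labs == lab].mean() - grand) ** 2 for lab in present
        )
        r2 = float(ssb / sst) if sst > 0 else 0.0
        rows.append({"trait": trait, "r2": r2, "df_between": len(present) - 1})
    return pd.DataFrame(rows).set_index("trait")
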