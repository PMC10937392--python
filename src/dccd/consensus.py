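"""Resampling-based consensus clustering with CDF delta-area k selection.

The cohort is repeatedly subsampled (80% of samples by default); each
subsample is clustered for every candidate k; the consensus matrix entry
for a sample pair is the fraction of co-samplings in which the pair
co-clustered.  Final labels cut an average-linkage tree of
(1 - consensus); the number of clusters is suggested by the relative
change in area under the consensus CDF, with k = 4 pinned by the pipeline
configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .matrix import ExpressionMatrix, GeneSetCollection
from .ssgsea import ssgsea

logger = logging.getLogger("dccd")

#: minimum relative delta-area for a k to count as a supported elbow
ELBOW_THRESHOLD = 0.1
#: maximum proportion of ambiguous consensus entries (in (0.1, 0.9)) for a
#: candidate k to count as confidently supported
PAC_THRESHOLD = 0.2

ASSIGNMENT_COLUMNS = ["sample_id", "subtype", "source", "distance", "p_value", "fdr"]


@dataclass
class ConsensusResult:
    consensus_matrices: dict[int, pd.DataFrame]
    labels: dict[int, pd.Series]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    low_confidence: bool = False


def _zscore_log_matrix(expr: ExpressionMatrix, features) -> tuple[np.ndarray, list[str]]:
    sub = expr.subset_features(features).to_log2()
    X = sub.values.to_numpy(float)
    sd = X.std(axis=1)
    keep = sd > 0
    X = X[keep]
    Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    return Xz.T, list(sub.values.columns)  # samples x genes


def _cluster_once(X: np.ndarray, k: int, inner: str, seed: int) -> np.ndarray:
    if inner == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(X)
    if inner == "hclust":
        Z = sch.linkage(X, method="average", metric="euclidean")
        return sch.fcluster(Z, t=k, criterion="maxclust")
    raise ValueError(f"unknown inner clusterer {inner!r}")


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus entries on [0, 1]."""
    n = consensus.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = np.sort(consensus[iu])
    xs = np.concatenate([[0.0], vals, [1.0]])
    # F is a right-continuous step function; integrate piecewise
    area = 0.0
    m = len(vals)
    for i in range(len(xs) - 1):
        f = np.searchsorted(vals, xs[i], side="right") / m
        area += (xs[i + 1] - xs[i]) * f
    return float(area)


def consensus_cluster(expr: ExpressionMatrix, features, k_range=(2, 3, 4, 5, 6),
                      n_resamples: int = 1000, subsample_fraction: float = 0.8,
                      seed: int = 0, inner: str = "kmeans") -> ConsensusResult:
    """Consensus clustering of a bulk cohort on a signature-gene submatrix.

    The inner clusterer runs on z-scored log2(TPM+1) of the signature
    genes.  Resample r uses seed + r so partial reruns are reproducible.
    Pairs never co-sampled get consensus 0 with a warning.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 2:
        raise ValueError("k_range values must be >= 2")
    X, sample_ids = _zscore_log_matrix(expr, features)
    n = X.shape[0]
    if X.shape[1] == 0:
        raise ValueError("no usable signature features in the matrix")
    if n < max(k_range) * 3:
        raise ValueError("need at least 3 x max(k) samples")
    m = max(2, int(round(subsample_fraction * n)))

    consensus_matrices: dict[int, pd.DataFrame] = {}
    labels: dict[int, pd.Series] = {}
    cdf_area: dict[int, float] = {}

    # pre-draw the shared subsamples so every k sees the same resampling plan
    subsamples = []
    for r in range(n_resamples):
        rng = np.random.default_rng(seed + r)
        subsamples.append(rng.choice(n, size=m, replace=False))

    cosampled = np.zeros((n, n))
    for idx in subsamples:
        sel = np.zeros(n)
        sel[idx] = 1.0
        cosampled += np.outer(sel, sel)
    if (cosampled == 0).any():
        logger.warning("consensus_cluster: %d sample pairs never co-sampled; "
                       "their consensus is set to 0",
                       int(((cosampled == 0).sum() - n) // 2))

    for k in k_range:
        coclust = np.zeros((n, n))
        for r, idx in enumerate(subsamples):
            lab = _cluster_once(X[idx], k, inner, seed + r)
            for c in np.unique(lab):
                sel = np.zeros(n)
                sel[idx[lab == c]] = 1.0
                coclust += np.outer(sel, sel)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(cosampled > 0, coclust / np.maximum(cosampled, 1), 0.0)
        C = (C + C.T) / 2.0
        np.fill_diagonal(C, 1.0)
        consensus_matrices[k] = pd.DataFrame(C, index=sample_ids, columns=sample_ids)
        Z = sch.linkage(squareform(1.0 - C, checks=False), method="average")
        labels[k] = pd.Series(sch.fcluster(Z, t=k, criterion="maxclust"),
                              index=sample_ids, name=f"k{k}")
        cdf_area[k] = _cdf_area(C)
        logger.info("consensus_cluster: k=%d area=%.4f", k, cdf_area[k])

    delta_area: dict[int, float] = {}
    ks = list(k_range)
    for i, k in enumerate(ks):
        if i == 0:
            delta_area[k] = cdf_area[k]
        else:
            prev = cdf_area[ks[i - 1]]
            delta_area[k] = (cdf_area[k] - prev) / prev if prev > 0 else 0.0

    # candidate: largest k still adding relative CDF area; confidence is
    # judged by the proportion of ambiguous consensus entries (PAC) at that
    # k — resampling noise also inflates delta areas, but only genuine
    # structure drives the consensus entries toward {0, 1}
    supported = [k for k in ks[1:] if delta_area[k] >= ELBOW_THRESHOLD]
    candidate = max(supported) if supported else ks[0]
    C = consensus_matrices[candidate].to_numpy()
    off = C[np.triu_indices(n, k=1)]
    pac = float(((off > 0.1) & (off < 0.9)).mean())
    if pac <= PAC_THRESHOLD:
        chosen_k, low_conf = candidate, False
    else:
        chosen_k, low_conf = ks[0], True
        logger.warning("consensus_cluster: ambiguous consensus (PAC=%.2f) at "
                       "k=%d; falling back to k=%d, low-confidence",
                       pac, candidate, chosen_k)
    return ConsensusResult(consensus_matrices, labels, cdf_area, delta_area,
                           chosen_k, low_conf)


def assign_subtype_names(result: ConsensusResult, expr: ExpressionMatrix,
                         anchor_sets: GeneSetCollection,
                         k: int | None = None) -> pd.DataFrame:
    """Name integer consensus clusters after anchor gene sets.

    Each cluster is matched to the anchor set with the highest mean ssGSEA
    score among its samples; the matching is made bijective by a global
    assignment maximizing total score (which also resolves ties
    deterministically).
    """
    k = result.chosen_k if k is None else k
    if k != len(anchor_sets):
        raise ValueError(f"chosen k={k} but {len(anchor_sets)} anchor sets given")
    labels = result.labels[k]
    scores = ssgsea(expr, anchor_sets, normalize=False).scores  # sets x samples
    clusters = sorted(labels.unique())
    names = list(anchor_sets)
    mean_score = np.zeros((len(clusters), len(names)))
    for ci, c in enumerate(clusters):
        cols = labels.index[labels == c]
        mean_score[ci] = scores[cols].mean(axis=1).to_numpy()
    row, col = linear_sum_assignment(-mean_score)
    mapping = {clusters[r]: names[c] for r, c in zip(row, col)}
    best = {clusters[r]: names[int(np.argmax(mean_score[r]))] for r in range(len(clusters))}
    if best != mapping:
        logger.info("assign_subtype_names: greedy best-match not bijective; "
                    "resolved by global assignment")
    return pd.DataFrame({
        "sample_id": labels.index,
        "subtype": [mapping[c] for c in labels],
        "source": "consensus",
        "distance": np.nan,
        "p_value": np.nan,
        "fdr": np.nan,
    })
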