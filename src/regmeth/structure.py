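"""Unsupervised sample structure: ordination and clustering.

Samples are embedded by classical metric multidimensional scaling
(principal coordinates) of Euclidean distances over the most variable
CpGs, and partitioned by agglomerative hierarchical clustering with the
high-methylation cluster selected by global mean beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .containers import BetaMatrix, ValidationError


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame   # sample x 2
    selected_cpgs: list[str]
    eigenvalues: np.ndarray
    stress: float               # RMS relative error of embedded distances


def mds_top_variable(beta: BetaMatrix, n_top: int = 1000) -> EmbeddingResult:
    """Classical MDS of samples on the ``n_top`` most variable CpGs.

    CpGs are ranked by variance across samples (ties broken lexically by
    id); classical metric MDS (principal-coordinates analysis) is run on
    the Euclidean distances between samples.  Axis signs are fixed so
    the largest-magnitude loading of each axis is positive, making the
    embedding reproducible across runs and sample orders.
    """
    frame = beta.frame
    if frame.shape[1] < 3:
        raise ValidationError("MDS needs at least 3 samples")
    if n_top > frame.shape[0]:
        import logging

        logging.getLogger("regmeth").warning(
            "n_top=%d exceeds %d available CpGs; using all", n_top, frame.shape[0]
        )
        n_top = frame.shape[0]
    variances = frame.var(axis=1)
    order = np.lexsort((np.array(frame.index, dtype=object), -variances.to_numpy()))
    selected = [frame.index[i] for i in order[:n_top]]
    sub = frame.loc[selected]

    dist = squareform(pdist(sub.to_numpy().T, metric="euclidean"))
    n = dist.shape[0]
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    idx = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[idx], eigvec[:, idx]
    k = 2
    lam = np.clip(eigval[:k], 0, None)
    coords = eigvec[:, :k] * np.sqrt(lam)[None, :]
    for axis in range(k):
        peak = np.argmax(np.abs(coords[:, axis]))
        if coords[peak, axis] < 0:
            coords[:, axis] = -coords[:, axis]

    emb_dist = squareform(pdist(coords))
    mask = dist > 0
    stress = float(
        np.sqrt(np.mean(((emb_dist[mask] - dist[mask]) / dist[mask]) ** 2))
    ) if mask.any() else 0.0
    return EmbeddingResult(
        coordinates=pd.DataFrame(coords, index=frame.columns, columns=["dim1", "dim2"]),
        selected_cpgs=selected,
        eigenvalues=eigval,
        stress=stress,
    )


def select_high_methylation_cluster(
    beta: BetaMatrix, k: int = 2, linkage: str = "average"
) -> list[str]:
    """Members of the highest-mean-beta cluster after hierarchical clustering.

    Samples are clustered on their beta profiles (Euclidean distance,
    configurable linkage), the tree is cut at ``k`` clusters, and the
    cluster with the highest mean beta over all its CpGs and members is
    returned.
    """
    frame = beta.frame
    n = frame.shape[1]
    if n < 2:
        raise ValidationError("clustering needs at least 2 samples")
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} available samples")
    z = hierarchy.linkage(frame.to_numpy().T, method=linkage, metric="euclidean")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    best_label, best_mean = None, -np.inf
    for lab in np.unique(labels):
        members = frame.columns[labels == lab]
        mean_beta = float(frame[members].to_numpy().mean())
        if mean_beta > best_mean:
            best_label, best_mean = lab, mean_beta
    return list(frame.columns[labels == best_label])
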