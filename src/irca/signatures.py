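"""Ramanome signatures: MP, MI, MC — distances, clustering, PCA.

Three complementary fingerprints summarize one ramanome:

* MP (metabolite profile) — the mean spectrum over cells; what the
  population contains.
* MI (metabolite interaction) — the matrix of significant pairwise
  correlations (P < alpha, others zeroed); which metabolite pools covary.
* MC (metabolite conversion) — the matrix keeping only significant strong
  negative correlations (rho <= threshold, P < alpha); which pools appear
  to interconvert.

Ramanomes are compared by Euclidean distance between signatures (strict
upper triangle for the symmetric MI/MC matrices), grouped by Ward
hierarchical clustering, and visualized by PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from irca.core import DegenerateInputError, IrcaError, Ramanome
from irca.network import CorrelationMatrix

__all__ = [
    "SignatureSet", "ClusterResult", "mp_signature", "mi_signature",
    "mc_signature", "compute_signatures", "signature_distance",
    "hca_cluster", "pca_project",
]


def mp_signature(r: Ramanome) -> np.ndarray:
    """Metabolite profile: elementwise mean spectrum over cells."""
    return r.matrix.mean(axis=0)


def mi_signature(cm: CorrelationMatrix, alpha: float = 0.05) -> np.ndarray:
    """Metabolite interaction matrix: rho where P < alpha, else 0.

    Diagonal and NaN pairs are zeroed.
    """
    with np.errstate(invalid="ignore"):
        keep = cm.pval < alpha
    mi = np.where(keep & np.isfinite(cm.rho), cm.rho, 0.0)
    np.fill_diagonal(mi, 0.0)
    return mi


def mc_signature(cm: CorrelationMatrix, rho_threshold: float = -0.6,
                 alpha: float = 0.05) -> np.ndarray:
    """Metabolite conversion matrix: rho where rho <= threshold and P < alpha."""
    with np.errstate(invalid="ignore"):
        keep = (cm.rho <= rho_threshold) & (cm.pval < alpha)
    mc = np.where(keep & np.isfinite(cm.rho), cm.rho, 0.0)
    np.fill_diagonal(mc, 0.0)
    return mc


@dataclass
class SignatureSet:
    """The three signatures of one ramanome."""

    ramanome_id: str
    mp: np.ndarray
    mi: np.ndarray
    mc: np.ndarray

    def __post_init__(self) -> None:
        f = self.mi.shape[0]
        if self.mi.shape != (f, f) or self.mc.shape != (f, f):
            raise IrcaError("MI/MC must be square F x F matrices")


def compute_signatures(r: Ramanome, alpha: float = 0.05,
                       rho_threshold: float = -0.6) -> SignatureSet:
    """MP, MI and MC of one (standardized) ramanome."""
    from irca.network import correlation_matrix, feature_labels_from_axis

    cm = correlation_matrix(r.matrix,
                            feature_labels_from_axis(r.axis.wavenumbers))
    return SignatureSet(
        ramanome_id=str(r.meta.get("ramanome_id", "")),
        mp=mp_signature(r),
        mi=mi_signature(cm, alpha),
        mc=mc_signature(cm, rho_threshold, alpha),
    )


def _vectorize(sig: SignatureSet, which: str) -> np.ndarray:
    if which == "mp":
        return np.asarray(sig.mp, dtype=float)
    if which in ("mi", "mc"):
        m = sig.mi if which == "mi" else sig.mc
        iu, ju = np.triu_indices(m.shape[0], k=1)
        return m[iu, ju]
    raise IrcaError(f"unknown signature kind {which!r}")


def signature_distance(sigs: list[SignatureSet], which: str) -> np.ndarray:
    """Pairwise Euclidean distances between signatures of one kind.

    MP compares mean-spectrum vectors; MI/MC compare the strict upper
    triangles of the correlation matrices (each symmetric entry counted
    once).
    """
    if len(sigs) < 2:
        raise DegenerateInputError("need >= 2 signature sets")
    vecs = [_vectorize(s, which) for s in sigs]
    dim = vecs[0].size
    if any(v.size != dim for v in vecs):
        raise IrcaError("signatures have mismatched dimensions")
    V = np.vstack(vecs)
    diff = V[:, None, :] - V[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


@dataclass
class ClusterResult:
    """Flat clustering of ramanomes from a Ward dendrogram."""

    labels: np.ndarray          # 1..k per ramanome
    k: int
    linkage_matrix: np.ndarray
    method: str


def hca_cluster(d: np.ndarray, k: int = 6, method: str = "ward") -> ClusterResult:
    """Ward hierarchical clustering of a distance matrix, cut at k clusters.

    Uses the Ward criterion on the raw Euclidean distances (the
    'ward.D2'-style variant); deterministic for fixed input.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise IrcaError("distance matrix must be square")
    if not (1 <= k <= n):
        raise IrcaError(f"k={k} out of range [1, {n}]")
    condensed = squareform(d, checks=False)
    Z = linkage(condensed, method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(labels=labels, k=int(labels.max()),
                         linkage_matrix=Z, method=method)


def pca_project(sigs: list[SignatureSet], which: str,
                n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA scores of the chosen signature, plus explained-variance
    ratios.

    Component signs are fixed so that the largest-magnitude loading of
    each component is positive, making the projection deterministic.
    """
    from sklearn.decomposition import PCA

    V = np.vstack([_vectorize(s, which) for s in sigs])
    n = V.shape[0]
    if n < 2:
        raise DegenerateInputError("PCA needs >= 2 samples")
    if n_components > min(n - 1, V.shape[1]):
        raise IrcaError(
            f"n_components={n_components} exceeds min(n-1, dim)="
            f"{min(n - 1, V.shape[1])}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(V)
    for c in range(n_components):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1.0
    return scores, pca.explained_variance_ratio_
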