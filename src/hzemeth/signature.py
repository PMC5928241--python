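"""Monte-Carlo cluster-discrimination test for methylation signatures.

Tests whether the methylation pattern of a fixed CpG probe set (a
"signature") separates tumor from normal samples better than random probe
sets of the same size.  Samples are clustered unsupervised (Manhattan
distance, agglomerative complete linkage, dendrogram cut at k = 2) and the
cluster/tissue association is scored with a Pearson chi-square test; the
observed p-value is then ranked against M resampled random probe sets
drawn from the detection-filtered array universe, giving the Monte-Carlo
p-value (r + 1) / (M + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "filter_signature_probes",
    "manhattan_distance_matrix",
    "complete_linkage_cut",
    "cluster_label_association",
    "monte_carlo_signature_test",
    "SignatureTestResult",
]


def filter_signature_probes(
    beta: pd.DataFrame, detection_p: pd.DataFrame | None, alpha: float = 0.05
) -> pd.Index:
    """Probes detected (p <= alpha) in every sample of the set.

    The same rule defines both the usable signature probes and the
    resampling pool.  With no detection table, all probes pass.
    """
    if detection_p is None:
        kept = beta.index
    else:
        if not detection_p.index.equals(beta.index) or not detection_p.columns.equals(beta.columns):
            raise ValueError("detection table must align with the beta matrix")
        kept = beta.index[(detection_p.to_numpy() <= alpha).all(axis=1)]
    if len(kept) == 0:
        raise ValueError("no probes pass the detection filter")
    return kept


def manhattan_distance_matrix(beta: pd.DataFrame) -> np.ndarray:
    """Sample x sample Manhattan distances d(i,j) = sum_p |beta_pi - beta_pj|."""
    values = beta.to_numpy(float)
    if np.isnan(values).any():
        raise ValueError(
            "missing values in the beta submatrix; apply filter_signature_probes first"
        )
    return squareform(pdist(values.T, metric="cityblock"))


def complete_linkage_cut(distances: np.ndarray, k: int = 2) -> np.ndarray:
    """Agglomerative complete-linkage clustering cut at exactly k clusters.

    Returns integer labels (1..k); deterministic given the distance matrix.
    """
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of samples")
    if k == n:
        return np.arange(1, n + 1)
    condensed = squareform(distances, checks=False)
    Z = linkage(condensed, method="complete")
    return fcluster(Z, t=k, criterion="maxclust")


def cluster_label_association(
    cluster_labels: np.ndarray, tissue_labels, correction: bool = False
) -> float:
    """Pearson chi-square p-value for the 2x2 cluster x tissue contingency.

    1 df, Yates continuity correction off by default.  A degenerate margin
    (an empty cluster or class) yields p = 1.
    """
    table = pd.crosstab(np.asarray(cluster_labels), np.asarray(tissue_labels))
    if table.shape != (2, 2) or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=correction)
    return float(p)


@dataclass
class SignatureTestResult:
    """Observed and Monte-Carlo significance of a signature's separation."""

    observed_p: float
    mc_p: float
    null_p_values: np.ndarray
    n_resamples: int
    seed: int
    k: int = 2
    cluster_labels: np.ndarray = field(default=None, repr=False)

    @property
    def null_min(self) -> float:
        return float(np.min(self.null_p_values))

    @property
    def null_max(self) -> float:
        return float(np.max(self.null_p_values))

    @property
    def null_median(self) -> float:
        return float(np.median(self.null_p_values))

    def to_dict(self) -> dict:
        return {
            "observed_p": self.observed_p,
            "mc_p": self.mc_p,
            "null_min": self.null_min,
            "null_max": self.null_max,
            "null_median": self.null_median,
            "n_resamples": self.n_resamples,
            "k": self.k,
            "seed": self.seed,
        }


def _clustering_p(values: np.ndarray, tissue, k: int, correction: bool) -> tuple[float, np.ndarray]:
    condensed = pdist(values.T, metric="cityblock")
    labels = fcluster(linkage(condensed, method="complete"), t=k, criterion="maxclust")
    return cluster_label_association(labels, tissue, correction=correction), labels


def monte_carlo_signature_test(
    beta: pd.DataFrame,
    tissue_labels: pd.Series,
    signature_probes,
    pool_probes=None,
    n_resamples: int = 1000,
    seed: int = 0,
    k: int = 2,
    correction: bool = False,
    ties: str = "conservative",
) -> SignatureTestResult:
    """Monte-Carlo significance of a signature versus random probe sets.

    The observed chi-square p comes from clustering on the signature
    probes; each of ``n_resamples`` draws takes the same number of probes
    uniformly without replacement from ``pool_probes`` (default: all rows
    of ``beta``), reclusters, and rescores.  mc_p uses the add-one
    estimator (1 + r) / (M + 1), never zero.

    ``ties`` controls how null p-values exactly equal to the observed one
    enter r.  "conservative" (default) counts every tie (r = #{null p <=
    observed p}), giving a valid but conservative p when the chi-square
    p-value is heavily discrete.  "random" breaks each tie by an
    independent fair coin (equivalently, lexicographic comparison with iid
    uniform jitter), which makes mc_p exactly uniform on
    {1/(M+1), ..., 1} under the null.
    """
    if ties not in ("conservative", "random"):
        raise ValueError("ties must be 'conservative' or 'random'")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    pool = pd.Index(pool_probes) if pool_probes is not None else beta.index
    signature = pd.Index(signature_probes)
    if not signature.isin(pool).all():
        raise ValueError("signature probes must be contained in the resampling pool")
    if len(pool) < len(signature):
        raise ValueError("pool smaller than the signature")
    tissue = tissue_labels.loc[beta.columns].to_numpy()

    values = beta.to_numpy(float)
    pool_rows = beta.index.get_indexer(pool)
    sig_rows = beta.index.get_indexer(signature)

    observed_p, observed_labels = _clustering_p(values[sig_rows], tissue, k, correction)

    rng = np.random.default_rng(seed)
    null_p = np.empty(n_resamples)
    for m in range(n_resamples):
        draw = rng.choice(pool_rows, size=len(sig_rows), replace=False)
        null_p[m], _ = _clustering_p(values[draw], tissue, k, correction)

    if ties == "random":
        u = rng.random(n_resamples + 1)  # u[-1] belongs to the observed p
        below = (null_p < observed_p) | ((null_p == observed_p) & (u[:-1] < u[-1]))
        r = int(np.sum(below))
    else:
        r = int(np.sum(null_p <= observed_p))
    mc_p = (1 + r) / (n_resamples + 1)
    return SignatureTestResult(
        observed_p=float(observed_p),
        mc_p=float(mc_p),
        null_p_values=null_p,
        n_resamples=n_resamples,
        seed=seed,
        k=k,
        cluster_labels=observed_labels,
    )
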