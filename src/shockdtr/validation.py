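"""k-means confirmation of the class number and PCA projection.

Seven classical cluster-number indices computed from the within/between
scatter matrices of k-means partitions (CH, DB, Hartigan, KL, Marriot, Rubin,
TraceW), each with its decision rule, plus a majority vote. The cubic
clustering criterion is excluded from the default battery (its hyperbox
derivation is tool-specific); a hook is kept so a custom implementation can be
registered, and every report records the exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = ["IndexTable", "kmeans_index_battery", "choose_k_from_indices", "pca_projection"]

#: index -> decision rule ("maximize", "minimize", "elbow")
INDEX_RULES = {
    "CH": "maximize",
    "DB": "minimize",
    "KL": "maximize",
    "Hartigan": "elbow",
    "Marriot": "elbow",
    "Rubin": "elbow",
    "TraceW": "elbow",
}

#: optional CCC hook: callable (X, labels, K) -> float, or None (excluded)
CCC_HOOK = None


@dataclass
class IndexTable:
    values: pd.DataFrame          # rows K, columns = index names
    rules: dict[str, str]
    notes: str = "CCC excluded from the battery (no registered implementation)"


def _scatter(X: np.ndarray, labels: np.ndarray, K: int):
    """Within-cluster scatter matrix W and per-cluster stats."""
    d = X.shape[1]
    W = np.zeros((d, d))
    centers = np.empty((K, d))
    for k in range(K):
        xk = X[labels == k]
        centers[k] = xk.mean(axis=0)
        dev = xk - centers[k]
        W += dev.T @ dev
    return W, centers


def _davies_bouldin(X, labels, centers):
    K = centers.shape[0]
    s = np.array([np.sqrt(((X[labels == k] - centers[k]) ** 2).sum(axis=1)).mean()
                  for k in range(K)])
    db = 0.0
    for i in range(K):
        ratios = [(s[i] + s[j]) / np.linalg.norm(centers[i] - centers[j])
                  for j in range(K) if j != i]
        db += max(ratios)
    return db / K


def kmeans_index_battery(matrix, K_range=range(2, 9), seed: int = 0,
                         n_init: int = 25) -> IndexTable:
    """Fit k-means per candidate K and compute the cluster-number indices.

    Indices are computed from the scatter matrices of the best-of-``n_init``
    partitions: CH = [tr(B)/(K-1)]/[tr(W)/(n-K)]; DB = mean over clusters of
    the worst (s_i+s_j)/d_ij; Hartigan = (tr(W_K)/tr(W_{K+1}) - 1)(n-K-1);
    KL = |DIFF_K| / |DIFF_{K+1}| with
    DIFF_K = (K-1)^{2/d} tr(W_{K-1}) - K^{2/d} tr(W_K); Marriot = K^2 det(W_K);
    Rubin = tr(T)/tr(W_K); TraceW = tr(W_K). Expects standardized features
    (distance-based statistics are scale-sensitive).
    """
    X = np.asarray(matrix, float)
    n, d = X.shape
    ks = sorted(K_range)
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError("K_range must lie within [2, n-1]")
    # Hartigan needs W at K+1, KL needs W at K-1 and K+1
    fit_ks = sorted(set(ks) | {k - 1 for k in ks} | {k + 1 for k in ks})
    fit_ks = [k for k in fit_ks if 1 <= k <= n - 1]

    T = np.cov(X.T, bias=True) * n  # total scatter
    if d == 1:
        T = T.reshape(1, 1)
    trW: dict[int, float] = {}
    detW: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    centers_by_k: dict[int, np.ndarray] = {}
    for k in fit_ks:
        if k == 1:
            W = T
            labels = np.zeros(n, dtype=int)
            centers = X.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
            labels, centers = km.labels_, km.cluster_centers_
            W, centers = _scatter(X, labels, k)
        trW[k] = float(np.trace(W))
        sign, logdet = np.linalg.slogdet(W)
        detW[k] = float(sign * np.exp(logdet)) if np.isfinite(logdet) else 0.0
        labels_by_k[k] = labels
        centers_by_k[k] = centers

    trT = float(np.trace(T))
    rows = []
    for k in ks:
        trB = trT - trW[k]
        ch = (trB / (k - 1)) / (trW[k] / (n - k))
        db = _davies_bouldin(X, labels_by_k[k], centers_by_k[k])
        hart = (trW[k] / trW[k + 1] - 1.0) * (n - k - 1) if k + 1 in trW else np.nan

        def diff(kk):
            if kk - 1 not in trW or kk not in trW:
                return np.nan
            return (kk - 1) ** (2.0 / d) * trW[kk - 1] - kk ** (2.0 / d) * trW[kk]

        dk, dk1 = diff(k), diff(k + 1)
        kl = abs(dk) / abs(dk1) if np.isfinite(dk) and np.isfinite(dk1) and dk1 != 0 else np.nan
        row = {"K": k, "CH": ch, "DB": db, "Hartigan": hart, "KL": kl,
               "Marriot": k**2 * detW[k], "Rubin": trT / trW[k], "TraceW": trW[k]}
        if CCC_HOOK is not None:
            row["CCC"] = CCC_HOOK(X, labels_by_k[k], k)
        rows.append(row)
    values = pd.DataFrame(rows).set_index("K")
    rules = dict(INDEX_RULES)
    if CCC_HOOK is not None:
        rules["CCC"] = "maximize"
    return IndexTable(values=values, rules=rules)


def choose_k_from_indices(table: IndexTable) -> dict:
    """Per-index votes and the majority class count.

    Maximize-rule indices vote their argmax, minimize-rule their argmin;
    elbow-rule indices vote the K maximizing the discrete second difference
    v(K-1) - 2 v(K) + v(K+1) over interior candidates. Vote ties go to the
    smallest tied K and are reported; if no K reaches a strict plurality the
    report carries a no-majority flag (smallest most-voted K still returned).
    """
    vals = table.values
    ks = list(vals.index)
    if len(ks) < 2:
        raise ValueError("need at least two candidate K")
    votes: dict[str, int] = {}
    for name, rule in table.rules.items():
        v = vals[name].astype(float)
        if v.isna().all():
            continue
        if rule == "maximize":
            votes[name] = int(v.idxmax())
        elif rule == "minimize":
            votes[name] = int(v.idxmin())
        else:  # elbow: maximal discrete second difference over interior K
            best, best_val = None, -np.inf
            for k in ks[1:-1]:
                if any(np.isnan(v.get(kk, np.nan)) for kk in (k - 1, k, k + 1)):
                    continue
                sd = v[k - 1] - 2.0 * v[k] + v[k + 1]
                if sd > best_val:
                    best, best_val = k, sd
            if best is not None:
                votes[name] = best
    tally = pd.Series(votes).value_counts()
    top = int(tally.max())
    tied = sorted(int(k) for k in tally.index[tally == top])
    majority = tied[0]
    return {
        "votes": votes,
        "tally": {int(k): int(c) for k, c in tally.items()},
        "majority_K": majority,
        "tie": len(tied) > 1,
        "no_majority": top <= len(votes) / 2.0,
        "notes": table.notes,
    }


def pca_projection(matrix, n_components: int = 3):
    """Principal-component scores for class-separation reporting.

    Returns ``(scores, loadings, variance_fractions)``; loadings are
    orthonormal columns (d x n_components), variance fractions non-increasing
    and summing to <= 1. Expects standardized input; a constant matrix has no
    variance to decompose and raises.
    """
    X = np.asarray(matrix, float)
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds feature count")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("constant matrix: no variance to decompose")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, pca.components_.T, pca.explained_variance_ratio_
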