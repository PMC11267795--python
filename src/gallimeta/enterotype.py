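"""Enterotype detection and characterisation.

Samples are clustered on the square root of the Jensen-Shannon divergence
between genus profiles with a deterministic k-medoids (PAM: BUILD + SWAP);
the number of enterotypes is chosen by the Calinski-Harabasz criterion,
with silhouette width reported alongside as a diagnostic.  Discriminating
genera are ranked by a LEfSe-style Kruskal-Wallis-screened linear
discriminant effect size, and genus co-occurrence networks are built from
thresholded Spearman correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import jensenshannon
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import silhouette_score


@dataclass
class EnterotypeResult:
    k: int
    labels: pd.Series  # sample -> cluster label in 1..k
    medoids: list[str]
    scores: dict[int, float] = field(default_factory=dict)  # k -> criterion value
    silhouette: float = float("nan")
    objective_history: list[float] = field(default_factory=list)  # BUILD cost, then per-SWAP


def jsd_distance(matrix: pd.DataFrame, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Pairwise sqrt-Jensen-Shannon distance between samples (columns).

    Rows of the genus x sample matrix get *pseudocount* added and are
    renormalised per sample before the divergence (base-2 logs, so the
    distance lies in [0, 1]).  The default pseudocount keeps the KL terms
    finite on zero-laden compositions; pass 0 to reproduce the disjoint-
    support maximum of exactly 1.
    """
    data = matrix.to_numpy(dtype=float).T
    if (data < 0).any():
        raise ValueError("abundances must be nonnegative")
    data = data + pseudocount
    data = data / data.sum(axis=1, keepdims=True)
    n = data.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = jensenshannon(data[i], data[j], base=2)
    return pd.DataFrame(dm, index=matrix.columns, columns=matrix.columns)


def _pam_cost(dist: np.ndarray, medoids: list[int]) -> float:
    return float(dist[:, medoids].min(axis=1).sum())


def pam(dist: pd.DataFrame, k: int) -> EnterotypeResult:
    """Deterministic k-medoids (PAM).

    BUILD greedily seeds the medoids (ties broken by index order) and SWAP
    applies best-improvement medoid/non-medoid exchanges until no swap
    lowers the total within-cluster distance to medoids, so reruns on the
    same input give identical labels.
    """
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError("need 2 <= k < n")

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=0)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.array([
            np.minimum(current, d[:, c]).sum() if c not in medoids else np.inf
            for c in range(n)
        ])
        medoids.append(int(np.argmin(gains)))

    # SWAP (best improvement)
    cost = _pam_cost(d, medoids)
    history = [cost]
    improved = True
    while improved:
        improved = False
        best = (cost, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                c = _pam_cost(d, trial)
                if c < best[0] - 1e-12:
                    best = (c, mi, h)
        if best[1] is not None:
            cost, mi, h = best
            medoids[mi] = h
            history.append(cost)
            improved = True

    medoids = sorted(medoids)
    assign = np.argmin(d[:, medoids], axis=1)
    labels = pd.Series(assign + 1, index=dist.index, name="enterotype")
    sil = float(silhouette_score(d, labels.to_numpy(), metric="precomputed")) \
        if len(set(assign)) > 1 else float("nan")
    return EnterotypeResult(k=k, labels=labels,
                            medoids=[str(dist.index[m]) for m in medoids],
                            silhouette=sil, objective_history=history)


def calinski_harabasz(dist: pd.DataFrame, result: EnterotypeResult) -> float:
    """CH index computed from the distance matrix via sum-of-squares identities.

    Within-cluster sum of squares is ``sum_{i<j in c} d_ij^2 / n_c`` and the
    between-cluster term is total minus within — the same among/within
    decomposition PERMANOVA uses.  This avoids the artifact of measuring
    between-cluster spread from an overall medoid, which sits inside one of
    the clusters and zeroes that cluster's contribution.
    """
    d2 = dist.to_numpy(dtype=float) ** 2
    n = d2.shape[0]
    k = result.k
    labels = result.labels.to_numpy()
    total = float(d2.sum()) / (2 * n)
    within = 0.0
    for c in np.unique(labels):
        mask = labels == c
        within += float(d2[np.ix_(mask, mask)].sum()) / (2 * int(mask.sum()))
    between = total - within
    if within <= 1e-12:
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


def select_k(dist: pd.DataFrame, k_max: int = 6) -> tuple[int, EnterotypeResult, dict[int, float]]:
    """Fit PAM for k = 2..k_max and pick the k maximising Calinski-Harabasz.

    Ties prefer the smaller k.  Returns (best k, its clustering, per-k CH).
    """
    n = len(dist)
    if n < 4:
        raise ValueError("need at least 4 samples")
    if k_max >= n:
        raise ValueError("k_max must be < number of samples")
    scores: dict[int, float] = {}
    fits: dict[int, EnterotypeResult] = {}
    for k in range(2, k_max + 1):
        fit = pam(dist, k)
        scores[k] = calinski_harabasz(dist, fit)
        fits[k] = fit
    best_k = max(sorted(scores), key=lambda k: scores[k])
    best = fits[best_k]
    best.scores = scores
    return best_k, best, scores


def lda_effect_size(matrix: pd.DataFrame, labels, kw_alpha: float = 0.05,
                    scale: float = 1e6) -> pd.DataFrame:
    """LEfSe-style discriminant ranking of features between classes.

    Features failing a Kruskal-Wallis screen at *kw_alpha* (raw p) are
    excluded.  Surviving features are scaled to a per-sample total of
    *scale* and, per class (one-vs-rest), scored as
    ``log10(1 + |0.5 * (w_f * s_f + delta_f)|)`` where ``delta_f`` is the
    between-class mean difference, ``w_f`` the linear-discriminant
    coefficient and ``s_f`` the pooled within-class standard deviation
    (putting the coefficient back on the abundance scale).  Unlike the
    original tool there is no bootstrap: the fit is a single deterministic
    least-squares LDA.  Each feature is reported for the class where its
    mean is highest; only the within-class ranking is meaningful.
    """
    y = pd.Series(list(labels), index=matrix.columns)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if (y.value_counts() < 2).any():
        raise ValueError("every class needs at least two samples")

    scaled = matrix / matrix.sum(axis=0) * scale
    rows = []
    for feature, values in scaled.iterrows():
        v = values.to_numpy(dtype=float)
        by_class = [v[(y == c).to_numpy()] for c in classes]
        if np.ptp(v) == 0:
            continue
        _, p = scipy.stats.kruskal(*by_class)
        if p >= kw_alpha:
            continue
        class_means = {c: g.mean() for c, g in zip(classes, by_class)}
        top_class = max(classes, key=lambda c: class_means[c])
        mask = (y == top_class).to_numpy()
        delta = v[mask].mean() - v[~mask].mean()
        sd = np.sqrt((np.var(v[mask], ddof=0) + np.var(v[~mask], ddof=0)) / 2)
        lda = LinearDiscriminantAnalysis(solver="lsqr")
        lda.fit(v.reshape(-1, 1), mask.astype(int))
        w = float(lda.coef_[0][0])
        effect = 0.5 * (abs(w) * sd + abs(delta))
        rows.append({"feature": feature, "class": top_class,
                     "kw_p": float(p), "lda_score": float(np.log10(1 + effect))})
    out = pd.DataFrame(rows, columns=["feature", "class", "kw_p", "lda_score"])
    return out.sort_values(["class", "lda_score"], ascending=[True, False]).reset_index(drop=True)


def top_features(effects: pd.DataFrame, n: int = 10) -> dict:
    """Top-*n* features per class from an ``lda_effect_size`` table."""
    return {c: sub["feature"].head(n).tolist()
            for c, sub in effects.groupby("class", sort=True)}


def cooccurrence_network(matrix: pd.DataFrame, rho_min: float = 0.5,
                         p_max: float = 0.01,
                         abundance_min: float = 1e-4) -> pd.DataFrame:
    """Genus co-occurrence edges from thresholded Spearman correlations.

    Keeps undirected pairs with |rho| > rho_min, p < p_max and both mean
    abundances above *abundance_min*; constant genera are skipped.
    """
    if matrix.shape[1] < 5:
        raise ValueError("need at least 5 samples")
    means = matrix.mean(axis=1)
    keep = matrix.loc[means > abundance_min]
    keep = keep[keep.apply(lambda r: np.ptp(r.to_numpy()) > 0, axis=1)]
    if len(keep) < 2:
        return pd.DataFrame(columns=["genus_a", "genus_b", "rho", "p"])
    rho, p = scipy.stats.spearmanr(keep.T)
    rho, p = np.atleast_2d(rho), np.atleast_2d(p)
    rows = []
    genera = list(keep.index)
    for i in range(len(genera)):
        for j in range(i + 1, len(genera)):
            if abs(rho[i, j]) > rho_min and p[i, j] < p_max:
                rows.append({"genus_a": genera[i], "genus_b": genera[j],
                             "rho": float(rho[i, j]), "p": float(p[i, j])})
    return pd.DataFrame(rows, columns=["genus_a", "genus_b", "rho", "p"])


def to_networkx(edges: pd.DataFrame):
    import networkx as nx

    graph = nx.Graph()
    for _, row in edges.iterrows():
        graph.add_edge(row["genus_a"], row["genus_b"], rho=row["rho"], p=row["p"])
    return graph


def pca_coordinates(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample PCA coordinates for plotting enterotype clouds."""
    coords = PCA(n_components=n_components, random_state=0).fit_transform(
        matrix.to_numpy(dtype=float).T)
    return pd.DataFrame(coords, index=matrix.columns,
                        columns=[f"PC{i + 1}" for i in range(n_components)])
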