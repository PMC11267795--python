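"""Abundance filtering, diversity, differential abundance and core species.

Conventions: matrices are features x samples; Shannon uses natural log;
Kruskal-Wallis p-values come from the chi-squared approximation with tie
correction; Benjamini-Hochberg is the classic step-up over all features of
a matrix.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats
import skbio
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import permanova as _skbio_permanova
from statsmodels.stats.multitest import multipletests


def cpm_filter(counts: pd.DataFrame, min_mean_cpm: float = 1.0) -> pd.DataFrame:
    """Keep features whose mean counts-per-million across samples is >= the floor."""
    if counts.shape[0] == 0:
        return counts
    depths = counts.sum(axis=0)
    if (depths <= 0).any():
        raise ValueError("all per-sample depths must be positive")
    cpm = counts / depths * 1e6
    return counts.loc[cpm.mean(axis=1) >= min_mean_cpm]


def alpha_diversity(abundances, metric: str = "shannon") -> float:
    """Shannon (natural log), inverse Simpson, or richness of one sample."""
    vec = np.asarray(abundances, dtype=float)
    if (vec < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = vec.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = vec[vec > 0] / total
    if metric == "shannon":
        return float(-(p * np.log(p)).sum())
    if metric == "inv_simpson":
        return float(1.0 / (p ** 2).sum())
    if metric == "richness":
        return int((vec > 0).sum())
    raise ValueError(f"unknown metric {metric!r}")


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (columns)."""
    data = matrix.to_numpy(dtype=float).T
    if data.shape[0] < 2:
        raise ValueError("need at least two samples")
    if int((data.sum(axis=1) == 0).sum()) >= 2:
        raise ValueError("multiple all-zero samples: Bray-Curtis undefined for the pair")
    dm = squareform(pdist(data, metric="braycurtis"))
    return pd.DataFrame(dm, index=matrix.columns, columns=matrix.columns)


def permanova(dist: pd.DataFrame, groups, n_perm: int = 999,
              seed: int | None = 0) -> tuple[float, float]:
    """PERMANOVA pseudo-F and permutation p for a grouping of samples.

    p = (1 + #{permuted F >= observed}) / (1 + n_perm); identical seeds give
    identical p-values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = pd.Series(list(groups))
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    dm = skbio.DistanceMatrix(dist.to_numpy(), ids=[str(i) for i in dist.index])
    res = _skbio_permanova(dm, labels.to_numpy(), permutations=n_perm, seed=seed)
    return float(res["test statistic"]), float(res["p-value"])


def kw_bh(matrix: pd.DataFrame, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis across groups with BH correction.

    Returns one row per feature: per-group means, H, raw p, BH-adjusted p,
    ``significant`` (adjusted p < alpha) and a ``constant`` flag (features
    identical everywhere get H = 0, p = 1).
    """
    labels = pd.Series(list(groups), index=matrix.columns)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for feature, values in matrix.iterrows():
        by_group = [values[labels == g].to_numpy(dtype=float) for g in uniq]
        means = {f"mean_{g}": float(v.mean()) for g, v in zip(uniq, by_group)}
        if np.ptp(values.to_numpy(dtype=float)) == 0:
            rows.append({"feature": feature, **means, "H": 0.0, "p": 1.0,
                         "constant": True})
            continue
        stat, p = scipy.stats.kruskal(*by_group)
        rows.append({"feature": feature, **means, "H": float(stat), "p": float(p),
                     "constant": False})
    out = pd.DataFrame(rows).set_index("feature")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    return out


def fold_enrichment(matrix: pd.DataFrame, groups, results: pd.DataFrame,
                    fold: float = 10.0) -> pd.Series:
    """Assign enrichment classes to significant features.

    A significant feature is enriched in group *g* when its mean abundance
    in *g* is at least *fold* times its mean in every other group (and is
    positive).  Non-significant features get ``none``.  For fold > 1 the
    classes are mutually exclusive.
    """
    labels = pd.Series(list(groups), index=matrix.columns)
    uniq = sorted(labels.unique())
    classes = {}
    for feature in matrix.index:
        cls = "none"
        if feature in results.index and bool(results.loc[feature, "significant"]):
            means = {g: float(matrix.loc[feature, labels[labels == g].index].mean())
                     for g in uniq}
            for g in uniq:
                others = [means[h] for h in uniq if h != g]
                if means[g] > 0 and all(means[g] >= fold * m for m in others):
                    cls = f"fold-enriched-{g}"
                    break
        classes[feature] = cls
    return pd.Series(classes, name="enrichment")


def core_species(matrix: pd.DataFrame, site_of_sample: Mapping[str, str],
                 sample_fraction: float = 0.90) -> tuple[pd.DataFrame, pd.Series]:
    """Core flags per feature and the per-sample core abundance share.

    ``site_core``: present (abundance > 0) in at least one sample of every
    site; ``sample_core``: present in >= *sample_fraction* of samples.  The
    returned series is each sample's summed abundance over sample-core
    features.
    """
    unmapped = [s for s in matrix.columns if s not in site_of_sample]
    if unmapped:
        raise ValueError(f"samples without a site: {unmapped[:3]}")
    sites = pd.Series({s: site_of_sample[s] for s in matrix.columns})
    present = matrix > 0

    site_hits = present.T.groupby(sites).any()  # site x feature
    flags = pd.DataFrame({
        "site_core": site_hits.all(axis=0),
        "sample_core": present.mean(axis=1) >= sample_fraction,
    })
    share = matrix.loc[flags["sample_core"]].sum(axis=0)
    share.name = "core_abundance_share"
    return flags, share
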