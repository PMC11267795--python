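"""Climate zoning, environmental variable selection and association tests.

Covers K-means climate zones on three standardised climate variables, VIF
pruning of collinear covariates, redundancy analysis of Hellinger-
transformed abundances on environmental constraints, Mantel tests,
per-feature Spearman associations with BH correction, AICc polynomial
selection for the altitude-diversity trend, and forward-backward stepwise
AIC linear models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import skbio
import statsmodels.api as sm
from skbio.stats.distance import mantel as _skbio_mantel
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

CLIMATE_COLUMNS = ["annual_mean_temperature", "annual_precipitation",
                   "precip_driest_quarter"]


@dataclass
class RDAResult:
    constraints: list[str]
    constrained_fraction: float
    axis_shares: np.ndarray  # eigenvalue shares of the constrained space


def kmeans_zones(climate: pd.DataFrame, k: int = 5, seed: int = 0,
                 n_init: int = 10) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster sites into climate zones with K-means on z-scored variables.

    Returns (labels 1..k, centroids in the original units).  Identical
    seeds reproduce identical labels.
    """
    if len(climate) < k:
        raise ValueError("fewer observations than clusters")
    data = climate.to_numpy(dtype=float)
    mu, sd = data.mean(axis=0), data.std(axis=0)
    sd[sd == 0] = 1.0
    z = (data - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = pd.Series(km.fit_predict(z) + 1, index=climate.index, name="zone")
    centroids = pd.DataFrame(km.cluster_centers_ * sd + mu,
                             columns=climate.columns,
                             index=pd.RangeIndex(1, k + 1, name="zone"))
    return labels, centroids


def vif_select(env: pd.DataFrame, vif_max: float = 20.0) -> list[str]:
    """Iteratively drop the highest-VIF column until all VIF < vif_max.

    Perfect collinearity (infinite VIF) is handled like any other maximum;
    ties break toward the earlier column.  Returns retained column names in
    their original order.
    """
    cols = list(env.columns)
    while len(cols) > 1:
        design = sm.add_constant(env[cols].to_numpy(dtype=float))
        with np.errstate(divide="ignore"):
            vifs = np.array([variance_inflation_factor(design, i + 1)
                             for i in range(len(cols))])
        vifs = np.where(np.isnan(vifs), np.inf, vifs)
        if (vifs < vif_max).all():
            break
        cols.pop(int(np.argmax(vifs)))
    return cols


def hellinger(matrix: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform (square root of per-sample relative abundance).

    Rows are features, columns samples; the result is samples x features,
    ready to be used as an RDA response.
    """
    rel = matrix / matrix.sum(axis=0)
    return np.sqrt(rel).T


def rda(response: pd.DataFrame, constraints: pd.DataFrame) -> RDAResult:
    """Redundancy analysis: variance of the response explained by constraints.

    *response* is samples x features (already transformed), *constraints*
    samples x variables.  Constraints are standardised; the constrained
    fraction is the trace of the fitted-value covariance over the trace of
    the centred response covariance.
    """
    y = response.to_numpy(dtype=float)
    x = constraints.to_numpy(dtype=float)
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValueError("response and constraints have different sample counts")
    if n <= x.shape[1]:
        raise ValueError("need more samples than constraints")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < x.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError("rank-deficient constraints (e.g. "
                         f"{constraints.columns[i]!r} vs {constraints.columns[j]!r})")

    y = y - y.mean(axis=0)
    total = float((y ** 2).sum())
    if total == 0:
        raise ValueError("zero-variance response")
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    x = x / np.where(sd == 0, 1.0, sd)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    constrained = float((fitted ** 2).sum())
    eigvals = np.linalg.svd(fitted, compute_uv=False) ** 2
    eigvals = eigvals[eigvals > 1e-12 * max(constrained, 1.0)]
    shares = eigvals / eigvals.sum() if eigvals.size else np.array([])
    return RDAResult(constraints=list(constraints.columns),
                     constrained_fraction=constrained / total,
                     axis_shares=shares)


def mantel(d1: pd.DataFrame, d2: pd.DataFrame, method: str = "spearman",
           n_perm: int = 999, seed: int | None = 0) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation p."""
    if d1.shape != d2.shape:
        raise ValueError("distance matrices differ in size")
    m1 = skbio.DistanceMatrix(d1.to_numpy(), ids=[str(i) for i in d1.index])
    m2 = skbio.DistanceMatrix(d2.to_numpy(), ids=[str(i) for i in d1.index])
    r, p, _ = _skbio_mantel(m1, m2, method=method, permutations=n_perm,
                            alternative="two-sided", seed=seed)
    return float(r), float(p)


def covariate_assoc(matrix: pd.DataFrame, covariate) -> pd.DataFrame:
    """Spearman association of every feature with one covariate, BH-corrected."""
    cov = np.asarray(covariate, dtype=float)
    if len(cov) < 5:
        raise ValueError("need at least 5 observations")
    rows = []
    for feature, values in matrix.iterrows():
        v = values.to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(cov) == 0:
            rows.append({"feature": feature, "rho": np.nan, "p": np.nan,
                         "constant": True})
            continue
        rho, p = scipy.stats.spearmanr(v, cov)
        rows.append({"feature": feature, "rho": float(rho), "p": float(p),
                     "constant": False})
    out = pd.DataFrame(rows).set_index("feature")
    tested = ~out["p"].isna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(out.loc[tested, "p"],
                                                 method="fdr_bh")[1]
    return out


def _aicc(fit, n: int) -> float:
    k = fit.df_model + 1  # + intercept
    penalty = 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
    return float(fit.aic + penalty)


def poly_fit_aic(x, y, max_order: int = 3) -> dict:
    """Polynomial trend selection by corrected AIC (AICc).

    Ordinary least squares is fitted for each order 1..max_order (capped at
    one less than the number of distinct x); the minimal-AICc order wins and
    its overall F-test p-value against the intercept-only model is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n <= max_order + 2:
        raise ValueError("need n > max_order + 2")
    max_order = min(max_order, len(np.unique(x)) - 1)
    results = {}
    for order in range(1, max_order + 1):
        design = sm.add_constant(np.vander(x, order + 1, increasing=True)[:, 1:])
        fit = sm.OLS(y, design).fit()
        results[order] = (fit, _aicc(fit, n))
    best_order = min(results, key=lambda o: results[o][1])
    fit = results[best_order][0]
    anova_p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
    return {
        "order": best_order,
        "coefficients": np.asarray(fit.params),  # intercept first
        "aicc": {o: results[o][1] for o in results},
        "anova_p": anova_p,
    }


def stepwise_aic(response, features: pd.DataFrame) -> tuple[list[str], object]:
    """Forward-backward stepwise OLS minimising AIC.

    Deterministic given the column order: at each round the single add or
    drop that lowers AIC the most is applied; stops when no move improves.
    Returns (selected columns, fitted model).
    """
    y = np.asarray(response, dtype=float)

    def _fit(cols):
        design = sm.add_constant(features[cols].to_numpy(dtype=float)) if cols \
            else np.ones((len(y), 1))
        return sm.OLS(y, design).fit()

    selected: list[str] = []
    current = _fit(selected)
    while True:
        moves = []
        for col in features.columns:
            if col not in selected:
                moves.append((selected + [col], _fit(selected + [col])))
        for col in selected:
            reduced = [c for c in selected if c != col]
            moves.append((reduced, _fit(reduced)))
        if not moves:
            break
        best_cols, best_fit = min(moves, key=lambda m: m[1].aic)
        if best_fit.aic < current.aic - 1e-9:
            selected, current = best_cols, best_fit
        else:
            break
    return selected, current
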