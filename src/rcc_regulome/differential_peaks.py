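"""Differential enhancer calling: library-size + quantile normalization,
a two-group negative-binomial Wald test (one histology vs the rest), the
histology-specific labelling rule, and Spearman sample clustering QC.

The NB test is a self-contained re-implementation of the standard
two-group design (method-of-moments dispersion shrunk toward a fitted
mean–dispersion trend, Wald statistic on the log2 fold change). Exact
numerical agreement with any particular external differential caller is
not a contract; recovery of planted truth is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .stats import bh_adjust


@dataclass
class CountMatrix:
    """Peak × sample read counts with histology labels and library sizes."""

    values: pd.DataFrame  # peaks × samples, non-negative
    sample_labels: pd.Series  # histology per sample (index = sample ids)
    libsizes: pd.Series  # total mapped reads per sample

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.sample_labels.index):
            raise ValueError("sample_labels index must match count matrix columns")
        if list(self.values.columns) != list(self.libsizes.index):
            raise ValueError("libsizes index must match count matrix columns")
        if (self.libsizes <= 0).any():
            raise ValueError("library sizes must be positive")
        if (self.values.values < 0).any():
            raise ValueError("counts must be non-negative")


def normalize_counts(m: CountMatrix) -> pd.DataFrame:
    """Reads-per-million scaling followed by quantile normalization.

    Quantile normalization replaces each column's sorted values with the
    cross-column means of the sorted values; ties within a column receive
    the mean of their rank range.
    """
    rpm = m.values.div(m.libsizes / 1e6, axis=1)
    return quantile_normalize(rpm)


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    x = df.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    row_means = sorted_x.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        by_position = np.empty_like(col)
        by_position[order[:, j]] = row_means
        # tied values share the mean of the rank-means over their rank range
        ser = pd.Series(by_position).groupby(col).transform("mean")
        out[:, j] = ser.to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _mom_dispersion(norm: np.ndarray, groups: np.ndarray, sizefac: np.ndarray) -> np.ndarray:
    """Per-peak method-of-moments NB dispersion, pooled across the two groups,
    shrunk toward the parametric trend alpha(mu) = a0 + a1 / mu."""
    resid_var = np.zeros(norm.shape[0])
    mean_all = np.zeros(norm.shape[0])
    shot = np.zeros(norm.shape[0])  # Poisson (shot-noise) part of the variance
    dof = 0
    for g in (0, 1):
        cols = groups == g
        sub = norm[:, cols]
        mu = sub.mean(axis=1)
        resid_var += sub.var(axis=1, ddof=1) * (cols.sum() - 1)
        mean_all += mu * cols.sum()
        shot += (mu[:, None] / sizefac[None, cols]).sum(axis=1)
        dof += cols.sum() - 1
    resid_var /= max(dof, 1)
    mu = mean_all / norm.shape[1]
    shot /= norm.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (resid_var - shot) / mu**2
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)
    alpha_mom = np.clip(alpha_mom, 1e-8, 10.0)
    # parametric trend fit on peaks with usable moments
    ok = mu > 0
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(X, alpha_mom[ok], rcond=None)
        a0, a1 = max(coef[0], 1e-8), max(coef[1], 0.0)
    else:
        a0, a1 = float(np.median(alpha_mom)), 0.0
    with np.errstate(divide="ignore"):
        alpha_trend = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-12), a0)
    # moderate: equal-weight shrinkage of the per-peak estimate toward the trend
    return np.clip(0.5 * alpha_mom + 0.5 * alpha_trend, 1e-8, 10.0)


def nb_differential(
    m: CountMatrix, target_histology: str, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Two-group NB Wald test of ``target_histology`` vs all other samples.

    Returns a peak-indexed frame with columns log2fc, pvalue, padj.
    All-zero peaks get NaN p-values and are excluded from the BH
    denominator.
    """
    labels = m.sample_labels.to_numpy()
    groups = (labels == target_histology).astype(int)
    for g, name in ((1, target_histology), (0, "rest")):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    sizefac = (m.libsizes / 1e6).to_numpy(dtype=float)
    norm = m.values.to_numpy(dtype=float) / sizefac[None, :]
    alpha = _mom_dispersion(norm, groups, sizefac)

    t_cols, r_cols = groups == 1, groups == 0
    mu_t = norm[:, t_cols].mean(axis=1)
    mu_r = norm[:, r_cols].mean(axis=1)
    log2fc = np.log2((mu_t + pseudocount) / (mu_r + pseudocount))

    # delta-method variance of log2 of the group mean of normalized counts:
    # var(c_i / s_i) = mu / s_i + alpha * mu^2 under NB on the raw scale
    def group_var(mu: np.ndarray, cols: np.ndarray) -> np.ndarray:
        per_sample = mu[:, None] / sizefac[None, cols] + alpha[:, None] * mu[:, None] ** 2
        return per_sample.sum(axis=1) / cols.sum() ** 2

    with np.errstate(divide="ignore", invalid="ignore"):
        var_log = group_var(mu_t, t_cols) / (mu_t + pseudocount) ** 2 + group_var(
            mu_r, r_cols
        ) / (mu_r + pseudocount) ** 2
    se_log2fc = np.sqrt(var_log) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se_log2fc
    pvalue = 2 * stats.norm.sf(np.abs(z))
    allzero = (m.values.to_numpy() == 0).all(axis=1)
    degenerate = allzero | ~np.isfinite(pvalue)
    pvalue = np.where(degenerate, np.nan, pvalue)
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalue, "padj": bh_adjust(pvalue)},
        index=m.values.index,
    )


def call_histology_specific(
    results: dict[str, pd.DataFrame],
    padj_max: float = 0.001,
    log2fc_min: float = 3.0,
) -> pd.Series:
    """Label each peak with the histology in which it is enriched, or "common".

    A peak is labelled with a histology iff its one-vs-rest test passes
    both thresholds (padj < padj_max AND log2fc > log2fc_min, strict).
    Peaks passing in several histologies take the largest log2fc.
    """
    histologies = list(results)
    universe = results[histologies[0]].index
    for h in histologies[1:]:
        if not universe.equals(results[h].index):
            raise ValueError("differential results cover mismatched peak universes")
    labels = pd.Series("common", index=universe, dtype=object)
    best_lfc = pd.Series(-np.inf, index=universe)
    for h in histologies:
        res = results[h]
        passing = (res["padj"] < padj_max) & (res["log2fc"] > log2fc_min)
        passing &= res["padj"].notna()
        better = passing & (res["log2fc"] > best_lfc)
        labels[better] = h
        best_lfc[better] = res.loc[better, "log2fc"]
    return labels


def sample_correlation_cluster(norm: pd.DataFrame):
    """Spearman sample–sample correlation and average-linkage tree on 1 − ρ.

    Returns (correlation DataFrame, scipy linkage matrix, leaf order as
    sample ids). Constant samples get correlation 0 (with a warning).
    """
    if norm.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    # Spearman = Pearson on per-column ranks; robust to constant columns
    rho = norm.rank(axis=0).corr(method="pearson").to_numpy()
    constant = norm.nunique(axis=0).to_numpy() == 1
    if constant.any():
        warnings.warn("constant sample(s) detected; correlations set to 0")
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    corr = pd.DataFrame(rho, index=norm.columns, columns=norm.columns)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaf_order = [norm.columns[i] for i in hierarchy.leaves_list(link)]
    return corr, link, leaf_order
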