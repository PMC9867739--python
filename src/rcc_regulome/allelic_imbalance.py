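"""Chromatin allelic-imbalance engine.

Models haplotype-resolved read counts at heterozygous SNPs with a
beta-binomial distribution: reads for individual *i* at SNP *j* follow
BetaBin(pi_j, rho_ij), where pi is the mean allelic ratio (0.5 =
balanced) and rho is a per-individual overdispersion (intra-class
correlation) estimated within copy-number strata. Imbalance is a
likelihood-ratio test of pi = 0.5 against free pi; differential
imbalance between two histology groups is an LRT of shared vs
group-specific pi. SNP p-values are Bonferroni-corrected within each
peak, the best SNP's corrected p becomes the peak p, and q-values are
assigned across peaks (Benjamini–Hochberg).

Parameterization: alpha = pi (1 - rho) / rho, beta = (1 - pi) (1 - rho) / rho;
rho -> 0 recovers the binomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import betaln, gammaln

from .stats import bh_adjust

PI_BOUNDS = (0.005, 0.995)
PI_TOL = 1e-6

REQUIRED_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "individual",
    "hap1_reads",
    "hap2_reads",
]


@dataclass(frozen=True)
class BetaBinModel:
    """Beta-binomial with mean allelic ratio ``pi`` and overdispersion ``rho``."""

    pi: float
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError(f"pi must lie in (0, 1), got {self.pi}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")


def betabin_loglik(k_alt, n_total, model: BetaBinModel | None = None, *, pi=None, rho=None):
    """Exact log beta-binomial pmf via log-gamma, vectorized over counts.

    ``rho`` may be a scalar or an array aligned with the counts. At rho = 0
    the binomial log-pmf is returned. Empty observations (n = 0) contribute 0.
    """
    if model is not None:
        pi, rho = model.pi, model.rho
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi must lie in (0, 1), got {pi}")
    k, n, rho_arr = np.broadcast_arrays(
        np.asarray(k_alt, dtype=float),
        np.asarray(n_total, dtype=float),
        np.asarray(rho, dtype=float),
    )
    if np.any(rho_arr < 0) or np.any(rho_arr >= 1):
        raise ValueError("rho must lie in [0, 1)")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k_alt <= n_total")
    choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = (1.0 - rho_arr) / np.maximum(rho_arr, 1e-300)
        a = pi * ab
        b = (1.0 - pi) * ab
        bb = choose + betaln(k + a, n - k + b) - betaln(a, b)
    binom = choose + k * np.log(pi) + (n - k) * np.log1p(-pi)
    out = np.where(rho_arr > 0, bb, binom)
    return out if out.ndim else float(out)


def _total_loglik(pi: float, k: np.ndarray, n: np.ndarray, rho) -> float:
    return float(np.sum(betabin_loglik(k, n, pi=pi, rho=rho)))


def fit_pi(k_alt, n_total, rho) -> float:
    """MLE of the mean allelic ratio by bounded 1-D search on [0.005, 0.995]."""
    k = np.asarray(k_alt, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if n.sum() <= 0:
        raise ValueError("zero total reads; pi is unidentifiable")
    res = minimize_scalar(
        lambda p: -_total_loglik(p, k, n, rho),
        bounds=PI_BOUNDS,
        method="bounded",
        options={"xatol": PI_TOL},
    )
    return float(res.x)


def estimate_rho(
    counts: pd.DataFrame,
    max_rho: float = 0.2,
    min_reads: int = 5,
    min_snps: int = 50,
    n_strata: int = 10,
) -> pd.Series:
    """Per-stratum overdispersion for one individual, null-anchored at pi = 0.5.

    ``counts`` holds one row per SNP with hap1_reads, hap2_reads and a
    ``cn_stratum`` column (copy-number decile, 1..n_strata). SNPs with
    total reads below ``min_reads`` are excluded. Strata with fewer than
    ``min_snps`` usable SNPs inherit the individual's global estimate.
    Returns a Series indexed 1..n_strata plus "global"; values capped at
    ``max_rho``.
    """
    df = counts.loc[(counts["hap1_reads"] + counts["hap2_reads"]) >= min_reads]
    if df.empty:
        raise ValueError("no usable SNPs for rho estimation")
    k = df["hap1_reads"].to_numpy(float)
    n = k + df["hap2_reads"].to_numpy(float)

    def mle(kk: np.ndarray, nn: np.ndarray) -> float:
        res = minimize_scalar(
            lambda r: -float(np.sum(betabin_loglik(kk, nn, pi=0.5, rho=r))),
            bounds=(1e-6, max_rho),
            method="bounded",
            options={"xatol": 1e-7},
        )
        return float(res.x)

    rho_global = mle(k, n)
    out = {}
    strata = df["cn_stratum"] if "cn_stratum" in df else pd.Series(1, index=df.index)
    for s in range(1, n_strata + 1):
        mask = (strata == s).to_numpy()
        if mask.sum() >= min_snps:
            out[s] = mle(k[mask], n[mask])
        else:
            out[s] = rho_global
    out["global"] = rho_global
    return pd.Series(out)


def build_rho_table(
    counts: pd.DataFrame, max_rho: float = 0.2, min_reads: int = 5, min_snps: int = 50
) -> pd.DataFrame:
    """Individual × copy-number-decile rho estimates (plus "global" column)."""
    rows = {}
    for ind, sub in counts.groupby("individual"):
        rows[ind] = estimate_rho(sub, max_rho=max_rho, min_reads=min_reads, min_snps=min_snps)
    return pd.DataFrame(rows).T


def _lookup_rho(rho_table: pd.DataFrame, individuals, strata) -> np.ndarray:
    out = np.empty(len(individuals))
    for i, (ind, s) in enumerate(zip(individuals, strata)):
        row = rho_table.loc[ind]
        out[i] = row[s] if s in row.index else row["global"]
    return out


def test_imbalance(k_alt, n_total, rho) -> tuple[float, float, float]:
    """LRT of pi = 0.5 vs free pi across individuals' counts at one SNP.

    Returns (pi_hat, lrt_statistic, p_value); chi-square with 1 df.
    """
    k = np.asarray(k_alt, dtype=float)
    n = np.asarray(n_total, dtype=float)
    pi_hat = fit_pi(k, n, rho)
    ll1 = _total_loglik(pi_hat, k, n, rho)
    ll0 = _total_loglik(0.5, k, n, rho)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lrt, df=1))
    return pi_hat, lrt, p


def test_differential_imbalance(
    k1, n1, rho1, k2, n2, rho2
) -> tuple[float, float, float, float]:
    """LRT of shared pi vs group-specific pi between two sample groups.

    Returns (pi1_hat, pi2_hat, lrt, p); chi-square with 1 df.
    """
    k1, n1 = np.asarray(k1, float), np.asarray(n1, float)
    k2, n2 = np.asarray(k2, float), np.asarray(n2, float)
    if n1.sum() <= 0 or n2.sum() <= 0:
        raise ValueError("both groups need reads at the peak")
    pi1 = fit_pi(k1, n1, rho1)
    pi2 = fit_pi(k2, n2, rho2)
    ll_sep = _total_loglik(pi1, k1, n1, rho1) + _total_loglik(pi2, k2, n2, rho2)
    res = minimize_scalar(
        lambda p: -(_total_loglik(p, k1, n1, rho1) + _total_loglik(p, k2, n2, rho2)),
        bounds=PI_BOUNDS,
        method="bounded",
        options={"xatol": PI_TOL},
    )
    ll_shared = -float(res.fun)
    lrt = max(0.0, 2.0 * (ll_sep - ll_shared))
    p = float(stats.chi2.sf(lrt, df=1))
    return pi1, pi2, lrt, p


def snp_tests(
    counts: pd.DataFrame,
    rho_table: pd.DataFrame,
    min_cov: int = 1,
    unit: str = "peak_sum",
) -> pd.DataFrame:
    """Per-SNP imbalance LRT.

    With ``unit="peak_sum"`` (the phasing-aware default) each
    individual's reads are summed per haplotype across the heterozygous
    SNPs of the peak, so every SNP of a peak is tested on the same
    peak-phased counts; ``unit="snp"`` tests each SNP on its own counts.
    SNPs where the pooled counts lack ``min_cov`` reads on either
    haplotype are skipped (at min_cov = 1: at least one read supporting
    each haplotype).
    """
    if unit not in {"peak_sum", "snp"}:
        raise ValueError(f"unknown unit {unit!r}")

    def run_test(sub: pd.DataFrame, per_individual: bool):
        if per_individual:
            agg = sub.groupby("individual")[["hap1_reads", "hap2_reads"]].sum()
            k = agg["hap1_reads"].to_numpy(float)
            n = k + agg["hap2_reads"].to_numpy(float)
            individuals = agg.index.to_numpy()
            strata = (
                sub.groupby("individual")["cn_stratum"].first().reindex(individuals).to_numpy()
                if "cn_stratum" in sub
                else np.ones(len(individuals), dtype=int)
            )
        else:
            k = sub["hap1_reads"].to_numpy(float)
            n = k + sub["hap2_reads"].to_numpy(float)
            individuals = sub["individual"].to_numpy()
            strata = (
                sub["cn_stratum"].to_numpy()
                if "cn_stratum" in sub
                else np.ones(len(individuals), dtype=int)
            )
        keep = n >= min_cov
        if not keep.any() or k[keep].sum() < min_cov or (n - k)[keep].sum() < min_cov:
            return None
        rho = _lookup_rho(rho_table, individuals[keep], strata[keep])
        pi_hat, lrt, p = test_imbalance(k[keep], n[keep], rho)
        return pi_hat, lrt, p, int(keep.sum()), float(n[keep].sum())

    rows = []
    for peak_id, peak_sub in counts.groupby("peak_id", sort=True):
        peak_stats = run_test(peak_sub, per_individual=True) if unit == "peak_sum" else None
        for snp_id, sub in peak_sub.groupby("snp_id", sort=True):
            stats_tuple = peak_stats if unit == "peak_sum" else run_test(sub, per_individual=False)
            if stats_tuple is None:
                continue
            pi_hat, lrt, p, n_ind, n_reads = stats_tuple
            rows.append(
                {
                    "peak_id": peak_id,
                    "snp_id": snp_id,
                    "pi_hat": pi_hat,
                    "lrt": lrt,
                    "pvalue": p,
                    "n_individuals": n_ind,
                    "total_reads": n_reads,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_id",
            "snp_id",
            "pi_hat",
            "lrt",
            "pvalue",
            "n_individuals",
            "total_reads",
        ],
    )


def peak_level_significance(snp_results: pd.DataFrame, q_max: float = 0.05) -> pd.DataFrame:
    """Bonferroni within peaks, BH q-values across peaks.

    Peak p = min(1, m * min SNP p) with m = number of SNPs tested in the
    peak; the best SNP is recorded. Peaks with q < ``q_max`` are flagged
    imbalanced.
    """
    if snp_results.empty:
        return pd.DataFrame(
            columns=["peak_id", "best_snp_id", "pi_hat", "n_snps", "bonferroni_p", "q_value", "imbalanced"]
        ).set_index("peak_id")
    rows = []
    for peak_id, sub in snp_results.groupby("peak_id"):
        m = len(sub)
        best = sub.loc[sub["pvalue"].idxmin()]
        rows.append(
            {
                "peak_id": peak_id,
                "best_snp_id": best["snp_id"],
                "pi_hat": best["pi_hat"],
                "n_snps": m,
                "bonferroni_p": min(1.0, m * best["pvalue"]),
            }
        )
    out = pd.DataFrame(rows).set_index("peak_id")
    out["q_value"] = bh_adjust(out["bonferroni_p"].to_numpy())
    out["imbalanced"] = out["q_value"] < q_max
    return out


def differential_peak_tests(
    counts: pd.DataFrame,
    group_of: pd.Series,
    rho_table: pd.DataFrame,
    group1: str,
    group2: str,
    min_cov: int = 1,
) -> pd.DataFrame:
    """Per-peak differential-imbalance LRT between two histology groups.

    Counts are summed per individual per haplotype within the peak
    (phasing makes the sums haplotype-consistent), then individuals are
    split by group and the shared-vs-separate pi LRT is applied.
    """
    groups = group_of.reindex(counts["individual"]).to_numpy()
    rows = []
    for peak_id, sub in counts.assign(_grp=groups).groupby("peak_id"):
        agg = sub.groupby(["individual", "_grp"], observed=True)[
            ["hap1_reads", "hap2_reads"]
        ].sum().reset_index()
        strata = (
            sub.groupby("individual")["cn_stratum"].first()
            if "cn_stratum" in sub
            else pd.Series(1, index=agg["individual"].unique())
        )
        g1 = agg[agg["_grp"] == group1]
        g2 = agg[agg["_grp"] == group2]
        n1 = (g1["hap1_reads"] + g1["hap2_reads"]).to_numpy(float)
        n2 = (g2["hap1_reads"] + g2["hap2_reads"]).to_numpy(float)
        if n1.sum() < min_cov or n2.sum() < min_cov:
            rows.append({"peak_id": peak_id, "pi_g1": np.nan, "pi_g2": np.nan, "diff_p": np.nan})
            continue
        rho1 = _lookup_rho(rho_table, g1["individual"].to_numpy(), strata.reindex(g1["individual"]).to_numpy())
        rho2 = _lookup_rho(rho_table, g2["individual"].to_numpy(), strata.reindex(g2["individual"]).to_numpy())
        pi1, pi2, _, p = test_differential_imbalance(
            g1["hap1_reads"].to_numpy(float), n1, rho1,
            g2["hap1_reads"].to_numpy(float), n2, rho2,
        )
        rows.append({"peak_id": peak_id, "pi_g1": pi1, "pi_g2": pi2, "diff_p": p})
    out = pd.DataFrame(rows).set_index("peak_id")
    out["diff_padj"] = bh_adjust(out["diff_p"].to_numpy())
    return out


def classify_group_specific(
    ai_g1: pd.DataFrame,
    ai_g2: pd.DataFrame,
    diff: pd.DataFrame,
    diff_alpha: float = 0.05,
    label_g1: str = "ccRCC",
    label_g2: str = "pRCC",
) -> pd.Series:
    """Label peaks as group-specific, shared, or none.

    A peak is ``label_g1``-specific iff (1) significantly imbalanced in
    group 1, (2) significantly differentially imbalanced between groups,
    and (3) not significantly imbalanced in group 2 alone (mirrored for
    group 2). Imbalanced in both without differential significance is
    "shared"; neither is "none".
    """
    universe = ai_g1.index.union(ai_g2.index)
    imb1 = ai_g1["imbalanced"].reindex(universe, fill_value=False)
    imb2 = ai_g2["imbalanced"].reindex(universe, fill_value=False)
    sig_diff = (diff["diff_padj"] < diff_alpha).reindex(universe, fill_value=False)
    labels = pd.Series("none", index=universe, dtype=object)
    labels[imb1 | imb2] = "shared"
    labels[imb1 & sig_diff & ~imb2] = f"{label_g1}-specific"
    labels[imb2 & sig_diff & ~imb1] = f"{label_g2}-specific"
    return labels


def assign_snps_to_peaks(counts: pd.DataFrame, peak_universe) -> pd.DataFrame:
    """Attach a ``peak_id`` column by locating each SNP inside a consensus peak.

    ``peak_universe`` is a PeakSet of disjoint regions (e.g. the 50-bp
    window consensus). SNP positions are 0-based. SNPs falling outside
    every peak are dropped.
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    names: dict[str, list[str]] = {}
    for p in peak_universe:
        c = p.interval.chrom
        starts.setdefault(c, []).append(p.interval.start)  # type: ignore[union-attr]
        ends.setdefault(c, []).append(p.interval.end)  # type: ignore[union-attr]
        names.setdefault(c, []).append(f"{c}:{p.interval.start}-{p.interval.end}")
    for c in starts:
        starts[c] = np.asarray(starts[c])
        ends[c] = np.asarray(ends[c])
    peak_ids = []
    for chrom, pos in zip(counts["chrom"], counts["pos"]):
        pid = None
        if chrom in starts:
            j = int(np.searchsorted(starts[chrom], pos, side="right")) - 1
            if j >= 0 and pos < ends[chrom][j]:
                pid = names[chrom][j]
        peak_ids.append(pid)
    out = counts.copy()
    out["peak_id"] = peak_ids
    return out.dropna(subset=["peak_id"])


def read_allelic_counts(path) -> pd.DataFrame:
    """Read the allelic-counts TSV (snp_id, chrom, pos, individual,
    hap1_reads, hap2_reads[, cn_stratum]); 1-based positions converted to
    0-based at this boundary."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"allelic counts file missing columns: {missing}")
    df["pos"] = df["pos"].astype(int) - 1
    return df
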