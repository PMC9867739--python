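"""GWAS risk-SNP enrichment in imbalanced peaks, allelic-imbalance ↔
allele-specific-expression linkage, and genotype-stratified signal tests.

Enrichment is estimated by permutation: the density of genome-wide
significant SNPs per base pair of the target (imbalanced) peaks is
compared with the densities over peak sets repeatedly drawn from the
full peak universe, optionally matched for number, peak size and
chromosome. The empiric one-sided p uses the add-one convention
(1 + #{background >= observed}) / (1 + n_iter), so it is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_genomics import PeakSet
from .stats import bh_adjust


@dataclass
class EnrichmentResult:
    observed_density: float
    background_densities: np.ndarray
    fold: float
    empiric_p: float
    n_iter: int


def read_gwas_catalog(path) -> pd.DataFrame:
    """GWAS catalog TSV: snp_id, chrom, pos (1-based), pheno, sig_flag."""
    df = pd.read_csv(path, sep="\t")
    required = {"snp_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"GWAS catalog needs columns {sorted(required)}")
    df["pos"] = df["pos"].astype(int) - 1
    if "sig_flag" in df.columns:
        df = df[df["sig_flag"].astype(bool)]
    return df


def _count_overlapping_snps(snps: pd.DataFrame, peaks: PeakSet) -> int:
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    from .core_genomics import merge_intervals

    for iv in merge_intervals(peaks.intervals()):
        starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[union-attr]
        ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[union-attr]
    for c in starts:
        starts[c] = np.asarray(starts[c])
        ends[c] = np.asarray(ends[c])
    count = 0
    for chrom, pos in zip(snps["chrom"], snps["pos"]):
        if chrom not in starts:
            continue
        j = int(np.searchsorted(starts[chrom], pos, side="right")) - 1
        if j >= 0 and pos < ends[chrom][j]:
            count += 1
    return count


def snp_density(snps: pd.DataFrame, peaks: PeakSet) -> float:
    """Genome-wide significant SNPs overlapping the peaks, per base pair of
    the peak union."""
    bp = peaks.total_bp()
    if bp == 0:
        raise ValueError("peak set covers zero base pairs")
    return _count_overlapping_snps(snps, peaks) / bp


def permutation_enrichment(
    snps: pd.DataFrame,
    target_peaks: PeakSet,
    universe_peaks: PeakSet,
    n_iter: int = 10000,
    matched: bool = False,
    size_bins: int = 10,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Permutation enrichment of SNP density in targets vs sampled background.

    Each iteration samples |targets| peaks without replacement from the
    universe; in matched mode sampling is stratified by chromosome and
    target-width decile (falling back to the nearest non-empty size bin
    with a warning when a stratum is exhausted). fold = observed density /
    mean background density.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = snp_density(snps, target_peaks)

    uni = list(universe_peaks)
    widths = np.array([p.interval.width for p in uni])
    chroms = np.array([p.interval.chrom for p in uni])
    # precompute per-peak SNP counts once; background density then needs no
    # re-sweep per iteration
    per_peak_counts = np.array(
        [_count_overlapping_snps(snps, PeakSet([p])) for p in uni]
    )

    if matched:
        t_widths = np.array([p.interval.width for p in target_peaks])
        bin_edges = np.quantile(t_widths, np.linspace(0, 1, size_bins + 1))
        bin_edges[0], bin_edges[-1] = -np.inf, np.inf
        uni_bins = np.digitize(widths, bin_edges[1:-1])
        strata: list[tuple[np.ndarray, int]] = []
        import warnings as _warnings

        for p in target_peaks:
            want_bin = int(np.digitize([p.interval.width], bin_edges[1:-1])[0])
            pool = np.flatnonzero((chroms == p.interval.chrom) & (uni_bins == want_bin))
            if len(pool) == 0:
                # nearest non-empty size bin on the same chromosome
                chrom_pool = np.flatnonzero(chroms == p.interval.chrom)
                if len(chrom_pool) == 0:
                    raise ValueError(
                        f"universe has no peaks on {p.interval.chrom} for matching"
                    )
                _warnings.warn(
                    f"size bin {want_bin} empty on {p.interval.chrom}; "
                    "falling back to nearest bin"
                )
                order = np.argsort(np.abs(uni_bins[chrom_pool] - want_bin), kind="stable")
                nearest = uni_bins[chrom_pool][order[0]]
                pool = chrom_pool[uni_bins[chrom_pool] == nearest]
            strata.append((pool, want_bin))

    bg = np.empty(n_iter)
    n_targets = len(target_peaks)
    for it in range(n_iter):
        if matched:
            chosen: list[int] = []
            taken: set[int] = set()
            for pool, _ in strata:
                avail = [i for i in pool if i not in taken]
                pick = int(rng.choice(avail)) if avail else int(rng.choice(pool))
                chosen.append(pick)
                taken.add(pick)
            idx = np.array(chosen)
        else:
            idx = rng.choice(len(uni), size=n_targets, replace=False)
        bp = int(widths[idx].sum())  # sampled peaks may overlap; widths summed
        bg[it] = per_peak_counts[idx].sum() / bp
    fold = observed / bg.mean() if bg.mean() > 0 else np.inf
    empiric_p = (1 + int(np.sum(bg >= observed))) / (1 + n_iter)
    return EnrichmentResult(observed, bg, float(fold), float(empiric_p), n_iter)


def ase_gene_test(
    gene_hap_counts: pd.DataFrame, padj_max: float = 0.01, min_reads: int = 1
) -> pd.DataFrame:
    """Two-sided binomial test of allele-specific expression per gene.

    ``gene_hap_counts`` has columns gene, hap1_reads, hap2_reads (counts
    already summed across samples). Genes below ``min_reads`` total are
    excluded. ASE iff BH-adjusted p < ``padj_max``.
    """
    agg = gene_hap_counts.groupby("gene")[["hap1_reads", "hap2_reads"]].sum()
    total = agg["hap1_reads"] + agg["hap2_reads"]
    agg = agg[total >= max(min_reads, 1)]
    total = total[agg.index]
    pvals = np.array(
        [
            stats.binomtest(int(k), int(n), 0.5).pvalue
            for k, n in zip(agg["hap1_reads"], total)
        ]
    )
    out = agg.copy()
    out["pvalue"] = pvals
    out["padj"] = bh_adjust(pvals)
    out["ase"] = out["padj"] < padj_max
    return out


def link_ai_to_ase(
    snp_positions: pd.DataFrame,
    ase_genes: set[str],
    tss: list,
    window_bp: int = 50000,
) -> dict:
    """2×2 association between chromatin allelic imbalance at SNPs and
    nearby allele-specific expression.

    ``snp_positions`` needs columns chrom, pos, imbalanced (bool). A SNP
    is "near ASE" iff some ASE gene's TSS lies within ``window_bp``.
    Returns the table, both proportions, odds ratio and two-sided Fisher
    exact p.
    """
    if snp_positions["imbalanced"].all() or (~snp_positions["imbalanced"]).all():
        raise ValueError("need both imbalanced and balanced SNPs")
    ase_tss: dict[str, list[int]] = {}
    for t in tss:
        if t.gene in ase_genes:
            ase_tss.setdefault(t.tss.chrom, []).append(t.tss.start)
    for c in ase_tss:
        ase_tss[c] = np.asarray(sorted(ase_tss[c]))  # type: ignore[assignment]
    near = []
    for chrom, pos in zip(snp_positions["chrom"], snp_positions["pos"]):
        arr = ase_tss.get(chrom)
        if arr is None or len(arr) == 0:
            near.append(False)
            continue
        j = int(np.searchsorted(arr, pos))
        dist = min(
            abs(int(arr[j]) - pos) if j < len(arr) else np.inf,
            abs(int(arr[j - 1]) - pos) if j > 0 else np.inf,
        )
        near.append(dist <= window_bp)
    near = np.asarray(near)
    imb = snp_positions["imbalanced"].to_numpy(bool)
    table = np.array(
        [
            [int((imb & near).sum()), int((imb & ~near).sum())],
            [int((~imb & near).sum()), int((~imb & ~near).sum())],
        ]
    )
    return contingency_summary(table)


def contingency_summary(table: np.ndarray) -> dict:
    """Proportions, odds ratio and two-sided Fisher exact p for a 2×2 table
    with rows = {imbalanced, balanced} and columns = {near ASE, not}."""
    table = np.asarray(table, dtype=float)
    a, b = table[0]
    c, d = table[1]
    prop_imbalanced = a / (a + b) if a + b else np.nan
    prop_balanced = c / (c + d) if c + d else np.nan
    if b * c == 0:
        odds_ratio = np.inf if a * d > 0 else np.nan
    else:
        odds_ratio = (a * d) / (b * c)
    fisher_p = stats.fisher_exact(table.astype(int), alternative="two-sided")[1]
    chi2_p = stats.chi2_contingency(table.astype(int), correction=False)[1] if table.min() >= 0 else np.nan
    return {
        "table": table.astype(int),
        "prop_imbalanced_near_ase": float(prop_imbalanced),
        "prop_balanced_near_ase": float(prop_balanced),
        "odds_ratio": float(odds_ratio),
        "fisher_p": float(fisher_p),
        "chi2_p": float(chi2_p),
    }


def genotype_signal_test(signal: np.ndarray, genotypes: np.ndarray) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) of per-sample signal across allele
    dosage groups; p from chi-square with (groups − 1) df."""
    signal = np.asarray(signal, dtype=float)
    genotypes = np.asarray(genotypes)
    groups = [signal[genotypes == g] for g in np.unique(genotypes)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 genotype groups")
    if all(np.all(g == groups[0][0]) for g in groups):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
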