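"""Master transcription-factor nomination.

Four lines of evidence are combined per TF and histology:

1. differential expression — one-sided Wilcoxon rank-sum of the TF's
   normalized expression in the query histology vs the rest, with a
   10-FPKM floor on the best histology's mean;
2. tissue specificity — a Jensen–Shannon-divergence score comparing the
   TF's mean expression profile across tumor types against an ideal
   one-hot profile (specificity = 1 − sqrt(JSD)); candidates sit in the
   top 5% of both specificity and query-type mean expression;
3. super-enhancer rank — ROSE-style peak stitching, rank–signal elbow
   calling, nearest-gene assignment, and a one-sided rank-sum on the
   per-sample minimum SE rank of each TF;
4. clique enrichment — mutual-motif auto-regulatory TF graphs restricted
   to open chromatin, maximal cliques, and the fraction of a sample's
   cliques containing each TF (CES), again compared one-sided between
   histologies.

A consensus master TF must be differentially expressed AND supported by
at least one of the other three analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .core_genomics import GenomicInterval, PeakSet, TssAnnotation
from .stats import bh_adjust, rank_sum_one_sided

# ---------------------------------------------------------------------------
# 1. Differential TF expression


def differential_tf_expression(
    expr: pd.DataFrame,
    sample_labels: pd.Series,
    histology: str,
    fdr_max: float = 0.1,
    log2fc_min: float = 1.0,
    min_fpkm: float = 10.0,
    min_tpm: float = 10.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One-sided rank-sum differential expression of TFs, query vs rest.

    TFs whose best per-histology mean expression is below ``min_fpkm``
    are excluded before testing. A TF passes iff FDR < ``fdr_max``,
    log2(mean_query + 1 / mean_rest + 1) >= ``log2fc_min``, and its
    query-histology mean is at least ``min_tpm``.
    """
    labels = sample_labels.reindex(expr.columns)
    q_cols = labels[labels == histology].index
    r_cols = labels[labels != histology].index
    if len(q_cols) < 2 or len(r_cols) < 2:
        raise ValueError("need >= 2 samples in the query group and the rest")
    hist_means = expr.T.groupby(labels).mean().T  # TF x histology
    tested = hist_means.max(axis=1) >= min_fpkm
    mean_q = expr[q_cols].mean(axis=1)
    mean_r = expr[r_cols].mean(axis=1)
    log2fc = np.log2((mean_q + pseudocount) / (mean_r + pseudocount))
    pvals = pd.Series(np.nan, index=expr.index)
    for tf in expr.index[tested]:
        pvals[tf] = rank_sum_one_sided(
            expr.loc[tf, q_cols].to_numpy(), expr.loc[tf, r_cols].to_numpy()
        )
    fdr = pd.Series(bh_adjust(pvals.to_numpy()), index=expr.index)
    passes = (
        tested
        & (fdr < fdr_max)
        & (log2fc >= log2fc_min)
        & (mean_q >= min_tpm)
    )
    return pd.DataFrame(
        {
            "mean_query": mean_q,
            "mean_rest": mean_r,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "tested": tested,
            "de_pass": passes.fillna(False),
        }
    )


# ---------------------------------------------------------------------------
# 2. JSD specificity scores


def cacts_scores(
    mean_expr_by_type: pd.DataFrame,
    query_type: str,
    top_frac: float = 0.05,
    zero_replacement: float = 1e-17,
) -> pd.DataFrame:
    """Tumor-type specificity score per TF against an ideal one-hot profile.

    ``mean_expr_by_type`` is TF × tumor-type mean expression. Values are
    shifted so the global minimum is 0; per-TF profiles are normalized to
    sum 1 (exact zeros replaced by ``zero_replacement`` first); the
    base-2 Jensen–Shannon divergence to the one-hot profile at
    ``query_type`` gives jsd, and specificity = 1 − sqrt(jsd). Candidates
    are TFs in the top ``top_frac`` of both specificity and query-type
    mean expression (ties at the quantile boundary included).
    """
    if query_type not in mean_expr_by_type.columns:
        raise ValueError(f"query type {query_type!r} not in columns")
    if mean_expr_by_type.shape[1] < 2:
        raise ValueError("need at least 2 tumor types")
    shifted = mean_expr_by_type - mean_expr_by_type.min().min()
    if (shifted.values < 0).any():
        raise ValueError("negative values remain after shifting")
    profile = shifted.where(shifted > 0, zero_replacement)
    profile = profile.div(profile.sum(axis=1), axis=0)
    ideal = np.zeros(shifted.shape[1])
    ideal[list(shifted.columns).index(query_type)] = 1.0
    jsd = np.array(
        [jensenshannon(row, ideal, base=2) ** 2 for row in profile.to_numpy()]
    )
    jsd = np.clip(np.nan_to_num(jsd), 0.0, 1.0)
    specificity = 1.0 - np.sqrt(jsd)
    mean_expr = shifted[query_type]
    spec_cut = np.quantile(specificity, 1 - top_frac)
    expr_cut = mean_expr.quantile(1 - top_frac)
    candidates = (specificity >= spec_cut) & (mean_expr >= expr_cut).to_numpy()
    return pd.DataFrame(
        {
            "jsd_divergence": jsd,
            "specificity_score": specificity,
            "mean_expression": mean_expr,
            "cacts_candidate": candidates,
        },
        index=mean_expr_by_type.index,
    )


# ---------------------------------------------------------------------------
# 3. ROSE-style super-enhancer calling


@dataclass
class StitchedRegion:
    interval: GenomicInterval
    total_signal: float
    n_peaks: int
    rank: int = 0
    is_super: bool = False
    assigned_gene: str | None = None


def stitch_peaks(
    peaks: PeakSet,
    stitch_bp: int = 12500,
    tss_exclusion_bp: int = 0,
    tss: list[TssAnnotation] | None = None,
) -> list[StitchedRegion]:
    """Merge peaks whose gap is <= ``stitch_bp`` transitively per chromosome.

    Peak scores are summed into the region's total signal. With
    ``tss_exclusion_bp`` > 0, peaks within that distance of a TSS are
    removed before stitching.
    """
    kept = list(peaks)
    if tss_exclusion_bp > 0 and tss:
        tss_by_chrom: dict[str, list[int]] = {}
        for t in tss:
            tss_by_chrom.setdefault(t.tss.chrom, []).append(t.tss.start)
        kept = [
            p
            for p in kept
            if not any(
                abs(p.interval.midpoint - pos) <= tss_exclusion_bp
                for pos in tss_by_chrom.get(p.interval.chrom, ())
            )
        ]
    out: list[StitchedRegion] = []
    by_chrom: dict[str, list] = {}
    for p in kept:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom], key=lambda p: (p.interval.start, p.interval.end))
        cur_s, cur_e = ps[0].interval.start, ps[0].interval.end
        cur_sig, cur_n = ps[0].score, 1
        for p in ps[1:]:
            if p.interval.start - cur_e <= stitch_bp:
                cur_e = max(cur_e, p.interval.end)
                cur_sig += p.score
                cur_n += 1
            else:
                out.append(StitchedRegion(GenomicInterval(chrom, cur_s, cur_e), cur_sig, cur_n))
                cur_s, cur_e, cur_sig, cur_n = p.interval.start, p.interval.end, p.score, 1
        out.append(StitchedRegion(GenomicInterval(chrom, cur_s, cur_e), cur_sig, cur_n))
    return out


def rose_cutoff(signals: np.ndarray) -> float:
    """Signal cutoff at the rank–signal elbow (slope-1 tangent convention).

    Signals are sorted ascending and plotted against rank index; the
    reference slope is (max − min) / n (slope 1 after rescaling both axes
    to the unit square). The cutoff is the signal at the point whose
    slope-matched tangent line leaves the fewest points below it —
    found by brute force over every candidate point.
    """
    y = np.sort(np.asarray(signals, dtype=float))
    n = len(y)
    slope = (y[-1] - y[0]) / n
    x = np.arange(1, n + 1)
    best_count, best_x = None, None
    for i in range(n):
        b = y[i] - slope * x[i]
        count = int(np.sum(y <= slope * x + b))
        if best_count is None or count < best_count:
            best_count, best_x = count, i
    return float(y[best_x])


def call_superenhancers(regions: list[StitchedRegion]) -> list[StitchedRegion]:
    """Rank stitched regions by signal and flag super-enhancers.

    Rank 1 = highest signal. Regions with signal strictly above the elbow
    cutoff are super-enhancers; if all signals are equal no region is
    flagged (with a warning).
    """
    if len(regions) < 3:
        raise ValueError("need at least 3 regions to place a cutoff")
    signals = np.array([r.total_signal for r in regions])
    order = np.argsort(-signals, kind="stable")
    for rank0, idx in enumerate(order):
        regions[idx].rank = rank0 + 1
    if np.allclose(signals, signals[0]):
        warnings.warn("constant signal across regions; no super-enhancers called")
        for r in regions:
            r.is_super = False
        return regions
    cutoff = rose_cutoff(signals)
    for r in regions:
        r.is_super = r.total_signal > cutoff
    return regions


def assign_se_to_gene(
    regions: list[StitchedRegion], tss: list[TssAnnotation]
) -> list[StitchedRegion]:
    """Assign each region the gene whose TSS is nearest its midpoint.

    Ties break toward the smaller genomic coordinate; chromosomes with no
    TSS leave the region unassigned (with a warning).
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for t in tss:
        by_chrom.setdefault(t.tss.chrom, []).append((t.tss.start, t.gene))
    for c in by_chrom:
        by_chrom[c].sort()
    warned: set[str] = set()
    for r in regions:
        cands = by_chrom.get(r.interval.chrom)
        if not cands:
            if r.interval.chrom not in warned:
                warnings.warn(f"no TSS on {r.interval.chrom}; regions left unassigned")
                warned.add(r.interval.chrom)
            r.assigned_gene = None
            continue
        mid = r.interval.midpoint
        best = min(cands, key=lambda pg: (abs(pg[0] - mid), pg[0]))
        r.assigned_gene = best[1]
    return regions


def tf_se_rank_matrix(
    per_sample_se: dict[str, list[StitchedRegion]], tf_list: list[str]
) -> tuple[pd.DataFrame, int]:
    """Per-TF, per-sample minimum SE rank; missing associations filled with
    the maximum SE rank observed across all samples. Only super-enhancer
    regions contribute."""
    fill = 0
    min_ranks: dict[str, dict[str, int]] = {s: {} for s in per_sample_se}
    for sample, regions in per_sample_se.items():
        for r in regions:
            if not r.is_super or r.assigned_gene is None:
                continue
            fill = max(fill, r.rank)
            g = r.assigned_gene
            if g in tf_list:
                prev = min_ranks[sample].get(g)
                min_ranks[sample][g] = r.rank if prev is None else min(prev, r.rank)
    if fill == 0:
        fill = 1
    mat = pd.DataFrame(
        {s: {tf: min_ranks[s].get(tf, fill) for tf in tf_list} for s in per_sample_se}
    )
    return mat, fill


def differential_se_rank(
    rank_matrix: pd.DataFrame,
    sample_labels: pd.Series,
    histology: str,
    mean_rank_max: float = 1000.0,
    fdr_max: float = 0.10,
) -> pd.DataFrame:
    """One-sided rank-sum of SE ranks, query histology LOWER than the rest.

    TFs whose overall mean rank exceeds ``mean_rank_max`` are excluded
    before testing; pass iff FDR <= ``fdr_max``.
    """
    labels = sample_labels.reindex(rank_matrix.columns)
    q_cols = labels[labels == histology].index
    r_cols = labels[labels != histology].index
    if len(q_cols) < 2 or len(r_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    tested = rank_matrix.mean(axis=1) <= mean_rank_max
    pvals = pd.Series(np.nan, index=rank_matrix.index)
    for tf in rank_matrix.index[tested]:
        pvals[tf] = rank_sum_one_sided(
            rank_matrix.loc[tf, q_cols].to_numpy(),
            rank_matrix.loc[tf, r_cols].to_numpy(),
            alternative="less",
        )
    fdr = pd.Series(bh_adjust(pvals.to_numpy()), index=rank_matrix.index)
    return pd.DataFrame(
        {
            "mean_rank": rank_matrix.mean(axis=1),
            "pvalue": pvals,
            "fdr": fdr,
            "tested": tested,
            "se_pass": (tested & (fdr <= fdr_max)).fillna(False),
        }
    )


# ---------------------------------------------------------------------------
# 4. Clique enrichment


_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def pwm_log_odds(pwm: np.ndarray, background: float = 0.25) -> np.ndarray:
    """Column-stochastic PWM (w × 4, ACGT order) to log2-odds weights."""
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("PWM must be w x 4 (ACGT)")
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-3):
        raise ValueError("PWM rows must sum to 1")
    return np.log2(np.maximum(pwm, 1e-6) / background)


def scan_sequence(pwm: np.ndarray, seq: str, threshold: float) -> bool:
    """True iff the max log-odds score on either strand reaches threshold.

    Windows containing non-ACGT symbols are skipped (with a warning the
    first time).
    """
    lo = pwm_log_odds(pwm)
    w = lo.shape[0]
    warned = False
    for s in (seq.upper(), seq.upper().translate(_COMPLEMENT)[::-1]):
        if len(s) < w:
            continue
        idx = np.array([_BASE_INDEX.get(c, -1) for c in s])
        bad = idx < 0
        if bad.any() and not warned:
            warnings.warn("non-ACGT symbols in sequence; affected windows skipped")
            warned = True
        idx_safe = np.where(bad, 0, idx)
        scores = np.zeros(len(s) - w + 1)
        valid = np.ones(len(s) - w + 1, dtype=bool)
        for offset in range(w):
            window_idx = idx_safe[offset : offset + len(scores)]
            scores += lo[offset, window_idx]
            valid &= ~bad[offset : offset + len(scores)]
        if valid.any() and scores[valid].max() >= threshold:
            return True
    return False


def scan_motifs(
    pwms: dict[str, np.ndarray],
    region_sequences: dict[str, str],
    threshold: float | dict[str, float],
) -> set[tuple[str, str]]:
    """All (TF, region) pairs where the TF's motif hits the region sequence.

    ``threshold`` may be a single log-odds cutoff or a per-TF mapping.
    Restricting to open chromatin is the caller's concern: pass only the
    sequences of SE ∩ ATAC-consensus regions.
    """
    hits: set[tuple[str, str]] = set()
    for tf, pwm in pwms.items():
        thr = threshold[tf] if isinstance(threshold, dict) else threshold
        for region_id, seq in region_sequences.items():
            if scan_sequence(pwm, seq, thr):
                hits.add((tf, region_id))
    return hits


def build_clique_graph(
    hits: set[tuple[str, str]],
    se_region_of_tf: dict[str, str],
    expressed_tfs: set[str],
) -> nx.Graph:
    """Undirected auto-regulatory graph for one sample.

    Nodes are TFs that are expressed, SE-associated (appear in
    ``se_region_of_tf``), and self-regulating (their own motif occurs in
    their own SE region). Edge {a, b} requires mutual motif occurrence:
    a's motif in b's region and b's in a's.
    """
    nodes = [
        tf
        for tf, region in se_region_of_tf.items()
        if tf in expressed_tfs and (tf, region) in hits
    ]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if (a, se_region_of_tf[b]) in hits and (b, se_region_of_tf[a]) in hits:
                g.add_edge(a, b)
    return g


def enumerate_cliques(graph: nx.Graph) -> list[frozenset[str]]:
    """Maximal cliques of size >= 2 (Bron–Kerbosch with pivoting)."""
    return [frozenset(c) for c in nx.find_cliques(graph) if len(c) >= 2]


def ces(cliques: list[frozenset[str]], tf_list: list[str]) -> pd.Series:
    """Clique enrichment score: fraction of cliques containing each TF."""
    out = pd.Series(0.0, index=pd.Index(tf_list, name="tf"))
    if not cliques:
        return out
    for tf in tf_list:
        out[tf] = sum(tf in c for c in cliques) / len(cliques)
    return out


def differential_ces(
    ces_matrix: pd.DataFrame,
    sample_labels: pd.Series,
    histology: str,
    min_ces: float = 0.05,
    fdr_max: float = 0.1,
) -> pd.DataFrame:
    """One-sided Mann–Whitney of CES, query histology vs the rest.

    TFs with average CES below ``min_ces`` in the query histology are
    excluded; pass iff FDR < ``fdr_max``.
    """
    labels = sample_labels.reindex(ces_matrix.columns)
    q_cols = labels[labels == histology].index
    r_cols = labels[labels != histology].index
    if len(q_cols) < 2 or len(r_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    tested = ces_matrix[q_cols].mean(axis=1) >= min_ces
    pvals = pd.Series(np.nan, index=ces_matrix.index)
    for tf in ces_matrix.index[tested]:
        pvals[tf] = rank_sum_one_sided(
            ces_matrix.loc[tf, q_cols].to_numpy(), ces_matrix.loc[tf, r_cols].to_numpy()
        )
    fdr = pd.Series(bh_adjust(pvals.to_numpy()), index=ces_matrix.index)
    return pd.DataFrame(
        {
            "mean_ces_query": ces_matrix[q_cols].mean(axis=1),
            "pvalue": pvals,
            "fdr": fdr,
            "tested": tested,
            "ces_pass": (tested & (fdr < fdr_max)).fillna(False),
        }
    )


# ---------------------------------------------------------------------------
# Consensus


def nominate_master_tfs(
    de: pd.DataFrame,
    cacts: pd.DataFrame,
    se_rank: pd.DataFrame,
    ces_res: pd.DataFrame,
) -> pd.DataFrame:
    """Integrate the four analyses for one histology.

    consensus_master iff de_pass AND (cacts_candidate OR se_pass OR
    ces_pass); evidence_count counts the passing analyses.
    """
    universe = de.index
    for other, col in ((cacts, "cacts_candidate"), (se_rank, "se_pass"), (ces_res, "ces_pass")):
        if not universe.sort_values().equals(other.index.sort_values()):
            raise ValueError("analyses cover mismatched TF universes")
    out = pd.DataFrame(
        {
            "de_significant": de["de_pass"].astype(bool),
            "cacts_candidate": cacts["cacts_candidate"].reindex(universe).astype(bool),
            "se_rank_significant": se_rank["se_pass"].reindex(universe).astype(bool),
            "ces_significant": ces_res["ces_pass"].reindex(universe).astype(bool),
        },
        index=universe,
    )
    out["evidence_count"] = out.sum(axis=1)
    out["consensus_master"] = out["de_significant"] & (
        out["cacts_candidate"] | out["se_rank_significant"] | out["ces_significant"]
    )
    return out


# ---------------------------------------------------------------------------
# MEME minimal motif I/O


def write_meme(pwms: dict[str, np.ndarray], path) -> None:
    """Write PWMs in MEME minimal motif format (ACGT, uniform background)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for name, pwm in pwms.items():
            pwm = np.asarray(pwm, dtype=float)
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.shape[0]} nsites= 10000 E= 0\n"
            )
            for row in pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> dict[str, np.ndarray]:
    """Read MEME minimal motifs into name -> (w × 4) probability matrices."""
    from Bio import motifs

    with open(path) as fh:
        records = motifs.parse(fh, "minimal")
    out: dict[str, np.ndarray] = {}
    for m in records:
        pwm = np.column_stack([m.pwm[base] for base in "ACGT"])
        out[m.name] = pwm
    return out
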