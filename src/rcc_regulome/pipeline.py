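"""End-to-end orchestration of the analysis stages on a cohort bundle.

Each function runs one stage of the study on a (typically simulated)
cohort and returns plain pandas objects; the numbered analysis scripts
and the acceptance checks are thin wrappers over these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import allelic_imbalance as ai
from . import differential_peaks as dp
from . import master_tf as mtf
from . import risk_annotation as risk
from .core_genomics import PeakSet, window_consensus
from .synthetic_data import HISTOLOGIES, SimBundle


# ---------------------------------------------------------------------------
# Differential enhancers


def run_differential_peaks(
    bundle: SimBundle, padj_max: float = 0.001, log2fc_min: float = 3.0
):
    """One-vs-rest NB tests for every histology and the specific/common
    labelling. Returns (per-histology results, peak labels)."""
    m = dp.CountMatrix(bundle.counts, bundle.sample_labels, bundle.libsizes)
    results = {h: dp.nb_differential(m, h) for h in HISTOLOGIES}
    labels = dp.call_histology_specific(results, padj_max=padj_max, log2fc_min=log2fc_min)
    return results, labels


def specific_peak_recovery(labels: pd.Series, truth_labels: pd.Series) -> dict:
    """Recall/precision of planted histology-specific peaks."""
    planted = truth_labels[truth_labels != "common"]
    called = labels[labels != "common"]
    correct = (labels.reindex(planted.index) == planted).sum()
    recall = correct / len(planted) if len(planted) else np.nan
    precision = (
        (truth_labels.reindex(called.index) == called).sum() / len(called)
        if len(called)
        else np.nan
    )
    return {"recall": float(recall), "precision": float(precision),
            "n_planted": int(len(planted)), "n_called": int(len(called))}


# ---------------------------------------------------------------------------
# Master TFs


def run_master_tf(bundle: SimBundle, expressed_min_fpkm: float = 10.0) -> dict[str, pd.DataFrame]:
    """Run the four nomination analyses and the consensus per histology."""
    # per-sample SE calls
    per_sample_se: dict[str, list] = {}
    for sample in bundle.sample_ids:
        regions = mtf.stitch_peaks(bundle.chip_peaksets[sample])
        regions = mtf.call_superenhancers(regions)
        regions = mtf.assign_se_to_gene(regions, bundle.tss)
        per_sample_se[sample] = regions
    rank_matrix, fill = mtf.tf_se_rank_matrix(per_sample_se, bundle.tf_list)

    # per-sample clique graphs restricted to motif-annotated, SE-associated,
    # expressed TFs
    thresholds = {
        tf: 0.8 * float(np.max(mtf.pwm_log_odds(pwm).max(axis=1).sum()))
        for tf, pwm in bundle.pwms.items()
    }
    ces_cols = {}
    for sample in bundle.sample_ids:
        seqs = bundle.se_sequences[sample]
        super_genes = {
            r.assigned_gene for r in per_sample_se[sample] if r.is_super and r.assigned_gene
        }
        se_region_of_tf = {tf: tf for tf in seqs if tf in super_genes}
        expressed = set(
            bundle.expression.index[bundle.expression[sample] >= expressed_min_fpkm]
        )
        hits = mtf.scan_motifs(bundle.pwms, {t: seqs[t] for t in se_region_of_tf}, thresholds)
        graph = mtf.build_clique_graph(hits, se_region_of_tf, expressed)
        cliques = mtf.enumerate_cliques(graph)
        ces_cols[sample] = mtf.ces(cliques, bundle.tf_list)
    ces_matrix = pd.DataFrame(ces_cols)

    out = {}
    for h in HISTOLOGIES:
        de = mtf.differential_tf_expression(bundle.expression, bundle.sample_labels, h)
        cacts = mtf.cacts_scores(bundle.pan_cancer_means, h)
        se = mtf.differential_se_rank(rank_matrix, bundle.sample_labels, h)
        ces_res = mtf.differential_ces(ces_matrix, bundle.sample_labels, h)
        out[h] = mtf.nominate_master_tfs(de, cacts, se, ces_res)
    out["se_rank_matrix"] = rank_matrix
    out["se_rank_fill"] = fill
    out["ces_matrix"] = ces_matrix
    return out


def master_tf_recovery(nominations: dict, truth_masters: dict[str, str]) -> dict:
    """Sensitivity and false-nomination rate of consensus master TF calls."""
    tp = fn = fp = 0
    nominated_total = 0
    for h in HISTOLOGIES:
        table = nominations[h]
        called = set(table.index[table["consensus_master"]])
        planted = {tf for tf, hh in truth_masters.items() if hh == h}
        tp += len(called & planted)
        fn += len(planted - called)
        fp += len(called - planted)
        nominated_total += len(called)
    sensitivity = tp / (tp + fn) if tp + fn else np.nan
    false_rate = fp / nominated_total if nominated_total else 0.0
    return {
        "sensitivity": float(sensitivity),
        "false_nomination_rate": float(false_rate),
        "n_planted": tp + fn,
        "n_nominated": nominated_total,
    }


# ---------------------------------------------------------------------------
# Allelic imbalance


def run_allelic_imbalance(bundle: SimBundle, q_max: float = 0.05) -> dict:
    """Consensus peak universe, per-group and combined stratAS-style tests,
    differential imbalance, and group-specific classification."""
    chip_samples = [
        s for s in bundle.sample_ids if bundle.sample_labels[s] in ("ccRCC", "pRCC")
    ]
    universe = window_consensus(
        [bundle.chip_peaksets[s] for s in chip_samples], window_bp=50, min_samples=2
    )
    counts = ai.assign_snps_to_peaks(bundle.allelic_counts, universe)
    rho_table = ai.build_rho_table(counts)
    group_of = bundle.ai_individual_groups

    results: dict[str, pd.DataFrame] = {}
    for h in ("ccRCC", "pRCC"):
        sub = counts[counts["individual"].map(group_of) == h]
        results[h] = ai.peak_level_significance(ai.snp_tests(sub, rho_table), q_max=q_max)
    results["combined"] = ai.peak_level_significance(ai.snp_tests(counts, rho_table), q_max=q_max)
    diff = ai.differential_peak_tests(counts, group_of, rho_table, "ccRCC", "pRCC")
    labels = ai.classify_group_specific(results["ccRCC"], results["pRCC"], diff)
    return {
        "universe": universe,
        "counts": counts,
        "rho_table": rho_table,
        "per_group": results,
        "differential": diff,
        "labels": labels,
    }


def map_planted_peaks_to_universe(bundle: SimBundle, universe: PeakSet) -> pd.Series:
    """Map each planted SNP-bearing peak id to the consensus region holding it."""
    snp_positions = bundle.allelic_counts.groupby("true_peak_id").first()[["chrom", "pos"]]
    snp_positions = snp_positions.reset_index().rename(columns={"true_peak_id": "peak_id"})
    mapped = ai.assign_snps_to_peaks(
        snp_positions.assign(snp_id=snp_positions["peak_id"], individual="x",
                             hap1_reads=0, hap2_reads=0),
        universe,
    )
    return mapped.set_index("snp_id")["peak_id"]


def ai_recovery(bundle: SimBundle, ai_out: dict) -> dict:
    """Recall of planted imbalanced peaks in the matching group analysis
    (shared peaks count if either group detects them)."""
    mapping = map_planted_peaks_to_universe(bundle, ai_out["universe"])
    truth = bundle.truth.ai_peak_classes
    per_group = ai_out["per_group"]

    def detected(group: str, planted_id: str) -> bool:
        region = mapping.get(planted_id)
        if region is None or region not in per_group[group].index:
            return False
        return bool(per_group[group].loc[region, "imbalanced"])

    tp = total = 0
    for planted_id, cls in truth.items():
        if cls == "balanced":
            continue
        total += 1
        if cls == "shared":
            hit = detected("ccRCC", planted_id) or detected("pRCC", planted_id)
        elif cls == "ccRCC-specific":
            hit = detected("ccRCC", planted_id)
        else:
            hit = detected("pRCC", planted_id)
        tp += hit
    balanced_ids = truth.index[truth == "balanced"]
    fp = 0
    n_bal = 0
    for planted_id in balanced_ids:
        region = mapping.get(planted_id)
        if region is None:
            continue
        n_bal += 1
        for g in ("ccRCC", "pRCC"):
            if region in per_group[g].index and per_group[g].loc[region, "imbalanced"]:
                fp += 1
                break
    return {
        "recall": tp / total if total else np.nan,
        "false_positive_rate_balanced": fp / n_bal if n_bal else np.nan,
        "n_planted_imbalanced": total,
    }


# ---------------------------------------------------------------------------
# GWAS enrichment


def run_gwas_enrichment(
    bundle: SimBundle,
    ai_out: dict,
    n_iter: int = 2000,
    matched: bool = False,
    seed: int = 0,
) -> risk.EnrichmentResult:
    """Permutation enrichment of the GWAS catalog in detected imbalanced
    peaks against the full consensus universe."""
    universe = ai_out["universe"]
    detected = set()
    for g in ("ccRCC", "pRCC", "combined"):
        res = ai_out["per_group"][g]
        detected |= set(res.index[res["imbalanced"]])
    target_peaks = PeakSet(
        p for p in universe
        if f"{p.interval.chrom}:{p.interval.start}-{p.interval.end}" in detected
    )
    snps = bundle.gwas_catalog.copy()
    snps["pos"] = snps["pos"].astype(int) - 1  # catalog holds 1-based positions
    return risk.permutation_enrichment(
        snps, target_peaks, universe, n_iter=n_iter, matched=matched, seed=seed
    )
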