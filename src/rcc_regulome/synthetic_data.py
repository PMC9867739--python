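"""Synthetic multi-histology RCC cohort with known ground truth.

Emulates the data shapes of a three-histology renal-cell-carcinoma
cohort (clear cell, papillary, chromophobe): per-sample enhancer peak
calls on a small synthetic genome, a peak × sample read-count matrix
with planted histology-specific peaks, a TF expression matrix and a
pan-cancer mean-expression table with planted master TFs, super-enhancer
clusters with planted motif wiring for clique analysis, phased allelic
read counts with planted beta-binomial imbalance (group-shared and
group-specific), per-individual copy-number profiles, a GWAS catalog
enriched in imbalanced peaks, and a repeat track.

Every artifact is deterministic given the seed, and every planted label
is recorded in SimTruth so downstream recovery is measurable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_genomics import GenomicInterval, Peak, PeakSet, TssAnnotation

HISTOLOGIES = ("ccRCC", "pRCC", "chRCC")
CHROM_LENGTH = 10_000_000
N_CHROMS = 3
PEAK_WIDTH = 600


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults are desk-scale: 6 samples per histology, 2,000 peaks, 300
    TFs with 5 planted masters per histology, 500 SNP-bearing peaks of
    which 20% are planted allelically imbalanced (60% of those shared
    between ccRCC and pRCC, the rest split equally between ccRCC- and
    pRCC-specific imbalance).
    """

    n_samples_per_histology: int = 6
    n_peaks: int = 2000
    frac_specific: float = 0.15
    log2fc_planted: float = 4.0
    nb_dispersion: float = 0.05
    base_mean: float = 200.0
    n_tfs: int = 300
    n_master_tfs_per_histology: int = 5
    n_housekeeping_tfs: int = 6
    pi_imbalanced: float = 0.7
    rho_true: float = 0.05
    read_depth_snp: float = 30.0
    n_ai_individuals_per_group: int = 20
    n_snp_peaks: int = 500
    frac_ai_shared: float = 0.12
    frac_ai_group_specific: float = 0.04  # each of ccRCC and pRCC
    n_gwas_snps: int = 200
    gwas_enrichment_fold: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_samples_per_histology",
            "n_peaks",
            "n_tfs",
            "n_master_tfs_per_histology",
            "n_snp_peaks",
            "n_gwas_snps",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.frac_specific < 1:
            raise ValueError("frac_specific must lie in (0, 1)")
        if not 0 < self.pi_imbalanced < 1:
            raise ValueError("pi_imbalanced must lie in (0, 1)")
        if not 0 < self.rho_true <= 0.2:
            raise ValueError("rho_true must lie in (0, 0.2]")
        n_special = 3 * self.n_master_tfs_per_histology + self.n_housekeeping_tfs
        if n_special > self.n_tfs:
            raise ValueError(
                f"{n_special} master+housekeeping TFs exceed n_tfs={self.n_tfs}"
            )
        if self.n_snp_peaks > self.n_peaks:
            raise ValueError("n_snp_peaks cannot exceed n_peaks")
        if self.frac_ai_shared + 2 * self.frac_ai_group_specific >= 1:
            raise ValueError("allelic-imbalance fractions must sum below 1")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SimTruth:
    """Planted ground truth of one simulated cohort."""

    specific_peak_labels: pd.Series  # peak_id -> histology or "common"
    master_tf_labels: dict[str, str]  # tf -> histology
    housekeeping_tfs: list[str]
    ai_peak_classes: pd.Series  # peak_id -> {shared, ccRCC-specific, pRCC-specific, balanced}
    ai_pi: pd.DataFrame  # peak_id x {pi_ccRCC, pi_pRCC}
    gwas_snp_in_ai_peak: pd.Series  # snp_id -> bool

    def to_json(self, path) -> None:
        payload = {
            "specific_peak_labels": self.specific_peak_labels.to_dict(),
            "master_tf_labels": self.master_tf_labels,
            "housekeeping_tfs": self.housekeeping_tfs,
            "ai_peak_classes": self.ai_peak_classes.to_dict(),
            "ai_pi": self.ai_pi.to_dict(orient="index"),
            "gwas_snp_in_ai_peak": self.gwas_snp_in_ai_peak.astype(bool).to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimBundle:
    """All artifacts of one simulated cohort."""

    config: SimConfig
    genome: dict[str, int]
    sample_ids: list[str]
    sample_labels: pd.Series  # sample -> histology
    peak_table: pd.DataFrame  # peak_id, chrom, start, end, label
    chip_peaksets: dict[str, PeakSet]  # per sample (H3K27ac incl. SE clusters)
    atac_peaksets: dict[str, PeakSet]
    counts: pd.DataFrame  # peaks x samples
    libsizes: pd.Series
    expression: pd.DataFrame  # TFs x samples (FPKM)
    tf_list: list[str]
    pan_cancer_means: pd.DataFrame  # TFs x tumor types
    tss: list[TssAnnotation]
    pwms: dict[str, np.ndarray]
    se_sequences: dict[str, dict[str, str]]  # sample -> {owner_tf: sequence}
    se_cluster_owner: dict[str, dict[str, tuple[str, int, int]]]  # tf -> (chrom, start, end) per histology presence
    allelic_counts: pd.DataFrame
    ai_individual_groups: pd.Series  # AI individual -> {ccRCC, pRCC}
    cn_segments: pd.DataFrame  # individual, chrom, start, end, cn_level
    gwas_catalog: pd.DataFrame
    repeat_track: PeakSet
    truth: SimTruth


def simulate_betabin(k_trials: int, pi: float, rho: float, n_draws: int, seed) -> np.ndarray:
    """Draw alternate-read counts from BetaBin(pi, rho) with ``k_trials``
    trials per draw; rho = 0 degenerates to the binomial."""
    if not 0 < pi < 1:
        raise ValueError("pi must lie in (0, 1)")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if k_trials == 0:
        return np.zeros(n_draws, dtype=int)
    if rho == 0:
        return rng.binomial(k_trials, pi, size=n_draws)
    ab = (1 - rho) / rho
    p = rng.beta(pi * ab, (1 - pi) * ab, size=n_draws)
    return rng.binomial(k_trials, p)


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _random_kmer(rng: np.random.Generator, k: int = 8) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))


def _consensus_pwm(kmer: str, p_match: float = 0.97) -> np.ndarray:
    pwm = np.full((len(kmer), 4), (1 - p_match) / 3)
    for i, base in enumerate(kmer):
        pwm[i, "ACGT".index(base)] = p_match
    return pwm


def simulate_cohort(config: SimConfig) -> SimBundle:
    rng = np.random.default_rng(config.seed)
    genome = {f"chr{i + 1}": CHROM_LENGTH for i in range(N_CHROMS)}
    chrom_names = list(genome)

    n_h = config.n_samples_per_histology
    sample_ids = [
        f"{prefix}{i + 1:02d}"
        for prefix, _ in zip(("cc", "pr", "ch"), HISTOLOGIES)
        for i in range(n_h)
    ]
    labels = [h for h in HISTOLOGIES for _ in range(n_h)]
    sample_labels = pd.Series(labels, index=sample_ids, name="histology")

    # --- peak layout: evenly spaced slots within [50 kb, 9 Mb) per chromosome
    per_chrom = [config.n_peaks // N_CHROMS] * N_CHROMS
    for i in range(config.n_peaks % N_CHROMS):
        per_chrom[i] += 1
    rows = []
    for chrom, n_c in zip(chrom_names, per_chrom):
        spacing = (9_000_000 - 100_000) // n_c
        for i in range(n_c):
            start = 50_000 + i * spacing
            rows.append((chrom, start, start + PEAK_WIDTH))
    peak_table = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    peak_table["peak_id"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(peak_table.chrom, peak_table.start, peak_table.end)
    ]

    # --- histology-specific labels: exact counts, randomly placed
    n_specific = round(config.frac_specific * config.n_peaks)
    spec_idx = rng.choice(config.n_peaks, size=n_specific, replace=False)
    peak_labels = np.array(["common"] * config.n_peaks, dtype=object)
    per_h = [n_specific // 3] * 3
    for i in range(n_specific % 3):
        per_h[i] += 1
    cursor = 0
    for h, n_this in zip(HISTOLOGIES, per_h):
        peak_labels[spec_idx[cursor : cursor + n_this]] = h
        cursor += n_this
    peak_table["label"] = peak_labels
    peak_table = peak_table.set_index("peak_id")

    # --- TF roster: masters, housekeeping, the rest
    tf_list = [f"TF{i:03d}" for i in range(config.n_tfs)]
    master_tf_labels: dict[str, str] = {}
    cursor = 0
    for h in HISTOLOGIES:
        for _ in range(config.n_master_tfs_per_histology):
            master_tf_labels[tf_list[cursor]] = h
            cursor += 1
    housekeeping = tf_list[cursor : cursor + config.n_housekeeping_tfs]
    cursor += config.n_housekeeping_tfs
    ordinary_tfs = tf_list[cursor:]

    # --- super-enhancer clusters: 3 tight peaks per special TF in the
    # [9.05, 9.95] Mb tail of each chromosome, far from ordinary slots
    special_tfs = list(master_tf_labels) + housekeeping
    se_cluster_coords: dict[str, tuple[str, int, int]] = {}
    for j, tf in enumerate(special_tfs):
        chrom = chrom_names[j % N_CHROMS]
        base = 9_050_000 + (j // N_CHROMS) * 40_000
        se_cluster_coords[tf] = (chrom, base, base + 4_000 + PEAK_WIDTH)

    def cluster_peaks(tf: str, score: float, sample: str) -> list[Peak]:
        chrom, base, _ = se_cluster_coords[tf]
        return [
            Peak(GenomicInterval(chrom, base + k * 2_000, base + k * 2_000 + PEAK_WIDTH),
                 score=score, sample_id=sample)
            for k in range(3)
        ]

    # --- per-sample ChIP and ATAC peak sets
    chip_peaksets: dict[str, PeakSet] = {}
    atac_peaksets: dict[str, PeakSet] = {}
    for sample, h in sample_labels.items():
        present = (peak_table["label"] == "common") | (peak_table["label"] == h)
        scores = rng.lognormal(mean=0.7, sigma=0.5, size=int(present.sum()))
        peaks = [
            Peak(GenomicInterval(r.chrom, r.start, r.end), score=float(sc), sample_id=sample)
            for (_, r), sc in zip(peak_table[present].iterrows(), scores)
        ]
        for tf, owner_h in master_tf_labels.items():
            if owner_h == h:
                peaks += cluster_peaks(tf, float(rng.normal(50, 3)), sample)
        for tf in housekeeping:
            peaks += cluster_peaks(tf, float(rng.normal(27, 2)), sample)
        chip_peaksets[sample] = PeakSet(peaks, genome=genome)
        atac_scores = rng.lognormal(mean=2.0, sigma=0.6, size=len(peaks))
        # a small fraction of ATAC calls are marginal and fall below the
        # score-per-million filter downstream
        weak = rng.random(len(peaks)) < 0.02
        atac_scores[weak] = rng.uniform(0.005, 0.03, size=int(weak.sum()))
        atac_peaksets[sample] = PeakSet(
            (Peak(p.interval, score=float(s), sample_id=sample)
             for p, s in zip(peaks, atac_scores)),
            genome=genome,
        )

    # --- count matrix with planted fold changes
    fold = 2.0 ** config.log2fc_planted
    libfactors = rng.uniform(0.8, 1.2, size=len(sample_ids))
    libsizes = pd.Series(libfactors * 1e6, index=sample_ids, name="libsize")
    means = np.full((config.n_peaks, len(sample_ids)), config.base_mean)
    for j, h in enumerate(labels):
        boost = (peak_table["label"] == h).to_numpy()
        means[boost, j] *= fold
    means *= libfactors[None, :]
    counts = pd.DataFrame(
        _nb_draw(rng, means, config.nb_dispersion, means.shape),
        index=peak_table.index,
        columns=sample_ids,
    )

    # --- TF expression (FPKM scale)
    expr = np.empty((config.n_tfs, len(sample_ids)))
    base_level = rng.uniform(5, 30, size=config.n_tfs)
    for i, tf in enumerate(tf_list):
        noise = rng.lognormal(0.0, 0.2, size=len(sample_ids))
        if tf in master_tf_labels:
            own = np.array([h == master_tf_labels[tf] for h in labels])
            expr[i] = np.where(
                own,
                np.clip(rng.normal(50, 5, size=len(sample_ids)), 15, None),
                np.clip(rng.normal(2, 0.4, size=len(sample_ids)), 0.05, None),
            )
        elif tf in housekeeping:
            expr[i] = np.clip(rng.normal(30, 3, size=len(sample_ids)), 10, None)
        else:
            expr[i] = base_level[i] * noise
    expression = pd.DataFrame(expr, index=tf_list, columns=sample_ids)

    # --- pan-cancer mean expression table (3 RCC types + synthetic others)
    bg_types = [f"TCGA_T{i + 1:02d}" for i in range(7)]
    all_types = list(HISTOLOGIES) + bg_types
    pan = np.empty((config.n_tfs, len(all_types)))
    for i, tf in enumerate(tf_list):
        if tf in master_tf_labels:
            pan[i] = 1.0
            pan[i, all_types.index(master_tf_labels[tf])] = 50.0
        elif tf in housekeeping:
            pan[i] = 30.0
        else:
            pan[i] = base_level[i] * rng.lognormal(0.0, 0.1, size=len(all_types))
    pan_cancer_means = pd.DataFrame(pan, index=tf_list, columns=all_types)

    # --- TSS annotation: special TFs near their clusters, the rest near
    # ordinary peak slots
    tss: list[TssAnnotation] = []
    for tf in special_tfs:
        chrom, base, _ = se_cluster_coords[tf]
        tss.append(TssAnnotation(tf, GenomicInterval(chrom, base - 500, base - 499)))
    for i, tf in enumerate(ordinary_tfs):
        row = peak_table.iloc[i]
        tss.append(
            TssAnnotation(tf, GenomicInterval(row.chrom, int(row.start) - 200, int(row.start) - 199))
        )

    # --- PWMs and SE sequences with planted motif wiring
    kmers: dict[str, str] = {}
    seen: set[str] = set()
    for tf in special_tfs:
        kmer = _random_kmer(rng)
        while kmer in seen:
            kmer = _random_kmer(rng)
        seen.add(kmer)
        kmers[tf] = kmer
    pwms = {tf: _consensus_pwm(kmer) for tf, kmer in kmers.items()}

    def planted_sequence(planted_kmers: list[str], length: int = 1000) -> str:
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, size=length)))
        slots = rng.choice(length // 20 - 1, size=len(planted_kmers), replace=False)
        for kmer, slot in zip(planted_kmers, slots):
            pos = int(slot) * 20 + 5
            seq[pos : pos + len(kmer)] = list(kmer)
        return "".join(seq)

    histology_masters = {
        h: [tf for tf, hh in master_tf_labels.items() if hh == h] for h in HISTOLOGIES
    }
    se_sequences: dict[str, dict[str, str]] = {}
    for sample, h in sample_labels.items():
        seqs: dict[str, str] = {}
        for tf in histology_masters[h]:
            seqs[tf] = planted_sequence([kmers[m] for m in histology_masters[h]])
        for tf in housekeeping:
            seqs[tf] = planted_sequence([kmers[m] for m in housekeeping])
        se_sequences[sample] = seqs

    # --- allelic imbalance: SNP-bearing peaks with planted group pi
    common_ids = peak_table.index[peak_table["label"] == "common"]
    snp_peak_ids = pd.Index(
        rng.choice(common_ids, size=config.n_snp_peaks, replace=False)
    )
    n_shared = round(config.frac_ai_shared * config.n_snp_peaks)
    n_spec_g = round(config.frac_ai_group_specific * config.n_snp_peaks)
    classes = np.array(["balanced"] * config.n_snp_peaks, dtype=object)
    classes[:n_shared] = "shared"
    classes[n_shared : n_shared + n_spec_g] = "ccRCC-specific"
    classes[n_shared + n_spec_g : n_shared + 2 * n_spec_g] = "pRCC-specific"
    rng.shuffle(classes)
    ai_classes = pd.Series(classes, index=snp_peak_ids, name="ai_class")
    pi_cc = np.where(
        np.isin(classes, ["shared", "ccRCC-specific"]), config.pi_imbalanced, 0.5
    )
    pi_pr = np.where(
        np.isin(classes, ["shared", "pRCC-specific"]), config.pi_imbalanced, 0.5
    )
    ai_pi = pd.DataFrame(
        {"pi_ccRCC": pi_cc, "pi_pRCC": pi_pr}, index=snp_peak_ids
    )

    # copy-number segments per AI individual. The genotyped allelic-imbalance
    # cohort is modelled as its own set of individuals per group (ccRCC and
    # pRCC), sharing the cohort's peak landscape; its size is not tied to the
    # number of ChIP samples per histology.
    n_ai = config.n_ai_individuals_per_group
    ai_individuals = [f"ai_cc{i + 1:02d}" for i in range(n_ai)] + [
        f"ai_pr{i + 1:02d}" for i in range(n_ai)
    ]
    ai_individual_groups = pd.Series(
        ["ccRCC"] * n_ai + ["pRCC"] * n_ai, index=ai_individuals, name="group"
    )
    seg_rows = []
    seg_levels: dict[tuple[str, str, int], float] = {}
    seg_len = CHROM_LENGTH // 4
    for ind in ai_individuals:
        for chrom in chrom_names:
            for k in range(4):
                level = float(rng.choice([1.0, 2.0, 3.0, 4.0], p=[0.1, 0.6, 0.2, 0.1]))
                seg_rows.append((ind, chrom, k * seg_len, (k + 1) * seg_len, level))
                seg_levels[(ind, chrom, k)] = level
    cn_segments = pd.DataFrame(
        seg_rows, columns=["individual", "chrom", "start", "end", "cn_level"]
    )

    snp_rows = []
    snp_counter = 0
    for peak_id in snp_peak_ids:
        row = peak_table.loc[peak_id]
        n_snps = int(rng.integers(1, 5))
        positions = np.sort(rng.choice(np.arange(row.start + 10, row.end - 10), size=n_snps, replace=False))
        for pos in positions:
            snp_id = f"rs{snp_counter:06d}"
            snp_counter += 1
            for ind in ai_individuals:
                if rng.random() > 0.5:  # not heterozygous in this individual
                    continue
                depth = int(rng.poisson(config.read_depth_snp))
                if depth == 0:
                    continue
                grp = ai_individual_groups[ind]
                pi = float(ai_pi.loc[peak_id, f"pi_{grp}"])
                k1 = int(simulate_betabin(depth, pi, config.rho_true, 1, rng)[0])
                level = seg_levels[(ind, row.chrom, int(pos) // seg_len)]
                snp_rows.append(
                    (snp_id, row.chrom, int(pos), ind, k1, depth - k1, level, peak_id)
                )
    allelic_counts = pd.DataFrame(
        snp_rows,
        columns=["snp_id", "chrom", "pos", "individual", "hap1_reads",
                 "hap2_reads", "cn_level", "true_peak_id"],
    )
    # copy-number deciles within each individual
    strata = []
    for ind, sub in allelic_counts.groupby("individual"):
        pct = sub["cn_level"].rank(pct=True, method="average")
        strata.append(np.minimum(np.ceil(pct * 10).astype(int), 10))
    allelic_counts["cn_stratum"] = pd.concat(strata).sort_index() if strata else []

    # --- GWAS catalog enriched in AI peaks
    ai_peak_ids = snp_peak_ids[classes != "balanced"]
    ai_bp = len(ai_peak_ids) * PEAK_WIDTH
    total_bp = config.n_peaks * PEAK_WIDTH
    p_in_ai = min(1.0, config.gwas_enrichment_fold * ai_bp / total_bp)
    non_ai_ids = peak_table.index.difference(ai_peak_ids)
    gwas_rows = []
    in_ai_flags = []
    for i in range(config.n_gwas_snps):
        in_ai = bool(rng.random() < p_in_ai)
        pool = ai_peak_ids if in_ai else non_ai_ids
        peak_id = pool[int(rng.integers(0, len(pool)))]
        row = peak_table.loc[peak_id]
        pos = int(rng.integers(row.start, row.end))
        gwas_rows.append((f"gwas{i:04d}", row.chrom, pos + 1, "RCC", True))
        in_ai_flags.append(in_ai)
    gwas_catalog = pd.DataFrame(
        gwas_rows, columns=["snp_id", "chrom", "pos", "pheno", "sig_flag"]
    )
    gwas_in_ai = pd.Series(in_ai_flags, index=gwas_catalog["snp_id"], name="in_ai_peak")

    # --- repeat track: fully contains the second peak slot of each
    # chromosome, partially overlaps the first, plus a peak-free tail block
    repeat_rows = []
    for chrom in chrom_names:
        slots = peak_table[peak_table["chrom"] == chrom]
        second = slots.iloc[1]
        repeat_rows.append(
            Peak(GenomicInterval(chrom, int(second.start) - 500, int(second.end) + 500))
        )
        first = slots.iloc[0]
        repeat_rows.append(Peak(GenomicInterval(chrom, int(first.start) - 300, int(first.start) + 100)))
        repeat_rows.append(Peak(GenomicInterval(chrom, 9_960_000, 9_990_000)))
    repeat_track = PeakSet(repeat_rows, genome=genome)

    truth = SimTruth(
        specific_peak_labels=peak_table["label"].copy(),
        master_tf_labels=master_tf_labels,
        housekeeping_tfs=list(housekeeping),
        ai_peak_classes=ai_classes,
        ai_pi=ai_pi,
        gwas_snp_in_ai_peak=gwas_in_ai,
    )
    return SimBundle(
        config=config,
        genome=genome,
        sample_ids=sample_ids,
        sample_labels=sample_labels,
        peak_table=peak_table,
        chip_peaksets=chip_peaksets,
        atac_peaksets=atac_peaksets,
        counts=counts,
        libsizes=libsizes,
        expression=expression,
        tf_list=tf_list,
        pan_cancer_means=pan_cancer_means,
        tss=tss,
        pwms=pwms,
        se_sequences=se_sequences,
        se_cluster_owner={tf: {"coords": coords} for tf, coords in se_cluster_coords.items()},
        allelic_counts=allelic_counts,
        ai_individual_groups=ai_individual_groups,
        cn_segments=cn_segments,
        gwas_catalog=gwas_catalog,
        repeat_track=repeat_track,
        truth=truth,
    )


def write_cohort(bundle: SimBundle, outdir) -> None:
    """Write every artifact in the standard formats the readers consume,
    plus the truth JSON and the config YAML."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.config.to_yaml(out / "config.yaml")
    with open(out / "genome.chrom.sizes", "w") as fh:
        for chrom, length in bundle.genome.items():
            fh.write(f"{chrom}\t{length}\n")
    peaks_dir = out / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    from .core_genomics import write_bed

    for sample, ps in bundle.chip_peaksets.items():
        write_bed(ps, peaks_dir / f"{sample}.h3k27ac.bed", scores=True)
    for sample, ps in bundle.atac_peaksets.items():
        write_bed(ps, peaks_dir / f"{sample}.atac.bed", scores=True)
    bundle.counts.to_csv(out / "peak_counts.tsv", sep="\t")
    pd.DataFrame(
        {"sample": bundle.sample_ids,
         "histology": bundle.sample_labels.values,
         "libsize": bundle.libsizes.values}
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
    bundle.expression.to_csv(out / "tf_expression_fpkm.tsv", sep="\t")
    bundle.pan_cancer_means.to_csv(out / "pan_cancer_tf_means.tsv", sep="\t")
    with open(out / "tf_list.txt", "w") as fh:
        fh.write("\n".join(bundle.tf_list) + "\n")
    with open(out / "tss.bed", "w") as fh:
        for t in bundle.tss:
            fh.write(f"{t.tss.chrom}\t{t.tss.start}\t{t.tss.end}\t{t.gene}\t0\t{t.strand}\n")
    from .master_tf import write_meme

    write_meme(bundle.pwms, out / "motifs.meme")
    ac = bundle.allelic_counts.copy()
    ac["pos"] = ac["pos"] + 1  # 1-based in the file
    ac.to_csv(out / "allelic_counts.tsv", sep="\t", index=False)
    bundle.ai_individual_groups.rename_axis("individual").to_frame().to_csv(
        out / "ai_individuals.tsv", sep="\t"
    )
    bundle.cn_segments.to_csv(out / "copy_number_segments.tsv", sep="\t", index=False)
    bundle.gwas_catalog.to_csv(out / "gwas_catalog.tsv", sep="\t", index=False)
    write_bed(bundle.repeat_track, out / "repeats.bed")
    bundle.truth.to_json(out / "truth.json")
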