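"""ATAC-seq "score per million" normalization, multi-sample consensus
regions, and repeat filtering.

spm rescales each peak's caller score (−log10 P) so that the scores of a
sample sum to one million; low-support peaks (spm <= 5, inclusive) are
dropped before consensus construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_genomics import GenomicInterval, Peak, PeakSet, merge_intervals


@dataclass(frozen=True)
class SpmPeak:
    peak: Peak
    spm: float


def spm_normalize(
    sample_peaks: PeakSet, spm_min: float = 5.0
) -> tuple[list[SpmPeak], PeakSet]:
    """Score-per-million normalization of one sample's peaks.

    spm_i = score_i / sum(scores) * 1e6. Returns (all spm-annotated peaks,
    PeakSet of peaks surviving the spm > spm_min filter). The filter
    boundary is inclusive: a peak at exactly spm_min is removed.
    """
    total = sum(p.score for p in sample_peaks)
    if total <= 0:
        raise ValueError("all peak scores are zero; cannot compute spm")
    annotated = [SpmPeak(p, p.score / total * 1e6) for p in sample_peaks]
    kept = PeakSet(sp.peak for sp in annotated if sp.spm > spm_min)
    return annotated, kept


def build_atac_consensus(spm_filtered_peaksets: Sequence[PeakSet]) -> PeakSet:
    """Regions covered by >= 2 samples, breaking up peaks where coverage
    changes. Delegates to the per-sample coverage sweep."""
    from .core_genomics import coverage_regions

    if len(spm_filtered_peaksets) < 2:
        raise ValueError("consensus requires at least 2 samples")
    return coverage_regions(spm_filtered_peaksets, min_cover=2)


def filter_repeats(regions: PeakSet, repeats: PeakSet) -> PeakSet:
    """Drop regions fully contained in the union of repeat intervals.

    Partial overlaps are kept intact (only regions whose full length is
    repeat-masked are removed).
    """
    rep_union = merge_intervals(repeats.intervals()) if len(repeats) else []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in rep_union:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    kept = []
    for p in regions:
        iv = p.interval
        contained = any(
            r.start <= iv.start and iv.end <= r.end
            for r in by_chrom.get(iv.chrom, ())
        )
        if not contained:
            kept.append(p)
    return PeakSet(kept, genome=regions.genome)
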