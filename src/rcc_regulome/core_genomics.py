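"""Genomic-interval data model, standard-format I/O and interval sweeps.

Coordinates are 0-based half-open (BED convention) throughout; 1-based
positions (e.g. SNP coordinates quoted like chr14:73279420) are converted
at the reader boundary. Strand is ignored for peak operations — histone
and ATAC peaks are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


class IntervalValidationError(ValueError):
    """An interval violates the coordinate invariants."""


class ParseError(ValueError):
    """A line of an interval file could not be parsed."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalValidationError("chrom must be non-empty")
        if self.start < 0:
            raise IntervalValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise IntervalValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval with a caller score (−log10 P) and sample id."""

    interval: GenomicInterval
    score: float = 0.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.score < 0:
            raise IntervalValidationError(f"peak score must be >= 0, got {self.score}")


@dataclass(frozen=True)
class TssAnnotation:
    """A transcription start site: a width-1 interval with gene symbol and strand."""

    gene: str
    tss: GenomicInterval
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss.width != 1:
            raise IntervalValidationError("TSS interval must have width exactly 1")
        if self.strand not in {"+", "-"}:
            raise IntervalValidationError(f"strand must be + or -, got {self.strand!r}")


class PeakSet:
    """An ordered collection of peaks, sorted by (chrom, start, end).

    Optionally carries a genome layout (chrom -> length); when present, no
    peak may extend beyond its chromosome.
    """

    def __init__(
        self,
        peaks: Iterable[Peak] = (),
        genome: Mapping[str, int] | None = None,
    ) -> None:
        self.peaks: list[Peak] = sorted(
            peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )
        self.genome = dict(genome) if genome is not None else None
        if self.genome is not None:
            for p in self.peaks:
                length = self.genome.get(p.interval.chrom)
                if length is None:
                    raise IntervalValidationError(
                        f"chromosome {p.interval.chrom!r} absent from genome layout"
                    )
                if p.interval.end > length:
                    raise IntervalValidationError(
                        f"peak {p.interval} extends beyond chromosome length {length}"
                    )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def total_bp(self) -> int:
        """Base pairs covered by the union of the peaks (no double counting)."""
        return sum(iv.width for iv in merge_intervals(self.intervals()))

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.interval.chrom, []).append(p)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.interval.chrom for p in self.peaks],
                "start": [p.interval.start for p in self.peaks],
                "end": [p.interval.end for p in self.peaks],
                "score": [p.score for p in self.peaks],
                "sample_id": [p.sample_id for p in self.peaks],
            }
        )


# ---------------------------------------------------------------------------
# I/O


def read_intervals(path, format: str = "bed", sample_id: str = "") -> PeakSet:
    """Read a BED / narrowPeak / headered-TSV interval file into a PeakSet.

    narrowPeak column 8 (1-based; −log10 P) populates the peak score.
    BED3 rows get score 0; BED6 uses column 5.
    """
    if format not in {"bed", "narrowPeak", "tsv"}:
        raise ValueError(f"unknown format {format!r}")
    peaks = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start_line = 0
    if format == "tsv":
        start_line = 1  # header row
    for lineno, line in enumerate(lines, start=1):
        if lineno <= start_line or not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed line: {line!r}") from exc
        score = 0.0
        if format == "narrowPeak":
            if len(fields) < 10:
                raise ParseError(
                    f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(fields)}"
                )
            score = float(fields[7])
        elif len(fields) >= 5:
            try:
                score = max(0.0, float(fields[4]))
            except ValueError:
                score = 0.0
        try:
            iv = GenomicInterval(chrom, start, end)
        except IntervalValidationError as exc:
            raise IntervalValidationError(f"{path}:{lineno}: {exc}") from exc
        peaks.append(Peak(iv, score=score, sample_id=sample_id))
    return PeakSet(peaks)


def write_bed(peaks: PeakSet | Iterable[GenomicInterval], path, scores: bool = False) -> None:
    with open(path, "w") as fh:
        for item in peaks:
            if isinstance(item, Peak):
                iv, score = item.interval, item.score
            else:
                iv, score = item, 0.0
            if scores:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{score:g}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            out[fields[0]] = int(fields[1])
    return out


def read_tss(path) -> list[TssAnnotation]:
    """BED-like TSS file: chrom, start, end (start+1), gene, score, strand."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 columns")
            strand = fields[5] if len(fields) >= 6 else "+"
            out.append(
                TssAnnotation(
                    gene=fields[3],
                    tss=GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    strand=strand,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Interval algebra


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: merge overlapping or book-ended intervals per chrom."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def overlap_any(a: PeakSet, b: PeakSet) -> np.ndarray:
    """For each peak of ``a``, does it share >= 1 bp with any peak of ``b``?

    Half-open semantics: intervals [0, 10) and [10, 20) do not overlap.
    """
    merged_b = merge_intervals(b.intervals())
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for iv in merged_b:
        starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[union-attr]
        ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[union-attr]
    for chrom in starts:
        starts[chrom] = np.asarray(starts[chrom])
        ends[chrom] = np.asarray(ends[chrom])
    out = np.zeros(len(a), dtype=bool)
    for i, p in enumerate(a):
        chrom = p.interval.chrom
        if chrom not in starts:
            continue
        # merged intervals are disjoint & sorted: candidate is the last one
        # starting before this peak ends
        j = int(np.searchsorted(starts[chrom], p.interval.end, side="left")) - 1
        out[i] = j >= 0 and ends[chrom][j] > p.interval.start
    return out


def coverage_regions(peaksets: Sequence[PeakSet], min_cover: int) -> PeakSet:
    """Maximal intervals where per-base coverage by distinct samples >= min_cover.

    Each PeakSet counts once per base (its peaks are unioned first), so
    coverage is by samples, not by peaks. Output intervals are disjoint,
    sorted, and broken up at every coverage change crossing the threshold.
    """
    if min_cover < 1:
        raise ValueError("min_cover must be >= 1")
    events: dict[str, list[tuple[int, int]]] = {}
    for ps in peaksets:
        for iv in merge_intervals(ps.intervals()):
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    out: list[Peak] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        depth = 0
        region_start: int | None = None
        for pos, delta in evs:
            new_depth = depth + delta
            # process all events at the same position together
            depth = new_depth
            if region_start is None and depth >= min_cover:
                region_start = pos
            elif region_start is not None and depth < min_cover:
                if pos > region_start:
                    out.append(Peak(GenomicInterval(chrom, region_start, pos)))
                region_start = None
        # events are balanced so depth returns to 0 and region_start closes
    # merge adjacent fragments produced by coincident events
    merged = merge_intervals([p.interval for p in out]) if out else []
    return PeakSet(Peak(iv) for iv in merged)


def window_consensus(
    peaksets: Sequence[PeakSet],
    window_bp: int = 50,
    min_samples: int = 2,
    merge_adjacent: bool = True,
) -> PeakSet:
    """Fixed-window consensus: tile the genome into half-open ``window_bp``
    windows and keep every window overlapped by peaks from >= ``min_samples``
    distinct samples. Adjacent retained windows are merged by default.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    counts: dict[tuple[str, int], int] = {}
    for ps in peaksets:
        seen: set[tuple[str, int]] = set()
        for iv in ps.intervals():
            first = iv.start // window_bp
            last = (iv.end - 1) // window_bp
            for k in range(first, last + 1):
                seen.add((iv.chrom, k))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    kept = sorted(key for key, c in counts.items() if c >= min_samples)
    windows = [
        GenomicInterval(chrom, k * window_bp, (k + 1) * window_bp) for chrom, k in kept
    ]
    if merge_adjacent:
        windows = merge_intervals(windows)
    return PeakSet(Peak(iv) for iv in windows)
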