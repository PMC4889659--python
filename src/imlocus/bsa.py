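"""Mapping-by-sequencing SNP-density scan.

Counts quality-filtered SNPs in fixed non-overlapping genomic windows and
locates the peak window — the bulked-segregant signal that localizes a
recessive locus.  Windows are anchored at the chromosome start; the last
window may be partial.  The quality filter is strictly greater-than.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np

from .io import VariantRecord

__all__ = ["WindowCounts", "PeakRegion", "window_density", "find_peak", "render_histogram"]


@dataclasses.dataclass
class WindowCounts:
    """Per-chromosome window counts of variants passing the quality filter."""

    window_size: int
    qual_min: float
    counts: dict[str, np.ndarray]
    n_passing: int
    n_indels_excluded: int

    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def window_span(self, chrom: str, index: int) -> tuple[int, int]:
        """1-based inclusive bp span of a window."""
        start = index * self.window_size + 1
        return start, start + self.window_size - 1


@dataclasses.dataclass
class PeakRegion:
    chromosome: str | None
    window_index: int | None
    start: int | None
    end: int | None
    count: int
    tie: bool = False
    tied_windows: list[tuple[str, int]] = dataclasses.field(default_factory=list)
    no_signal: bool = False


def window_density(
    variants: Iterable[VariantRecord],
    window_size: int = 10_000_000,
    qual_min: float = 50.0,
    snps_only: bool = True,
    chrom_lengths: Mapping[str, int] | None = None,
) -> WindowCounts:
    """Bin variants with ``qual > qual_min`` into ``window_size`` windows.

    A variant at 1-based position p falls in window ``(p - 1) // window_size``.
    With ``snps_only`` (the default: the scan statistic counts SNPs), indels
    are excluded from the counts but tallied for reporting.  ``chrom_lengths``
    fixes the number of windows per chromosome so empty trailing windows are
    represented; otherwise windows extend to the last observed variant.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    per_chrom: dict[str, list[int]] = {}
    n_passing = 0
    n_indels_excluded = 0
    for v in variants:
        if not v.qual > qual_min:
            continue
        if snps_only and v.is_indel:
            n_indels_excluded += 1
            continue
        n_passing += 1
        per_chrom.setdefault(v.chrom, []).append((v.pos - 1) // window_size)
    counts: dict[str, np.ndarray] = {}
    chroms = set(per_chrom)
    if chrom_lengths:
        chroms |= set(chrom_lengths)
    for chrom in sorted(chroms):
        idx = per_chrom.get(chrom, [])
        if chrom_lengths and chrom in chrom_lengths:
            n_windows = max(1, -(-chrom_lengths[chrom] // window_size))
        else:
            n_windows = (max(idx) + 1) if idx else 1
        arr = np.zeros(n_windows, dtype=np.int64)
        if idx:
            np.add.at(arr, np.asarray(idx), 1)
        counts[chrom] = arr
    return WindowCounts(
        window_size=window_size,
        qual_min=qual_min,
        counts=counts,
        n_passing=n_passing,
        n_indels_excluded=n_indels_excluded,
    )


def find_peak(wc: WindowCounts) -> PeakRegion:
    """Argmax window; lexicographic (chromosome, index) tie-break.

    All-zero counts are reported as a flagged no-signal result, not an error.
    Ties are broken toward the lexicographically first window and reported.
    """
    if not wc.counts:
        raise ValueError("no windows to scan")
    best = -1
    winners: list[tuple[str, int]] = []
    for chrom in sorted(wc.counts):
        arr = wc.counts[chrom]
        for i in np.nonzero(arr == arr.max())[0] if arr.size else []:
            c = int(arr[i])
            if c > best:
                best = c
                winners = [(chrom, int(i))]
            elif c == best:
                winners.append((chrom, int(i)))
    if best <= 0:
        return PeakRegion(
            chromosome=None, window_index=None, start=None, end=None, count=0, no_signal=True
        )
    chrom, idx = winners[0]
    start, end = wc.window_span(chrom, idx)
    return PeakRegion(
        chromosome=chrom,
        window_index=idx,
        start=start,
        end=end,
        count=best,
        tie=len(winners) > 1,
        tied_windows=winners if len(winners) > 1 else [],
    )


def render_histogram(wc: WindowCounts, width: int = 60) -> str:
    """Text histogram of window counts, one row per window."""
    peak = max((int(c.max()) for c in wc.counts.values() if c.size), default=0)
    scale = width / peak if peak else 0.0
    lines = [f"# SNPs with qual > {wc.qual_min:g} per {wc.window_size:,}-bp window"]
    for chrom in sorted(wc.counts):
        for i, c in enumerate(wc.counts[chrom]):
            start, end = wc.window_span(chrom, i)
            bar = "#" * int(round(c * scale))
            lines.append(f"{chrom}\t{start}-{end}\t{int(c)}\t{bar}")
    return "\n".join(lines)
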