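"""Peak-to-gene assignment under the window, nearest-gene and loop paradigms.

Three linkage strategies are supported:

* **window** — a peak is linked to every gene whose promoter window
  (centred on the most-5' TSS) it overlaps by at least 1 bp;
* **nearest gene** — a peak is linked exclusively to the gene with the
  closest most-5' TSS on the same chromosome (ties broken by gene id), so
  the assignment partitions the assignable peak set;
* **loop-augmented** — chromatin loops whose one anchor falls in a promoter
  search window contribute their other anchor as a distal window; peaks in
  distal windows are linked without distance decay, and a peak already in
  the promoter window is never counted twice.

A chromatin-state filter can further restrict any assignment to peaks that
touch a kept promoter/enhancer segment linked to the same gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome_model import ChromatinLoop, ChromHMMSegment, Gene, GenomicInterval, Peak

__all__ = [
    "AssignedPeak",
    "GenePeakAssignment",
    "promoter_window",
    "window_linkage",
    "nearest_gene_linkage",
    "assign_segments_window",
    "assign_segments_nearest",
    "chromhmm_filter",
    "loop_linkage",
    "distal_peak_assignment",
    "distal_segment_assignment",
]


@dataclass(frozen=True)
class AssignedPeak:
    """A peak linked to one gene, with its linkage context and TSS distance."""

    peak: Peak
    context: str  # "promoter" or "loop"
    dist: float  # |peak centre - most-5' TSS|, bp


class GenePeakAssignment(dict):
    """gene_id -> list[AssignedPeak]; genes without peaks simply absent."""

    def peaks_of(self, gene_id: str) -> list[Peak]:
        return [ap.peak for ap in self.get(gene_id, [])]

    def n_assigned(self) -> int:
        return sum(len(v) for v in self.values())

    def to_table(self):
        import pandas as pd

        rows = [
            {
                "gene_id": gid,
                "chrom": ap.peak.interval.chrom,
                "start": ap.peak.interval.start,
                "end": ap.peak.interval.end,
                "context": ap.context,
                "dist": ap.dist,
            }
            for gid, aps in self.items()
            for ap in aps
        ]
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "context", "dist"])


def promoter_window(gene: Gene, window_size: int) -> GenomicInterval:
    """Symmetric window of ``window_size`` bp centred on the most-5' TSS.

    Half-open; for odd sizes the upstream half rounds down.  Clipped at 0.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    tss = gene.tss
    start = max(0, tss - window_size // 2)
    end = tss + (window_size - window_size // 2)
    return GenomicInterval(gene.chrom, start, end)


def _interval_trees(intervals: Iterable[tuple[GenomicInterval, object]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv, payload in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
    return trees


def window_linkage(
    genes: Sequence[Gene], peaks: Sequence[Peak], window_size: int
) -> GenePeakAssignment:
    """Link every peak to every gene whose promoter window it overlaps >=1 bp."""
    trees = _interval_trees((promoter_window(g, window_size), g) for g in genes)
    out = GenePeakAssignment()
    for peak in peaks:
        tree = trees.get(peak.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(peak.interval.start, peak.interval.end):
            gene: Gene = hit.data
            out.setdefault(gene.gene_id, []).append(
                AssignedPeak(peak, "promoter", abs(peak.center - gene.tss))
            )
    return out


def nearest_gene_linkage(
    genes: Sequence[Gene], peaks: Sequence[Peak]
) -> tuple[GenePeakAssignment, list[Peak]]:
    """Assign each peak exclusively to the gene with the closest most-5' TSS.

    Distance is peak centre to TSS on the same chromosome; ties are broken
    by the lexicographically smaller gene_id.  Returns the assignment and
    the list of peaks on chromosomes without genes (unassignable).
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    sorted_tss: dict[str, tuple[np.ndarray, list[Gene]]] = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.tss, g.gene_id))
        sorted_tss[chrom] = (np.array([g.tss for g in gs], dtype=float), gs)

    out = GenePeakAssignment()
    unassigned: list[Peak] = []
    for peak in peaks:
        entry = sorted_tss.get(peak.interval.chrom)
        if entry is None:
            unassigned.append(peak)
            continue
        tss_arr, gs = entry
        c = peak.center
        i = int(np.searchsorted(tss_arr, c))
        # candidates around the insertion point, expanded to cover exact ties
        lo, hi = max(0, i - 1), min(len(gs), i + 1)
        best_dist = min(abs(tss_arr[j] - c) for j in range(lo, hi))
        candidates = [g for g, t in zip(gs, tss_arr) if abs(t - c) == best_dist]
        gene = min(candidates, key=lambda g: g.gene_id)
        out.setdefault(gene.gene_id, []).append(AssignedPeak(peak, "promoter", best_dist))
    return out, unassigned


def assign_segments_window(
    genes: Sequence[Gene], segments: Sequence[ChromHMMSegment], window_size: int
) -> dict[str, list[ChromHMMSegment]]:
    """Window-linkage for chromatin-state segments (same rule as for peaks)."""
    trees = _interval_trees((promoter_window(g, window_size), g) for g in genes)
    out: dict[str, list[ChromHMMSegment]] = {}
    for seg in segments:
        tree = trees.get(seg.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(seg.interval.start, seg.interval.end):
            out.setdefault(hit.data.gene_id, []).append(seg)
    return out


def assign_segments_nearest(
    genes: Sequence[Gene], segments: Sequence[ChromHMMSegment]
) -> dict[str, list[ChromHMMSegment]]:
    """Nearest-gene linkage for segments, by segment centre to most-5' TSS."""
    pseudo = [Peak(s.interval) for s in segments]
    assignment, _ = nearest_gene_linkage(genes, pseudo)
    seg_by_iv: dict[tuple[str, int, int], list[ChromHMMSegment]] = {}
    for s in segments:
        seg_by_iv.setdefault((s.interval.chrom, s.interval.start, s.interval.end), []).append(s)
    out: dict[str, list[ChromHMMSegment]] = {}
    for gid, aps in assignment.items():
        for ap in aps:
            iv = ap.peak.interval
            seg = seg_by_iv[(iv.chrom, iv.start, iv.end)]
            out.setdefault(gid, []).extend(seg)
    return out


def chromhmm_filter(
    assignment: GenePeakAssignment,
    segments_by_gene: Mapping[str, Sequence[ChromHMMSegment]],
) -> GenePeakAssignment:
    """Keep only assigned peaks overlapping (>=1 bp) a segment of the same gene.

    A gene with no assigned segments keeps no peaks.  Never adds peaks.
    """
    out = GenePeakAssignment()
    for gid, aps in assignment.items():
        segs = segments_by_gene.get(gid, ())
        if not segs:
            continue
        tree = IntervalTree()
        for s in segs:
            tree.addi(s.interval.start, s.interval.end, s)
        kept = [
            ap
            for ap in aps
            if ap.peak.interval.chrom == segs[0].interval.chrom
            and tree.overlaps(ap.peak.interval.start, ap.peak.interval.end)
        ]
        if kept:
            out[gid] = kept
    return out


def loop_linkage(
    genes: Sequence[Gene],
    loops: Sequence[ChromatinLoop],
    search_window_r: int,
    anchor_padding: int = 0,
) -> dict[str, list[GenomicInterval]]:
    """Collect distal windows per gene from chromatin loops.

    A loop is associated with a gene if either anchor overlaps the promoter
    search window of size ``search_window_r`` centred on the most-5' TSS;
    the *other* anchor (optionally padded) then becomes a distal window.
    If both anchors fall in the search window, both are recorded; the
    promoter-priority rule downstream prevents double counting of peaks.
    Identical windows arising from several loops are deduplicated.
    """
    if search_window_r <= 0:
        raise ValueError("search_window_r must be positive")
    windows: dict[str, list[GenomicInterval]] = {}
    seen: dict[str, set[tuple[str, int, int]]] = {}
    trees = _interval_trees((promoter_window(g, search_window_r), g) for g in genes)
    for loop in loops:
        tree = trees.get(loop.chrom)
        if tree is None:
            continue
        for near, far in ((loop.anchor1, loop.anchor2), (loop.anchor2, loop.anchor1)):
            for hit in tree.overlap(near.start, near.end):
                gene: Gene = hit.data
                v = GenomicInterval(
                    far.chrom, max(0, far.start - anchor_padding), far.end + anchor_padding
                )
                key = (v.chrom, v.start, v.end)
                if key not in seen.setdefault(gene.gene_id, set()):
                    seen[gene.gene_id].add(key)
                    windows.setdefault(gene.gene_id, []).append(v)
    return windows


def distal_peak_assignment(
    gene: Gene,
    loop_windows: Sequence[GenomicInterval],
    peaks: Sequence[Peak],
    promoter_peaks: Iterable[Peak],
) -> list[AssignedPeak]:
    """Peaks overlapping any distal window, minus the gene's promoter peaks.

    A peak overlapping several distal windows of the gene is counted once;
    a peak that also overlaps the promoter window is kept on the promoter
    side only (it never reaches the distal feature set).
    """
    if not loop_windows:
        return []
    tree = IntervalTree()
    for v in loop_windows:
        tree.addi(v.start, v.end, v)
    promoter_keys = {
        (p.interval.chrom, p.interval.start, p.interval.end) for p in promoter_peaks
    }
    tss = gene.tss
    out: list[AssignedPeak] = []
    seen: set[tuple[str, int, int]] = set()
    for peak in peaks:
        iv = peak.interval
        if iv.chrom != loop_windows[0].chrom:
            continue
        key = (iv.chrom, iv.start, iv.end)
        if key in seen or key in promoter_keys:
            continue
        if tree.overlaps(iv.start, iv.end):
            seen.add(key)
            out.append(AssignedPeak(peak, "loop", abs(peak.center - tss)))
    return out


def distal_segment_assignment(
    loop_windows: Sequence[GenomicInterval], segments: Sequence[ChromHMMSegment]
) -> list[ChromHMMSegment]:
    """Segments overlapping any distal window of a gene (for the distal
    chromatin-state filter)."""
    if not loop_windows:
        return []
    tree = IntervalTree()
    for v in loop_windows:
        tree.addi(v.start, v.end, v)
    return [
        s
        for s in segments
        if s.interval.chrom == loop_windows[0].chrom
        and tree.overlaps(s.interval.start, s.interval.end)
    ]
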