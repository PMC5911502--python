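"""Read-depth pileup and coverage-based repeat detection.

Repeat-rich draft genomes collapse multi-copy segments into single
assembly copies, so the reads of all copies pile onto one locus and its
depth rises in proportion to the copy number. A segment is called a
repeat when it is longer than ``min_length`` bases (strictly) and its
per-base depth is at least ``fold_threshold`` times the median depth of
its contig; the copy number is estimated as the interval's mean depth
divided by that median, rounded, and floored at 2.

Defaults (min_length=20, fold_threshold=1.6) are the thresholds used for
Holospora assemblies; the median is per-contig by default with an
assembly-wide option. No gap bridging is performed between
above-threshold runs, so a long repeat crossing a low-coverage dip is
reported as two intervals — a deliberately conservative choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pysam

from .synthetic import ReadPlacement

__all__ = [
    "CoverageTrack",
    "RepeatInterval",
    "RepeatSummary",
    "pileup_depth",
    "pileup_from_sam",
    "call_repeats",
    "call_repeats_all",
    "summarize_repeats",
    "write_bed",
]


@dataclass
class CoverageTrack:
    """Per-base read depth along one contig (0-based)."""

    contig_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def contig_length(self) -> int:
        return len(self.depth)

    def median(self) -> float:
        return float(np.median(self.depth))


@dataclass(frozen=True)
class RepeatInterval:
    """A called duplicated segment, 0-based half-open."""

    contig_id: str
    start: int
    end: int
    mean_depth: float
    copy_number_estimate: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatSummary:
    n_repeats: int
    total_repeat_bp: int
    assembly_length: int
    repeat_fraction: float
    copy_number_histogram: dict[int, int]
    length_distribution: tuple[int, ...]


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------


def pileup_depth(
    placements: list[ReadPlacement], contigs: dict[str, int]
) -> list[CoverageTrack]:
    """Per-base depth from read placements via a difference array.

    ``depth[i]`` counts the placements covering position *i*. Every
    placement must reference a known contig and lie within its bounds.
    """
    diff = {c: np.zeros(length + 1, dtype=np.int64) for c, length in contigs.items()}
    for p in placements:
        if p.contig_id not in diff:
            raise ValueError(f"read {p.read_id}: unknown contig {p.contig_id!r}")
        if p.start < 0 or p.start + p.length > contigs[p.contig_id]:
            raise ValueError(
                f"read {p.read_id}: placement [{p.start}, {p.start + p.length}) "
                f"outside contig {p.contig_id} of length {contigs[p.contig_id]}"
            )
        diff[p.contig_id][p.start] += 1
        diff[p.contig_id][p.start + p.length] -= 1
    return [
        CoverageTrack(c, np.cumsum(diff[c][:-1])) for c in sorted(contigs)
    ]


def pileup_from_sam(sam_path) -> list[CoverageTrack]:
    """Per-base depth from a SAM file; only primary alignments counted.

    Soft-clipped bases and insertions do not contribute; aligned (M) blocks
    do. Deleted reference positions inside a read are not counted as
    covered.
    """
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=True) as sam:
        lengths = dict(zip(sam.references, sam.lengths))
        diff = {c: np.zeros(n + 1, dtype=np.int64) for c, n in lengths.items()}
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            contig = aln.reference_name
            for start, end in aln.get_blocks():
                if start < 0 or end > lengths[contig]:
                    raise ValueError(
                        f"read {aln.query_name}: alignment outside contig {contig}"
                    )
                diff[contig][start] += 1
                diff[contig][end] -= 1
    return [CoverageTrack(c, np.cumsum(diff[c][:-1])) for c in sorted(lengths)]


# ---------------------------------------------------------------------------
# repeat calling
# ---------------------------------------------------------------------------


def call_repeats(
    track: CoverageTrack,
    min_length: int = 20,
    fold_threshold: float = 1.6,
    median: float | None = None,
    copy_quantile: float = 0.75,
) -> list[RepeatInterval]:
    """Call repeats as maximal above-threshold runs longer than min_length.

    A position qualifies when ``depth >= fold_threshold * median`` (the
    boundary is inclusive); a run is kept only when strictly longer than
    ``min_length`` bases. ``median`` defaults to the track's own per-base
    median; pass the assembly-wide median for assembly-scope thresholds.

    Copy number per interval = round(Q(depth, copy_quantile) / median),
    floored at 2. The upper-quartile depth sits on the interval's
    coverage plateau, so the estimate is robust to the read-length-wide
    ramps at interval edges that bias a plain mean downward; on
    constant-depth runs it coincides with the mean. Returns intervals
    sorted by start; they are disjoint by construction.
    """
    if track.contig_length == 0:
        raise ValueError("empty coverage track")
    med = track.median() if median is None else float(median)
    if med <= 0:
        warnings.warn(
            f"{track.contig_id}: median coverage is zero, no repeats callable",
            stacklevel=2,
        )
        return []
    above = track.depth >= fold_threshold * med
    intervals: list[RepeatInterval] = []
    # run boundaries from the padded diff of the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start <= min_length:  # "longer than" is strict
            continue
        run = track.depth[start:end]
        mean_depth = float(run.mean())
        cn = max(2, int(round(float(np.quantile(run, copy_quantile)) / med)))
        intervals.append(
            RepeatInterval(track.contig_id, int(start), int(end), mean_depth, cn)
        )
    return intervals


def call_repeats_all(
    tracks: list[CoverageTrack],
    min_length: int = 20,
    fold_threshold: float = 1.6,
    median_scope: str = "contig",
    refine_baseline: bool = True,
) -> list[RepeatInterval]:
    """Call repeats on every track, per-contig or assembly-wide median.

    With ``refine_baseline`` (default) a second pass recomputes the median
    over positions *outside* the first-pass calls and re-calls against it.
    In a repeat-rich genome the raw per-base median is inflated by the
    elevated repeat coverage itself, which both raises the calling
    threshold and biases copy-number estimates low; the refined median
    estimates the single-copy baseline. On repeat-poor tracks the two
    passes coincide.
    """
    if median_scope not in ("contig", "assembly"):
        raise ValueError("median_scope must be 'contig' or 'assembly'")

    def _median(depths: list[np.ndarray]) -> float:
        return float(np.median(np.concatenate(depths)))

    def _uncalled(track: CoverageTrack, intervals: list[RepeatInterval]) -> np.ndarray:
        mask = np.ones(track.contig_length, dtype=bool)
        for iv in intervals:
            mask[iv.start : iv.end] = False
        kept = track.depth[mask]
        return kept if kept.size else track.depth

    shared = (
        _median([t.depth for t in tracks]) if median_scope == "assembly" else None
    )
    first = {
        t.contig_id: call_repeats(t, min_length, fold_threshold, median=shared)
        for t in tracks
    }
    if not refine_baseline:
        return [iv for t in tracks for iv in first[t.contig_id]]

    if median_scope == "assembly":
        refined = _median([_uncalled(t, first[t.contig_id]) for t in tracks])
        medians = {t.contig_id: refined for t in tracks}
    else:
        medians = {
            t.contig_id: float(np.median(_uncalled(t, first[t.contig_id])))
            for t in tracks
        }
    out: list[RepeatInterval] = []
    for track in tracks:
        out.extend(
            call_repeats(
                track, min_length, fold_threshold, median=medians[track.contig_id]
            )
        )
    return out


def summarize_repeats(
    intervals: list[RepeatInterval], assembly_length: int
) -> RepeatSummary:
    """Genome-wide repeat summary: count, total bp, fraction, histograms."""
    if assembly_length <= 0:
        raise ValueError("assembly_length must be positive")
    total = sum(iv.length for iv in intervals)
    hist: dict[int, int] = {}
    for iv in intervals:
        hist[iv.copy_number_estimate] = hist.get(iv.copy_number_estimate, 0) + 1
    return RepeatSummary(
        n_repeats=len(intervals),
        total_repeat_bp=total,
        assembly_length=assembly_length,
        repeat_fraction=total / assembly_length,
        copy_number_histogram=hist,
        length_distribution=tuple(iv.length for iv in intervals),
    )


def write_bed(intervals: list[RepeatInterval], path) -> None:
    """BED6: name = interval id, score = copy-number estimate."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals, 1):
            fh.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\trepeat{i}\t"
                f"{iv.copy_number_estimate}\t+\n"
            )
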