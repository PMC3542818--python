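"""Decorrelated nucleosome calls from the triangle-statistic track.

The binary N-statistic keeps a window only if its triangle statistic is a
strict maximum over the 25 windows to its left, a (tie-tolerant) maximum
over the 26 windows to its right, reaches the cutoff t_c, and no comparable
clump of high statistics sits one nucleosome-width away on either side
(the two "insurance" sums).  At most one window fires per 51-window span,
with ties broken leftmost.

Chunked scanning splits each chromosome into overlapping intervals whose
non-overlapping cores tile it; flanks are wide enough that every decision
about a core window is computable locally, so parallel chunk execution
reproduces a serial whole-chromosome run.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from nucleoscan.center_model import (
    OFFSET_MAX,
    OffsetDistribution,
    _landscape_span,
)
from nucleoscan.formats_io import (
    FORWARD,
    CandidateNucleosome,
    GenomeTable,
    ReadAlignment,
)
from nucleoscan.triangle import TriangleTrack, WindowPartition, scan_triangle

logger = logging.getLogger(__name__)

# Neighborhood geometry of the N-statistic (window-index offsets).
_LEFT_SPAN = 25          # strict-maximum span to the left
_RIGHT_SPAN = 26         # tie-tolerant span to the right
_INS_OFFSETS_RIGHT = range(69, 79)   # i+68+j, j = 1..10
_INS_OFFSETS_LEFT = range(-77, -67)  # i-78+j, j = 1..10
_INS_THRESHOLD = 10.0

#: Interval flank beyond each core, in bp.  A core decision at window start
#: i needs t at window starts i-77 .. i+78, and each of those needs W bins
#: of landscape; W + 103 covers both with margin.
def _flank(partition: WindowPartition) -> int:
    return partition.W + 103


@dataclass
class NStatTrack:
    """Binary track aligned with a TriangleTrack's window starts."""

    chrom: str
    n_values: np.ndarray


@dataclass(frozen=True)
class Chunk:
    """One scanning interval and the core region it is responsible for."""

    chrom: str
    start: int
    end: int
    core_start: int
    core_end: int


@dataclass
class ChunkPlan:
    """Per-chromosome intervals whose cores tile the genome."""

    chunks: list[Chunk]

    def for_chrom(self, chrom: str) -> list[Chunk]:
        return [c for c in self.chunks if c.chrom == chrom]


def n_statistic(track: TriangleTrack, t_c: float) -> NStatTrack:
    """Evaluate the N-statistic at every window of a triangle track.

    Out-of-range neighborhood terms are neutral (treated as t = 0), so
    windows near chromosome ends remain callable.  Requires ``t_c > 0``.
    """
    if t_c <= 0:
        raise ValueError("t_c must be positive")
    t = track.t_values
    n = np.zeros(len(t), dtype=np.uint8)
    if len(t) == 0:
        return NStatTrack(chrom=track.chrom, n_values=n)
    # Cheap prefilter: only windows reaching t_c can fire.
    for i in np.nonzero(t >= t_c)[0]:
        ti = t[i]
        left = t[max(0, i - _LEFT_SPAN) : i]
        if left.size and left.max() >= ti:
            continue
        right = t[i + 1 : i + 1 + _RIGHT_SPAN]
        if right.size and right.max() > ti:
            continue
        lo = max(0, i + _INS_OFFSETS_RIGHT.start)
        if t[lo : i + _INS_OFFSETS_RIGHT.stop].sum() > _INS_THRESHOLD:
            continue
        lo = max(0, i + _INS_OFFSETS_LEFT.start)
        hi = max(0, i + _INS_OFFSETS_LEFT.stop)
        if t[lo:hi].sum() > _INS_THRESHOLD:
            continue
        n[i] = 1
    return NStatTrack(chrom=track.chrom, n_values=n)


def candidates(
    track: TriangleTrack,
    nstat: NStatTrack,
    partition: WindowPartition | None = None,
) -> list[CandidateNucleosome]:
    """Emit one candidate per non-zero N at the window's center coordinate."""
    partition = partition or WindowPartition()
    if len(track.t_values) != len(nstat.n_values):
        raise ValueError("triangle and N tracks are not aligned")
    half = partition.W // 2
    out = []
    for i in np.nonzero(nstat.n_values)[0]:
        out.append(
            CandidateNucleosome(
                chrom=track.chrom,
                center=int(track.start_offset + i + half),
                t_stat=float(track.t_values[i]),
            )
        )
    return out


def plan_chunks(
    genome: GenomeTable,
    partition: WindowPartition | None = None,
    target_interval: int = 1_000_000,
) -> ChunkPlan:
    """Split every chromosome into flanked intervals with tiling cores."""
    partition = partition or WindowPartition()
    if target_interval < 10 * partition.W:
        raise ValueError(
            f"target_interval must be >= 10*W = {10 * partition.W}"
        )
    flank = _flank(partition)
    chunks: list[Chunk] = []
    for chrom, length in genome.items():
        n_cores = max(1, -(-length // target_interval))
        bounds = np.linspace(0, length, n_cores + 1).astype(int)
        for k in range(n_cores):
            core_start = int(bounds[k]) + 1
            core_end = int(bounds[k + 1])
            chunks.append(
                Chunk(
                    chrom=chrom,
                    start=max(1, core_start - flank),
                    end=min(length, core_end + flank),
                    core_start=core_start,
                    core_end=core_end,
                )
            )
    return ChunkPlan(chunks=chunks)


def detect_chromosome(
    reads: Iterable[ReadAlignment],
    chrom: str,
    chrom_length: int,
    pmf: OffsetDistribution,
    partition: WindowPartition | None = None,
    t_c: float = 1.7,
) -> list[CandidateNucleosome]:
    """Serial whole-chromosome run: landscape -> triangle -> N -> candidates."""
    partition = partition or WindowPartition()
    landscape = _landscape_span(reads, 1, chrom_length, pmf, chrom=chrom)
    track = scan_triangle(landscape, partition)
    nstat = n_statistic(track, t_c)
    return candidates(track, nstat, partition)


def _detect_chunk(
    chunk: Chunk,
    reads: Sequence[ReadAlignment],
    pmf: OffsetDistribution,
    partition: WindowPartition,
    t_c: float,
) -> list[CandidateNucleosome]:
    """Run the pipeline on one interval, keeping candidates in its core.

    ``reads`` must already be restricted to the chunk's chromosome but may
    cover the whole chromosome; reads whose offset footprint cannot touch
    the interval are filtered here, preserving input order so per-position
    float accumulation matches the serial run bit for bit.
    """
    lo, hi = chunk.start - OFFSET_MAX, chunk.end + OFFSET_MAX
    local = [r for r in reads if lo <= r.pos5 <= hi]
    landscape = _landscape_span(local, chunk.start, chunk.end, pmf, chrom=chunk.chrom)
    track = scan_triangle(landscape, partition)
    nstat = n_statistic(track, t_c)
    return [
        c
        for c in candidates(track, nstat, partition)
        if chunk.core_start <= c.center <= chunk.core_end
    ]


def detect_genome(
    reads_by_chrom: dict[str, list[ReadAlignment]],
    genome: GenomeTable,
    pmf: OffsetDistribution,
    partition: WindowPartition | None = None,
    t_c: float = 1.7,
    threads: int = 1,
    target_interval: int = 1_000_000,
    plan: ChunkPlan | None = None,
) -> list[CandidateNucleosome]:
    """Chunked, optionally parallel detection across a genome.

    Workers are pure functions over chunks; results are concatenated in
    chunk order, so the output is independent of ``threads``.
    """
    partition = partition or WindowPartition()
    if plan is None:
        plan = plan_chunks(genome, partition, target_interval)
    jobs = [c for c in plan.chunks if reads_by_chrom.get(c.chrom)]

    def work(chunk: Chunk) -> list[CandidateNucleosome]:
        return _detect_chunk(
            chunk, reads_by_chrom[chunk.chrom], pmf, partition, t_c
        )

    if threads <= 1:
        results = [work(c) for c in jobs]
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(work, jobs))
    out: list[CandidateNucleosome] = []
    for r in results:
        out.extend(r)
    return out


def group_reads(
    reads: Iterable[ReadAlignment],
) -> dict[str, list[ReadAlignment]]:
    """Bucket a read stream by chromosome, preserving input order."""
    by_chrom: dict[str, list[ReadAlignment]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    return by_chrom
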