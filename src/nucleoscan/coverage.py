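"""Display-oriented nucleosome coverage and raw read-position histograms.

A forward read is extended 75 bp rightward from its 5' end and shifted
+37 bp; a reverse read is extended 75 bp leftward and shifted -37 bp.  Both
footprints then straddle the nucleosome center, so stacked counts peak at
positioned nucleosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from nucleoscan.formats_io import FORWARD, ReadAlignment

#: Footprint length a read is extended to, and the recentering shift.
EXTENSION = 75
SHIFT = 37


@dataclass
class CoverageTrack:
    chrom: str
    counts: np.ndarray  # one non-negative integer per bp, index 0 = coord 1


def coverage_track(
    reads: Iterable[ReadAlignment], chrom_length: int, chrom: str | None = None
) -> CoverageTrack:
    """Shifted-extended read coverage over one chromosome.

    A forward read at p covers [p+37, p+111]; a reverse read at p covers
    [p-111, p-37].  Positions outside [1, chrom_length] are dropped.
    """
    reads = list(reads)
    if chrom is None:
        chrom = reads[0].chrom if reads else ""
    counts = np.zeros(chrom_length, dtype=np.int64)
    # difference-array trick: +1 at span start, -1 past span end
    diff = np.zeros(chrom_length + 1, dtype=np.int64)
    for r in reads:
        if r.chrom != chrom:
            raise ValueError("reads span multiple chromosomes")
        if r.strand == FORWARD:
            lo, hi = r.pos5 + SHIFT, r.pos5 + SHIFT + EXTENSION - 1
        else:
            lo, hi = r.pos5 - SHIFT - EXTENSION + 1, r.pos5 - SHIFT
        lo = max(lo, 1)
        hi = min(hi, chrom_length)
        if lo > hi:
            continue
        diff[lo - 1] += 1
        diff[hi] -= 1
    counts = np.cumsum(diff[:-1])
    return CoverageTrack(chrom=chrom, counts=counts)


def strand_histograms(
    reads: Iterable[ReadAlignment], start: int, stop: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bp counts of read 5' ends on each strand over [start, stop]."""
    if start > stop:
        raise ValueError(f"empty range [{start}, {stop}]")
    n = stop - start + 1
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for r in reads:
        if start <= r.pos5 <= stop:
            (fwd if r.strand == FORWARD else rev)[r.pos5 - start] += 1
    return fwd, rev


def write_bedgraph(track: CoverageTrack, out_path: str | Path) -> Path:
    """Export a coverage track as BedGraph (0-based half-open runs)."""
    out_path = Path(out_path)
    counts = track.counts
    with open(out_path, "wt", encoding="utf-8") as fh:
        if len(counts):
            # run-length encode
            change = np.nonzero(np.diff(counts))[0]
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [len(counts)]])
            for s, e in zip(starts, ends):
                v = counts[s]
                if v != 0:
                    fh.write(f"{track.chrom}\t{s}\t{e}\t{v}\n")
    return out_path


def plot_region(
    reads: Sequence[ReadAlignment],
    track: CoverageTrack,
    centers: Sequence[int],
    start: int,
    stop: int,
    out_path: str | Path,
) -> Path:
    """Render the read-position histogram and coverage/centers overlay.

    Thin optional layer over matplotlib; the arrays above are the tested
    surface.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fwd, rev = strand_histograms(reads, start, stop)
    coords = np.arange(start, stop + 1)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    ax1.bar(coords, fwd, width=1, color="blue", label="forward 5' ends")
    ax1.bar(coords, -rev, width=1, color="red", label="reverse 5' ends")
    ax1.set_ylabel("read count")
    ax1.legend(loc="upper right", fontsize=8)
    cov = track.counts[start - 1 : stop]
    ax2.fill_between(coords[: len(cov)], cov, color="0.6")
    for c in centers:
        if start <= c <= stop:
            ax2.axvline(c, color="red", lw=1)
    ax2.set_xlabel(f"{track.chrom} position (bp)")
    ax2.set_ylabel("coverage")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return Path(out_path)
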