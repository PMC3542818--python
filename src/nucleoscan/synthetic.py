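"""Ground-truthed alignment fixtures: planted nucleosomes plus background.

A positioned nucleosome at center c yields forward-strand 5' ends near
c - 73 and reverse-strand 5' ends near c + 73.  Jitter is Gaussian-rounded
(deliberately not beta-distributed, so the generator stays independent of
the offset model under test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from nucleoscan.formats_io import (
    FORWARD,
    REVERSE,
    GenomeTable,
    ReadAlignment,
)

#: Half a nucleosome footprint: distance from a flanking read 5' end to the
#: nucleosome center.
HALF_FOOTPRINT = 73

#: Length of the alignments written by :func:`write_fixture`.
READ_LENGTH = 50

_EDGE_MARGIN = 112  # keeps a planted cluster's reads comfortably in-bounds


@dataclass
class SimSpec:
    """Parameters of one synthetic chromosome."""

    chrom_length: int
    centers: Sequence[int]
    reads_per_side: int = 50
    jitter_sd: float = 5.0
    background_rate: float = 0.0
    seed: int = 0
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        if self.chrom_length < 1:
            raise ValueError("chrom_length must be positive")
        if self.reads_per_side < 0:
            raise ValueError("reads_per_side must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for c in self.centers:
            if not _EDGE_MARGIN <= c <= self.chrom_length - _EDGE_MARGIN:
                raise ValueError(
                    f"center {c} closer than {_EDGE_MARGIN} bp to a "
                    "chromosome end"
                )


def simulate_reads(spec: SimSpec) -> tuple[list[ReadAlignment], list[int]]:
    """Generate reads for a SimSpec; returns (reads, true center list).

    Per center: ``reads_per_side`` forward reads at
    ``c - 73 + round(N(0, jitter_sd))`` and as many reverse reads at
    ``c + 73 + round(N(0, jitter_sd))``.  Background reads are Poisson in
    number (rate * length), uniform in position, random in strand.
    """
    rng = np.random.default_rng(spec.seed)
    reads: list[ReadAlignment] = []
    clamp = lambda p: min(max(int(p), 1), spec.chrom_length)
    for c in spec.centers:
        jit = np.rint(
            rng.normal(0.0, spec.jitter_sd, size=spec.reads_per_side)
        ).astype(int)
        for dx in jit:
            reads.append(
                ReadAlignment(spec.chrom, clamp(c - HALF_FOOTPRINT + dx), FORWARD)
            )
        jit = np.rint(
            rng.normal(0.0, spec.jitter_sd, size=spec.reads_per_side)
        ).astype(int)
        for dx in jit:
            reads.append(
                ReadAlignment(spec.chrom, clamp(c + HALF_FOOTPRINT + dx), REVERSE)
            )
    n_bg = rng.poisson(spec.background_rate * spec.chrom_length)
    if n_bg:
        pos = rng.integers(1, spec.chrom_length + 1, size=n_bg)
        strands = rng.integers(0, 2, size=n_bg)
        for p, s in zip(pos, strands):
            reads.append(
                ReadAlignment(spec.chrom, int(p), FORWARD if s else REVERSE)
            )
    return reads, list(spec.centers)


def genome_for(spec: SimSpec) -> GenomeTable:
    """Single-chromosome genome table matching a SimSpec."""
    return GenomeTable([(spec.chrom, spec.chrom_length)])


def write_fixture(
    reads: Sequence[ReadAlignment],
    format: str,
    path: str | Path,
    genome: GenomeTable,
) -> Path:
    """Write reads as a standard-conformant BED6 or headered SAM file.

    Each read becomes a 50 bp alignment; re-reading the file through
    ``formats_io.read_alignments`` recovers (chrom, pos5, strand) exactly.
    Reads whose 50 bp footprint would overhang the chromosome are clipped
    in length (never in 5'-end position).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "bed":
        with open(path, "wt", encoding="utf-8") as fh:
            for i, r in enumerate(reads):
                if r.strand == FORWARD:
                    start = r.pos5 - 1
                    end = min(r.pos5 - 1 + READ_LENGTH, genome[r.chrom])
                else:
                    start = max(r.pos5 - READ_LENGTH, 0)
                    end = r.pos5
                fh.write(
                    f"{r.chrom}\t{start}\t{end}\tr{i}\t0\t{r.strand}\n"
                )
    elif fmt == "sam":
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            for name, length in genome.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
            for i, r in enumerate(reads):
                if r.strand == FORWARD:
                    flag = 0
                    pos = r.pos5
                    seg = min(READ_LENGTH, genome[r.chrom] - r.pos5 + 1)
                else:
                    flag = 16
                    pos = max(r.pos5 - READ_LENGTH + 1, 1)
                    seg = r.pos5 - pos + 1
                fh.write(
                    f"r{i}\t{flag}\t{r.chrom}\t{pos}\t60\t{seg}M\t*\t0\t0"
                    f"\t{'N' * seg}\t*\n"
                )
    else:
        raise ValueError(f"unknown fixture format {format!r}")
    return path


def write_truth_bed(
    centers: Sequence[int], chrom: str, path: str | Path
) -> Path:
    """Write true center coordinates as a BED file for scoring."""
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        for i, c in enumerate(centers):
            fh.write(f"{chrom}\t{c - 1}\t{c}\ttrue_center_{i}\t0\t+\n")
    return path


def match_centers(
    called: Sequence[int], truth: Sequence[int], tolerance: int = 5
) -> tuple[int, int]:
    """Greedy one-to-one matching of called to true centers.

    Returns (number of matched true centers, number of spurious calls).
    """
    truth_left = sorted(truth)
    matched = 0
    spurious = 0
    for c in sorted(called):
        hit = None
        for t in truth_left:
            if abs(c - t) <= tolerance:
                hit = t
                break
            if t > c + tolerance:
                break
        if hit is None:
            spurious += 1
        else:
            truth_left.remove(hit)
            matched += 1
    return matched, spurious
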