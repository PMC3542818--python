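"""Alignment / genome-table input and TXT / WIG output.

Coordinates are 1-based inclusive everywhere inside the package.  BED input
(0-based, half-open) is converted on read.  A read is reduced to the triple
(chromosome, 5'-end coordinate, strand); the 5' end of a reverse-strand
alignment is its rightmost aligned reference base.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"

#: Assemblies whose chromosome-length tables ship with the package.
GENOME_PRESETS = ("ce10", "mm9", "mm10", "hg18", "hg19")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """One aligned single-end read reduced to its 5'-end position.

    ``pos5`` is 1-based; for a reverse-strand read it is the rightmost
    aligned reference coordinate (the biological 5' end of the read).
    """

    chrom: str
    pos5: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pos5 < 1:
            raise ValueError(f"pos5 must be >= 1, got {self.pos5}")


class GenomeTable:
    """Ordered map from reference-sequence name to chromosome length (bp)."""

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self._lengths: dict[str, int] = {}
        for name, length in entries:
            if name in self._lengths:
                raise FormatError(f"duplicate reference name {name!r}")
            length = int(length)
            if length <= 0:
                raise FormatError(f"non-positive length {length} for {name!r}")
            self._lengths[name] = length

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __len__(self) -> int:
        return len(self._lengths)

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(self._lengths.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeTable):
            return NotImplemented
        return self._lengths == other._lengths

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GenomeTable({len(self)} references)"


@dataclass
class CandidateNucleosome:
    """A scan-window center nominated by the N-statistic.

    ``fdr`` is ``None`` until FDR estimation has run; on output it is
    clamped to [0, 1].
    """

    chrom: str
    center: int
    t_stat: float
    fdr: float | None = None


def load_chrom_lengths(path: str | Path) -> GenomeTable:
    """Parse a two-column tab-separated chromosome-length file.

    The length column must be plain digits (no thousands separators).
    Duplicate names and malformed lines are fatal.
    """
    path = Path(path)
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            name, length_s = fields[0].strip(), fields[1].strip()
            if not name:
                raise FormatError(f"{path}:{lineno}: empty reference name")
            if not length_s.isdigit():
                raise FormatError(
                    f"{path}:{lineno}: length {length_s!r} is not a plain "
                    "integer (no thousands separators allowed)"
                )
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate name {name!r}")
            seen.add(name)
            entries.append((name, int(length_s)))
    if not entries:
        raise FormatError(f"{path}: empty chromosome-length file")
    return GenomeTable(entries)


def load_genome_preset(name: str) -> GenomeTable:
    """Load a packaged chromosome-length table (ce10/mm9/mm10/hg18/hg19)."""
    if name not in GENOME_PRESETS:
        raise ValueError(
            f"unknown genome preset {name!r}; available: {GENOME_PRESETS}"
        )
    ref = resources.files("nucleoscan") / "data" / f"{name}.tsv"
    with resources.as_file(ref) as p:
        return load_chrom_lengths(p)


def _iter_sam_bam(
    path: Path, mode: str, genome: GenomeTable, min_mapq: int
) -> Iterator[ReadAlignment]:
    warned: set[str] = set()
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            chrom = rec.reference_name
            if chrom not in genome:
                if chrom not in warned:
                    logger.warning(
                        "skipping reads on unknown reference %r", chrom
                    )
                    warned.add(chrom)
                continue
            if rec.is_reverse:
                # reference_end is 0-based exclusive == 1-based rightmost base
                yield ReadAlignment(chrom, rec.reference_end, REVERSE)
            else:
                yield ReadAlignment(chrom, rec.reference_start + 1, FORWARD)


def _iter_bed(path: Path, genome: GenomeTable) -> Iterator[ReadAlignment]:
    warned: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: BED line has {len(fields)} columns; "
                    "6 required (strand in column 6)"
                )
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            if chrom not in genome:
                if chrom not in warned:
                    logger.warning(
                        "skipping reads on unknown reference %r", chrom
                    )
                    warned.add(chrom)
                continue
            try:
                start = int(start_s)
                end = int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from exc
            if strand == FORWARD:
                yield ReadAlignment(chrom, start + 1, FORWARD)
            elif strand == REVERSE:
                yield ReadAlignment(chrom, end, REVERSE)
            else:
                raise FormatError(
                    f"{path}:{lineno}: invalid strand {strand!r}"
                )


def read_alignments(
    path: str | Path,
    format: str,
    genome: GenomeTable,
    min_mapq: int = 0,
) -> Iterator[ReadAlignment]:
    """Stream ``ReadAlignment`` triples from a BAM, SAM or BED file.

    Unmapped, secondary and supplementary SAM/BAM records are skipped, as
    are records below ``min_mapq`` (BED records are never MAPQ-filtered).
    Reads on references absent from ``genome`` are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"alignment file not found: {path}")
    fmt = format.lower()
    if fmt == "bam":
        yield from _iter_sam_bam(path, "rb", genome, min_mapq)
    elif fmt == "sam":
        yield from _iter_sam_bam(path, "r", genome, min_mapq)
    elif fmt == "bed":
        yield from _iter_bed(path, genome)
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def guess_format(path: str | Path) -> str:
    """Infer the alignment format from a filename suffix."""
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("bam", "sam", "bed"):
        return suffix
    raise ValueError(f"cannot infer alignment format from {path!r}")


def _ordered(
    candidates: Sequence[CandidateNucleosome],
    chrom_order: Sequence[str] | None,
) -> list[CandidateNucleosome]:
    if chrom_order is None:
        order: dict[str, int] = {}
        for c in candidates:
            order.setdefault(c.chrom, len(order))
    else:
        order = {name: i for i, name in enumerate(chrom_order)}
    return sorted(candidates, key=lambda c: (order[c.chrom], c.center))


def _fmt_fdr(fdr: float | None) -> str:
    if fdr is None:
        return "NA"
    return format(min(max(fdr, 0.0), 1.0), ".6g")


def write_centers_txt(
    candidates: Sequence[CandidateNucleosome],
    out_path: str | Path,
    chrom_order: Sequence[str] | None = None,
) -> Path:
    """Write the tab-separated centers table (chrom, center, t, FDR)."""
    out_path = Path(out_path)
    rows = _ordered(candidates, chrom_order)
    with open(out_path, "wt", encoding="utf-8") as fh:
        fh.write("chrom\tcenter\tt_stat\tfdr\n")
        for c in rows:
            fh.write(
                f"{c.chrom}\t{c.center}\t{c.t_stat:.6g}\t{_fmt_fdr(c.fdr)}\n"
            )
    return out_path


def write_wig(
    candidates: Sequence[CandidateNucleosome],
    out_path: str | Path,
    chrom_order: Sequence[str] | None = None,
) -> Path:
    """Write a variableStep span=1 WIG of centers vs triangle statistics."""
    out_path = Path(out_path)
    rows = _ordered(candidates, chrom_order)
    with open(out_path, "wt", encoding="utf-8") as fh:
        current: str | None = None
        for c in rows:
            if c.chrom != current:
                fh.write(f"variableStep chrom={c.chrom} span=1\n")
                current = c.chrom
            fh.write(f"{c.center}\t{c.t_stat:.6g}\n")
    return out_path


def output_basename(
    alignment_path: str | Path, when: _dt.datetime | None = None
) -> str:
    """``[alignment filename]_[datestamp]_[timestamp]`` output-name stem."""
    when = when or _dt.datetime.now()
    name = Path(alignment_path).name
    return f"{name}_{when:%Y%m%d}_{when:%H%M%S}"
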