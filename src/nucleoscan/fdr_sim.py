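"""Monte Carlo FDR estimation by uniform read shaking.

Each simulation shifts every read position by an independent integer drawn
uniformly from {-73, ..., 73}, destroying the tight flanking clusters that
mark positioned nucleosomes while preserving coverage.  Candidates found in
shaken data estimate, per triangle-statistic threshold, how many real calls
could arise from delocalized nucleosomes alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from nucleoscan.center_model import beta_offset_pmf
from nucleoscan.config import SHAKE_HALF_RANGE, ScanConfig
from nucleoscan.detection import ChunkPlan, detect_genome, group_reads
from nucleoscan.formats_io import CandidateNucleosome, GenomeTable, ReadAlignment

logger = logging.getLogger(__name__)


@dataclass
class FdrTable:
    """Exceedance counts and FDR estimates for one candidate set.

    For candidate j: ``t[j]`` is its triangle statistic, ``M[j]`` the number
    of real candidates with statistic >= t[j], ``m[k, j]`` the analogous
    count in simulation k, and ``fdr[j] = mean_k m[k, j] / M[j]``.
    """

    S: int
    t: np.ndarray
    M: np.ndarray
    m: np.ndarray
    fdr: np.ndarray


def shake_reads(
    reads: Sequence[ReadAlignment],
    genome: GenomeTable,
    rng: np.random.Generator,
    half_range: int = SHAKE_HALF_RANGE,
) -> list[ReadAlignment]:
    """Shift every read by an independent uniform integer in [-h, h].

    Strand is unchanged; shifted positions are clamped into
    [1, chromosome length] so the read count is conserved.
    """
    shifts = rng.integers(-half_range, half_range + 1, size=len(reads))
    out = []
    for r, dx in zip(reads, shifts):
        pos = min(max(r.pos5 + int(dx), 1), genome[r.chrom])
        out.append(replace(r, pos5=pos))
    return out


def _exceedance(sorted_t: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Count of values >= each threshold, given ``sorted_t`` ascending."""
    return len(sorted_t) - np.searchsorted(sorted_t, thresholds, side="left")


def estimate_fdr(
    real_candidates: Sequence[CandidateNucleosome],
    reads_by_chrom: dict[str, list[ReadAlignment]],
    genome: GenomeTable,
    config: ScanConfig,
    seed: int | np.random.SeedSequence | None = None,
    plan: ChunkPlan | None = None,
) -> FdrTable:
    """Per-candidate FDR from ``config.S`` read-shaking simulations.

    Every simulation shakes the full read set and re-runs detection with
    the real-data configuration (same partition, t_c and chunk plan).
    Simulation k uses the k-th child of the seed sequence, so results do
    not depend on the worker count.
    """
    if config.S < 1:
        raise ValueError("number of simulations S must be >= 1")
    if seed is None:
        seed = config.seed
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(config.S)

    t_real = np.array([c.t_stat for c in real_candidates], dtype=float)
    sorted_real = np.sort(t_real)
    M = _exceedance(sorted_real, t_real)

    pmf = beta_offset_pmf(config.alpha, config.beta_param)
    m = np.zeros((config.S, len(t_real)), dtype=np.int64)
    for k in range(config.S):
        rng = np.random.default_rng(children[k])
        shaken: dict[str, list[ReadAlignment]] = {}
        for chrom in reads_by_chrom:
            shaken[chrom] = shake_reads(
                reads_by_chrom[chrom], genome, rng, config.shake_half_range
            )
        sim = detect_genome(
            shaken,
            genome,
            pmf,
            config.partition,
            t_c=config.t_c,
            threads=config.T,
            target_interval=config.chunk_interval,
            plan=plan,
        )
        sorted_sim = np.sort(np.array([c.t_stat for c in sim], dtype=float))
        m[k] = _exceedance(sorted_sim, t_real)
        logger.info("simulation %d/%d: %d candidates", k + 1, config.S, len(sim))

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(M > 0, m.mean(axis=0) / np.maximum(M, 1), 0.0)
    return FdrTable(S=config.S, t=t_real, M=M, m=m, fdr=fdr)


def filter_candidates(
    candidates: Sequence[CandidateNucleosome],
    fdr_table: FdrTable,
    F: float,
) -> list[CandidateNucleosome]:
    """Keep candidates with estimated FDR <= F, populating their FDR field."""
    if len(candidates) != len(fdr_table.fdr):
        raise ValueError("FDR table does not cover the candidate list")
    kept = []
    for c, fdr in zip(candidates, fdr_table.fdr):
        if fdr <= F:
            kept.append(replace(c, fdr=float(fdr)))
    return kept
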