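"""Read-to-center offset model and the nucleosome-center probability landscape.

Each read's 5' end sits roughly half a nucleosome (~73 bp) away from the
center it flanks.  The offset is modelled as a beta distribution rescaled
onto [68, 79) and discretized into eleven 1-bp bins {68..78}; summing every
read's discretized distribution along the genome yields a per-base relative
probability landscape of nucleosome centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special

from nucleoscan.config import DEFAULT_ALPHA, DEFAULT_BETA
from nucleoscan.formats_io import FORWARD, ReadAlignment

#: Inclusive support of the discretized read-to-center offset, in bp.
OFFSET_MIN = 68
OFFSET_MAX = 78
N_BINS = OFFSET_MAX - OFFSET_MIN + 1  # 11


@dataclass(frozen=True)
class OffsetDistribution:
    """Discretized beta pmf over read-to-center offsets {68..78}.

    ``probs[k]`` is P(offset == 68 + k); the eleven probabilities sum to 1.
    """

    alpha: float
    beta_param: float
    probs: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(OFFSET_MIN, OFFSET_MAX + 1)

    def __getitem__(self, offset: int) -> float:
        if not OFFSET_MIN <= offset <= OFFSET_MAX:
            raise IndexError(f"offset {offset} outside [{OFFSET_MIN}, {OFFSET_MAX}]")
        return float(self.probs[offset - OFFSET_MIN])


@dataclass
class Landscape:
    """Per-chromosome array of summed center probabilities.

    ``scores[k]`` holds the value at 1-based genomic coordinate
    ``start + k``; ``start`` is 1 for a whole-chromosome landscape.
    """

    chrom: str
    scores: np.ndarray
    start: int = 1

    @property
    def stop(self) -> int:
        """Last covered 1-based coordinate (inclusive)."""
        return self.start + len(self.scores) - 1


def beta_offset_pmf(
    alpha: float = DEFAULT_ALPHA, beta_param: float = DEFAULT_BETA
) -> OffsetDistribution:
    """Discretize Beta(alpha, beta) rescaled to [68, 79) into 11 bins.

    The bin mass is the integral of ``(t-68)^(a-1) (79-t)^(b-1)`` over
    ``[x, x+1]`` divided by ``B(a,b) * 11^(a+b-1)``.  Substituting
    ``u = (t-68)/11`` makes this exactly a difference of regularized
    incomplete beta values at the rescaled bin edges, so the pmf is exact
    (no quadrature) and sums to 1 by construction.
    """
    if alpha <= 0 or beta_param <= 0:
        raise ValueError(
            f"beta shapes must be positive, got ({alpha}, {beta_param})"
        )
    edges = np.arange(N_BINS + 1) / N_BINS
    cdf = special.betainc(alpha, beta_param, edges)
    probs = np.diff(cdf)
    return OffsetDistribution(alpha=alpha, beta_param=beta_param, probs=probs)


def build_landscape(
    reads: Iterable[ReadAlignment],
    chrom_length: int,
    pmf: OffsetDistribution,
    chrom: str | None = None,
) -> Landscape:
    """Sum every read's discretized center distribution along a chromosome.

    A forward read at ``y`` deposits ``pmf[x]`` at coordinate ``y + x`` for
    each offset x in {68..78}; a reverse read at ``y`` deposits at ``y - x``.
    Mass falling outside ``[1, chrom_length]`` is dropped; the read keeps
    its in-bounds bins.
    """
    return _landscape_span(reads, 1, chrom_length, pmf, chrom=chrom)


def _landscape_span(
    reads: Iterable[ReadAlignment],
    lo: int,
    hi: int,
    pmf: OffsetDistribution,
    chrom: str | None = None,
) -> Landscape:
    """Landscape restricted to the 1-based inclusive span ``[lo, hi]``.

    Deposits are clipped to the span; used both for whole chromosomes
    (``lo=1, hi=L``) and for chunked scanning intervals.
    """
    if hi < lo:
        raise ValueError(f"empty span [{lo}, {hi}]")
    reads = list(reads)
    if chrom is None:
        chrom = reads[0].chrom if reads else ""
    for r in reads:
        if r.chrom != chrom:
            raise ValueError(
                f"reads span multiple chromosomes: {chrom!r} vs {r.chrom!r}"
            )
    scores = np.zeros(hi - lo + 1)
    if not reads:
        return Landscape(chrom=chrom, scores=scores, start=lo)
    pos = np.fromiter((r.pos5 for r in reads), dtype=np.int64, count=len(reads))
    fwd = np.fromiter(
        (r.strand == FORWARD for r in reads), dtype=bool, count=len(reads)
    )
    sign = np.where(fwd, 1, -1)
    for k, x in enumerate(range(OFFSET_MIN, OFFSET_MAX + 1)):
        coord = pos + sign * x
        inb = (coord >= lo) & (coord <= hi)
        np.add.at(scores, coord[inb] - lo, pmf.probs[k])
    return Landscape(chrom=chrom, scores=scores, start=lo)


def fit_beta_shapes(
    half_distances: Sequence[float], min_count: int = 10
) -> tuple[float, float]:
    """Maximum-likelihood beta shapes from read-to-center half-distances.

    Values outside the open interval (68, 79) are discarded.  The MLE
    solves the pair of digamma equations

        mean(log((t-68)/11)) = psi(a) - psi(a+b)
        mean(log((79-t)/11)) = psi(b) - psi(a+b)

    numerically, started at (2, 2).

    Returns
    -------
    (alpha, beta_param) with residuals below 1e-8.
    """
    arr = np.asarray(half_distances, dtype=float)
    arr = arr[(arr > OFFSET_MIN) & (arr < OFFSET_MAX + 1)]
    if len(arr) < min_count:
        raise ValueError(
            f"need at least {min_count} half-distances strictly inside "
            f"({OFFSET_MIN}, {OFFSET_MAX + 1}); got {len(arr)}"
        )
    c1 = float(np.mean(np.log((arr - OFFSET_MIN) / N_BINS)))
    c2 = float(np.mean(np.log((OFFSET_MAX + 1 - arr) / N_BINS)))

    def equations(shapes: np.ndarray) -> list[float]:
        a, b = shapes
        if a <= 0 or b <= 0:  # steer the solver back into the domain
            return [1e6, 1e6]
        d = special.digamma(a + b)
        return [special.digamma(a) - d - c1, special.digamma(b) - d - c2]

    sol, info, ier, msg = optimize.fsolve(
        equations, x0=(2.0, 2.0), full_output=True
    )
    resid = np.abs(equations(sol))
    if ier != 1 or np.max(resid) >= 1e-8:
        raise RuntimeError(
            f"beta-shape solver failed (ier={ier}, residuals={resid}): {msg}"
        )
    return float(sol[0]), float(sol[1])
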